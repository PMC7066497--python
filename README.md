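# bgtcsim

A population-level (Wilson–Cowan) simulator of the combined
cerebellar–basal-ganglia–thalamocortical motor network, built to study how
this circuit supports oscillations in the frequency bands relevant to
movement disorders — tremor (~3–8 Hz), beta (13–30 Hz, associated with
Parkinsonian hypokinesia) and gamma (>30 Hz, treated as the pro-kinetic
"healthy" regime) — and how square-pulse deep brain stimulation (DBS)
reshapes them.  It is aimed at computational neuroscientists and DBS
researchers who want a small, fully reproducible network model for
exploring regime boundaries, stimulation targets and stimulation
parameters.

## Model

Seven neural populations — cortex (Cx), thalamic relay (Th), thalamic
reticular nucleus (nRT), deep cerebellar nuclei (DCN), external and
internal globus pallidus (GPe, GPi) and subthalamic nucleus (STN) — each
described by the fraction of cells firing per unit time, `a_p(t)`:

    tau_p da_p/dt = -a_p + (k_p - a_p) * Z_p(drive_p)

with `tau_p` = 10 ms for every population and `Z_p` the sigmoid response

    Z_p(x) = 1/(1 + exp(-b_p (x - theta_p))) - 1/(1 + exp(b_p theta_p)),

using the classic Wilson–Cowan limit-cycle constants b_e = 1.3,
theta_e = 4.0, b_i = 2.0, theta_i = 3.7, whose response ceilings are
k_e = 0.9945 and k_i = 0.9994 (Wilson & Cowan, *Biophys. J.* 1972).  The
drives are weighted sums over the network's eleven connections
(w1: Th→Cx, w2: Cx→Th, w3: nRT⊣Th, w4: DCN→Th, w5: GPi⊣Th, w6: Cx→nRT,
w7: STN→GPe, w8: GPe⊣GPe, w9: STN→GPi, w10: Cx→STN, w11: GPe⊣STN) plus a
constant ascending drive `ext` into the DCN.  The DCN receives no network
input, so it relaxes to the closed-form equilibrium
`k_e Z_e(ext) / (1 + Z_e(ext))` and simply drives the thalamus.

DBS of a target population (STN, Th, GPi or GPe) is the truncated Fourier
series of a square wave, added inside the target's sigmoid argument:

    DBS(t) = A (4/pi) * sum_{n=1,3,...,1001} sin(2 pi n f t) / n.

Trajectories are integrated with an adaptive stiff solver (LSODA,
rel_tol 1e-6 / abs_tol 1e-9, step capped at 0.1 ms) or fixed-step RK4 at
0.1 ms; the two agree to better than 1e-3 and serve as mutual oracles.
Oscillations are characterised by Welch spectra of the post-transient
activity (single Hann window over the last half of a 4 s run, zero-padded
to a 0.25 Hz grid) and classified as tremor/beta/gamma-band, entrained to
the stimulus, suppressed (low-amplitude high-frequency), or
non-oscillatory.

## Worked example

Three reference parameter sets (`healthy`, `tremor`, `beta`) ship with the
package.  Simulating the tremor set for 4 s and summarising its spectrum:

```
$ bgtc simulate --preset tremor --duration 4 --integrator rk4
oscillatory: True
dominant_frequency_hz: 8.50
network_amplitude: 0.4912
state: oscillatory_other
```

Every population except the DCN locks to one high-amplitude rhythm
(peak-to-trough 0.49 of the active fraction; in this implementation the
tremor-like set oscillates at 8.5 Hz — see `docs/methods.md` for how the
regime frequencies depend on the response-function constants).  Applying
high-frequency STN stimulation to the same network:

```
$ bgtc dbs --preset tremor --duration 4 --integrator rk4 \
      --dbs-target STN --dbs-amplitude 10 --dbs-frequency 120
oscillatory: True
dominant_frequency_hz: 120.00
network_amplitude: 0.1354
state: entrained
```

The pathological high-amplitude low-frequency rhythm is replaced by
low-amplitude activity locked to the 120 Hz stimulus — the model's account
of therapeutic DBS.  The same library calls are available in Python
(`bgtcsim.simulate`, `bgtcsim.summarize`, `bgtcsim.dbs_sweep`,
`bgtcsim.random_survey`, ...), and `bgtc sweep` / `bgtc survey` /
`bgtc spectrum` cover parameter sweeps, random parameter surveys and
spectra of stored trajectories.

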
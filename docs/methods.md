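# Methods

## Model

The network couples seven Wilson–Cowan populations in the fixed order
(Cx, Th, nRT, DCN, GPe, GPi, STN); this ordering is used by every vector,
matrix, file and CLI output.  Each population's active fraction obeys

    tau_p da_p/dt = -a_p + (k_p - a_p) * Z_p(drive_p),

where the drive of each population is a signed, weighted sum of afferent
activity: Cx receives w1·E_Th; Th receives w2·E_Cx − w3·I_nRT + w4·E_DCN −
w5·I_GPi; nRT receives w6·E_Cx; DCN receives the constant `ext`; GPe
receives w7·E_STN − w8·I_GPe; GPi receives w9·E_STN; STN receives
w10·E_Cx − w11·I_GPe.  Weights are stored as non-negative magnitudes —
connection polarity is fixed by the equations, and the parameter loader
rejects signed weights.  With all-equal time constants the value of tau
is a pure time rescaling of the dynamics; tau = 10 ms (a conventional
membrane time constant) is the default for all populations, configurable
per population.

Because the DCN receives only `ext`, its equation decouples: the DCN
relaxes to `k_e·Z_e(ext)/(1+Z_e(ext))` regardless of the weights, and in
every oscillatory regime it is the one population that does not
oscillate.  This closed form is used as a test oracle.

## Response-function constants

`Z_p(x) = 1/(1+exp(-b_p(x-theta_p))) - 1/(1+exp(b_p·theta_p))`, shifted
so that `Z_p(0) = 0` exactly (making the origin an equilibrium when
`ext = 0`).  The defaults are Wilson & Cowan's classic limit-cycle
constants: slope b_e = 1.3 and threshold theta_e = 4.0 for excitatory
populations, b_i = 2.0 and theta_i = 3.7 for inhibitory ones.  The
response ceilings implied by these constants, `1 - 1/(1+exp(b·theta))`,
are k_e = 0.9945 and k_i = 0.9994; the constructor checks this
consistency to 5e-4.  Note that the ceilings depend only on the product
b·theta, so they cannot distinguish this assignment from the transposed
one (b_e = 4, theta_e = 1.3, b_i = 3.7, theta_i = 2.0) — a reading that
occasionally appears in the literature.  The transposed assignment was
evaluated and rejected: under it the reference gamma and beta parameter
sets do not oscillate at all (their equilibria are strongly stable) and
none of the documented regime structure exists, whereas under the classic
assignment all three regimes, the dispensable-connection pattern, the
tremor-state phase ordering and the DBS suppression phenomenology are
reproduced.  Users can set any constants explicitly via `SigmoidParams`
or the flat config keys.

With these constants the three shipped presets oscillate at ≈38.8 Hz
(healthy/gamma), ≈8.5 Hz (tremor-like) and ≈18.5 Hz (beta).  The regime
*structure* — which connections sustain which rhythm, the amplitude and
phase orderings, and the response to stimulation — is robust, but the
absolute frequencies are sensitive to the response-function constants and
should be treated as model-relative rather than physiological constants.

## Numerical integration

Default integrator: LSODA (adaptive, stiffness-switching) with
rel_tol 1e-6, abs_tol 1e-9 and the step capped at 0.1 ms; a fixed-step
classical RK4 at 0.1 ms is provided as an independent oracle.  The two
agree to < 1e-3 (max-abs over 1 s) on all presets, and tightening the
adaptive tolerances tenfold moves the final state by < 1e-5 per component.
Initial conditions are never part of the model definition; the default is
all populations at 0.1, with an optional seeded uniform draw in
[0.05, 0.2].  The dominant frequency of every preset is
initial-condition-robust (tested to ±0.25 Hz over interior starts).  A
solver failure raises an `IntegrationError` carrying the failing time.

The shifted sigmoid takes small negative values for negative drive, so
activity can dip slightly below zero: the exact forward-invariant box for
each population is `[-k·o/(1-o), k]` with `o = 1/(1+exp(b·theta))`
(lower edge ≈ −0.0055 for excitatory populations).  Property tests assert
this box, not the naive `[0, k]`.

Sweeps and surveys run many parameter vectors through a batched RK4
engine whose arithmetic is elementwise, so each batch row is bit-identical
to the corresponding single-simulation RK4 run; this underwrites the
record/simulation coherence tests.  Trajectories are processed in chunks
(default 1000) and discarded after summarisation, so survey memory stays
bounded.

## DBS stimulus

The stimulus is the odd-harmonic Fourier series of a ±A square wave
truncated at harmonic 1001, evaluated literally (including its Gibbs
ripple) rather than replaced by an ideal square wave; an ideal mode
exists behind a flag for sensitivity checks.  The waveform has zero mean
over each period and enters the model only inside the sigmoid argument of
the stimulated population (STN, Th, GPi or GPe).  Amplitude A is the peak
value in the arbitrary units of membrane drive; stimulation is on from
t = 0 by default (configurable onset) — the analysis window excludes the
onset transient either way.

## Spectral analysis and classification

Spectra use Welch's method on the post-transient part of a trajectory.  A
0.5 s window cannot resolve a ~4–8 Hz rhythm with conventional
segmenting, so the default protocol simulates 4 s and analyses the final
2 s as a single Hann-tapered segment zero-padded to a 0.25 Hz frequency
grid; shorter (e.g. 1 s) runs remain available through
`SimulationConfig`/`SpectralSettings`.  A trajectory counts as
*oscillatory* when (a) some non-DCN population has peak-to-trough
excursion > 1e-3 over the window and (b) the spectral peak at or above
0.5 Hz exceeds the DC-adjacent floor by 10×.  Both cutoffs are settings;
they were chosen to accept the low-amplitude gamma regime while rejecting
decaying transients, and all classification output is logged with the
settings used.

State labels: tremor_band [3, 8) Hz, beta_band [13, 30) Hz, gamma_band
[30, 90) Hz (gamma reserved for unstimulated runs), `entrained` when the
dominant frequency lies within one grid bin of the stimulation frequency,
`low_amp_high_freq` when the network amplitude falls below a suppression
fraction (default 0.2) of the no-DBS baseline with a higher dominant
frequency, `oscillatory_other` for oscillatory activity outside all
bands, and `non_oscillatory` otherwise.  *Suppression* of a baseline
rhythm additionally counts trajectories that stop oscillating
altogether.  Suppression thresholds along a grid are located by
`find_threshold`, which returns the start of the trailing run of
suppressed records and warns on non-monotone patterns (reporting the
first crossing).  Thresholds are always reported together with the
suppression fraction and the grid searched.

In this implementation the entrained high-frequency states retain a
stimulus-locked ripple of roughly 25% of the baseline amplitude in the
non-stimulated populations, which sits just above the default 20%
suppression fraction for some targets; threshold results should therefore
be read jointly with the amplitude values, and the fraction is exposed as
a setting rather than hard-coded.

Phase ordering ranks the six non-DCN populations by the circular mean of
their oscillation peak times relative to the thalamus within the dominant
cycle, with cross-correlation lag as tie-break.  In the tremor-like
regime the order is Th, Cx, nRT, STN, GPe, GPi.

Burst-like activity (seen under low-frequency stimulation of the beta
state) is detected as bimodality of successive cycle-peak heights: the
best two-cluster split of the peak heights, scored as the cluster gap
over the pooled within-cluster spread (floored at 1e-4 activity units);
regular oscillations score ≈0, bursting scores ≫5.

## Sweeps and surveys

Single and pairwise sweeps hold a base parameter set fixed and vary one
or two of {w1..w11, ext} over explicit grids (default integer step 1 over
0–40, matching the granularity at which the STN→GPe switch is defined).
DBS sweeps cover amplitude × frequency products (defaults A ∈ 0..10 a.u.,
f ∈ 10..160 Hz in steps of 10) and label each record against the no-DBS
baseline.  The random survey draws all eleven weights uniformly from
[0, 30] and `ext` from [0, 10] — per-dimension ranges may be overridden,
and zero-width ranges pin a dimension — from a single seeded generator
with fixed draw order (w1..w11 then ext, simulation by simulation), so a
seed reproduces the record table byte-for-byte regardless of chunking.
Survey simulations default to 1 s (analysing the second half), which
resolves the oscillation-frequency range of interest on the zero-padded
grid while keeping 10,000 simulations to a few minutes on one CPU; sweep
records default to the full 4 s protocol.

## Problem sizes used by the acceptance script

Single-parameter-set quantities use one 4 s simulation each; suppression
thresholds search the integer amplitude grid 1–10 a.u. (or the 10–160 Hz
frequency grid) at 120 Hz; the survey is run at 10,000 simulations.

## Known limitations

- No spatial structure, conduction delays, multi-channel replication or
  biophysical single-neuron detail; all populations share one rhythm in
  oscillatory regimes.
- Absolute regime frequencies depend on the sigmoid-constant assignment
  (see above) and on the analysis protocol; band labels for states near a
  band edge (e.g. the 8.5 Hz tremor-like rhythm) fall into the
  neighbouring `oscillatory_other` class.
- Thresholds are located by grid search only; there is no numerical
  continuation of limit cycles.
- Charge-balanced biphasic pulse shapes, pulse-width effects and
  closed-loop (phase-locked) stimulation are out of scope.
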
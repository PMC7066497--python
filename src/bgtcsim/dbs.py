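"""Square-pulse deep-brain-stimulation (DBS) forcing.

The stimulus is the truncated odd-harmonic Fourier series of a square wave,

    DBS(t) = A * (4/pi) * sum_{n=1,3,...,n_max} sin(2 pi n f (t - onset)) / n,

which converges to a +/-A square wave of frequency ``f`` as ``n_max`` grows.
The default truncation keeps harmonics up to n = 1001, so the stimulus
carries the Gibbs ripple of the finite series rather than an ideal
discontinuous square wave; an ``ideal`` mode (sign of a sinusoid) is
available for sensitivity checks.

The forcing is applied *inside* the sigmoid argument of the stimulated
population (see :func:`bgtcsim.model.synaptic_drives`), i.e. it perturbs the
average membrane drive of that population, not its firing rate directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

#: Populations that can be stimulated (the clinically used targets).
DBS_TARGETS = ("STN", "Th", "GPi", "GPe")


@dataclass(frozen=True)
class DBSSpec:
    """Specification of a DBS stimulus.

    Parameters
    ----------
    target : str
        Stimulated population, one of ``STN``, ``Th``, ``GPi``, ``GPe``.
    amplitude : float
        Stimulus amplitude ``A`` in arbitrary units (peak of the square
        wave, so the waveform swings between -A and +A). Must be >= 0.
    frequency : float
        Stimulation frequency in Hz. Must be > 0.
    n_max : int
        Highest odd harmonic retained in the truncated series (odd, >= 1).
    onset : float
        Time (seconds) at which the stimulus switches on; the waveform is
        identically zero before ``onset``.
    ideal : bool
        If True, use an ideal +/-A square wave instead of the truncated
        Fourier series.
    """

    target: str
    amplitude: float
    frequency: float
    n_max: int = 1001
    onset: float = 0.0
    ideal: bool = False

    def __post_init__(self) -> None:
        if self.target not in DBS_TARGETS:
            raise ConfigurationError(
                f"unknown DBS target {self.target!r}; valid targets: {DBS_TARGETS}"
            )
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ConfigurationError("DBS amplitude must be finite and >= 0")
        if not np.isfinite(self.frequency) or self.frequency <= 0:
            raise ConfigurationError("DBS frequency must be finite and > 0")
        if self.n_max < 1 or self.n_max % 2 == 0:
            raise ConfigurationError("n_max must be an odd integer >= 1")
        if self.onset < 0:
            raise ConfigurationError("DBS onset must be >= 0")


def harmonics(n_max: int) -> np.ndarray:
    """Odd harmonic indices 1, 3, 5, ..., n_max as a float array."""
    return np.arange(1.0, n_max + 1.0, 2.0)


def dbs_waveform(t, spec: DBSSpec):
    """Evaluate the DBS forcing at time(s) ``t`` (seconds).

    Returns a float for scalar ``t``, else an array of the same shape.
    The waveform is zero for ``t < onset``, has zero mean over each full
    period, and is antisymmetric about the half period.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t) - spec.onset
    if spec.ideal:
        w = spec.amplitude * np.sign(np.sin(2.0 * np.pi * spec.frequency * tt))
    else:
        h = harmonics(spec.n_max)
        phase = (2.0 * np.pi * spec.frequency) * tt[..., None] * h
        w = spec.amplitude * (4.0 / np.pi) * np.sum(np.sin(phase) / h, axis=-1)
    w = np.where(tt >= 0.0, w, 0.0)
    return float(w[0]) if scalar else w


def _waveform_batch(
    t: float,
    frequencies: np.ndarray,
    amplitudes: np.ndarray,
    h: np.ndarray,
    onset: float = 0.0,
) -> np.ndarray:
    """Vectorised waveform for one scalar time and per-simulation (f, A).

    Used by the batched integrator in :mod:`bgtcsim.sweeps`, where each
    simulation in a batch may carry a different stimulus. ``h`` is the
    precomputed odd-harmonic vector.
    """
    if t < onset:
        return np.zeros_like(amplitudes)
    s = np.sin(((2.0 * np.pi) * (t - onset)) * np.outer(frequencies, h))
    return amplitudes * (4.0 / np.pi) * (s / h).sum(axis=1)
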
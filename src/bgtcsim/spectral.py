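"""Spectral analysis and dynamical-state classification of trajectories.

Power spectra are estimated with Welch's method on the post-transient part
of a trajectory (by default the second half), using a single full-window
Hann segment zero-padded to a 0.25 Hz frequency grid.  A trajectory counts
as oscillatory when (a) some non-DCN population has peak-to-trough
excursion above a small epsilon over the analysis window and (b) the
spectral peak above ``min_freq`` stands clear of the DC-adjacent floor by
a fixed factor.  Oscillatory states are labelled by frequency band
(tremor/beta/gamma), or — under stimulation — as entrained to the DBS
frequency or as suppressed low-amplitude high-frequency activity relative
to the unstimulated baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dbs import DBSSpec
from .errors import AnalysisError, ConfigurationError
from .model import POPULATIONS, POP_INDEX, Trajectory

#: State labels.
NON_OSCILLATORY = "non_oscillatory"
TREMOR_BAND = "tremor_band"
BETA_BAND = "beta_band"
GAMMA_BAND = "gamma_band"
LOW_AMP_HIGH_FREQ = "low_amp_high_freq"
ENTRAINED = "entrained"
OSCILLATORY_OTHER = "oscillatory_other"

#: Frequency bands (Hz, half-open [lo, hi)).
DEFAULT_BANDS = {
    TREMOR_BAND: (3.0, 8.0),
    BETA_BAND: (13.0, 30.0),
    GAMMA_BAND: (30.0, 90.0),
}

_DCN = POP_INDEX["DCN"]
_NON_DCN = np.array([i for i in range(7) if i != _DCN])


@dataclass(frozen=True)
class SpectralSettings:
    """Settings for spectral summarisation.

    Parameters
    ----------
    analysis_start : float
        Fraction of the trajectory discarded as transient (default 0.5:
        analyse the second half).
    window : str
        Taper applied to each Welch segment.
    nperseg : int or None
        Segment length in samples; None means one full-window segment.
    resolution : float
        Target frequency-grid spacing in Hz, achieved by zero-padding.
    min_freq : float
        Lowest frequency (Hz) considered when locating the dominant peak.
    epsilon : float
        Peak-to-trough threshold (activity units) below which the network
        counts as quiescent.
    peak_floor_ratio : float
        The dominant peak must exceed the DC-adjacent floor by this factor
        for the trajectory to count as oscillatory.
    suppression_fraction : float
        "Suppressed" means network amplitude below this fraction of the
        no-DBS baseline (with a higher dominant frequency).
    """

    analysis_start: float = 0.5
    window: str = "hann"
    nperseg: int | None = None
    resolution: float = 0.25
    min_freq: float = 0.5
    epsilon: float = 1e-3
    peak_floor_ratio: float = 10.0
    suppression_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.analysis_start < 1.0:
            raise ConfigurationError("analysis_start must lie in [0, 1)")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be > 0")


@dataclass(frozen=True)
class SpectralSummary:
    """Per-population PSDs plus network-level oscillation summary.

    ``freqs``/``psd`` may be None for memory-lean batch summaries that
    keep only scalar statistics.
    """

    freqs: np.ndarray | None               # (n_freq,)
    psd: np.ndarray | None                 # (7, n_freq)
    peak_to_trough: np.ndarray             # (7,) activity units
    population_frequency: np.ndarray       # (7,) Hz (argmax above min_freq)
    dominant_frequency: float | None       # network dominant frequency, Hz
    oscillatory: bool
    state_label: str | None = None
    lead_order: tuple[str, ...] | None = None

    @property
    def network_amplitude(self) -> float:
        """Largest peak-to-trough excursion among non-DCN populations."""
        return float(np.max(self.peak_to_trough[_NON_DCN]))

    def amplitude(self, pop: str) -> float:
        return float(self.peak_to_trough[POP_INDEX[pop]])


def power_spectrum(x: np.ndarray, fs: float,
                   settings: SpectralSettings | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of ``x`` along its last axis.

    Returns ``(freqs, psd)`` with the grid spacing no coarser than the
    settings' target resolution (reached by zero-padding).
    """
    settings = settings or SpectralSettings()
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 64:
        raise AnalysisError("signal too short for spectral analysis (< 64 samples)")
    nperseg = settings.nperseg or x.shape[-1]
    nperseg = min(nperseg, x.shape[-1])
    nfft = max(nperseg, int(round(fs / settings.resolution)))
    freqs, psd = sps.welch(
        x, fs=fs, window=settings.window, nperseg=nperseg, nfft=nfft,
        detrend="constant", axis=-1,
    )
    return freqs, psd


def dominant_frequency(freqs: np.ndarray, psd: np.ndarray,
                       min_freq: float = 0.5) -> float | None:
    """Frequency of the maximal spectral peak at or above ``min_freq``."""
    mask = freqs >= min_freq
    if not np.any(mask):
        return None
    p = psd[mask]
    if np.max(p) <= 0:
        return None
    return float(freqs[mask][np.argmax(p)])


def _analysis_slice(times: np.ndarray, analysis_start: float) -> slice:
    t0, t1 = times[0], times[-1]
    start = t0 + analysis_start * (t1 - t0)
    i0 = int(np.searchsorted(times, start - 1e-12))
    return slice(i0, times.size)


def oscillation_amplitude(traj: Trajectory,
                          settings: SpectralSettings | None = None
                          ) -> dict[str, float]:
    """Peak-to-trough excursion of each population over the analysis window."""
    settings = settings or SpectralSettings()
    sl = _analysis_slice(traj.times, settings.analysis_start)
    ptp = np.ptp(traj.activity[sl], axis=0)
    return {p: float(v) for p, v in zip(POPULATIONS, ptp)}


def _stats_from_psd(p: np.ndarray, freqs: np.ndarray, ptp_row: np.ndarray,
                    settings: SpectralSettings):
    """(pop_freq, net_freq, oscillatory) for one (7, n_freq) PSD."""
    mask = freqs >= settings.min_freq
    floor_mask = ~mask
    f_hi = freqs[mask]
    pop_freq = f_hi[np.argmax(p[:, mask], axis=1)]
    sub = p[_NON_DCN][:, mask]
    j_pop, j_bin = np.unravel_index(np.argmax(sub), sub.shape)
    peak_power = sub[j_pop, j_bin]
    net_freq = float(f_hi[j_bin])
    floor = float(np.max(p[_NON_DCN[j_pop]][floor_mask])) if np.any(floor_mask) else 0.0
    amp_ok = float(np.max(ptp_row[_NON_DCN])) > settings.epsilon
    peak_ok = peak_power > settings.peak_floor_ratio * floor and peak_power > 0
    return pop_freq, net_freq, bool(amp_ok and peak_ok)


def _summaries_from_windows(act_w: np.ndarray, fs: float,
                            settings: SpectralSettings) -> list[SpectralSummary]:
    """Full summaries (with PSDs) for a small (n, n_samples, 7) stack."""
    ptp = np.ptp(act_w, axis=1)                        # (n, 7)
    freqs, psd = power_spectrum(np.swapaxes(act_w, 1, 2), fs, settings)  # (n,7,nf)
    out: list[SpectralSummary] = []
    for i in range(act_w.shape[0]):
        pop_freq, net_freq, osc = _stats_from_psd(psd[i], freqs, ptp[i], settings)
        out.append(SpectralSummary(
            freqs=freqs, psd=psd[i], peak_to_trough=ptp[i],
            population_frequency=pop_freq,
            dominant_frequency=net_freq if osc else None,
            oscillatory=osc,
        ))
    return out


def batch_window_stats(act_w: np.ndarray, fs: float,
                       settings: SpectralSettings) -> list[SpectralSummary]:
    """Memory-lean summaries for a large window stack (PSDs not retained).

    Rows whose non-DCN peak-to-trough stays below epsilon are classified
    non-oscillatory from the amplitude test alone; Welch spectra are
    computed only for the remaining rows, and the per-row PSD is dropped
    once its scalar statistics are extracted.
    """
    ptp = np.ptp(act_w, axis=1)
    needs = np.max(ptp[:, _NON_DCN], axis=1) > settings.epsilon
    out: list[SpectralSummary | None] = [None] * act_w.shape[0]
    idx = np.flatnonzero(needs)
    if idx.size:
        freqs, psd = power_spectrum(np.swapaxes(act_w[idx], 1, 2), fs, settings)
        for row, i in enumerate(idx):
            pop_freq, net_freq, osc = _stats_from_psd(psd[row], freqs,
                                                      ptp[i], settings)
            out[i] = SpectralSummary(
                freqs=None, psd=None, peak_to_trough=ptp[i],
                population_frequency=pop_freq,
                dominant_frequency=net_freq if osc else None,
                oscillatory=osc,
            )
    quiet = np.full(7, np.nan)
    for i in np.flatnonzero(~needs):
        out[i] = SpectralSummary(
            freqs=None, psd=None, peak_to_trough=ptp[i],
            population_frequency=quiet, dominant_frequency=None,
            oscillatory=False,
        )
    return out


def summarize(traj: Trajectory, settings: SpectralSettings | None = None,
              baseline: SpectralSummary | None = None,
              dbs: DBSSpec | None = None,
              include_phase: bool = False) -> SpectralSummary:
    """Summarise one trajectory: PSDs, amplitudes, dominant frequency, label.

    ``dbs`` defaults to the trajectory's own stimulus.  When a baseline
    (no-DBS) summary is supplied, the state label distinguishes entrained
    and suppressed activity; without one, oscillatory states are labelled
    by frequency band alone.
    """
    settings = settings or SpectralSettings()
    dbs = dbs if dbs is not None else traj.dbs
    sl = _analysis_slice(traj.times, settings.analysis_start)
    summary = _summaries_from_windows(traj.activity[None, sl, :], traj.fs, settings)[0]
    # DBS-specific labels (entrained / suppressed) need a no-DBS baseline;
    # without one, fall back to plain band labelling.
    label = classify_state(summary, baseline=baseline,
                           dbs=dbs if baseline is not None else None,
                           settings=settings)
    lead = None
    if include_phase and summary.oscillatory:
        lead = tuple(phase_order(traj, settings))
    return SpectralSummary(
        freqs=summary.freqs, psd=summary.psd,
        peak_to_trough=summary.peak_to_trough,
        population_frequency=summary.population_frequency,
        dominant_frequency=summary.dominant_frequency,
        oscillatory=summary.oscillatory, state_label=label, lead_order=lead,
    )


def is_oscillatory(traj: Trajectory, settings: SpectralSettings | None = None,
                   epsilon: float | None = None) -> bool:
    """Two-part oscillation test: amplitude epsilon + spectral-peak floor."""
    settings = settings or SpectralSettings()
    if epsilon is not None:
        settings = dataclasses.replace(settings, epsilon=epsilon)
    sl = _analysis_slice(traj.times, settings.analysis_start)
    return _summaries_from_windows(traj.activity[None, sl, :], traj.fs,
                                   settings)[0].oscillatory


def classify_state(summary: SpectralSummary,
                   baseline: SpectralSummary | None = None,
                   dbs: DBSSpec | None = None,
                   bands: dict[str, tuple[float, float]] | None = None,
                   settings: SpectralSettings | None = None) -> str:
    """Label the dynamical state of a summarised trajectory.

    Band labels (tremor/beta) apply with or without stimulation; the gamma
    label is reserved for unstimulated dynamics.  Under DBS, activity
    within one frequency bin of the stimulation frequency is ``entrained``
    and activity whose amplitude has collapsed below the suppression
    fraction of the baseline (at a higher frequency) is
    ``low_amp_high_freq``.
    """
    settings = settings or SpectralSettings()
    bands = bands or DEFAULT_BANDS
    if dbs is not None and dbs.amplitude > 0 and baseline is None:
        raise ConfigurationError("DBS state labels require a no-DBS baseline summary")
    if not summary.oscillatory:
        return NON_OSCILLATORY
    f = summary.dominant_frequency
    lo, hi = bands[TREMOR_BAND]
    if lo <= f < hi:
        return TREMOR_BAND
    lo, hi = bands[BETA_BAND]
    if lo <= f < hi:
        return BETA_BAND
    under_dbs = dbs is not None and dbs.amplitude > 0
    lo, hi = bands[GAMMA_BAND]
    if not under_dbs and lo <= f < hi:
        return GAMMA_BAND
    if under_dbs:
        if abs(f - dbs.frequency) <= settings.resolution + 1e-9:
            return ENTRAINED
        if (summary.network_amplitude
                < settings.suppression_fraction * baseline.network_amplitude
                and baseline.dominant_frequency is not None
                and f > baseline.dominant_frequency):
            return LOW_AMP_HIGH_FREQ
    return OSCILLATORY_OTHER


def oscillation_suppressed(summary: SpectralSummary,
                           baseline: SpectralSummary,
                           suppression_fraction: float = 0.2) -> bool:
    """True when the baseline rhythm is abolished or replaced.

    Either the trajectory is no longer oscillatory at all, or its network
    amplitude has fallen below ``suppression_fraction`` of the baseline
    amplitude while the dominant frequency moved above the baseline's.
    """
    if not summary.oscillatory:
        return True
    if baseline.dominant_frequency is None:
        return False
    return (summary.network_amplitude
            < suppression_fraction * baseline.network_amplitude
            and summary.dominant_frequency > baseline.dominant_frequency)


def cycle_amplitude_bimodality(traj: Trajectory, pop: str = "STN",
                               settings: SpectralSettings | None = None
                               ) -> float:
    """Bimodality score of successive cycle-peak heights (burst detector).

    Burst-like activity alternates large and small cycles, so the
    distribution of oscillation peak heights splits into two clusters.
    The score is the gap between the best two-cluster split of the peak
    heights divided by the pooled within-cluster spread (floored at 1e-4
    activity units); unimodal (regular) oscillations score ~0, clearly
    burst-like activity scores far above 5.
    """
    settings = settings or SpectralSettings()
    sl = _analysis_slice(traj.times, settings.analysis_start)
    x = traj.population(pop)[sl]
    if np.ptp(x) < settings.epsilon:
        return 0.0
    peaks, _ = sps.find_peaks(x, prominence=0.05 * np.ptp(x))
    h = np.sort(x[peaks])
    if h.size < 6 or np.ptp(h) < 1e-3:
        return 0.0
    best = None
    for i in range(1, h.size):
        a, b = h[:i], h[i:]
        w = a.var() * a.size + b.var() * b.size
        if best is None or w < best[0]:
            best = (w, i)
    i = best[1]
    a, b = h[:i], h[i:]
    pooled = np.sqrt((a.var() * a.size + b.var() * b.size) / h.size)
    return float((b.mean() - a.mean()) / max(pooled, 1e-4))


# ---------------------------------------------------------------------------
# Phase ordering
# ---------------------------------------------------------------------------

def phase_lags(signals: np.ndarray, times: np.ndarray, f0: float,
               ref: int = 0) -> np.ndarray:
    """Per-row lag (seconds, in [0, 1/f0)) relative to the ``ref`` row.

    Each row's phase is the circular mean of ``2 pi f0 t_peak`` over its
    local maxima; a positive lag means the row peaks after the reference.
    """
    period = 1.0 / f0
    dt = times[1] - times[0]
    min_dist = max(1, int(0.5 * period / dt))
    phases = np.empty(signals.shape[0])
    for i, x in enumerate(signals):
        prom = 0.25 * np.ptp(x)
        peaks, _ = sps.find_peaks(x, prominence=max(prom, 1e-12), distance=min_dist)
        if peaks.size == 0:
            raise AnalysisError("no oscillation peaks found for phase analysis")
        phases[i] = np.angle(np.mean(np.exp(2j * np.pi * f0 * times[peaks])))
    lags = np.mod(phases - phases[ref], 2.0 * np.pi) / (2.0 * np.pi * f0)
    return lags


def _xcorr_lag(x_ref: np.ndarray, x: np.ndarray, dt: float, period: float) -> float:
    """Lag (in [0, period)) maximising the circular cross-correlation."""
    a = x_ref - x_ref.mean()
    b = x - x.mean()
    n = min(a.size, int(round(period / dt)))
    # circular correlation over one period via FFT
    nfft = int(2 ** np.ceil(np.log2(a.size)))
    c = np.fft.irfft(np.fft.rfft(a, nfft) * np.conj(np.fft.rfft(b, nfft)), nfft)
    lags = np.arange(n) * dt
    return float(lags[np.argmax(c[:n])])


def phase_order(traj: Trajectory, settings: SpectralSettings | None = None
                ) -> list[str]:
    """Rank the oscillating (non-DCN) populations by phase lead.

    The thalamus is the phase reference; populations are ordered by their
    circular-mean peak-time lag within the dominant cycle, ties broken by
    the cross-correlation lag at the dominant period.

    Raises
    ------
    AnalysisError
        If the trajectory is not oscillatory.
    """
    settings = settings or SpectralSettings()
    sl = _analysis_slice(traj.times, settings.analysis_start)
    summary = _summaries_from_windows(traj.activity[None, sl, :], traj.fs,
                                      settings)[0]
    if not summary.oscillatory:
        raise AnalysisError("phase ordering requires an oscillatory trajectory")
    f0 = summary.dominant_frequency
    times_w = traj.times[sl]
    names = [POPULATIONS[i] for i in _NON_DCN]
    sigs = traj.activity[sl][:, _NON_DCN].T
    ref = names.index("Th")
    lags = phase_lags(sigs, times_w, f0, ref=ref)
    dt = traj.dt
    period = 1.0 / f0
    keys = []
    for i, name in enumerate(names):
        primary = int(round(lags[i] / dt))
        keys.append((primary, i))
    # tie-break identical primary lags by cross-correlation lag
    order = sorted(range(len(names)), key=lambda i: (
        keys[i][0],
        _xcorr_lag(sigs[ref], sigs[i], dt, period) if _is_tied(keys, i) else 0.0,
    ))
    return [names[i] for i in order]


def _is_tied(keys: list[tuple[int, int]], i: int) -> bool:
    primary = keys[i][0]
    return sum(1 for k in keys if k[0] == primary) > 1
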
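"""Parameter surveys, single/pairwise sweeps and DBS grids.

All sweep drivers share a batched fixed-step RK4 engine: each record's
trajectory is integrated with elementwise arithmetic identical to a single
``simulate(..., integrator="rk4")`` call, so any row of a sweep table can
be reproduced independently.  Trajectories are processed in chunks and
discarded after summarisation; only the per-record summaries are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spectral
from .dbs import DBSSpec
from .errors import ConfigurationError
from .model import (PARAM_NAMES, POP_INDEX, POPULATIONS, ModelParameters,
                    SimulationConfig, simulate_batch)
from .spectral import SpectralSettings, SpectralSummary

#: Default simulation settings for sweeps: 4 s of activity, analysed over
#: the final 2 s, integrated with fixed-step RK4 at 0.1 ms.
SWEEP_SIM_CONFIG = SimulationConfig(duration=4.0, integrator="rk4")

#: The survey follows the random-exploration protocol: 1 s simulations,
#: second half analysed.
SURVEY_SIM_CONFIG = SimulationConfig(duration=1.0, integrator="rk4")


@dataclass(frozen=True)
class SweepRecord:
    """One (parameter vector -> spectral summary) row of a sweep table."""

    params: dict[str, float]
    oscillatory: bool
    dominant_frequency: float | None
    state_label: str
    amplitudes: dict[str, float]
    network_amplitude: float
    dbs_target: str | None = None
    dbs_amplitude: float | None = None
    dbs_frequency: float | None = None
    swept: dict[str, float] = field(default_factory=dict)

    def value(self, axis: str) -> float:
        """Grid value of this record along a swept axis."""
        if axis in self.swept:
            return self.swept[axis]
        if axis == "dbs_amplitude" and self.dbs_amplitude is not None:
            return self.dbs_amplitude
        if axis == "dbs_frequency" and self.dbs_frequency is not None:
            return self.dbs_frequency
        if axis in self.params:
            return self.params[axis]
        raise ConfigurationError(f"record has no axis {axis!r}")


@dataclass(frozen=True)
class SurveyConfig:
    """Random-survey settings: independent uniform draws per dimension.

    ``weight_range`` is one (low, high) pair shared by all 11 weights or
    an (11, 2) array of per-weight pairs; zero-width ranges pin a
    dimension to a fixed value.
    """

    n_sims: int
    weight_range: object = (0.0, 30.0)
    ext_range: tuple[float, float] = (0.0, 10.0)
    seed: int | None = None
    chunk_size: int = 1000

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")
        wr = np.asarray(self.weight_range, dtype=float)
        if wr.shape == (2,):
            wr = np.tile(wr, (11, 1))
        if wr.shape != (11, 2):
            raise ConfigurationError(
                "weight_range must be a (low, high) pair or an (11, 2) array")
        er = np.asarray(self.ext_range, dtype=float)
        if er.shape != (2,):
            raise ConfigurationError("ext_range must be a (low, high) pair")
        if np.any(wr[:, 1] < wr[:, 0]) or er[1] < er[0]:
            raise ConfigurationError("ranges must satisfy low <= high")
        wr.setflags(write=False)
        object.__setattr__(self, "weight_range", wr)
        object.__setattr__(self, "ext_range", (float(er[0]), float(er[1])))


def records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    """Flatten records into a table, one row per simulation."""
    rows = []
    for r in records:
        row: dict[str, object] = dict(r.params)
        row.update({
            "dbs_target": r.dbs_target,
            "dbs_amplitude": r.dbs_amplitude,
            "dbs_frequency": r.dbs_frequency,
            "oscillatory": r.oscillatory,
            "dominant_frequency": (np.nan if r.dominant_frequency is None
                                   else r.dominant_frequency),
            "state_label": r.state_label,
            "network_amplitude": r.network_amplitude,
        })
        row.update({f"amp_{p}": r.amplitudes[p] for p in POPULATIONS})
        rows.append(row)
    return pd.DataFrame(rows)


def _summarize_chunk(times, activity, settings, fs):
    sl = spectral._analysis_slice(times, settings.analysis_start)
    return spectral.batch_window_stats(activity[:, sl, :], fs, settings)


def _make_records(weight_rows, ext_col, summaries, settings, baseline=None,
                  dbs_info=None, swept_rows=None) -> list[SweepRecord]:
    records = []
    for i, s in enumerate(summaries):
        params = {f"w{j + 1}": float(weight_rows[i, j]) for j in range(11)}
        params["ext"] = float(ext_col[i])
        if dbs_info is not None:
            spec = dbs_info["specs"][i]
            label = spectral.classify_state(s, baseline=baseline, dbs=spec,
                                            settings=settings)
            tgt, amp, freq = spec.target, spec.amplitude, spec.frequency
        else:
            label = spectral.classify_state(s, settings=settings)
            tgt = amp = freq = None
        records.append(SweepRecord(
            params=params, oscillatory=s.oscillatory,
            dominant_frequency=s.dominant_frequency, state_label=label,
            amplitudes={p: float(v) for p, v in
                        zip(POPULATIONS, s.peak_to_trough)},
            network_amplitude=s.network_amplitude,
            dbs_target=tgt, dbs_amplitude=amp, dbs_frequency=freq,
            swept=dict(swept_rows[i]) if swept_rows is not None else {},
        ))
    return records


def random_survey(config: SurveyConfig,
                  sim_config: SimulationConfig | None = None,
                  settings: SpectralSettings | None = None
                  ) -> list[SweepRecord]:
    """Uniform random exploration of the (w1..w11, ext) parameter box.

    Draw order is fixed (w1..w11 then ext, simulation by simulation) from
    a single seeded generator, so a given seed reproduces the table
    exactly.  Trajectories are simulated in chunks and discarded after
    summarisation.
    """
    sim_config = sim_config or SURVEY_SIM_CONFIG
    settings = settings or SpectralSettings()
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(size=(config.n_sims, 12))
    wr = np.asarray(config.weight_range)
    lo_e, hi_e = config.ext_range
    draws = np.empty_like(u)
    draws[:, :11] = wr[:, 0] + (wr[:, 1] - wr[:, 0]) * u[:, :11]
    draws[:, 11] = lo_e + (hi_e - lo_e) * u[:, 11]
    fs = 1.0 / sim_config.dt_output
    records: list[SweepRecord] = []
    for start in range(0, config.n_sims, config.chunk_size):
        chunk = draws[start:start + config.chunk_size]
        times, act = simulate_batch(chunk[:, :11], chunk[:, 11], sim_config)
        summaries = _summarize_chunk(times, act, settings, fs)
        records.extend(_make_records(chunk[:, :11], chunk[:, 11],
                                     summaries, settings))
    return records


def _check_param_name(name: str) -> None:
    if name not in PARAM_NAMES:
        raise ConfigurationError(
            f"unknown parameter {name!r}; sweepable parameters: {PARAM_NAMES}")


def single_param_sweep(base: ModelParameters, name: str, grid,
                       sim_config: SimulationConfig | None = None,
                       settings: SpectralSettings | None = None
                       ) -> list[SweepRecord]:
    """Vary one parameter over ``grid``, all others held at ``base``."""
    _check_param_name(name)
    sim_config = sim_config or SWEEP_SIM_CONFIG
    settings = settings or SpectralSettings()
    grid = np.asarray(grid, dtype=float).reshape(-1)
    n = grid.size
    weights = np.tile(base.weights, (n, 1))
    exts = np.full(n, base.ext)
    if name == "ext":
        exts = grid.copy()
    else:
        weights[:, int(name[1:]) - 1] = grid
    times, act = simulate_batch(weights, exts, sim_config,
                                sigmoid=base.sigmoid, tau_ms=base.tau_ms)
    summaries = _summarize_chunk(times, act, settings, 1.0 / sim_config.dt_output)
    swept = [{name: float(v)} for v in grid]
    return _make_records(weights, exts, summaries, settings, swept_rows=swept)


def pairwise_sweep(base: ModelParameters, name_a: str, name_b: str,
                   grid_a, grid_b,
                   sim_config: SimulationConfig | None = None,
                   settings: SpectralSettings | None = None
                   ) -> list[SweepRecord]:
    """Vary two parameters jointly; records in row-major (a, b) order."""
    _check_param_name(name_a)
    _check_param_name(name_b)
    if name_a == name_b:
        raise ConfigurationError("pairwise sweep needs two distinct parameters")
    sim_config = sim_config or SWEEP_SIM_CONFIG
    settings = settings or SpectralSettings()
    grid_a = np.asarray(grid_a, dtype=float).reshape(-1)
    grid_b = np.asarray(grid_b, dtype=float).reshape(-1)
    va, vb = np.meshgrid(grid_a, grid_b, indexing="ij")
    va, vb = va.ravel(), vb.ravel()
    n = va.size
    weights = np.tile(base.weights, (n, 1))
    exts = np.full(n, base.ext)
    for name, col in ((name_a, va), (name_b, vb)):
        if name == "ext":
            exts = col.copy()
        else:
            weights[:, int(name[1:]) - 1] = col
    times, act = simulate_batch(weights, exts, sim_config,
                                sigmoid=base.sigmoid, tau_ms=base.tau_ms)
    summaries = _summarize_chunk(times, act, settings, 1.0 / sim_config.dt_output)
    swept = [{name_a: float(a), name_b: float(b)} for a, b in zip(va, vb)]
    return _make_records(weights, exts, summaries, settings, swept_rows=swept)


def baseline_summary(base: ModelParameters,
                     sim_config: SimulationConfig | None = None,
                     settings: SpectralSettings | None = None
                     ) -> SpectralSummary:
    """No-DBS summary of ``base`` under the sweep simulation settings."""
    sim_config = sim_config or SWEEP_SIM_CONFIG
    settings = settings or SpectralSettings()
    times, act = simulate_batch(base.weights[None, :], np.asarray([base.ext]),
                                sim_config, sigmoid=base.sigmoid,
                                tau_ms=base.tau_ms)
    return _summarize_chunk(times, act, settings, 1.0 / sim_config.dt_output)[0]


def dbs_sweep(base: ModelParameters, target: str, amplitudes, frequencies,
              sim_config: SimulationConfig | None = None,
              settings: SpectralSettings | None = None,
              n_max: int = 1001) -> list[SweepRecord]:
    """Stimulate ``target`` over an amplitude x frequency grid.

    Records are labelled against the no-DBS baseline of ``base`` and come
    in row-major (amplitude, frequency) order.
    """
    sim_config = sim_config or SWEEP_SIM_CONFIG
    settings = settings or SpectralSettings()
    amplitudes = np.asarray(amplitudes, dtype=float).reshape(-1)
    frequencies = np.asarray(frequencies, dtype=float).reshape(-1)
    aa, ff = np.meshgrid(amplitudes, frequencies, indexing="ij")
    aa, ff = aa.ravel(), ff.ravel()
    n = aa.size
    specs = [DBSSpec(target=target, amplitude=float(a), frequency=float(f),
                     n_max=n_max) for a, f in zip(aa, ff)]
    base_sum = baseline_summary(base, sim_config, settings)
    weights = np.tile(base.weights, (n, 1))
    exts = np.full(n, base.ext)
    dbs_batch = {
        "target_idx": np.full(n, POP_INDEX[target]),
        "amplitude": aa, "frequency": ff, "n_max": n_max,
    }
    times, act = simulate_batch(weights, exts, sim_config,
                                dbs_batch=dbs_batch, sigmoid=base.sigmoid,
                                tau_ms=base.tau_ms)
    summaries = _summarize_chunk(times, act, settings, 1.0 / sim_config.dt_output)
    swept = [{"dbs_amplitude": float(a), "dbs_frequency": float(f)}
             for a, f in zip(aa, ff)]
    return _make_records(weights, exts, summaries, settings,
                         baseline=base_sum, dbs_info={"specs": specs},
                         swept_rows=swept)


def find_threshold(records: list[SweepRecord], predicate, axis: str):
    """Smallest grid value from which the predicate holds for good.

    ``records`` must be ordered along the swept ``axis``.  Returns the
    value of the first record such that it and every later record satisfy
    ``predicate``; ``None`` if the predicate never stabilises to true.
    Non-monotone satisfaction triggers a warning naming the first
    crossing.
    """
    if not records:
        raise ConfigurationError("find_threshold needs at least one record")
    sat = [bool(predicate(r)) for r in records]
    values = [r.value(axis) for r in records]
    if not any(sat):
        return None
    # index of the start of the trailing all-true run, if any
    suffix = None
    if sat[-1]:
        suffix = len(sat)
        while suffix > 0 and sat[suffix - 1]:
            suffix -= 1
    first = sat.index(True)
    if suffix is None:
        warnings.warn(
            f"predicate satisfaction along {axis!r} is non-monotone and does "
            f"not stabilise; first crossing at {axis}={values[first]!r}")
        return None
    if first < suffix:
        warnings.warn(
            f"predicate satisfaction along {axis!r} is non-monotone; first "
            f"crossing at {axis}={values[first]!r}, stable from "
            f"{axis}={values[suffix]!r}")
    return values[suffix]


def suppression_predicate(baseline: SpectralSummary,
                          suppression_fraction: float = 0.2):
    """Predicate factory: record's rhythm suppressed relative to baseline."""
    base_amp = baseline.network_amplitude
    base_f = baseline.dominant_frequency

    def predicate(record: SweepRecord) -> bool:
        if not record.oscillatory:
            return True
        if base_f is None:
            return False
        return (record.network_amplitude < suppression_fraction * base_amp
                and record.dominant_frequency > base_f)

    return predicate
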
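"""Flat key-value run configuration (YAML/JSON).

A config file resolves to model parameters, simulation settings, an
optional DBS stimulus and spectral-analysis settings.  Keys are flat
(``w1``..``w11``, ``ext``, ``tau_ms``, sigmoid constants, solver and DBS
fields); a ``preset`` key seeds the weights before any override is
applied.  Unknown keys are rejected by name and invalid values (negative
weights, even harmonic truncation, ...) raise configuration errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .dbs import DBSSpec
from .errors import ConfigurationError
from .model import (WEIGHT_NAMES, ModelParameters, SigmoidParams,
                    SimulationConfig)
from .presets import load_preset
from .spectral import SpectralSettings

_SIGMOID_KEYS = ("theta_e", "b_e", "theta_i", "b_i", "k_e", "k_i")
_SIM_KEYS = {"duration": "duration", "dt_output": "dt_output",
             "integrator": "integrator", "rel_tol": "rel_tol",
             "abs_tol": "abs_tol", "max_step": "max_step",
             "rk4_dt": "rk4_dt", "initial_state": "initial_state",
             "seed": "seed"}
_DBS_KEYS = {"dbs_target": "target", "dbs_amplitude": "amplitude",
             "dbs_frequency": "frequency", "dbs_harmonics": "n_max",
             "dbs_onset": "onset", "dbs_ideal": "ideal"}
_SPECTRAL_KEYS = {"analysis_start": "analysis_start",
                  "resolution": "resolution", "min_freq": "min_freq",
                  "epsilon": "epsilon",
                  "peak_floor_ratio": "peak_floor_ratio",
                  "suppression_fraction": "suppression_fraction"}

_KNOWN_KEYS = (set(WEIGHT_NAMES) | {"preset", "ext", "tau_ms"}
               | set(_SIGMOID_KEYS) | set(_SIM_KEYS) | set(_DBS_KEYS)
               | set(_SPECTRAL_KEYS))


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one run."""

    params: ModelParameters
    sim: SimulationConfig
    dbs: DBSSpec | None
    spectral: SpectralSettings


def resolve_config(raw: dict) -> RunConfig:
    """Resolve a flat key-value mapping into a :class:`RunConfig`."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(map(str, unknown)))}")
    if "preset" in raw:
        params = load_preset(raw["preset"])
    else:
        params = ModelParameters(weights=[0.0] * 11, ext=0.0)
    overrides = {k: raw[k] for k in (*WEIGHT_NAMES, "ext") if k in raw}
    if overrides:
        params = params.replace(**overrides)
    sig_over = {k: raw[k] for k in _SIGMOID_KEYS if k in raw}
    if sig_over or "tau_ms" in raw:
        sigmoid = (SigmoidParams(**{**{k: getattr(params.sigmoid, k)
                                       for k in _SIGMOID_KEYS}, **sig_over}))
        params = ModelParameters(weights=params.weights, ext=params.ext,
                                 tau_ms=raw.get("tau_ms", params.tau_ms),
                                 sigmoid=sigmoid)
    sim = SimulationConfig(**{dst: raw[src] for src, dst in _SIM_KEYS.items()
                              if src in raw})
    dbs = None
    if any(k in raw for k in _DBS_KEYS):
        dbs_kwargs = {dst: raw[src] for src, dst in _DBS_KEYS.items() if src in raw}
        for req in ("target", "amplitude", "frequency"):
            if req not in dbs_kwargs:
                raise ConfigurationError(
                    f"DBS configuration requires dbs_{req if req != 'n_max' else 'harmonics'}")
        dbs = DBSSpec(**dbs_kwargs)
    spec = SpectralSettings(**{dst: raw[src] for src, dst in
                               _SPECTRAL_KEYS.items() if src in raw})
    return RunConfig(params=params, sim=sim, dbs=dbs, spectral=spec)


def load_config(path) -> RunConfig:
    """Load and resolve a YAML/JSON configuration file.

    Raises
    ------
    ConfigurationError
        On malformed files (with line context) or invalid keys/values.
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1}, column {mark.column + 1})" if mark else ""
        raise ConfigurationError(f"malformed config file {path}{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return resolve_config(raw)


def save_config(config: RunConfig, path) -> None:
    """Write a resolved configuration back to a flat YAML file."""
    flat: dict = dict(config.params.as_dict())
    flat["tau_ms"] = [float(t) for t in config.params.tau_ms]
    flat.update({k: getattr(config.params.sigmoid, k) for k in _SIGMOID_KEYS})
    for src, dst in _SIM_KEYS.items():
        val = getattr(config.sim, dst)
        if isinstance(val, (str, int, float, type(None))):
            flat[src] = val
    if config.dbs is not None:
        for src, dst in _DBS_KEYS.items():
            flat[src] = getattr(config.dbs, dst)
    for src, dst in _SPECTRAL_KEYS.items():
        flat[src] = getattr(config.spectral, dst)
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))
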
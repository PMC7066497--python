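"""Reading and writing trajectories, PSDs and sweep tables.

Text outputs (CSV) carry provenance as ``#``-prefixed header lines: the
full parameter set, any stimulus, solver settings, seed and package
version, each as ``# key: <json>``.  Binary sweep tables use Parquet with
the same provenance embedded in the file metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dbs import DBSSpec
from .errors import ConfigurationError
from .model import POPULATIONS, ModelParameters, SigmoidParams, Trajectory
from .sweeps import SweepRecord, records_to_frame


def _provenance(metadata: dict | None) -> dict:
    meta = {"bgtcsim_version": __version__}
    if metadata:
        meta.update(metadata)
    return meta


def _params_meta(params: ModelParameters) -> dict:
    return {
        "params": params.as_dict(),
        "tau_ms": list(map(float, params.tau_ms)),
        "sigmoid": {k: getattr(params.sigmoid, k)
                    for k in ("theta_e", "b_e", "theta_i", "b_i", "k_e", "k_i")},
    }


def _dbs_meta(dbs: DBSSpec | None) -> dict:
    if dbs is None:
        return {"dbs": None}
    return {"dbs": {"target": dbs.target, "amplitude": dbs.amplitude,
                    "frequency": dbs.frequency, "n_max": dbs.n_max,
                    "onset": dbs.onset, "ideal": dbs.ideal}}


def _write_csv_with_meta(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        # %.17g keeps float64 exactly round-trippable through text
        df.to_csv(fh, index=False, float_format="%.17g")


def read_csv_meta(path) -> dict:
    """Provenance dict from the ``#`` header of a bgtcsim CSV file."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = json.loads(val.strip())
    return meta


def write_trajectory(traj: Trajectory, path, metadata: dict | None = None) -> None:
    """Write a trajectory as CSV (time_s, Cx, ..., STN) with provenance."""
    meta = _provenance(metadata)
    meta.update(_params_meta(traj.params))
    meta.update(_dbs_meta(traj.dbs))
    _write_csv_with_meta(traj.to_frame(), Path(path), meta)


def load_trajectory(path) -> Trajectory:
    """Load a trajectory CSV written by :func:`write_trajectory`."""
    path = Path(path)
    meta = read_csv_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("time_s", *POPULATIONS) if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trajectory file missing columns: {missing}")
    if "params" not in meta:
        raise ConfigurationError("trajectory file has no embedded parameter set")
    pdict = meta["params"]
    params = ModelParameters(
        weights=[pdict[f"w{i}"] for i in range(1, 12)], ext=pdict["ext"],
        tau_ms=meta.get("tau_ms", 10.0),
        sigmoid=SigmoidParams(**meta["sigmoid"]) if "sigmoid" in meta else SigmoidParams(),
    )
    dbs = None
    if meta.get("dbs"):
        dbs = DBSSpec(**meta["dbs"])
    act = df[list(POPULATIONS)].to_numpy()
    return Trajectory(df["time_s"].to_numpy(), act, params, dbs)


def write_psd(freqs: np.ndarray, psd: np.ndarray, path,
              metadata: dict | None = None) -> None:
    """Write a per-population PSD table (frequency_hz, power_<pop>)."""
    data = {"frequency_hz": freqs}
    data.update({f"power_{p}": psd[i] for i, p in enumerate(POPULATIONS)})
    _write_csv_with_meta(pd.DataFrame(data), Path(path), _provenance(metadata))


def write_records(records, path, fmt: str | None = None,
                  metadata: dict | None = None) -> None:
    """Write sweep records (or a DataFrame) as CSV or Parquet.

    The format defaults to the path suffix (``.csv`` / ``.parquet``).
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    fmt = fmt or path.suffix.lstrip(".").lower()
    meta = _provenance(metadata)
    if fmt == "csv":
        _write_csv_with_meta(df, path, meta)
    elif fmt in ("parquet", "pq"):
        import pyarrow as pa
        import pyarrow.parquet as pq

        table = pa.Table.from_pandas(df, preserve_index=False)
        schema_meta = dict(table.schema.metadata or {})
        schema_meta[b"bgtcsim_meta"] = json.dumps(meta).encode()
        pq.write_table(table.replace_schema_metadata(schema_meta), path)
    else:
        raise ConfigurationError(f"unknown record format {fmt!r}; use csv or parquet")


def load_records(path, fmt: str | None = None) -> pd.DataFrame:
    """Load a sweep table written by :func:`write_records`."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    if fmt in ("parquet", "pq"):
        return pd.read_parquet(path)
    raise ConfigurationError(f"unknown record format {fmt!r}; use csv or parquet")
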
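"""Flat-file I/O: TSV tables with '#' metadata headers, JSON results, and
flat key-value configuration files.

All tabular artifacts are tab-separated text.  Traces carry their
acquisition metadata (sampling rate, decimation, rates, condition labels)
as ``# key: value`` header lines so that a trace file is self-describing.
Units follow the package conventions: seconds, nanometres, s^-1, nM.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dwells import DwellSet
from .schemes import RateConstants
from .simulate import Trace

__all__ = [
    "write_trace", "read_trace",
    "write_dwells", "read_dwells",
    "write_table", "read_table",
    "write_json", "read_json",
    "load_config", "save_config",
    "rates_from_config", "rates_to_config",
]


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = _coerce(v.strip())
    return meta


def _coerce(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def write_trace(trace: Trace, path) -> None:
    """Two-column TSV (time_s, extension_nm) with '#'-metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_lines(trace.meta))
        fh.write("time_s\textension_nm\n")
        np.savetxt(fh, np.column_stack([trace.t, trace.z]),
                   fmt="%.6f\t%.4f")


def read_trace(path) -> Trace:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return Trace(t=df["time_s"].to_numpy(), z=df["extension_nm"].to_numpy(),
                 meta=meta)


def write_dwells(dwells: DwellSet, path) -> None:
    """Dwell TSV: label, start_s (when known), duration_s, censored."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# t_min: {dwells.t_min}\n")
        cols = ["label", "duration_s", "censored"]
        has_starts = dwells.starts is not None
        if has_starts:
            cols.insert(1, "start_s")
        fh.write("\t".join(cols) + "\n")
        for i in range(len(dwells)):
            row = [str(dwells.labels[i])]
            if has_starts:
                row.append(f"{dwells.starts[i]:.6f}")
            row += [f"{dwells.durations[i]:.6f}", str(int(dwells.censored[i]))]
            fh.write("\t".join(row) + "\n")


def read_dwells(path) -> DwellSet:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    starts = df["start_s"].to_numpy() if "start_s" in df.columns else None
    return DwellSet(labels=df["label"].to_numpy(dtype=object),
                    durations=df["duration_s"].to_numpy(dtype=float),
                    censored=df["censored"].to_numpy(dtype=bool),
                    t_min=float(meta.get("t_min", 0.0)),
                    starts=starts)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def load_config(path) -> dict:
    """Load a flat key-value config (YAML scalars; dotted keys allowed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to scalars")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)


def rates_from_config(cfg: dict, prefix: str = "rates.") -> RateConstants:
    """Rate constants from flat config keys, e.g. ``rates.k2: 0.45`` (s^-1;
    k1 in nM^-1 s^-1, R_conc in nM)."""
    d = {k[len(prefix):]: v for k, v in cfg.items() if k.startswith(prefix)}
    return RateConstants.from_dict(d)


def rates_to_config(rates: RateConstants, prefix: str = "rates.") -> dict:
    return {prefix + k: v for k, v in rates.to_dict().items()}
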
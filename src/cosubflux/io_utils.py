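"""Deterministic tabular writers with a metadata header block.

All CSVs open with ``#``-prefixed metadata lines (package version, seed,
config hash) and serialize floats with 17 significant digits so that a
rerun with identical inputs produces byte-identical numeric payloads.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .simulate import Trajectory
from .steady_state import FeasibilityMap
from .survey import SurveyResult

__all__ = ["write_trajectory", "write_feasibility_map", "write_survey_report",
           "config_hash"]

_FLOAT_FMT = "%.17g"


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed=None, extra: Mapping | None = None) -> str:
    lines = [f"# cosubflux {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path: Path, seed=None,
               extra: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, extra))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_trajectory(traj: Trajectory, out_dir, *, seed=None,
                     stem: str = "trajectory") -> list[Path]:
    """Write trajectory (and influx events, if any) CSVs; returns manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    path = out_dir / f"{stem}.csv"
    _write_csv(traj.as_dataframe(), path, seed, traj.metadata)
    manifest.append(path)
    if traj.events:
        epath = out_dir / f"{stem}_events.csv"
        events = pd.DataFrame(traj.events, columns=["time", "kin_1", "kin_2"])
        _write_csv(events, epath, seed, traj.metadata)
        manifest.append(epath)
    return manifest


def write_feasibility_map(fmap: FeasibilityMap, path, *, seed=None) -> Path:
    """Long-format CSV: Atot, kin, feasible (1/0/-1 boundary), m0_star."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, a in enumerate(fmap.Atot):
        for j, k in enumerate(fmap.kin):
            rows.append({"Atot": a, "kin": k,
                         "feasible": int(fmap.status[i, j]),
                         "m0_star": fmap.m0_star[i, j]})
    _write_csv(pd.DataFrame(rows), path, seed)
    return path


def write_survey_report(result: SurveyResult, out_dir, *, seed=None) -> list[Path]:
    """summary.json + fits.csv + normalized_flux.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []

    summary = {"package": f"cosubflux {__version__}"}
    if seed is not None:
        summary["seed"] = seed
    summary.update(result.summary_dict())
    spath = out_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest.append(spath)

    fits = pd.DataFrame([{
        "reaction_id": f.reaction_id, "source": f.source, "n": f.n,
        "slope": f.slope, "intercept": f.intercept, "nrmse": f.nrmse,
        "pearson_r": f.pearson_r, "p_value": f.p_value,
        "q_value": f.q_value, "flag": f.flag,
    } for f in result.fits])
    fpath = out_dir / "fits.csv"
    _write_csv(fits, fpath, seed)
    manifest.append(fpath)

    npath = out_dir / "normalized_flux.csv"
    _write_csv(result.normalized_flux, npath, seed)
    manifest.append(npath)
    return manifest
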
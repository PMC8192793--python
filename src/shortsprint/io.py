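"""Reading split-time CSVs and writing the cohort report.

Input is long-format UTF-8 CSV with one row per athlete x gate:

    athlete_id,distance_m,time_s[,body_mass_kg,stature_m]

Output is a directory of four CSVs (parameters, FV profiles, bias table,
cohort summary) plus a plain-text run log echoing configuration, package
version and seed.  Numeric output uses fixed precision: 4 decimals for
seconds and m/s, 2 for percentages.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_analysis import bias_table, summarize_cohort
from .fitting import FitResult, SplitSet
from .fv_profile import FVProfile
from .model_core import CorrectionMode
from .synthetic_data import SyntheticCohort

logger = logging.getLogger("shortsprint")

__all__ = ["read_splits", "write_splits", "write_report"]

_REQUIRED = ["athlete_id", "distance_m", "time_s"]
_OPTIONAL = ["body_mass_kg", "stature_m"]


def read_splits(path: str | Path, strict: bool = True) -> list[SplitSet]:
    """Parse a long-format split CSV into per-athlete split sets.

    Rows are grouped by athlete and sorted by distance.  In strict mode the
    first invalid athlete aborts the read; in lenient mode offending
    athletes are dropped with a logged warning and a final summary count.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"athlete_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    for col in ("distance_m", "time_s"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(
                f"{path}: non-numeric value(s) in column {col!r} at file "
                f"row(s) {rows} (comma decimals are not accepted)"
            )
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["athlete_id", "distance_m"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["athlete_id", "distance_m"]].drop_duplicates()
        raise ValueError(
            f"{path}: duplicate (athlete, distance) pairs: "
            f"{[tuple(r) for r in pairs.itertuples(index=False)]}"
        )

    out: list[SplitSet] = []
    dropped = 0
    for athlete_id, grp in df.groupby("athlete_id", sort=True):
        grp = grp.sort_values("distance_m")
        mass = grp["body_mass_kg"].iloc[0] if "body_mass_kg" in grp else None
        stat = grp["stature_m"].iloc[0] if "stature_m" in grp else None
        try:
            out.append(SplitSet(
                athlete_id=str(athlete_id),
                distances=tuple(grp["distance_m"]),
                times=tuple(grp["time_s"]),
                body_mass=None if mass is None or pd.isna(mass) else float(mass),
                stature=None if stat is None or pd.isna(stat) else float(stat),
            ))
        except ValueError as exc:
            if strict:
                raise ValueError(f"{path}: {exc}") from exc
            dropped += 1
            logger.warning("dropping athlete %r: %s", athlete_id, exc)
    if dropped:
        logger.warning("read_splits: dropped %d invalid athlete(s), kept %d",
                       dropped, len(out))
    return out


def write_splits(cohort: SyntheticCohort, path: str | Path,
                 truth_path: str | Path | None = None) -> None:
    """Write a synthetic cohort in the long CSV schema ``read_splits`` reads,
    optionally with the generating truth beside it."""
    rows = []
    for s in cohort.splits:
        for d, t in zip(s.distances, s.times):
            rows.append({
                "athlete_id": s.athlete_id, "distance_m": d,
                "time_s": round(t, 10),
                "body_mass_kg": s.body_mass, "stature_m": s.stature,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    if truth_path is not None:
        cohort.truth.to_csv(truth_path, index=False)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    """Fixed output precision: 4 decimals generally, 2 for percent columns."""
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind != "f":
            continue
        decimals = 2 if col in ("rf_max", "drf") else 4
        df[col] = df[col].round(decimals)
    return df


def write_report(
    fits: dict[str, dict[CorrectionMode, FitResult]],
    profiles: dict[str, FVProfile],
    out_dir: str | Path,
    gate_distances: tuple[float, ...],
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the four report CSVs plus the run log.

    ``fits`` maps athlete id -> mode -> FitResult; ``profiles`` maps athlete
    id -> FVProfile (may be empty when anthropometrics were absent).
    Re-running with identical inputs produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    param_rows = []
    for athlete_id in sorted(fits):
        for mode, fit in fits[athlete_id].items():
            p = fit.parameters
            param_rows.append({
                "athlete_id": athlete_id, "mode": CorrectionMode(mode).value,
                "mss": p.mss, "tau": p.tau, "mac": p.mac,
                "time_correction": p.time_correction,
                "rse": fit.rse, "converged": fit.converged,
            })
    paths = {"parameters": out_dir / "parameters.csv"}
    _fmt(pd.DataFrame(param_rows)).to_csv(paths["parameters"], index=False)

    prof_rows = [{
        "athlete_id": a, "f0_rel": pr.f0_rel, "v0": pr.v0, "pmax_rel": pr.pmax_rel,
        "fv_slope": pr.fv_slope, "rf_max": pr.rf_max, "drf": pr.drf,
        "drag_k": pr.drag_k, "body_mass": pr.body_mass, "stature": pr.stature,
    } for a, pr in sorted(profiles.items())]
    paths["fv_profiles"] = out_dir / "fv_profiles.csv"
    _fmt(pd.DataFrame(prof_rows)).to_csv(paths["fv_profiles"], index=False)

    by_mode: dict[CorrectionMode, list[FitResult]] = {}
    for per_athlete in fits.values():
        for mode, fit in per_athlete.items():
            by_mode.setdefault(CorrectionMode(mode), []).append(fit)
    paths["bias"] = out_dir / "bias.csv"
    _fmt(bias_table(by_mode, gate_distances)).to_csv(paths["bias"], index=False)
    paths["summary"] = out_dir / "summary.csv"
    _fmt(summarize_cohort(by_mode)).to_csv(paths["summary"], index=False)

    paths["log"] = out_dir / "run_log.txt"
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write(f"shortsprint {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}, numpy {np.__version__}, "
                 f"pandas {pd.__version__}\n")
        fh.write(f"athletes: {len(fits)}; modes: "
                 f"{sorted({CorrectionMode(m).value for f in fits.values() for m in f})}\n")
        for key, val in sorted((config or {}).items()):
            fh.write(f"config {key} = {val}\n")
    return paths
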
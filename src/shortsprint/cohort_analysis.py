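"""Cohort-level comparison of the three correction regimes.

Provides the descriptive surface used to compare models across a cohort of
athletes: per-distance bias tables (mean and SD of the split-time residuals
at each gate), paired Cohen's d effect sizes between regimes with the
conventional magnitude bands, and the Pearson correlation of the estimated
time correction with maximal acceleration and maximal sprint speed.
Inferential machinery (repeated-measures ANOVA, post-hoc tests) is
deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitResult
from .model_core import CorrectionMode

__all__ = [
    "bias_by_distance",
    "bias_table",
    "cohens_d",
    "effect_size_label",
    "correlation_tc_vs_kinetics",
    "summarize_cohort",
]

# |d| magnitude bands; boundary ties go to the lower band.
_D_BANDS = [
    (0.2, "trivial"),
    (0.6, "small"),
    (1.20, "moderate"),
    (2.0, "large"),
    (4.0, "very large"),
]


def bias_by_distance(fits_by_mode: dict[CorrectionMode, list[FitResult]]) -> pd.DataFrame:
    """Per (mode, gate distance) bias table.

    Bias is the mean residual (observed − predicted split time, s) across
    athletes; its spread is the sample SD (reported as NaN for a single
    athlete).  All fits within a mode must share the same gate layout.
    """
    rows = []
    for mode, fits in fits_by_mode.items():
        n_gates = {len(f.residuals) for f in fits}
        if len(n_gates) != 1:
            bad = [i for i, f in enumerate(fits) if len(f.residuals) != len(fits[0].residuals)]
            raise ValueError(
                f"mode {CorrectionMode(mode).value!r}: fits at indices {bad} have a "
                "different gate layout than the first athlete"
            )
        resid = np.array([f.residuals for f in fits])  # (athletes, gates)
        # distances are implicit in gate order; caller provides them via index
        for gate in range(resid.shape[1]):
            col = resid[:, gate]
            rows.append({
                "mode": CorrectionMode(mode).value,
                "gate_index": gate,
                "bias": float(col.mean()),
                "sd": float(col.std(ddof=1)) if len(col) > 1 else math.nan,
                "n": len(col),
            })
    return pd.DataFrame(rows)


def bias_table(
    fits_by_mode: dict[CorrectionMode, list[FitResult]],
    gate_distances: tuple[float, ...],
) -> pd.DataFrame:
    """:func:`bias_by_distance` with gate indices labelled by distance (m)."""
    df = bias_by_distance(fits_by_mode)
    df["distance_m"] = [gate_distances[i] for i in df["gate_index"]]
    return df[["mode", "distance_m", "bias", "sd", "n"]]


def cohens_d(x, y) -> tuple[float, str]:
    """Paired-samples Cohen's d using the pooled SD of the two vectors.

    d = (mean(x) − mean(y)) / sd_pooled with
    sd_pooled = sqrt((var(x) + var(y)) / 2) (equal n by construction).
    Returns the signed d and the magnitude label assigned from |d|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("cohens_d requires two equal-length samples of size >= 2")
    pooled = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    if pooled == 0.0:
        raise ValueError("zero pooled SD: effect size undefined for constant samples")
    d = (x.mean() - y.mean()) / pooled
    return float(d), effect_size_label(d)


def effect_size_label(d: float) -> str:
    """Magnitude band of |d|: trivial < 0.2 <= small <= 0.6 < moderate <= 1.2
    < large <= 2.0 < very large."""
    mag = abs(d)
    for upper, label in _D_BANDS:
        if mag <= upper:
            return label
    return "extremely large"


def correlation_tc_vs_kinetics(fits: list[FitResult]) -> dict[str, float]:
    """Pearson r of the estimated time correction against MAC and MSS.

    Only meaningful for estimated-mode fits, where the correction varies
    between athletes.
    """
    if len(fits) < 3:
        raise ValueError("correlation requires at least 3 athletes")
    tc = np.array([f.parameters.time_correction for f in fits])
    mac = np.array([f.parameters.mac for f in fits])
    mss = np.array([f.parameters.mss for f in fits])
    for name, v in (("time correction", tc), ("mac", mac), ("mss", mss)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant across athletes; correlation undefined")
    return {
        "r_tc_mac": float(np.corrcoef(tc, mac)[0, 1]),
        "r_tc_mss": float(np.corrcoef(tc, mss)[0, 1]),
    }


def summarize_cohort(fits_by_mode: dict[CorrectionMode, list[FitResult]]) -> pd.DataFrame:
    """Mean (SD) of each sprint parameter per mode, plus pairwise effect sizes.

    Returns a tidy frame with one row per (mode, parameter) and one row per
    (mode pair, parameter) carrying Cohen's d and its magnitude label.
    """
    params = {
        "mss": lambda f: f.parameters.mss,
        "tau": lambda f: f.parameters.tau,
        "mac": lambda f: f.parameters.mac,
        "time_correction": lambda f: f.parameters.time_correction,
    }
    rows = []
    vectors: dict[tuple[str, str], np.ndarray] = {}
    for mode, fits in fits_by_mode.items():
        mode = CorrectionMode(mode)
        for name, get in params.items():
            v = np.array([get(f) for f in fits])
            vectors[(mode.value, name)] = v
            rows.append({
                "kind": "summary", "mode": mode.value, "parameter": name,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else math.nan,
                "d": math.nan, "label": "",
            })
    modes = [CorrectionMode(m).value for m in fits_by_mode]
    for i, m1 in enumerate(modes):
        for m2 in modes[i + 1:]:
            for name in params:
                x, y = vectors[(m1, name)], vectors[(m2, name)]
                if np.allclose(x, y):
                    continue  # e.g. time_correction identical under none/fixed
                try:
                    d, label = cohens_d(x, y)
                except ValueError:
                    continue  # constant vectors (tc under none or fixed mode)
                rows.append({
                    "kind": "contrast", "mode": f"{m1} vs {m2}", "parameter": name,
                    "mean": math.nan, "sd": math.nan, "d": d, "label": label,
                })
    return pd.DataFrame(rows)
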
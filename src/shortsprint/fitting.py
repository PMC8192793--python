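"""Non-linear least-squares estimation of sprint parameters from gate splits.

Three correction regimes are supported:

* ``none``      — two free parameters (MSS, TAU), time correction fixed at 0;
* ``fixed``     — two free parameters, time correction fixed a priori
                  (conventionally +0.3 s for start-line gates);
* ``estimated`` — three free parameters (MSS, TAU, tc), the correction
                  estimated jointly with the kinematics.

The objective in every mode is the unweighted sum of squared differences
between observed cumulative gate times and the model's gate-clock split
times.  Fitting is deterministic: no random numbers are used, and results
are invariant to the ordering of input gate rows (sorted internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model_core import CorrectionMode, SprintParameters, time_at_distance

__all__ = [
    "SplitSet",
    "FitResult",
    "FitBounds",
    "fit_splits",
    "initial_values",
    "compare_modes",
]

# Max physically plausible segment speed for human sprinting, m/s.
_MAX_SEGMENT_SPEED = 13.0


@dataclass(frozen=True)
class SplitSet:
    """Gate distances and cumulative times for one athlete's best sprint."""

    athlete_id: str
    distances: tuple[float, ...]
    times: tuple[float, ...]
    body_mass: float | None = None
    stature: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if d.size != t.size or d.size < 2:
            raise ValueError(
                f"athlete {self.athlete_id!r}: need >= 2 gates with matching "
                f"distances/times, got {d.size}/{t.size}"
            )
        order = np.argsort(d)
        d, t = d[order], t[order]
        if not (np.all(d > 0) and np.all(np.diff(d) > 0)):
            raise ValueError(
                f"athlete {self.athlete_id!r}: gate distances must be positive "
                "and strictly increasing"
            )
        if not (np.all(t > 0) and np.all(np.diff(t) > 0)):
            raise ValueError(
                f"athlete {self.athlete_id!r}: gate times must be positive and "
                "strictly increasing with distance"
            )
        seg_speed = np.diff(d, prepend=0.0) / np.diff(t, prepend=0.0)
        if np.any(seg_speed >= _MAX_SEGMENT_SPEED):
            raise ValueError(
                f"athlete {self.athlete_id!r}: implied segment speed "
                f"{seg_speed.max():.1f} m/s is not physically plausible "
                f"(limit {_MAX_SEGMENT_SPEED} m/s)"
            )
        object.__setattr__(self, "distances", tuple(d))
        object.__setattr__(self, "times", tuple(t))

    @property
    def n_gates(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class FitResult:
    """Parameters, residuals and convergence diagnostics for one model fit."""

    parameters: SprintParameters
    predicted_times: tuple[float, ...]
    residuals: tuple[float, ...]          # observed - predicted, gate order
    rse: float                            # sqrt(SSR / (n - p))
    converged: bool
    n_iterations: int
    mode: CorrectionMode
    fixed_correction_value: float | None = None

    @property
    def ssr(self) -> float:
        return float(np.dot(self.residuals, self.residuals))


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the optimiser, wide enough not to bind on
    plausible sprint data."""

    mss: tuple[float, float] = (2.0, 12.0)
    tau: tuple[float, float] = (0.05, 3.0)
    tc: tuple[float, float] = (-0.5, 1.0)


_DEFAULT_BOUNDS = FitBounds()
_MAX_NFEV = 500


def initial_values(splits: SplitSet, mode: CorrectionMode | str) -> np.ndarray:
    """Starting parameter vector [mss0, tau0(, tc0)] for the optimiser.

    mss0 is 1.1x the last segment's average speed; tau0 is the first gate
    time minus the time that gate would take at mss0, clamped to [0.3, 1.5] s
    so degenerate inputs still give finite, in-bounds starts.
    """
    mode = CorrectionMode(mode)
    d = np.asarray(splits.distances)
    t = np.asarray(splits.times)
    last_speed = (d[-1] - d[-2]) / (t[-1] - t[-2]) if len(d) >= 2 else d[-1] / t[-1]
    mss0 = float(np.clip(1.1 * last_speed, *_DEFAULT_BOUNDS.mss))
    tau0 = float(np.clip(t[0] - d[0] / mss0, 0.3, 1.5))
    if mode == CorrectionMode.ESTIMATED:
        return np.array([mss0, tau0, 0.2])
    return np.array([mss0, tau0])


def _required_gates(mode: CorrectionMode) -> int:
    return 4 if mode == CorrectionMode.ESTIMATED else 3


def _n_free(mode: CorrectionMode) -> int:
    return 3 if mode == CorrectionMode.ESTIMATED else 2


def fit_splits(
    splits: SplitSet,
    mode: CorrectionMode | str = CorrectionMode.ESTIMATED,
    fixed_correction: float = 0.3,
    bounds: FitBounds = _DEFAULT_BOUNDS,
) -> FitResult:
    """Fit the sprint model to one athlete's splits under one regime.

    Minimises ``sum((observed - predicted gate time)^2)`` over (MSS, TAU) for
    modes ``none``/``fixed`` — the former is the latter with correction 0 —
    or over (MSS, TAU, tc) for mode ``estimated``.  Bounded trust-region
    least squares; one restart from perturbed starting values (mss0 * 1.2)
    before a non-converged result is flagged, never raised silently.
    """
    mode = CorrectionMode(mode)
    if splits.n_gates <= _n_free(mode):
        raise ValueError(
            f"mode {mode.value!r} needs at least {_required_gates(mode)} gates "
            f"(free parameters: {_n_free(mode)}); athlete {splits.athlete_id!r} "
            f"has {splits.n_gates}"
        )
    d = np.asarray(splits.distances)
    t_obs = np.asarray(splits.times)
    tc_fixed = {CorrectionMode.NONE: 0.0, CorrectionMode.FIXED: float(fixed_correction)}.get(mode)

    def predict(theta: np.ndarray) -> np.ndarray:
        mss, tau = theta[0], theta[1]
        tc = theta[2] if mode == CorrectionMode.ESTIMATED else tc_fixed
        p = SprintParameters(mss, tau, tc, correction_mode=mode)
        return np.asarray(time_at_distance(p, d))

    def residual(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - t_obs

    if mode == CorrectionMode.ESTIMATED:
        lb = [bounds.mss[0], bounds.tau[0], bounds.tc[0]]
        ub = [bounds.mss[1], bounds.tau[1], bounds.tc[1]]
    else:
        lb = [bounds.mss[0], bounds.tau[0]]
        ub = [bounds.mss[1], bounds.tau[1]]

    x0 = initial_values(splits, mode)
    sol = least_squares(residual, x0, bounds=(lb, ub),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV)
    n_iter = int(sol.nfev)
    if not sol.success:
        x0_retry = x0.copy()
        x0_retry[0] = np.clip(x0_retry[0] * 1.2, *bounds.mss)
        sol = least_squares(residual, x0_retry, bounds=(lb, ub),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV)
        n_iter += int(sol.nfev)

    theta = sol.x
    tc = float(theta[2]) if mode == CorrectionMode.ESTIMATED else float(tc_fixed)
    params = SprintParameters(float(theta[0]), float(theta[1]), tc, correction_mode=mode)
    predicted = predict(theta)
    resid = t_obs - predicted
    dof = splits.n_gates - _n_free(mode)
    rse = float(np.sqrt(np.dot(resid, resid) / dof))
    return FitResult(
        parameters=params,
        predicted_times=tuple(float(x) for x in predicted),
        residuals=tuple(float(x) for x in resid),
        rse=rse,
        converged=bool(sol.success),
        n_iterations=n_iter,
        mode=mode,
        fixed_correction_value=float(fixed_correction) if mode == CorrectionMode.FIXED else None,
    )


def compare_modes(
    splits: SplitSet, fixed_correction: float = 0.3
) -> dict[CorrectionMode, FitResult]:
    """Fit all three correction regimes to identical data.

    Returns a dict ordered none -> fixed -> estimated.  Errors raised by a
    single regime are annotated with the regime's name.
    """
    out: dict[CorrectionMode, FitResult] = {}
    for mode in (CorrectionMode.NONE, CorrectionMode.FIXED, CorrectionMode.ESTIMATED):
        try:
            out[mode] = fit_splits(splits, mode, fixed_correction=fixed_correction)
        except ValueError as exc:
            raise ValueError(f"[mode {mode.value}] {exc}") from exc
    return out
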
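"""Closed-form kinematics of the mono-exponential short-sprint model.

The model describes an athlete's horizontal velocity during a maximal short
sprint as

    v(t) = MSS * (1 - exp(-t / TAU))

where MSS is the maximal sprinting speed (m/s) and TAU the time constant (s):
the time needed to reach 63.2% of MSS.  Maximal acceleration is the derived
quantity MAC = MSS / TAU, the model's acceleration at t = 0.

Integrating v(t) gives distance as a function of time; inverting that with
Lambert's W function gives the split time a gate at distance ``d`` would
record.  Timing gates placed at the start line trigger *after* first force
production, so gate-clock time lags model time by a per-sprint correction:

    t_gate(d) = TAU * W0(-exp(-d/(MSS*TAU) - 1)) + d/MSS + TAU - tc

All public split-time operations use gate-clock time; internal model time is
measured from first force production.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

__all__ = [
    "CorrectionMode",
    "SprintParameters",
    "velocity_at_time",
    "acceleration_at_time",
    "distance_at_time",
    "time_at_distance",
]


class CorrectionMode(str, enum.Enum):
    """How the start-gate lag is handled when modelling split times."""

    NONE = "none"
    FIXED = "fixed"
    ESTIMATED = "estimated"


@dataclass(frozen=True)
class SprintParameters:
    """Fitted description of one sprint.

    Parameters
    ----------
    mss
        Maximal sprinting speed, m/s. Must be positive.
    tau
        Time constant of the velocity curve, s. Must be positive.
    time_correction
        Lag between first force production and the start-gate trigger, s.
        Subtracted from model time to yield gate-clock time. 0 when absent.
    correction_mode
        Regime under which ``time_correction`` was obtained.
    """

    mss: float
    tau: float
    time_correction: float = 0.0
    correction_mode: CorrectionMode = CorrectionMode.NONE

    def __post_init__(self) -> None:
        if not (self.mss > 0):
            raise ValueError(f"mss must be positive, got {self.mss}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.correction_mode == CorrectionMode.NONE and self.time_correction != 0.0:
            raise ValueError(
                "correction_mode 'none' requires time_correction == 0, "
                f"got {self.time_correction}"
            )

    @property
    def mac(self) -> float:
        """Maximal acceleration MSS / TAU, m/s²; never stored independently."""
        return self.mss / self.tau


def _check_nonnegative(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {x}")
    return arr


def velocity_at_time(p: SprintParameters, t):
    """Instantaneous horizontal velocity (m/s) at model time ``t`` (s).

    ``t`` is elapsed time since first force production.  Accepts scalars or
    arrays; strictly increasing in ``t`` and bounded above by ``p.mss``.
    """
    t = _check_nonnegative(t, "t")
    out = p.mss * (-np.expm1(-t / p.tau))
    return float(out) if out.ndim == 0 else out


def acceleration_at_time(p: SprintParameters, t):
    """Horizontal acceleration (m/s²) at model time ``t`` (s).

    Equals ``p.mac`` at t = 0 and decays exponentially to zero.
    """
    t = _check_nonnegative(t, "t")
    out = (p.mss / p.tau) * np.exp(-t / p.tau)
    return float(out) if out.ndim == 0 else out


def distance_at_time(p: SprintParameters, t):
    """Distance covered (m) after model time ``t`` (s).

    Closed form of the integral of the velocity curve:
    ``d(t) = mss*t - mss*tau*(1 - exp(-t/tau))``.
    """
    t = _check_nonnegative(t, "t")
    out = p.mss * t + p.mss * p.tau * np.expm1(-t / p.tau)
    return float(out) if out.ndim == 0 else out


# Beyond this exponent the W0 term underflows; its true magnitude is < 1e-300 s.
_W_UNDERFLOW = 700.0


def time_at_distance(p: SprintParameters, d):
    """Gate time (s) at which the athlete passes distance ``d`` (m).

    Inverts ``distance_at_time`` via the principal branch W0 of Lambert's W
    (the argument ``-exp(-d/(mss*tau) - 1)`` lies in (-1/e, 0] for d >= 0,
    where only W0 yields t = 0 at d = 0 and monotone times), then subtracts
    the time correction to convert model time to gate-clock time.

    With a positive correction, ``time_at_distance(p, 0)`` is ``-tc``: the
    model legitimately places first movement before the gate trigger.
    """
    d = _check_nonnegative(d, "d")
    x = d / (p.mss * p.tau)
    with np.errstate(under="ignore"):
        arg = -np.exp(-x - 1.0)
    # at d = 0 the argument sits on the branch point -1/e, where W0 = -1
    # exactly but the numeric evaluation returns nan; handle it explicitly
    at_branch = arg <= -np.exp(-1.0)
    w = np.real(lambertw(np.where(at_branch, -0.5, arg), k=0))
    w = np.where(at_branch, -1.0, w)
    w = np.where(x > _W_UNDERFLOW, 0.0, w)
    out = p.tau * w + d / p.mss + p.tau - p.time_correction
    return float(out) if out.ndim == 0 else out
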
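"""Force-velocity-power profiling of a modelled sprint.

Given fitted sprint parameters and the athlete's body mass and stature, the
horizontal ground-reaction force is reconstructed at each instant of the
modelled sprint as inertial force plus aerodynamic drag,

    F_h(t) = m * a(t) + k * v(t)^2,

with the drag constant k estimated from stature, mass and air density via a
frontal-area regression.  A straight line fitted to the (v, F_h/m) samples
gives the profile intercepts: F0 (theoretical maximal relative horizontal
force, N/kg), V0 (theoretical maximal velocity, the zero crossing of the
F-v line, m/s), from which Pmax = F0*V0/4 (apex of the parabolic
power-velocity relation) and the FV slope = -F0/V0.  The ratio of force
RF = F_h / sqrt(F_h^2 + (m*g)^2) is evaluated from 0.3 s onward (excluding
the initial push phase); RFmax is its value at 0.3 s and DRF the slope of
the linear RF-v fit, in percent per m/s.

All drag-model constants (Cd = 0.9, the frontal-area regression, the air
density formula) are the conventional field-method values, pinned here as
defaults and overridable through :class:`AirConditions`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    SprintParameters,
    acceleration_at_time,
    time_at_distance,
    velocity_at_time,
)

__all__ = [
    "AirConditions",
    "FVProfile",
    "drag_constant",
    "horizontal_force_at_time",
    "compute_fv_profile",
]

G = 9.81               # m/s²
DRAG_COEFFICIENT = 0.9
RF_WINDOW_START = 0.3  # s of model time excluded as the initial push phase
DEFAULT_DT = 0.001     # s, sampling grid (convergence-tested)
SPRINT_DISTANCE = 35.0 # m, default modelled sprint length


@dataclass(frozen=True)
class AirConditions:
    """Ambient air state for the drag model.

    Air density follows ρ = 1.293 · (P/760) · 273/(273 + T) kg/m³, which at
    the defaults (20 °C, 760 mmHg) gives ≈ 1.205 kg/m³.
    """

    temperature: float = 20.0          # °C
    barometric_pressure: float = 760.0 # mmHg

    @property
    def air_density(self) -> float:
        rho = 1.293 * (self.barometric_pressure / 760.0) * 273.0 / (273.0 + self.temperature)
        if not rho > 0:
            raise ValueError("air density must be positive; check temperature/pressure")
        return rho


@dataclass(frozen=True)
class FVProfile:
    """Force-velocity-power metrics of one modelled sprint."""

    f0_rel: float     # N/kg
    v0: float         # m/s
    pmax_rel: float   # W/kg
    fv_slope: float   # N·s/m/kg
    rf_max: float     # %
    drf: float        # % per m/s
    drag_k: float     # N·s²/m² (absolute)
    body_mass: float  # kg
    stature: float    # m


def drag_constant(
    body_mass: float, stature: float, air: AirConditions = AirConditions()
) -> float:
    """Aerodynamic drag constant k (N·s²/m²) for a running human.

    Frontal area from the stature/mass regression
    A = (0.2025 · h^0.725 · m^0.425) · 0.266; k = 0.5 · ρ · A · Cd.
    """
    if body_mass is None or stature is None:
        raise ValueError(
            "force-velocity profiling requires body mass (kg) and stature (m)"
        )
    if not (30.0 <= body_mass <= 150.0):
        raise ValueError(f"body mass {body_mass} kg outside plausible range [30, 150]")
    if not (1.2 <= stature <= 2.2):
        raise ValueError(f"stature {stature} m outside plausible range [1.2, 2.2]")
    area = (0.2025 * stature**0.725 * body_mass**0.425) * 0.266
    return 0.5 * air.air_density * area * DRAG_COEFFICIENT


def horizontal_force_at_time(
    p: SprintParameters, body_mass: float, drag_k: float, t
):
    """Total horizontal force F_h(t) = m·a(t) + k·v(t)², in N (absolute).

    Equals ``m * mac`` at t = 0 (drag vanishes with velocity) and tends to
    the drag-only plateau ``k * mss²`` as t grows.
    """
    a = acceleration_at_time(p, t)
    v = velocity_at_time(p, t)
    return body_mass * a + drag_k * v**2


def compute_fv_profile(
    p: SprintParameters,
    body_mass: float,
    stature: float,
    air: AirConditions = AirConditions(),
    duration: float | None = None,
    dt: float = DEFAULT_DT,
) -> FVProfile:
    """Derive the full force-velocity-power profile from fitted parameters.

    The sprint is sampled on a uniform grid of model time from 0 to
    ``duration`` (default: the model time needed to cover 35 m).  F0 and V0
    come from an ordinary least-squares line through all (v, F_h/m) samples;
    RFmax and DRF use only the samples at t >= 0.3 s.

    With ``drag_k = 0`` the F-v relation is exactly linear —
    ``a(v) = mac * (1 - v/mss)`` — so F0 equals MAC and V0 equals MSS.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if duration is None:
        # model time to cover the sprint distance: gate time + correction
        duration = time_at_distance(p, SPRINT_DISTANCE) + p.time_correction
    if duration <= RF_WINDOW_START:
        raise ValueError(
            f"duration must exceed {RF_WINDOW_START} s to evaluate RF metrics, "
            f"got {duration}"
        )
    k = drag_constant(body_mass, stature, air)

    t = np.arange(0.0, duration + 0.5 * dt, dt)
    v = velocity_at_time(p, t)
    f_rel = horizontal_force_at_time(p, body_mass, k, t) / body_mass

    slope, f0_rel = np.polyfit(v, f_rel, 1)
    v0 = -f0_rel / slope
    pmax_rel = f0_rel * v0 / 4.0
    fv_slope = -f0_rel / v0

    window = t >= RF_WINDOW_START
    f_abs = f_rel[window] * body_mass
    rf = 100.0 * f_abs / np.hypot(f_abs, body_mass * G)
    rf_max = float(rf[0])
    drf = float(np.polyfit(v[window], rf, 1)[0])

    return FVProfile(
        f0_rel=float(f0_rel),
        v0=float(v0),
        pmax_rel=float(pmax_rel),
        fv_slope=float(fv_slope),
        rf_max=rf_max,
        drf=drf,
        drag_k=k,
        body_mass=float(body_mass),
        stature=float(stature),
    )
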
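"""Antagonistic pneumatic-muscle joint model.

Implements the braided (McKibben-type) muscle force law
``F = P * [a * (1 - eps)^2 - b]`` with ``a = 3*pi*D0^2 / (4*tan^2 theta0)``
and ``b = pi*D0^2 / (4*sin^2 theta0)``, the kinematic coupling between
elbow angle and the two muscles' contraction rates, the forward force
computation of the pressurised pair, the inverse map from a force pair
back to the differential pressure, and the conversion of a target angle
into a valve command.

Angles are degrees at the API surface; pressures Pa, lengths m, forces N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidConfigurationError,
    InvalidInputError,
    RangeExceededError,
    SaturationError,
    SingularConfigurationError,
)

GRAVITY_M_S2 = 9.81

#: Force-closure rules accepted by :func:`angle_to_command`.
CLOSURES = ("balance", "antagonist_hold", "symmetric")


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one pneumatic muscle.

    Defaults: 20 mm initial diameter, 25 degree initial braiding angle,
    25% maximum contraction rate, 0.6 MPa pressure ceiling.
    """

    D0_m: float = 0.020
    theta0_deg: float = 25.0
    eps_max: float = 0.25
    P_max_Pa: float = 0.6e6

    def __post_init__(self) -> None:
        if not (0 < self.theta0_deg < 90):
            raise InvalidConfigurationError("theta0_deg must lie in (0, 90)")
        if self.D0_m <= 0 or self.P_max_Pa <= 0:
            raise InvalidConfigurationError("D0_m and P_max_Pa must be positive")
        if not (0 < self.eps_max < 1):
            raise InvalidConfigurationError("eps_max must lie in (0, 1)")

    @property
    def a_m2(self) -> float:
        th = math.radians(self.theta0_deg)
        return 3.0 * math.pi * self.D0_m**2 / (4.0 * math.tan(th) ** 2)

    @property
    def b_m2(self) -> float:
        th = math.radians(self.theta0_deg)
        return math.pi * self.D0_m**2 / (4.0 * math.sin(th) ** 2)

    @property
    def eps_zero_force(self) -> float:
        """Contraction rate where force vanishes: 1 - 1/(sqrt(3)*cos theta0)."""
        return 1.0 - 1.0 / (math.sqrt(3.0) * math.cos(math.radians(self.theta0_deg)))


@dataclass(frozen=True)
class JointGeometry:
    """Joint and muscle-mounting constants of the antagonistic pair.

    The 0.03 m radius matches a 6 cm diameter joint axis. ``L0_m``,
    ``eps0`` and ``P0_Pa`` describe the balanced initial state in which
    both muscles sit at equal pressure, length and force; the defaults
    are chosen so the full 0-90 degree range stays inside a 25% maximum
    contraction rate and the 0.6 MPa ceiling.
    """

    R_m: float = 0.03
    L0_m: float = 0.40
    eps0: float = 0.125
    P0_Pa: float = 0.3e6
    theta2_range_deg: tuple[float, float] = (0.0, 90.0)
    forearm_length_m: float = 0.25
    load_kg: float = 1.0

    def __post_init__(self) -> None:
        if self.R_m <= 0 or self.L0_m <= 0:
            raise InvalidConfigurationError("R_m and L0_m must be positive")
        if self.P0_Pa < 0:
            raise InvalidConfigurationError("P0_Pa must be >= 0")
        lo, hi = self.theta2_range_deg
        if not hi > lo:
            raise InvalidConfigurationError("theta2_range_deg must be increasing")

    def check_reachable(self, params: MuscleParams) -> None:
        """Raise if the extreme angle violates the contraction limits."""
        hi = self.theta2_range_deg[1]
        dl = delta_length(hi, self)
        if self.eps0 + dl / self.L0_m > params.eps_max:
            raise InvalidConfigurationError(
                "agonist exceeds eps_max at the range limit; joint unreachable"
            )
        if self.eps0 - dl / self.L0_m < 0:
            raise InvalidConfigurationError(
                "antagonist would need negative contraction at the range limit"
            )

    def f0_N(self, params: MuscleParams) -> float:
        """Balanced initial contraction force F0 = P0 * [a*(1-eps0)^2 - b]."""
        return muscle_force(self.P0_Pa, self.eps0, params)


@dataclass(frozen=True)
class ActuatorCommand:
    """One resolved command for the antagonistic pair."""

    theta2_deg: float
    dP_Pa: float
    Pa_Pa: float
    Pb_Pa: float
    voltage_V: float


def muscle_force(P_Pa: float, eps: float, params: MuscleParams) -> float:
    """Contraction force F = P * [a*(1-eps)^2 - b].

    Linear in pressure; decreasing in contraction rate. Negative beyond
    the zero-force contraction rate — callers keep eps in range.
    """
    eps = float(eps)
    if not (0.0 <= eps < 1.0):
        raise InvalidInputError(f"contraction rate must lie in [0, 1), got {eps}")
    if P_Pa < 0:
        raise InvalidInputError(f"pressure must be >= 0, got {P_Pa}")
    return P_Pa * (params.a_m2 * (1.0 - eps) ** 2 - params.b_m2)


def delta_length(theta2_deg: float, geom: JointGeometry) -> float:
    """Arc length wound onto the joint axis: dL = theta2 * pi * R / 180."""
    return float(theta2_deg) * math.pi * geom.R_m / 180.0


def contraction_rates(
    theta2_deg: float,
    geom: JointGeometry,
    eps_max: float | None = None,
) -> tuple[float, float]:
    """(eps_a, eps_b) = eps0 +/- dL/L0 for the agonist/antagonist.

    With ``eps_max`` given, violations raise naming the offending muscle.
    """
    dl = delta_length(theta2_deg, geom)
    eps_a = geom.eps0 + dl / geom.L0_m
    eps_b = geom.eps0 - dl / geom.L0_m
    if eps_max is not None and eps_a > eps_max + 1e-12:
        raise RangeExceededError(
            f"agonist contraction {eps_a:.4f} exceeds eps_max={eps_max}"
        )
    if eps_b < -1e-12:
        raise RangeExceededError(f"antagonist contraction {eps_b:.4f} is negative")
    return eps_a, eps_b


def _denominators(
    theta2_deg: float, geom: JointGeometry, params: MuscleParams
) -> tuple[float, float]:
    eps_a, eps_b = contraction_rates(theta2_deg, geom)
    da = params.a_m2 * (1.0 - eps_a) ** 2 - params.b_m2
    db = params.a_m2 * (1.0 - eps_b) ** 2 - params.b_m2
    return da, db


def pair_forces(
    theta2_deg: float,
    dP_Pa: float,
    geom: JointGeometry,
    params: MuscleParams,
) -> tuple[float, float]:
    """Forward force pair at pressures P0 + dP (agonist) and P0 - dP."""
    Pa = geom.P0_Pa + dP_Pa
    Pb = geom.P0_Pa - dP_Pa
    if not (0.0 <= Pa <= params.P_max_Pa) or not (0.0 <= Pb <= params.P_max_Pa):
        raise SaturationError(
            f"absolute pressures ({Pa:.0f}, {Pb:.0f}) Pa leave [0, {params.P_max_Pa:.0f}]"
        )
    eps_a, eps_b = contraction_rates(theta2_deg, geom, eps_max=params.eps_max)
    return muscle_force(Pa, eps_a, params), muscle_force(Pb, eps_b, params)


def pressure_signal(
    theta2_deg: float,
    F_a: float,
    F_b: float,
    geom: JointGeometry,
    params: MuscleParams,
) -> float:
    """Invert the force pair to the differential pressure.

    dP = F_a / (2*[a*(1-eps_a)^2 - b]) - F_b / (2*[a*(1-eps_b)^2 - b]).
    """
    da, db = _denominators(theta2_deg, geom, params)
    if abs(da) < 1e-15 or abs(db) < 1e-15:
        raise SingularConfigurationError(
            "contraction rate at the zero-force point; pressure undefined"
        )
    return F_a / (2.0 * da) - F_b / (2.0 * db)


def _closure_forces(
    theta2_deg: float,
    geom: JointGeometry,
    params: MuscleParams,
    closure: str,
) -> tuple[float, float]:
    """Pick the (F_a, F_b) pair the pressure inversion operates on.

    The load torque is the gravitational moment of the held mass about
    the elbow: m * g * l * sin(theta2).
    """
    da, db = _denominators(theta2_deg, geom, params)
    torque = (
        geom.load_kg
        * GRAVITY_M_S2
        * geom.forearm_length_m
        * math.sin(math.radians(theta2_deg))
    )
    net = torque / geom.R_m  # required F_a - F_b
    if closure == "balance":
        # both pressures move as P0 +/- dP and the pair balances the load:
        # (P0+dP)*da - (P0-dP)*db = net  =>  solve for dP, then Eqs. 5-6
        if abs(da + db) < 1e-15:
            raise SingularConfigurationError("degenerate pair stiffness")
        dP = (net + geom.P0_Pa * (db - da)) / (da + db)
        return (geom.P0_Pa + dP) * da, (geom.P0_Pa - dP) * db
    if closure == "antagonist_hold":
        # antagonist stays at supply pressure P0 at its new length
        F_b = geom.P0_Pa * db
        return F_b + net, F_b
    if closure == "symmetric":
        # constant co-contraction about the balanced initial force F0
        F0 = geom.f0_N(params)
        return F0 + net / 2.0, F0 - net / 2.0
    raise InvalidConfigurationError(f"unknown closure {closure!r}; pick one of {CLOSURES}")


def pressure_to_voltage(
    dP_Pa: float,
    dP_max_Pa: float,
    table: np.ndarray | None = None,
    clamp: bool = False,
) -> float:
    """Map a differential pressure onto the 0-10 V valve command.

    Default map is affine: [-dP_max, +dP_max] onto [0, 10] V with 5 V at
    dP = 0. A user calibration curve may be supplied as a strictly
    monotone (dP, V) table, linearly interpolated.
    """
    if dP_max_Pa <= 0:
        raise InvalidConfigurationError("dP_max_Pa must be positive")
    if abs(dP_Pa) > dP_max_Pa:
        if not clamp:
            raise SaturationError(
                f"|dP| = {abs(dP_Pa):.0f} Pa exceeds headroom {dP_max_Pa:.0f} Pa"
            )
        dP_Pa = math.copysign(dP_max_Pa, dP_Pa)
    if table is not None:
        table = np.asarray(table, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
            raise InvalidConfigurationError("calibration table must be (n>=2, 2)")
        if np.any(np.diff(table[:, 0]) <= 0):
            raise InvalidConfigurationError("calibration pressures must increase")
        return float(np.interp(dP_Pa, table[:, 0], table[:, 1]))
    return 5.0 + 5.0 * dP_Pa / dP_max_Pa


def angle_to_command(
    theta2_deg: float,
    geom: JointGeometry,
    params: MuscleParams,
    closure: str = "balance",
    table: np.ndarray | None = None,
    clamp: bool = False,
) -> ActuatorCommand:
    """Resolve a target elbow angle into a full actuator command.

    Chooses the force pair via ``closure``, inverts it to dP, bounds the
    absolute pressures by the ceiling, and maps dP to a valve voltage.
    With ``clamp`` (the streaming-controller mode) out-of-range
    pressures saturate instead of raising.
    """
    lo, hi = geom.theta2_range_deg
    if not (lo <= theta2_deg <= hi):
        raise InvalidInputError(
            f"theta2 = {theta2_deg} deg outside range [{lo}, {hi}]"
        )
    F_a, F_b = _closure_forces(theta2_deg, geom, params, closure)
    dP = pressure_signal(theta2_deg, F_a, F_b, geom, params)
    head = min(geom.P0_Pa, params.P_max_Pa - geom.P0_Pa)
    if head <= 0:
        raise InvalidConfigurationError("P0 leaves no differential-pressure headroom")
    if abs(dP) > head and not clamp:
        raise SaturationError(
            f"closure {closure!r} needs |dP| = {abs(dP):.0f} Pa, headroom is {head:.0f} Pa"
        )
    dP_c = max(-head, min(head, dP))
    return ActuatorCommand(
        theta2_deg=float(theta2_deg),
        dP_Pa=dP_c,
        Pa_Pa=geom.P0_Pa + dP_c,
        Pb_Pa=geom.P0_Pa - dP_c,
        voltage_V=pressure_to_voltage(dP_c, head, table=table, clamp=clamp),
    )
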
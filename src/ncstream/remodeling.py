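"""FN secretion timing, fiber assembly from puncta, and fiber reorientation.

Secretory cells deposit new FN puncta at their centers at exponentially
distributed intervals, gated on currently sensing at least one other FN
element. Any cell allowed to remodel converts puncta it covers (within
``R_cell``) into fibers aligned with its velocity, and relaxes the
orientation of covered fibers toward its heading with half-angle time
``T_half``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FnElement",
    "SecretionSchedule",
    "sample_secretion_interval",
    "secretion_due",
    "attempt_secretion",
    "assemble_fiber",
    "reorient_fiber",
    "fiber_angle_exact",
    "wrap_angle",
]

LN2 = math.log(2.0)


@dataclass
class FnElement:
    """A fibronectin element: an unoriented punctum or an oriented fiber."""

    position: np.ndarray
    kind: str = "punctum"          # "punctum" | "fiber"
    phi: float | None = None       # orientation in (−π, π], fibers only

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.kind == "fiber":
            if self.phi is None:
                raise ValueError("fibers require an orientation")
            self.phi = wrap_angle(float(self.phi))
        elif self.phi is not None:
            raise ValueError("puncta carry no orientation")


@dataclass
class SecretionSchedule:
    """Per-cell deposition clock: last event time and sampled interval."""

    t_last: float
    t_r: float


def sample_secretion_interval(T_ave: float, rng: np.random.Generator) -> float:
    """Draw a positive waiting interval with mean ``T_ave`` (exponential)."""
    if T_ave <= 0:
        raise ValueError("T_ave must be positive")
    return float(rng.exponential(T_ave))


def secretion_due(schedule: SecretionSchedule, t: float, sensed_any_fn: bool) -> bool:
    """Deposition fires iff the interval elapsed AND the cell senses FN."""
    return sensed_any_fn and (t - schedule.t_last) >= schedule.t_r


def attempt_secretion(
    cell_position: np.ndarray,
    schedule: SecretionSchedule,
    t: float,
    sensed_any_fn: bool,
    T_ave: float,
    rng: np.random.Generator,
) -> FnElement | None:
    """Deposit a punctum at the cell center if the clock and gate allow.

    On deposition the schedule is updated in place (``t_last = t`` and a
    fresh interval is drawn); otherwise nothing changes.
    """
    if not secretion_due(schedule, t, sensed_any_fn):
        return None
    schedule.t_last = t
    schedule.t_r = sample_secretion_interval(T_ave, rng)
    return FnElement(np.array(cell_position, dtype=float), "punctum")


def assemble_fiber(
    punctum: FnElement,
    cell_velocity: np.ndarray,
    remodeling_allowed: bool = True,
) -> FnElement:
    """Convert a covered punctum into a fiber along the cell velocity.

    Cells at rest (zero velocity) have no defined heading and leave the
    punctum unchanged, as does a remodeling knockout.
    """
    vx, vy = float(cell_velocity[0]), float(cell_velocity[1])
    if not remodeling_allowed or (vx == 0.0 and vy == 0.0):
        return punctum
    return FnElement(punctum.position.copy(), "fiber", math.atan2(vy, vx))


def wrap_angle(phi: float) -> float:
    """Wrap an angle to (−π, π]."""
    wrapped = (phi + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if wrapped == -math.pi else wrapped


def reorient_fiber(phi: float, theta: float, dt: float, T_half: float) -> float:
    """One Euler step of dφ/dt = (ln 2 / T_half) sin(θ − φ), wrapped.

    θ is the covering cell's heading. φ = θ is a stable fixed point with
    linearized decay time ``T_half / ln 2`` (i.e. the misalignment angle
    halves every ``T_half`` minutes); φ = θ + π is the unstable antipodal
    equilibrium and is left unchanged.
    """
    if dt <= 0 or T_half <= 0:
        raise ValueError("dt and T_half must be positive")
    return wrap_angle(phi + dt * (LN2 / T_half) * math.sin(theta - phi))


def fiber_angle_exact(phi0: float, theta: float, t: float, T_half: float) -> float:
    """Closed-form solution of the reorientation ODE (tests/oracle).

    Separation of variables gives
    ``tan((θ − φ(t))/2) = tan((θ − φ0)/2) · exp(−t ln2 / T_half)``.
    """
    delta0 = wrap_angle(theta - phi0)
    if abs(abs(delta0) - math.pi) < 1e-12:
        return wrap_angle(phi0)
    delta = 2.0 * math.atan(math.tan(delta0 / 2.0) * math.exp(-t * LN2 / T_half))
    return wrap_angle(theta - delta)
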
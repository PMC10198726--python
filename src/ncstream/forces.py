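"""Per-cell force laws: haptotaxis, contact guidance, repulsion, velocity.

These are the reference (single-cell) implementations of the force model.
The simulation engine evaluates the same quantities vectorized across all
cells; agreement between the two paths is enforced by tests.

Directional cues are stochastic: the haptotaxis and repulsion headings are
drawn from von Mises distributions whose mean is the direction of a
Gaussian-kernel density gradient and whose concentration is the gradient
norm, so a cell surrounded symmetrically by sources turns at random while
a cell next to a strong density imbalance heads almost deterministically
up (or, for repulsion, down) the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import GuidingScope, SimulationParameters

__all__ = [
    "ForceSample",
    "gaussian_kernel_gradient",
    "sample_von_mises",
    "haptotaxis_direction",
    "contact_guidance_direction",
    "radial_force_magnitude",
    "cell_ecm_force",
    "repulsion_force",
    "compose_velocity",
]

_EPS = 1e-12


@dataclass
class ForceSample:
    """A force as magnitude plus unit direction (``None`` = absent cue)."""

    magnitude: float
    direction: np.ndarray | None

    def vector(self) -> np.ndarray:
        if self.direction is None:
            return np.zeros(2)
        return self.magnitude * self.direction

    @property
    def is_zero(self) -> bool:
        return self.direction is None or self.magnitude == 0.0


def gaussian_kernel_gradient(
    center: np.ndarray,
    sources: np.ndarray,
    sigma: float,
    gamma: float,
) -> np.ndarray:
    """Gradient at ``center`` of a sum of Gaussian bumps on ``sources``.

    Returns ``gamma * sum_j grad_center exp(-|center - s_j|^2 / (2 sigma^2))``,
    which points toward the sources. Sources coincident with the center are
    skipped (their gradient term is undefined in direction but zero in value).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sources = np.asarray(sources, dtype=float).reshape(-1, 2)
    if sources.shape[0] == 0:
        return np.zeros(2)
    center = np.asarray(center, dtype=float)
    diff = sources - center[None, :]
    d2 = np.einsum("ij,ij->i", diff, diff)
    weights = np.exp(-d2 / (2.0 * sigma * sigma)) / (sigma * sigma)
    return gamma * (diff * weights[:, None]).sum(axis=0)


def sample_von_mises(
    mu: float,
    kappa: float,
    rng: np.random.Generator,
    kappa_cap: float = 700.0,
) -> float:
    """Draw an angle in (−π, π] from von Mises(mu, kappa).

    ``kappa = 0`` gives the uniform circular distribution; large
    concentrations are clamped at ``kappa_cap`` for numerical stability.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    angle = rng.vonmises(mu, min(kappa, kappa_cap))
    return _wrap(float(angle))


def _wrap(angle: float) -> float:
    """Wrap an angle to (−π, π]."""
    wrapped = (angle + math.pi) % (2.0 * math.pi) - math.pi
    if wrapped == -math.pi:
        wrapped = math.pi
    return wrapped


def haptotaxis_direction(
    cell_position: np.ndarray,
    fn_in_annulus: np.ndarray,
    params: SimulationParameters,
    rng: np.random.Generator,
    is_leader: bool = True,
) -> np.ndarray | None:
    """Sampled unit haptotaxis heading, or ``None`` with no FN sensed.

    ``fn_in_annulus`` holds positions of every FN element (punctum or
    fiber) with ``R_cell < d <= R_filo``. The heading is von Mises about
    the FN density gradient; the concentration is the per-element mean
    gradient norm, so an isolated punctum draws a near-deterministic
    approach while a symmetric surround leaves the heading noisy.
    """
    fn_in_annulus = np.asarray(fn_in_annulus, dtype=float).reshape(-1, 2)
    if fn_in_annulus.shape[0] == 0:
        return None
    sigma = params.R_filo - params.R_cell
    grad = gaussian_kernel_gradient(
        cell_position, fn_in_annulus, sigma, params.gamma_fn_for(is_leader)
    )
    mu = math.atan2(grad[1], grad[0]) if np.any(grad) else 0.0
    kappa = float(np.hypot(*grad)) / fn_in_annulus.shape[0]
    angle = sample_von_mises(mu, kappa, rng, params.kappa_cap)
    return np.array([math.cos(angle), math.sin(angle)])


def contact_guidance_direction(fiber_angles: np.ndarray) -> np.ndarray | None:
    """Unit vector along the mean orientation of the sensed fibers.

    Returns ``None`` if there are no fibers or the raw unit vectors cancel
    (e.g. two antiparallel fibers).
    """
    fiber_angles = np.asarray(fiber_angles, dtype=float).ravel()
    if fiber_angles.size == 0:
        return None
    mean_vec = np.array([np.cos(fiber_angles).mean(), np.sin(fiber_angles).mean()])
    norm = np.hypot(*mean_vec)
    if norm < _EPS:
        return None
    return mean_vec / norm


def radial_force_magnitude(
    center: np.ndarray,
    neighbors: np.ndarray,
    weights: np.ndarray | float,
    R_filo: float,
) -> float:
    """Summed strength of the radial forces from the neighbours.

    Each neighbour exerts a radially oriented force of strength
    ``w_j (1 - d_j/R_filo)^2`` that decays quadratically and vanishes at
    the sensing radius; the total magnitude is the sum of the individual
    strengths (the *direction* of the resultant is set separately by the
    sampled cues, so opposing neighbours do not cancel the magnitude —
    a cell in a symmetric environment still generates traction, it just
    has no preferred heading). Neighbours coincident with the center are
    skipped (their radial direction is undefined).
    """
    neighbors = np.asarray(neighbors, dtype=float).reshape(-1, 2)
    if neighbors.shape[0] == 0:
        return 0.0
    center = np.asarray(center, dtype=float)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (neighbors.shape[0],))
    diff = center[None, :] - neighbors
    d = np.hypot(diff[:, 0], diff[:, 1])
    keep = d > 0
    if not np.any(keep):
        return 0.0
    d, w = d[keep], weights[keep]
    return float((w * (1.0 - d / R_filo) ** 2).sum())


def cell_ecm_force(
    cell_position: np.ndarray,
    fn_positions: np.ndarray,
    fiber_angles: np.ndarray,
    params: SimulationParameters,
    rng: np.random.Generator,
    is_leader: bool = True,
) -> ForceSample:
    """Total cell–ECM force from the FN elements in the sensing annulus.

    The direction blends the sampled haptotaxis heading (weight χ) with
    the mean fiber orientation (weight 1−χ), renormalized; absent cues
    contribute zero vectors, and if both cues are absent (or cancel) the
    force is null. The magnitude is the radial sum over all sensed FN
    with unit weights.
    """
    fn_positions = np.asarray(fn_positions, dtype=float).reshape(-1, 2)
    if fn_positions.shape[0] == 0:
        return ForceSample(0.0, None)
    chi = params.chi_for(is_leader)
    hap = haptotaxis_direction(cell_position, fn_positions, params, rng, is_leader)
    cg = contact_guidance_direction(fiber_angles)
    combo = np.zeros(2)
    if hap is not None:
        combo = combo + chi * hap
    if cg is not None:
        combo = combo + (1.0 - chi) * cg
    norm = np.hypot(*combo)
    magnitude = radial_force_magnitude(cell_position, fn_positions, 1.0, params.R_filo)
    if norm < _EPS:
        return ForceSample(0.0, None)
    return ForceSample(magnitude, combo / norm)


def repulsion_force(
    cell_position: np.ndarray,
    neighbor_positions: np.ndarray,
    params: SimulationParameters,
    rng: np.random.Generator,
    is_leader: bool = True,
) -> ForceSample:
    """Cell–cell repulsion from neighbours within the filopodial radius.

    Direction is von Mises about the *negative* neighbour-density
    gradient (cells head for low density); the concentration is the
    gradient norm. The magnitude is the radial sum weighted by the acting
    cell's phenotype-specific repulsion strength.
    """
    neighbor_positions = np.asarray(neighbor_positions, dtype=float).reshape(-1, 2)
    if neighbor_positions.shape[0] == 0:
        return ForceSample(0.0, None)
    grad = gaussian_kernel_gradient(
        cell_position, neighbor_positions, params.R_cell, params.gamma_cell
    )
    mu = math.atan2(-grad[1], -grad[0]) if np.any(grad) else 0.0
    kappa = float(np.hypot(*grad)) / neighbor_positions.shape[0]
    angle = sample_von_mises(mu, kappa, rng, params.kappa_cap)
    magnitude = radial_force_magnitude(
        cell_position, neighbor_positions, params.c_for(is_leader), params.R_filo
    )
    return ForceSample(magnitude, np.array([math.cos(angle), math.sin(angle)]))


def compose_velocity(
    f_ecm: ForceSample,
    f_rep: ForceSample,
    sensed_fn: bool,
    is_leader: bool,
    params: SimulationParameters,
    f_contact: np.ndarray | None = None,
) -> np.ndarray | str:
    """Overdamped velocity update with speed caps and the guiding force.

    Returns the new velocity vector, or the sentinel ``"unchanged"`` when
    the cell sensed neither FN nor neighbours (persistence rule). The
    speed is the raw force norm capped at ``s_fn_max`` (sensing FN) or
    ``s_off_max`` (not sensing); when the guiding force applies to this
    cell the *direction* is re-blended toward the corridor axis with
    weight ``z`` while the speed is unchanged.
    """
    if not sensed_fn and f_rep.is_zero:
        return "unchanged"
    raw = (f_ecm.vector() + f_rep.vector()) / params.eta
    if f_contact is not None:
        raw = raw + f_contact
    s_max = params.s_fn_max if sensed_fn else params.s_off_max
    speed = min(s_max, float(np.hypot(*raw)))
    guided = params.z > 0 and (
        params.guiding_scope is GuidingScope.BOTH
        or (params.guiding_scope is GuidingScope.LEADERS_ONLY and is_leader)
    )
    if guided:
        blend = (1.0 - params.z) * raw + params.z * np.array([1.0, 0.0])
    else:
        blend = raw
    norm = float(np.hypot(*blend))
    if norm < _EPS:
        return np.zeros(2)
    return speed * blend / norm
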
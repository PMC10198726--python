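"""Per-realization summary statistics and the jamming/break classifiers.

All statistics act on a :class:`~ncstream.engine.Snapshot` (usually the
final state of a 12-hour realization). Distances are in µm. A stream is
"jammed" when its front advanced less than 100 µm over the full run, and
"broken" when the mean leader-to-nearest-follower distance exceeds two
cell diameters (30 µm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .engine import Snapshot
from .params import SimulationParameters

__all__ = [
    "SummaryRecord",
    "horizontal_distance",
    "lateral_spread",
    "mean_nn_distance",
    "leader_follower_separation",
    "classify_jammed",
    "classify_break",
    "mean_follower_angle",
    "mean_fiber_alignment",
    "summarize",
]

JAM_THRESHOLD = 100.0    # µm of front travel below which the stream is jammed
BREAK_THRESHOLD = 30.0   # µm of leader–follower separation defining a break


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's preconditions (cell counts) are not met."""


@dataclass
class SummaryRecord:
    """One realization's metrics (NaN marks a statistic that was undefined)."""

    horizontal_distance: float
    lateral_spread: float
    mean_nn_distance: float
    leader_follower_separation: float
    n_followers: int
    jammed: bool
    broken: bool
    mean_follower_angle: float
    mean_fiber_alignment: float
    seed: int | None = None
    condition: str | None = None


def horizontal_distance(state: Snapshot, start_x: float | None = None) -> float:
    """Stream-front travel: max cell x minus the initial leader x (≥ 0)."""
    if state.n_cells == 0:
        raise UndefinedStatisticError("no cells")
    if start_x is None:
        start_x = 7.5
    return max(0.0, float(state.pos[:, 0].max()) - start_x)


def lateral_spread(state: Snapshot) -> float:
    """Vertical range of the cell population (max y − min y)."""
    if state.n_cells == 0:
        raise UndefinedStatisticError("no cells")
    y = state.pos[:, 1]
    return float(y.max() - y.min())


def mean_nn_distance(state: Snapshot) -> float:
    """Mean over cells of the distance to the nearest other cell."""
    if state.n_cells < 2:
        raise UndefinedStatisticError("needs at least two cells")
    d = cdist(state.pos, state.pos)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def leader_follower_separation(state: Snapshot) -> float:
    """Mean over leaders of the distance to the nearest follower."""
    leaders = state.pos[state.leader]
    followers = state.pos[~state.leader]
    if leaders.shape[0] == 0 or followers.shape[0] == 0:
        raise UndefinedStatisticError("both phenotypes required")
    return float(cdist(leaders, followers).min(axis=1).mean())


def classify_jammed(h_distance: float) -> bool:
    """Jammed iff the front travelled strictly less than 100 µm."""
    return h_distance < JAM_THRESHOLD


def classify_break(separation: float) -> bool:
    """Broken iff leader–follower separation strictly exceeds 30 µm."""
    return separation > BREAK_THRESHOLD


def rescue_success(broken_flags: np.ndarray) -> bool:
    """An ensemble rescue succeeds iff unbroken in at least half the runs."""
    flags = np.asarray(broken_flags, dtype=bool)
    return (~flags).sum() >= flags.size / 2.0


def mean_follower_angle(state: Snapshot) -> float:
    """Circular mean of moving followers' velocity angles vs the x-axis."""
    v = state.vel[~state.leader]
    v = v[np.hypot(v[:, 0], v[:, 1]) > 0]
    if v.shape[0] == 0:
        raise UndefinedStatisticError("no moving follower cells")
    ang = np.arctan2(v[:, 1], v[:, 0])
    return float(math.atan2(np.sin(ang).mean(), np.cos(ang).mean()))


def mean_fiber_alignment(state: Snapshot) -> float:
    """Mean |cos φ| over fibers (1 = corridor-aligned, 0 = perpendicular)."""
    phi = state.fn_phi[state.fn_fiber]
    if phi.size == 0:
        raise UndefinedStatisticError("no fibers")
    return float(np.abs(np.cos(phi)).mean())


def summarize(
    state: Snapshot,
    params: SimulationParameters | None = None,
    seed: int | None = None,
    condition: str | None = None,
) -> SummaryRecord:
    """Compute the full record; unavailable statistics become NaN.

    A realization in which no follower ever entered (so the separation is
    undefined) is recorded as broken: the trailing population is missing
    entirely, which is the extreme form of a stream break.
    """
    start_x = params.R_cell if params is not None else None
    hd = horizontal_distance(state, start_x=start_x)
    ls = lateral_spread(state)
    nn = mean_nn_distance(state) if state.n_cells >= 2 else float("nan")
    try:
        sep = leader_follower_separation(state)
        broken = classify_break(sep)
    except UndefinedStatisticError:
        sep, broken = float("nan"), True
    try:
        ang = mean_follower_angle(state)
    except UndefinedStatisticError:
        ang = float("nan")
    try:
        align = mean_fiber_alignment(state)
    except UndefinedStatisticError:
        align = float("nan")
    return SummaryRecord(
        horizontal_distance=hd,
        lateral_spread=ls,
        mean_nn_distance=nn,
        leader_follower_separation=sep,
        n_followers=int((~state.leader).sum()),
        jammed=classify_jammed(hd),
        broken=broken,
        mean_follower_angle=ang,
        mean_fiber_alignment=align,
        seed=seed,
        condition=condition,
    )
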
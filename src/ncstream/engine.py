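"""World state, initialization, and the per-step update loop.

The update loop follows a fixed order within each time step: (a) compute
all cell velocities synchronously from the start-of-step state, (b) move
all cells with a two-step Adams–Bashforth rule, (c) secrete FN puncta,
(d) reflect cells at the domain boundary, (e) admit new follower cells at
vacated entry sites, (f) remodel the FN matrix (punctum→fiber conversion
and fiber reorientation), (g) advance the clock.

Cells are stored as a struct of numpy arrays and all per-step quantities
are evaluated vectorized; FN neighbour queries go through a KD-tree that
is rebuilt lazily (freshly secreted puncta sit in a small linear-scan
buffer until the next rebuild), which keeps a full 12-hour realization in
the low seconds. One ``numpy`` Generator per realization supplies every
stochastic draw in a fixed order (haptotaxis headings for cells sensing
FN in ascending id, then repulsion headings, then secretion intervals),
so runs are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import (
    GuidingScope,
    RemodelingScope,
    SecretionScope,
    SimulationParameters,
    validate,
)
from ._kernels import (
    cell_accumulate,
    contact_repulsion,
    fn_accumulate,
    remodel_pass,
)

from .remodeling import LN2

__all__ = [
    "World",
    "Snapshot",
    "Trajectory",
    "initialize_world",
    "leader_positions",
    "reflect_boundary",
    "advance_positions",
    "insert_followers",
    "step",
    "run_simulation",
]

_EPS = 1e-12
_PENDING_LIMIT = 64  # FN appends tolerated before a KD-tree rebuild
_PAIR_SLACK = 4.0    # extra query radius (µm) making cached pairs reusable


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

class World:
    """Mutable simulation state: cells, FN elements, edge agents, clock."""

    def __init__(self, params: SimulationParameters, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.t = 0.0
        self.step_index = 0
        cap = 32
        self.pos = np.zeros((cap, 2))
        self.vel = np.zeros((cap, 2))
        self.vel_prev = np.zeros((cap, 2))
        self.leader = np.zeros(cap, dtype=bool)
        self.has_prev = np.zeros(cap, dtype=bool)
        self.t_last = np.zeros(cap)
        self.t_r = np.full(cap, np.inf)
        self.sensed_fn = np.zeros(cap, dtype=bool)
        self.sensed_cells = np.zeros(cap, dtype=bool)
        self.n = 0
        self.edge_pos = np.zeros((0, 2))
        fcap = 1024
        self.fn_pos = np.zeros((fcap, 2))
        self.fn_fiber = np.zeros(fcap, dtype=bool)
        self.fn_phi = np.zeros(fcap)
        self.m = 0
        self._tree: cKDTree | None = None
        self._tree_m = 0
        # cell–FN pair cache: all pairs within R_filo + _PAIR_SLACK of the
        # cell position at refresh time. Cells displace at most
        # 2·s_fn_max·dt per step, so the cache stays a superset of the true
        # R_filo neighbourhood for `_pair_horizon` steps.
        self._pair_i = np.zeros(0, dtype=np.intp)
        self._pair_j = np.zeros(0, dtype=np.intp)
        self._pair_age = 0
        self._pair_dirty = True
        self._pair_horizon = max(
            1, int(_PAIR_SLACK / (2.0 * params.s_fn_max * params.dt))
        )

    # -- capacity management ------------------------------------------------
    def _grow_cells(self, need: int) -> None:
        cap = self.pos.shape[0]
        if need <= cap:
            return
        new = max(need, 2 * cap)
        for name in ("pos", "vel", "vel_prev"):
            arr = getattr(self, name)
            out = np.zeros((new, 2))
            out[: self.n] = arr[: self.n]
            setattr(self, name, out)
        for name, fill in (
            ("leader", False), ("has_prev", False),
            ("sensed_fn", False), ("sensed_cells", False),
        ):
            arr = getattr(self, name)
            out = np.full(new, fill, dtype=bool)
            out[: self.n] = arr[: self.n]
            setattr(self, name, out)
        for name, fill in (("t_last", 0.0), ("t_r", np.inf)):
            arr = getattr(self, name)
            out = np.full(new, fill)
            out[: self.n] = arr[: self.n]
            setattr(self, name, out)

    def _grow_fn(self, need: int) -> None:
        cap = self.fn_pos.shape[0]
        if need <= cap:
            return
        new = max(need, 2 * cap)
        out = np.zeros((new, 2))
        out[: self.m] = self.fn_pos[: self.m]
        self.fn_pos = out
        fib = np.zeros(new, dtype=bool)
        fib[: self.m] = self.fn_fiber[: self.m]
        self.fn_fiber = fib
        phi = np.zeros(new)
        phi[: self.m] = self.fn_phi[: self.m]
        self.fn_phi = phi

    def add_cell(
        self, position: np.ndarray, leader: bool,
        t_last: float = 0.0, t_r: float = np.inf,
    ) -> int:
        self._grow_cells(self.n + 1)
        i = self.n
        self.pos[i] = position
        self.vel[i] = 0.0
        self.vel_prev[i] = 0.0
        self.leader[i] = leader
        self.has_prev[i] = False
        self.sensed_fn[i] = False
        self.sensed_cells[i] = False
        self.t_last[i] = t_last
        self.t_r[i] = t_r
        self.n += 1
        self._pair_dirty = True
        return i

    def add_fn(self, positions: np.ndarray) -> None:
        positions = np.atleast_2d(positions)
        k = positions.shape[0]
        start = self.m
        self._grow_fn(self.m + k)
        self.fn_pos[start : start + k] = positions
        self.fn_fiber[start : start + k] = False
        self.m += k
        if not self._pair_dirty and self.n:
            # splice the new elements into the live pair cache
            diff = self.pos[None, : self.n, :] - positions[:, None, :]
            d = np.hypot(diff[..., 0], diff[..., 1])
            jp, ip = np.nonzero(d <= self.params.R_filo + _PAIR_SLACK)
            if ip.size:
                self._pair_i = np.concatenate([self._pair_i, ip])
                self._pair_j = np.concatenate([self._pair_j, jp + start])

    # -- FN neighbour queries -------------------------------------------------
    def _ensure_tree(self) -> None:
        if self._tree is None or self.m - self._tree_m > _PENDING_LIMIT:
            self._tree = cKDTree(self.fn_pos[: self.m]) if self.m else None
            self._tree_m = self.m

    def fn_pairs(self, points: np.ndarray, radius: float):
        """All (point index, FN index, distance) with d <= radius."""
        npts = points.shape[0]
        if self.m == 0 or npts == 0:
            empty = np.zeros(0, dtype=np.intp)
            return empty, empty, np.zeros(0)
        self._ensure_tree()
        if self._tree_m > 0:
            lists = self._tree.query_ball_point(points, radius)
            counts = np.fromiter((len(l) for l in lists), dtype=np.intp, count=npts)
            i = np.repeat(np.arange(npts), counts)
            j = (
                np.concatenate([np.asarray(l, dtype=np.intp) for l in lists])
                if counts.sum()
                else np.zeros(0, dtype=np.intp)
            )
        else:
            i = np.zeros(0, dtype=np.intp)
            j = np.zeros(0, dtype=np.intp)
        pend = self.m - self._tree_m
        if pend > 0:
            diff = points[:, None, :] - self.fn_pos[None, self._tree_m : self.m, :]
            d = np.hypot(diff[..., 0], diff[..., 1])
            ip, jp = np.nonzero(d <= radius)
            i = np.concatenate([i, ip])
            j = np.concatenate([j, jp + self._tree_m])
        diff = points[i] - self.fn_pos[j]
        return i, j, np.hypot(diff[:, 0], diff[:, 1])

    def current_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached superset of all cell–FN pairs within R_filo (see above)."""
        if self._pair_dirty or self._pair_age >= self._pair_horizon:
            i, j, _ = self.fn_pairs(
                self.pos[: self.n], self.params.R_filo + _PAIR_SLACK
            )
            self._pair_i, self._pair_j = i, j
            self._pair_age = 0
            self._pair_dirty = False
        return self._pair_i, self._pair_j


@dataclass
class Snapshot:
    """Immutable copy of the cell and FN state at one time point."""

    t: float
    pos: np.ndarray
    vel: np.ndarray
    leader: np.ndarray
    fn_pos: np.ndarray
    fn_fiber: np.ndarray
    fn_phi: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    @property
    def n_fn(self) -> int:
        return self.fn_pos.shape[0]


@dataclass
class Trajectory:
    """Time-ordered snapshots of one realization plus its provenance."""

    params: SimulationParameters
    seed: int | None
    snapshots: list[Snapshot] = field(default_factory=list)

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def take_snapshot(world: World) -> Snapshot:
    n, m = world.n, world.m
    return Snapshot(
        t=world.t,
        pos=world.pos[:n].copy(),
        vel=world.vel[:n].copy(),
        leader=world.leader[:n].copy(),
        fn_pos=world.fn_pos[:m].copy(),
        fn_fiber=world.fn_fiber[:m].copy(),
        fn_phi=world.fn_phi[:m].copy(),
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def leader_positions(params: SimulationParameters) -> np.ndarray:
    """Initial secretory-cell centers on the entrance strip.

    Leaders sit at x = R_cell with centers evenly spaced strictly inside
    the strip, mutually non-overlapping; the count is the largest N with
    (N−1)·2·R_cell < l_entr − 2·R_cell (7 at baseline).
    """
    half = params.l_entr / 2.0 - params.R_cell
    q = (params.l_entr - 2.0 * params.R_cell) / (2.0 * params.R_cell)
    n = int(math.floor(q - 1e-12)) + 1
    ys = np.linspace(-half, half, n) if n > 1 else np.array([0.0])
    out = np.empty((n, 2))
    out[:, 0] = params.R_cell
    out[:, 1] = ys
    return out


def fn_lattice(params: SimulationParameters) -> np.ndarray:
    """Initial punctate FN lattice with spacing λFN.

    The first column sits a distance R_cell + 0.5·R_filo to the right of
    the leader centers (so every leader senses at least one punctum at
    t = 0); rows are registered so the j = 0 row lies on y = 0.
    """
    x0 = params.R_cell + params.R_cell + 0.5 * params.R_filo
    xs = np.arange(x0, params.domain_side + 1e-9, params.lambda_fn)
    half = params.domain_side / 2.0
    jmax = int(math.floor(half / params.lambda_fn + 1e-9))
    ys = np.arange(-jmax, jmax + 1) * params.lambda_fn
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def initialize_world(
    params: SimulationParameters,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> World:
    """Build the t = 0 state: leader column, edge agents, FN lattice."""
    issues = validate(params)
    if issues:
        raise ValueError("invalid parameters: " + "; ".join(issues))
    if rng is None:
        rng = np.random.default_rng(seed)
    world = World(params, rng)
    leaders = leader_positions(params)
    secrete = params.secretion_scope is not SecretionScope.NONE
    for xy in leaders:
        t_r = rng.exponential(params.T_ave) if secrete else np.inf
        world.add_cell(xy, leader=True, t_last=0.0, t_r=t_r)
    world.edge_pos = leaders.copy()
    world.add_fn(fn_lattice(params))
    return world


# ---------------------------------------------------------------------------
# boundary and integration helpers
# ---------------------------------------------------------------------------

def reflect_boundary(position: np.ndarray, domain_side: float = 500.0) -> np.ndarray:
    """Mirror a position across violated boundaries until inside the domain.

    The domain is [0, L] × [−L/2, +L/2].
    """
    x, y = float(position[0]), float(position[1])
    half = domain_side / 2.0
    for _ in range(64):
        if x < 0:
            x = -x
        elif x > domain_side:
            x = 2.0 * domain_side - x
        elif y < -half:
            y = -2.0 * half - y
        elif y > half:
            y = 2.0 * half - y
        else:
            break
    return np.array([x, y])


def advance_positions(
    pos: np.ndarray,
    vel: np.ndarray,
    vel_prev: np.ndarray,
    has_prev: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Second-order Adams–Bashforth position update.

    ``x_{n+1} = x_n + dt (3/2 v_n − 1/2 v_{n−1})``; cells without a stored
    previous velocity (first step after entry) take a forward Euler step.
    """
    ab2 = pos + dt * (1.5 * vel - 0.5 * vel_prev)
    euler = pos + dt * vel
    return np.where(has_prev[:, None], ab2, euler)


def insert_followers(world: World) -> int:
    """Admit one non-secretory cell at each uncovered entry site.

    A site is covered when any cell center lies within 2·R_cell of it (a
    new cell there would overlap an existing one). New cells start at
    rest; they get a secretion clock only if followers secrete.
    """
    p = world.params
    if world.edge_pos.shape[0] == 0:
        return 0
    if world.n:
        diff = world.edge_pos[:, None, :] - world.pos[None, : world.n, :]
        dmin = np.hypot(diff[..., 0], diff[..., 1]).min(axis=1)
        free = dmin >= 2.0 * p.R_cell
    else:
        free = np.ones(world.edge_pos.shape[0], dtype=bool)
    added = 0
    follower_secretes = p.secretion_scope is SecretionScope.BOTH
    for site in np.flatnonzero(free):
        t_r = (
            world.rng.exponential(p.T_ave_follower)
            if follower_secretes
            else np.inf
        )
        world.add_cell(world.edge_pos[site], leader=False, t_last=world.t, t_r=t_r)
        added += 1
    return added


# ---------------------------------------------------------------------------
# the step
# ---------------------------------------------------------------------------

def _remodeling_allowed(params: SimulationParameters, leader: np.ndarray) -> np.ndarray:
    scope = params.remodeling_scope
    if scope is RemodelingScope.BOTH:
        return np.ones_like(leader, dtype=bool)
    if scope is RemodelingScope.LEADERS_ONLY:
        return leader.copy()
    if scope is RemodelingScope.FOLLOWERS_ONLY:
        return ~leader
    return np.zeros_like(leader, dtype=bool)


def _secretors(params: SimulationParameters, leader: np.ndarray) -> np.ndarray:
    scope = params.secretion_scope
    if scope is SecretionScope.LEADERS_ONLY:
        return leader.copy()
    if scope is SecretionScope.BOTH:
        return np.ones_like(leader, dtype=bool)
    return np.zeros_like(leader, dtype=bool)


def step(world: World) -> World:
    """Advance the world by one time step (order documented above)."""
    p = world.params
    n = world.n
    rng = world.rng
    if n > 0:
        pos = world.pos[:n]
        leader = world.leader[:n]

        # --- (a) velocities, synchronously from the start-of-step state ---
        i_all, j_all = world.current_pairs()
        cnt, ghx, ghy, mag_ecm, cgx, cgy, ncg = fn_accumulate(
            pos, world.fn_pos, world.fn_fiber, world.fn_phi,
            i_all, j_all, p.R_cell, p.R_filo, p.R_filo - p.R_cell,
        )
        sensed = cnt > 0
        gamma_i = np.where(
            leader,
            p.gamma_fn if p.gamma_fn_leader is None else p.gamma_fn_leader,
            p.gamma_fn if p.gamma_fn_follower is None else p.gamma_fn_follower,
        )
        ghx = gamma_i * ghx
        ghy = gamma_i * ghy
        cg_norm = np.hypot(cgx, cgy)
        has_cg = (ncg > 0) & (cg_norm > _EPS)

        ccnt, gcx, gcy, mag_r = cell_accumulate(pos, p.R_cell, p.R_filo)
        has_nb = ccnt > 0
        gcx = p.gamma_cell * gcx
        gcy = p.gamma_cell * gcy
        c_i = np.where(leader, p.c_leader, p.c_follower)
        mag_rep = c_i * mag_r

        # stochastic headings (fixed draw order: haptotaxis, then repulsion)
        # stochastic headings: von Mises about the density-gradient
        # direction, concentration = the per-neighbour mean gradient norm
        hap = np.zeros((n, 2))
        if sensed.any():
            mu = np.arctan2(ghy[sensed], ghx[sensed])
            kap = np.hypot(ghx[sensed], ghy[sensed]) / cnt[sensed]
            angles = rng.vonmises(mu, np.minimum(kap, p.kappa_cap))
            hap[sensed, 0] = np.cos(angles)
            hap[sensed, 1] = np.sin(angles)
        rep = np.zeros((n, 2))
        if has_nb.any():
            mu = np.arctan2(-gcy[has_nb], -gcx[has_nb])
            kap = np.hypot(gcx[has_nb], gcy[has_nb]) / ccnt[has_nb]
            angles = rng.vonmises(mu, np.minimum(kap, p.kappa_cap))
            rep[has_nb, 0] = np.cos(angles)
            rep[has_nb, 1] = np.sin(angles)

        cg_unit = np.zeros((n, 2))
        cg_unit[has_cg, 0] = cgx[has_cg] / cg_norm[has_cg]
        cg_unit[has_cg, 1] = cgy[has_cg] / cg_norm[has_cg]

        chi_i = np.where(
            leader,
            p.chi if p.chi_leader is None else p.chi_leader,
            p.chi if p.chi_follower is None else p.chi_follower,
        )[:, None]
        ecm_dir = chi_i * hap + (1.0 - chi_i) * cg_unit
        ecm_n = np.hypot(ecm_dir[:, 0], ecm_dir[:, 1])
        ok = ecm_n > _EPS
        ecm_unit = np.zeros((n, 2))
        ecm_unit[ok] = ecm_dir[ok] / ecm_n[ok, None]

        raw = (mag_ecm[:, None] * ecm_unit + mag_rep[:, None] * rep) / p.eta
        if p.contact_strength > 0.0:
            cfx, cfy = contact_repulsion(pos, p.R_cell, p.contact_strength)
            raw[:, 0] += cfx
            raw[:, 1] += cfy
        persist = ~sensed & ~has_nb
        s_max = np.where(sensed, p.s_fn_max, p.s_off_max)
        speed = np.minimum(np.hypot(raw[:, 0], raw[:, 1]), s_max)

        blend = raw.copy()
        if p.z > 0 and p.guiding_scope is not GuidingScope.NONE:
            guided = (
                np.ones(n, dtype=bool)
                if p.guiding_scope is GuidingScope.BOTH
                else leader.copy()
            )
            blend[guided] = (1.0 - p.z) * raw[guided]
            blend[guided, 0] += p.z
        bn = np.hypot(blend[:, 0], blend[:, 1])
        vdir = np.zeros((n, 2))
        nz = bn > _EPS
        vdir[nz] = blend[nz] / bn[nz, None]
        v_new = speed[:, None] * vdir
        v_new[persist] = world.vel[:n][persist]
        world.sensed_fn[:n] = sensed
        world.sensed_cells[:n] = has_nb

        # --- (b) position update -----------------------------------------
        new_pos = advance_positions(
            pos, v_new, world.vel[:n], world.has_prev[:n], p.dt
        )
        world.vel_prev[:n] = world.vel[:n]
        world.vel[:n] = v_new
        world.has_prev[:n] = True
        world.pos[:n] = new_pos

        # --- (c) secretion -------------------------------------------------
        due = (
            _secretors(p, leader)
            & sensed
            & (world.t - world.t_last[:n] >= world.t_r[:n])
        )
        idx = np.flatnonzero(due)
        if idx.size:
            scale = np.where(world.leader[idx], p.T_ave, p.T_ave_follower)
            world.t_last[idx] = world.t
            world.t_r[idx] = rng.exponential(scale)
            world.add_fn(world.pos[idx].copy())

        # --- (d) boundary reflection ---------------------------------------
        _reflect_cells(world)

    # --- (e) follower entry -----------------------------------------------
    insert_followers(world)

    # --- (f) FN remodeling --------------------------------------------------
    _remodel(world)

    # --- (g) clock ----------------------------------------------------------
    world.t += p.dt
    world.step_index += 1
    world._pair_age += 1
    if world.n and not (
        np.isfinite(world.pos[: world.n]).all()
        and np.isfinite(world.vel[: world.n]).all()
    ):
        raise FloatingPointError(
            f"non-finite cell state at step {world.step_index}"
        )
    return world


def _reflect_cells(world: World) -> None:
    """Mirror out-of-domain cells back inside, flipping their velocity.

    The stored previous velocity is flipped as well so the two-step
    integrator does not keep pushing a bounced cell outward.
    """
    p = world.params
    n = world.n
    half = p.domain_side / 2.0
    pos = world.pos[:n]
    for _ in range(8):
        moved = False
        for axis, lo, hi in ((0, 0.0, p.domain_side), (1, -half, half)):
            low = pos[:, axis] < lo
            if low.any():
                pos[low, axis] = 2.0 * lo - pos[low, axis]
                world.vel[:n][low, axis] *= -1.0
                world.vel_prev[:n][low, axis] *= -1.0
                moved = True
            high = pos[:, axis] > hi
            if high.any():
                pos[high, axis] = 2.0 * hi - pos[high, axis]
                world.vel[:n][high, axis] *= -1.0
                world.vel_prev[:n][high, axis] *= -1.0
                moved = True
        if not moved:
            return


def _remodel(world: World) -> None:
    """Punctum→fiber conversion and fiber reorientation by covering cells.

    Each FN element covered (d ≤ R_cell, post-move positions) by one or
    more moving, remodeling-enabled cells is processed by those cells in
    ascending cell id: the first converts a punctum to a fiber along its
    heading, every subsequent pass applies one Euler step of the
    reorientation ODE. Cells at rest have no heading and leave covered
    FN unchanged.
    """
    p = world.params
    n = world.n
    if n == 0 or world.m == 0:
        return
    allowed = _remodeling_allowed(p, world.leader[:n])
    speed = np.hypot(world.vel[:n, 0], world.vel[:n, 1])
    active = allowed & (speed > 0.0)
    if not active.any():
        return
    # the cached pairs are a superset of the coverage neighbourhood; note
    # cells admitted this step are at rest and so never remodel, hence
    # their absence from a not-yet-refreshed cache is harmless
    pi, pj = world._pair_i, world._pair_j
    if pi.size == 0:
        return
    theta = np.arctan2(world.vel[:n, 1], world.vel[:n, 0])
    remodel_pass(
        world.pos[:n], world.vel[:n], active, theta,
        world.fn_pos, world.fn_fiber, world.fn_phi,
        pi, pj, p.R_cell, p.dt * LN2 / p.T_half, n,
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_simulation(
    params: SimulationParameters,
    seed: int | None = None,
    snapshot_every: float | None = 30.0,
) -> Trajectory:
    """Run one realization for ``params.duration`` minutes.

    Snapshots are stored at t = 0, every ``snapshot_every`` simulated
    minutes (``None`` → initial and final only), and at the final time.
    Fully reproducible given (params, seed).
    """
    issues = validate(params)
    if issues:
        raise ValueError("invalid parameters: " + "; ".join(issues))
    world = initialize_world(params, seed=seed)
    n_steps = int(round(params.duration / params.dt))
    stride = (
        max(1, int(round(snapshot_every / params.dt)))
        if snapshot_every is not None
        else None
    )
    traj = Trajectory(params=params, seed=seed, snapshots=[take_snapshot(world)])
    for k in range(1, n_steps + 1):
        step(world)
        if (stride is not None and k % stride == 0) or k == n_steps:
            traj.snapshots.append(take_snapshot(world))
    return traj
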
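"""Global sensitivity analysis: eFAST Sobol indices and PRCC.

The extended Fourier amplitude sensitivity test (eFAST) explores the
(R_filo, χ, c) box — plus a dummy factor that the simulator never sees —
along periodic search curves, one block per factor in which that factor
carries the highest interference-free frequency. First-order indices
come from the spectral power at the principal frequency's harmonics;
total-order indices from the complement of the low-frequency power.
Each factor's indices are compared with the dummy's across resampled
curves by a two-sample t-test. Partial rank correlation coefficients
(PRCC) give signed monotone associations controlling for the other
varied factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .params import SimulationParameters, default_parameters

__all__ = [
    "SensitivityDesign",
    "EfastSample",
    "SobolResult",
    "efast_sample",
    "sobol_from_efast",
    "test_vs_dummy",
    "prcc",
    "sample_row_parameters",
    "evaluate_design_on_abm",
]

#: parameter regime held fixed during the sensitivity analysis (it differs
#: from the migration baseline in these five values)
SENSITIVITY_FIXED: dict[str, float] = {
    "R_cell": 10.0,
    "l_entr": 150.0,
    "T_half": 60.0,
    "s_fn_max": 0.75,
    "lambda_fn": 35.0,
}


@dataclass
class SensitivityDesign:
    """Factor ranges and sampling sizes for the eFAST design."""

    factors: Sequence[tuple[str, float, float]] = (
        ("R_filo", 30.0, 75.0),
        ("chi", 0.25, 1.0),
        ("c", 0.0, 5.0),
        ("dummy", 0.0, 1.0),
    )
    n_per_curve: int = 131
    n_curves: int = 3
    replicates_per_sample: int = 20
    interference: int = 4          # eFAST interference factor M
    fixed: dict[str, float] = field(default_factory=lambda: dict(SENSITIVITY_FIXED))

    @property
    def names(self) -> list[str]:
        return [f[0] for f in self.factors]

    @property
    def k(self) -> int:
        return len(self.factors)


@dataclass
class EfastSample:
    """Sampled parameter matrix plus the block structure needed to score it."""

    X: np.ndarray              # (n_curves * k * n_per_curve, k)
    principal: np.ndarray      # per-row index of the high-frequency factor
    curve: np.ndarray          # per-row resampling-curve index
    omega_max: int
    design: SensitivityDesign

    def block_rows(self, factor: int, curve: int) -> np.ndarray:
        return np.flatnonzero((self.principal == factor) & (self.curve == curve))


def efast_sample(design: SensitivityDesign, seed: int | None = None) -> EfastSample:
    """Generate eFAST search curves (one block per factor per curve).

    Within a block the principal factor oscillates at the highest
    interference-free frequency ``(Ns − 1) / (2M)`` while the others take
    low frequencies; every factor's marginal is approximately uniform on
    its range. Curves are re-randomized with independent phase shifts.
    """
    rng = np.random.default_rng(seed)
    Ns, k, M = design.n_per_curve, design.k, design.interference
    omega_max = (Ns - 1) // (2 * M)
    if omega_max < 1:
        raise ValueError(
            f"n_per_curve={Ns} too small for interference factor M={M}"
        )
    max_compl = max(1, omega_max // (2 * M))
    compl = 1 + (np.arange(k - 1) % max_compl)
    s = (2.0 * np.pi / Ns) * np.arange(Ns)
    lows = np.array([f[1] for f in design.factors])
    highs = np.array([f[2] for f in design.factors])

    rows_X, rows_p, rows_c = [], [], []
    for curve in range(design.n_curves):
        for principal in range(k):
            omega = np.empty(k)
            omega[principal] = omega_max
            omega[[i for i in range(k) if i != principal]] = compl
            phase = rng.uniform(0.0, 2.0 * np.pi, size=k)
            g = 0.5 + (1.0 / np.pi) * np.arcsin(
                np.sin(omega[None, :] * s[:, None] + phase[None, :])
            )
            rows_X.append(lows + (highs - lows) * g)
            rows_p.append(np.full(Ns, principal, dtype=np.intp))
            rows_c.append(np.full(Ns, curve, dtype=np.intp))
    return EfastSample(
        X=np.vstack(rows_X),
        principal=np.concatenate(rows_p),
        curve=np.concatenate(rows_c),
        omega_max=omega_max,
        design=design,
    )


@dataclass
class SobolResult:
    """First/total-order Sobol indices per factor, per resampling curve."""

    names: list[str]
    S1: np.ndarray             # (k, n_curves)
    ST: np.ndarray             # (k, n_curves)

    @property
    def S1_mean(self) -> np.ndarray:
        return self.S1.mean(axis=1)

    @property
    def ST_mean(self) -> np.ndarray:
        return self.ST.mean(axis=1)


def _spectrum_indices(y: np.ndarray, omega: int, M: int) -> tuple[float, float]:
    n = y.size
    f = np.fft.fft(y)
    sp = np.abs(f[1 : (n + 1) // 2]) ** 2 / n
    variance = 2.0 * sp.sum()
    if variance <= 0.0:
        return 0.0, 0.0
    harmonics = np.arange(1, M + 1) * omega - 1
    d1 = 2.0 * sp[harmonics].sum()
    dt = 2.0 * sp[: omega // 2].sum()
    return d1 / variance, 1.0 - dt / variance


def sobol_from_efast(sample: EfastSample, outputs: np.ndarray) -> SobolResult:
    """Score model outputs (one per sample row) into Sobol indices."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape[0] != sample.X.shape[0]:
        raise ValueError("outputs must align with the sample matrix rows")
    design = sample.design
    k, nc = design.k, design.n_curves
    S1 = np.zeros((k, nc))
    ST = np.zeros((k, nc))
    degenerate = False
    for i in range(k):
        for r in range(nc):
            y = outputs[sample.block_rows(i, r)]
            if np.ptp(y) == 0.0:
                degenerate = True
                continue
            S1[i, r], ST[i, r] = _spectrum_indices(
                y, sample.omega_max, design.interference
            )
    if degenerate:
        warnings.warn("degenerate (constant) outputs in an eFAST block; "
                      "indices reported as 0", RuntimeWarning, stacklevel=2)
    return SobolResult(names=list(design.names), S1=S1, ST=ST)


def test_vs_dummy(
    result: SobolResult, dummy: str = "dummy"
) -> dict[str, tuple[float, float]]:
    """Two-sample t-test of each factor's per-curve indices vs the dummy's.

    Returns ``{factor: (p_first_order, p_total_order)}`` for every
    non-dummy factor; needs at least two resampling curves.
    """
    if result.S1.shape[1] < 2:
        raise ValueError("at least two resampling curves are required")
    d = result.names.index(dummy)
    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(result.names):
        if i == d:
            continue
        p1 = _ttest_p(result.S1[i], result.S1[d])
        pt = _ttest_p(result.ST[i], result.ST[d])
        out[name] = (p1, pt)
    return out


def _ttest_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b).pvalue)


def prcc(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None
) -> list[tuple[float, float]]:
    """Partial rank correlation of each column of X with y.

    Ranks everything, then correlates the residuals of factor j and of y
    after regressing out the other (non-constant) factors. The p-value is
    a two-tailed t-test of the null PRCC = 0 with n − 2 − (k − 1) degrees
    of freedom. Constant columns are excluded with a warning and reported
    as (nan, nan).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n < 10:
        raise ValueError("at least 10 rows are required")
    varying = np.array([np.ptp(X[:, j]) > 0 for j in range(k)])
    if not varying.all():
        bad = [j for j in range(k) if not varying[j]]
        labels = [names[j] if names else str(j) for j in bad]
        warnings.warn(f"constant column(s) excluded from PRCC: {labels}",
                      RuntimeWarning, stacklevel=2)
    rx = np.column_stack([stats.rankdata(X[:, j]) for j in range(k)])
    ry = stats.rankdata(y)
    out: list[tuple[float, float]] = []
    for j in range(k):
        if not varying[j]:
            out.append((float("nan"), float("nan")))
            continue
        others = [i for i in range(k) if i != j and varying[i]]
        Z = np.column_stack([np.ones(n)] + [rx[:, i] for i in others])
        res_x = rx[:, j] - Z @ np.linalg.lstsq(Z, rx[:, j], rcond=None)[0]
        res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        denom = math.sqrt((res_x @ res_x) * (res_y @ res_y))
        r = float(res_x @ res_y / denom) if denom > 0 else 0.0
        dof = n - 2 - len(others)
        if abs(r) >= 1.0 or dof <= 0:
            p = 0.0 if dof > 0 else float("nan")
        else:
            t = r * math.sqrt(dof / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), dof))
        out.append((r, p))
    return out


# ---------------------------------------------------------------------------
# coupling the design to the migration model
# ---------------------------------------------------------------------------

def sample_row_parameters(
    row: np.ndarray, design: SensitivityDesign
) -> SimulationParameters:
    """Translate one sample row into simulator parameters.

    ``R_filo``, ``chi`` and ``c`` (both phenotypes) are taken from the
    row; the dummy factor is never passed on; the design's fixed
    overrides are applied on top of the baseline.
    """
    values = dict(zip(design.names, row))
    return default_parameters(
        R_filo=float(values["R_filo"]),
        chi=float(values["chi"]),
        c_leader=float(values["c"]),
        c_follower=float(values["c"]),
        **design.fixed,
    )


def evaluate_design_on_abm(
    X: np.ndarray,
    design: SensitivityDesign,
    base_seed: int,
    statistic: str = "horizontal_distance",
    replicates: int | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> np.ndarray:
    """Run the model at each sample row; return replicate-averaged outputs."""
    from .engine import run_simulation
    from .statistics import summarize

    reps = design.replicates_per_sample if replicates is None else replicates
    out = np.empty(X.shape[0])
    for r, row in enumerate(X):
        params = sample_row_parameters(row, design)
        vals = []
        for j in range(reps):
            traj = run_simulation(
                params, seed=base_seed + r * reps + j, snapshot_every=None
            )
            vals.append(getattr(summarize(traj.final, params), statistic))
        out[r] = float(np.mean(vals))
        if progress is not None:
            progress(r + 1, X.shape[0])
    return out
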
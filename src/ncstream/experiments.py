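"""Named in-silico experimental conditions and ensemble comparisons.

The catalog encodes the gain/loss-of-function, sparse-lattice, guiding-
force, and stream-break rescue experiments as parameter overrides on the
baseline (WT) regime. Ensembles are compared with a two-sided
Mann–Whitney U test, Bonferroni-corrected, alongside the percent change
of ensemble means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from scipy.stats import mannwhitneyu

from .engine import run_simulation
from .params import (
    GuidingScope,
    RemodelingScope,
    SecretionScope,
    SimulationParameters,
    default_parameters,
    validate,
)
from .statistics import SummaryRecord, summarize

__all__ = [
    "Condition",
    "ComparisonResult",
    "condition_catalog",
    "get_condition",
    "run_replicates",
    "compare",
]

GUIDING_LEVELS = (0.25, 0.5, 0.75)

# the demonstrated stream-break inducer: leader-only guiding at z = 0.75
BREAK_BASE: dict[str, Any] = {
    "z": 0.75,
    "guiding_scope": GuidingScope.LEADERS_ONLY,
}


@dataclass
class Condition:
    """A named experiment: overrides applied to the baseline parameters."""

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)

    def parameters(self, base: SimulationParameters | None = None) -> SimulationParameters:
        params = (base or default_parameters()).replace(**self.overrides)
        issues = validate(params)
        if issues:
            raise ValueError(f"condition {self.name!r} invalid: {'; '.join(issues)}")
        return params


def _rescue(name: str, **overrides: Any) -> Condition:
    merged = dict(BREAK_BASE)
    merged.update(overrides)
    return Condition(name, merged)


def condition_catalog() -> dict[str, Condition]:
    """All named conditions of the simulated experiment catalog."""
    cat: dict[str, Condition] = {}

    def add(name: str, **ov: Any) -> None:
        cat[name] = Condition(name, ov)

    # secretion perturbations
    add("WT")
    add("leader_FN_pp", T_ave=10.0)
    add("no_FN_secretion", secretion_scope=SecretionScope.NONE)
    add("both_FN_baseline", secretion_scope=SecretionScope.BOTH, T_ave_follower=30.0)
    add(
        "both_FN_pp",
        secretion_scope=SecretionScope.BOTH,
        T_ave=10.0,
        T_ave_follower=10.0,
    )

    # remodeling (secretion + fiber assembly) knockouts
    add(
        "remodel_KO_leaders",
        secretion_scope=SecretionScope.NONE,
        remodeling_scope=RemodelingScope.FOLLOWERS_ONLY,
    )
    add("remodel_KO_followers", remodeling_scope=RemodelingScope.LEADERS_ONLY)
    add(
        "remodel_KO_both",
        secretion_scope=SecretionScope.NONE,
        remodeling_scope=RemodelingScope.NONE,
    )

    # sparse initial lattice and its rescues
    add("sparse", lambda_fn=60.0)
    add("sparse_CG_pp", lambda_fn=60.0, chi=0.33)
    add("sparse_rep_pp", lambda_fn=60.0, c_leader=5.0, c_follower=5.0)
    add("sparse_FN_pp", lambda_fn=60.0, T_ave=10.0)

    # guiding-force sweeps
    for z in GUIDING_LEVELS:
        add(f"guiding_z{z}_both", z=z, guiding_scope=GuidingScope.BOTH)
        add(
            f"guiding_z{z}_leaders_only",
            z=z,
            guiding_scope=GuidingScope.LEADERS_ONLY,
        )

    # stream-break rescue catalog (layered on leader-only guiding, z = 0.75)
    cat["rescue_base"] = Condition("rescue_base", dict(BREAK_BASE))
    for cond in (
        _rescue("rescue_CG_pp_both", chi=0.33),
        _rescue("rescue_CG_pp_FO", chi_follower=0.33),
        _rescue("rescue_leader_FN_pp", T_ave=10.0),
        _rescue(
            "rescue_follower_FN_p",
            secretion_scope=SecretionScope.BOTH,
            T_ave_follower=90.0,
        ),
        _rescue("rescue_rep_low_both", c_leader=0.05, c_follower=0.05),
        _rescue("rescue_rep_pp_both", c_leader=2.0, c_follower=2.0),
        _rescue("rescue_rep_low_LO", c_leader=0.05),
        _rescue("rescue_rep_pp_LO", c_leader=2.0),
        _rescue("rescue_rep_low_FO", c_follower=0.05),
        _rescue("rescue_rep_pp_FO", c_follower=2.0),
        _rescue("rescue_hap_pp_both", gamma_fn=3000.0),
        _rescue("rescue_hap_pp_FO", gamma_fn_follower=3000.0),
    ):
        cat[cond.name] = cond
    return cat


def get_condition(name: str) -> Condition:
    cat = condition_catalog()
    if name not in cat:
        raise KeyError(
            f"unknown condition {name!r}; known: {', '.join(sorted(cat))}"
        )
    return cat[name]


def run_replicates(
    condition: Condition | str,
    n: int,
    base_seed: int,
    base: SimulationParameters | None = None,
) -> list[SummaryRecord]:
    """Run ``n`` independent realizations (seeds base_seed..base_seed+n−1).

    ``base`` replaces the baseline regime under the condition's overrides
    (used e.g. to shorten runs). A realization that raises is recorded as
    an all-NaN record (the run continues); the result is deterministic
    given (condition, n, seed).
    """
    if isinstance(condition, str):
        condition = get_condition(condition)
    params = condition.parameters(base)
    records: list[SummaryRecord] = []
    for k in range(n):
        seed = base_seed + k
        try:
            traj = run_simulation(params, seed=seed, snapshot_every=None)
            records.append(
                summarize(traj.final, params, seed=seed, condition=condition.name)
            )
        except FloatingPointError:
            nan = float("nan")
            records.append(
                SummaryRecord(nan, nan, nan, nan, 0, False, True, nan, nan,
                              seed=seed, condition=condition.name)
            )
    return records


@dataclass
class ComparisonResult:
    """Two-arm ensemble comparison on one summary statistic."""

    statistic: str
    baseline_mean: float
    condition_mean: float
    percent_change: float
    p_value: float
    p_corrected: float
    n_condition: int
    n_baseline: int


def _values(records: Iterable[SummaryRecord], statistic: str) -> np.ndarray:
    vals = np.array([getattr(r, statistic) for r in records], dtype=float)
    return vals[np.isfinite(vals)]


def compare(
    condition_records: list[SummaryRecord],
    baseline_records: list[SummaryRecord],
    statistic: str = "horizontal_distance",
    n_tests: int = 1,
) -> ComparisonResult:
    """Mann–Whitney U (two-sided) + percent change of means + Bonferroni."""
    x = _values(condition_records, statistic)
    y = _values(baseline_records, statistic)
    if x.size == 0 or y.size == 0:
        raise ValueError("both ensembles must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        p = 1.0
    else:
        p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
    mb, mc = float(y.mean()), float(x.mean())
    return ComparisonResult(
        statistic=statistic,
        baseline_mean=mb,
        condition_mean=mc,
        percent_change=100.0 * (mc - mb) / mb,
        p_value=p,
        p_corrected=min(1.0, p * n_tests),
        n_condition=int(x.size),
        n_baseline=int(y.size),
    )
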
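"""Model parameters, phenotype/experiment switches, and validation.

All quantities are in micrometres and minutes. The defaults reproduce the
baseline regime of the chick cranial neural crest migration model: cells of
body radius ``R_cell`` sense fibronectin (FN) and neighbours out to a
filopodial radius ``R_filo``, migrate on an open square domain whose left
boundary represents the neural tube, and remodel an initially punctate FN
lattice of spacing ``lambda_fn`` into oriented fibers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from enum import Enum
from typing import Any


class GuidingScope(str, Enum):
    """Which phenotype feels the corridor-aligned guiding force."""

    NONE = "none"
    LEADERS_ONLY = "leaders_only"
    BOTH = "both"


class SecretionScope(str, Enum):
    """Which phenotype may deposit new FN puncta."""

    LEADERS_ONLY = "leaders_only"
    NONE = "none"
    BOTH = "both"


class RemodelingScope(str, Enum):
    """Which phenotype may assemble puncta into fibers and reorient fibers."""

    BOTH = "both"
    FOLLOWERS_ONLY = "followers_only"
    LEADERS_ONLY = "leaders_only"
    NONE = "none"


_ENUM_FIELDS = {
    "guiding_scope": GuidingScope,
    "secretion_scope": SecretionScope,
    "remodeling_scope": RemodelingScope,
}


@dataclass
class SimulationParameters:
    """All model constants plus experiment switches.

    Lengths in µm, times in min, speeds in µm/min; force weights are
    dimensionless (arbitrary units). ``chi`` weights haptotaxis (χ=1)
    against contact guidance (χ=0) in the cell–ECM force direction;
    ``z`` weights the corridor guiding force against the physical forces.

    ``chi_leader``/``chi_follower`` and ``gamma_fn_leader``/
    ``gamma_fn_follower`` are optional per-phenotype overrides (``None``
    means "use the global value"); they exist so gain/loss-of-function
    experiments can target a single phenotype.
    """

    R_filo: float = 27.5          # filopodial sensing radius
    R_cell: float = 7.5           # cell body radius
    l_entr: float = 120.0         # entrance strip width on the neural tube
    T_ave: float = 30.0           # mean FN secretion interval (secretory cells)
    T_half: float = 30.0          # fiber reorientation half-angle time
    s_fn_max: float = 0.8         # speed cap when sensing FN
    s_off_max: float = 0.05       # speed cap when not sensing FN
    dt: float = 0.1               # time step
    gamma_fn: float = 300.0       # haptotaxis kernel height γFN
    gamma_cell: float = 100.0     # repulsion kernel height γcell
    lambda_fn: float = 20.0       # initial FN lattice spacing
    chi: float = 0.5              # haptotaxis–contact-guidance weight χ
    c_leader: float = 0.5         # repulsion strength of secretory cells
    c_follower: float = 0.5       # repulsion strength of non-secretory cells
    z: float = 0.0                # guiding-force weight
    guiding_scope: GuidingScope = GuidingScope.NONE
    secretion_scope: SecretionScope = SecretionScope.LEADERS_ONLY
    T_ave_follower: float = 30.0  # follower secretion interval (if enabled)
    remodeling_scope: RemodelingScope = RemodelingScope.BOTH
    eta: float = 1.0              # friction coefficient (fixed at 1)
    contact_strength: float = 10.0  # overlap (contact) repulsion strength
    domain_side: float = 500.0    # square domain side length
    duration: float = 720.0       # simulated time (12 hr)
    kappa_cap: float = 700.0      # clamp on von Mises concentration
    chi_leader: float | None = None
    chi_follower: float | None = None
    gamma_fn_leader: float | None = None
    gamma_fn_follower: float | None = None

    def __post_init__(self) -> None:
        for name, enum_cls in _ENUM_FIELDS.items():
            value = getattr(self, name)
            if not isinstance(value, enum_cls):
                setattr(self, name, enum_cls(value))

    # -- phenotype-resolved accessors -------------------------------------
    def chi_for(self, is_leader: bool) -> float:
        override = self.chi_leader if is_leader else self.chi_follower
        return self.chi if override is None else override

    def gamma_fn_for(self, is_leader: bool) -> float:
        override = self.gamma_fn_leader if is_leader else self.gamma_fn_follower
        return self.gamma_fn if override is None else override

    def c_for(self, is_leader: bool) -> float:
        return self.c_leader if is_leader else self.c_follower

    def replace(self, **overrides: Any) -> "SimulationParameters":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = value.value if isinstance(value, Enum) else value
        return out


def default_parameters(**overrides: Any) -> SimulationParameters:
    """Return the baseline parameter regime (optionally overridden)."""
    return SimulationParameters(**overrides)


def parameters_from_dict(data: dict[str, Any]) -> SimulationParameters:
    """Build parameters from a flat mapping; unknown keys are rejected."""
    known = {f.name for f in fields(SimulationParameters)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise KeyError(f"unknown parameter key(s): {', '.join(unknown)}")
    return SimulationParameters(**data)


_POSITIVE_FIELDS = (
    "R_filo", "R_cell", "l_entr", "T_ave", "T_half", "s_fn_max",
    "s_off_max", "dt", "lambda_fn", "T_ave_follower", "domain_side",
    "kappa_cap",
)


def validate(params: SimulationParameters) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    issues: list[str] = []
    for name in _POSITIVE_FIELDS:
        if not getattr(params, name) > 0:
            issues.append(f"{name} must be > 0")
    if params.duration < 0:
        issues.append("duration must be >= 0")
    if not params.R_cell < params.R_filo:
        issues.append("R_cell < R_filo is required")
    for name in ("chi", "z"):
        if not 0.0 <= getattr(params, name) <= 1.0:
            issues.append(f"{name} must lie in [0, 1]")
    for name in ("chi_leader", "chi_follower"):
        value = getattr(params, name)
        if value is not None and not 0.0 <= value <= 1.0:
            issues.append(f"{name} must lie in [0, 1]")
    for name in ("c_leader", "c_follower", "gamma_fn", "gamma_cell",
                 "contact_strength"):
        if getattr(params, name) < 0:
            issues.append(f"{name} must be >= 0")
    for name in ("gamma_fn_leader", "gamma_fn_follower"):
        value = getattr(params, name)
        if value is not None and value < 0:
            issues.append(f"{name} must be >= 0")
    if params.eta != 1.0:
        issues.append("eta is fixed at 1")
    return issues
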
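"""Run configuration: dataclasses, validation, and YAML round-trip.

A single configuration document drives the whole pipeline.  The default
shipped with the package (``data/default_config.yaml``) holds the base-case
inputs: drug prices and dosing, transition probabilities, state utilities,
unit costs, willingness-to-pay thresholds, sensitivity-analysis settings and
an illustrative budget-impact block.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ArmConfig",
    "UncertaintyConfig",
    "ComparisonConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "default_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration document is missing or inconsistent."""


@dataclass
class ArmConfig:
    """One treatment strategy: dosing, price and transition inputs.

    ``n_effective`` is the sample size behind the arm's transition
    probabilities (matched effective sample size for the weighted arm,
    trial enrolment for the comparator); it sets the binomial standard
    errors used when transition probabilities are sampled probabilistically.
    """

    name: str
    price_per_tablet: float
    tablets_per_day: int
    p_ah: float
    p_hs: float
    n_effective: int

    def drug_cost_per_cycle(self, days_per_cycle: int) -> float:
        return self.price_per_tablet * self.tablets_per_day * days_per_cycle

    def validate(self) -> None:
        if self.price_per_tablet < 0:
            raise ConfigError(f"arm {self.name}: negative price_per_tablet")
        for p in ("p_ah", "p_hs"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"arm {self.name}: {p}={v} outside [0, 1]")
        if self.n_effective < 1:
            raise ConfigError(f"arm {self.name}: n_effective < 1")


@dataclass
class UncertaintyConfig:
    n_draws: int = 1000
    seed: int = 20240607
    dsa_pct: float = 0.10
    sample_transitions: bool = True
    ceac_grid_points: int = 500


@dataclass
class ComparisonConfig:
    """Anchor-arm summaries for the indirect comparison.

    The rabeprazole (anchor) arm results of the two source trials were not
    published in usable form; the values shipped in the default document are
    synthetic placeholders that support qualitative checks only.
    """

    anchor1_n: int = 218
    anchor1_healing_rate: float = 0.853
    anchor1_adr_rate: float = 0.102
    anchor2_n: int = 130
    anchor2_healing_rate: float = 0.820
    anchor2_adr_rate: float = 0.055
    comparator_n: int = 129
    comparator_healing_rate: float = 0.837
    comparator_adr_rate: float = 0.0698


_REQUIRED_BLOCKS = (
    "arms",
    "transitions",
    "cycles",
    "utilities",
    "costs",
    "wtp",
)


@dataclass
class RunConfig:
    """Full model configuration (see the default YAML for field semantics)."""

    arms: dict[str, ArmConfig]
    p_sr: float
    p_recur: float
    n_cycles: int
    cycle_length_weeks: int
    days_per_cycle: int
    utilities: dict[str, float]
    exam_cost: float
    gastroscopy_cost: float
    followup_cost_per_cycle: float
    fixed_program_cost: float
    treatment_cycles: int = 2
    retreat_on_recurrence: bool = True
    gdp_per_capita: float = 85698.0
    wtp: float = 85698.0
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    bia: dict[str, Any] | None = None
    seed: int = 20240607

    def validate(self) -> None:
        for arm in self.arms.values():
            arm.validate()
        if set(self.utilities) != {"A", "H", "S", "R"}:
            raise ConfigError("utilities block must define states A, H, S, R")
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ConfigError(f"utility for state {s} outside [0, 1]")
        for nm in ("exam_cost", "gastroscopy_cost", "followup_cost_per_cycle",
                   "fixed_program_cost"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"{nm} is negative")
        for nm in ("p_sr", "p_recur"):
            if not 0.0 <= getattr(self, nm) <= 1.0:
                raise ConfigError(f"{nm} outside [0, 1]")
        if self.treatment_cycles > self.n_cycles:
            raise ConfigError("treatment_cycles exceeds n_cycles")

    def copy(self) -> "RunConfig":
        return copy.deepcopy(self)


def _build(doc: dict[str, Any]) -> RunConfig:
    for block in _REQUIRED_BLOCKS:
        if block not in doc:
            raise ConfigError(f"configuration missing required block: {block!r}")
    arms = {}
    for name, a in doc["arms"].items():
        tr = doc["transitions"].get(name)
        if tr is None:
            raise ConfigError(f"transitions block missing arm {name!r}")
        arms[name] = ArmConfig(
            name=name,
            price_per_tablet=float(a["price_per_tablet"]),
            tablets_per_day=int(a["tablets_per_day"]),
            p_ah=float(tr["p_ah"]),
            p_hs=float(tr["p_hs"]),
            n_effective=int(a["n_effective"]),
        )
    cyc = doc["cycles"]
    costs = doc["costs"]
    unc = UncertaintyConfig(**doc.get("uncertainty", {}))
    comp = ComparisonConfig(**doc.get("comparison", {}))
    cfg = RunConfig(
        arms=arms,
        p_sr=float(doc["transitions"]["p_sr"]),
        p_recur=float(doc["transitions"]["p_recur"]),
        n_cycles=int(cyc["n_cycles"]),
        cycle_length_weeks=int(cyc["cycle_length_weeks"]),
        days_per_cycle=int(cyc["days_per_cycle"]),
        utilities={k: float(v) for k, v in doc["utilities"].items()},
        exam_cost=float(costs["exam_cost"]),
        gastroscopy_cost=float(costs["gastroscopy_cost"]),
        followup_cost_per_cycle=float(costs["followup_cost_per_cycle"]),
        fixed_program_cost=float(costs["fixed_program_cost"]),
        treatment_cycles=int(cyc.get("treatment_cycles", 2)),
        retreat_on_recurrence=bool(cyc.get("retreat_on_recurrence", True)),
        gdp_per_capita=float(doc["wtp"]["gdp_per_capita"]),
        wtp=float(doc["wtp"]["threshold"]),
        uncertainty=unc,
        comparison=comp,
        bia=doc.get("bia"),
        seed=int(doc.get("seed", 20240607)),
    )
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("configuration document is not a mapping")
    return _build(doc)


def default_config() -> RunConfig:
    """The base-case configuration shipped with the package."""
    text = (
        importlib.resources.files("ducem")
        .joinpath("data/default_config.yaml")
        .read_text()
    )
    return _build(yaml.safe_load(text))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of a configuration, for run manifests."""
    payload = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
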
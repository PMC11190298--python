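"""Cost-utility analysis: incremental ratios, decision rule, base-case run.

The headline statistic is the incremental cost-utility ratio

    ICUR = (Cost_1 - Cost_2) / (QALY_1 - QALY_2)

judged against a willingness-to-pay (WTP) threshold of 1x China's 2022
per-capita GDP (85,698 ¥/QALY), with 2x and 3x multiples for acceptability
curves.  An intervention that is cheaper and more effective strictly
dominates; costlier and less effective is dominated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .markov import (
    MarkovSpec,
    StateValues,
    accrue_costs,
    accrue_qalys,
    build_transition_matrix,
    run_cohort,
)

__all__ = [
    "CEResult",
    "icur",
    "decide",
    "net_monetary_benefit",
    "run_arm",
    "run_base_case",
]


@dataclass
class CEResult:
    """Incremental cost-utility comparison of strategy 1 against strategy 2.

    ``icur`` is ``nan`` when the ratio is undefined (zero QALY difference)
    or suppressed by a dominance classification; ``dominance`` is one of
    ``None``, ``"dominant"`` (1 cheaper and more effective), ``"dominated"``
    (1 costlier and less effective) or ``"undefined"``.
    """

    cost1: float
    qalys1: float
    cost2: float
    qalys2: float
    delta_cost: float
    delta_qalys: float
    icur: float
    dominance: str | None

    @property
    def cost_utility_ratio_1(self) -> float:
        return self.cost1 / self.qalys1 if self.qalys1 > 0 else math.nan

    @property
    def cost_utility_ratio_2(self) -> float:
        return self.cost2 / self.qalys2 if self.qalys2 > 0 else math.nan


def icur(cost1: float, qalys1: float, cost2: float, qalys2: float) -> CEResult:
    """Incremental cost-utility ratio with dominance classification."""
    for v in (cost1, qalys1, cost2, qalys2):
        if not math.isfinite(v):
            raise ValueError("costs and QALYs must be finite")
    dc = cost1 - cost2
    dq = qalys1 - qalys2
    dominance: str | None = None
    ratio = math.nan
    if dq == 0.0:
        dominance = "undefined"
    elif dc < 0 and dq > 0:
        dominance = "dominant"
    elif dc > 0 and dq < 0:
        dominance = "dominated"
    else:
        ratio = dc / dq
    return CEResult(cost1, qalys1, cost2, qalys2, dc, dq, ratio, dominance)


def decide(result: CEResult, wtp: float) -> bool:
    """Cost-effective at ``wtp``? True iff dominant, or ICUR defined and
    strictly below the threshold."""
    if result.dominance == "dominant":
        return True
    if result.dominance in ("dominated", "undefined"):
        return False
    return result.icur < wtp


def net_monetary_benefit(cost: float, qalys: float, wtp: float) -> float:
    """wtp x QALYs - cost.  For positive incremental QALYs, a positive
    incremental NMB is equivalent to ICUR < wtp."""
    return wtp * qalys - cost


def run_arm(
    cfg: RunConfig,
    arm: str,
    utilities: np.ndarray | None = None,
    drug_cost_per_cycle: float | None = None,
    exam_cost: float | None = None,
    gastroscopy_cost: float | None = None,
    p_ah: float | None = None,
    p_hs: float | None = None,
) -> tuple[float, float]:
    """Run one strategy's cohort model; return (total cost, total QALYs).

    Keyword overrides exist so sensitivity analyses can perturb single
    inputs without mutating the configuration.
    """
    a = cfg.arms[arm]
    P = build_transition_matrix(
        a.p_ah if p_ah is None else p_ah,
        a.p_hs if p_hs is None else p_hs,
        cfg.p_sr,
        cfg.p_recur,
    )
    spec = MarkovSpec(P, n_cycles=cfg.n_cycles,
                      cycle_length_weeks=cfg.cycle_length_weeks)
    trace = run_cohort(spec)
    if utilities is None:
        utilities = np.array([cfg.utilities[s] for s in "AHSR"])
    values = StateValues(
        utilities=utilities,
        drug_cost_per_cycle=(
            a.drug_cost_per_cycle(cfg.days_per_cycle)
            if drug_cost_per_cycle is None else drug_cost_per_cycle
        ),
        exam_cost=cfg.exam_cost if exam_cost is None else exam_cost,
        gastroscopy_cost=(
            cfg.gastroscopy_cost if gastroscopy_cost is None else gastroscopy_cost
        ),
        followup_cost_per_cycle=cfg.followup_cost_per_cycle,
        fixed_program_cost=cfg.fixed_program_cost,
    )
    cost = accrue_costs(trace, values, cfg.treatment_cycles,
                        cfg.retreat_on_recurrence)
    qalys = accrue_qalys(trace, values)
    return cost, qalys


def run_base_case(cfg: RunConfig, arm1: str = "anaprazole",
                  arm2: str = "ilaprazole") -> CEResult:
    """Base-case two-arm cost-utility comparison."""
    c1, q1 = run_arm(cfg, arm1)
    c2, q2 = run_arm(cfg, arm2)
    return icur(c1, q1, c2, q2)
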
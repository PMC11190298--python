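"""Four-state cohort Markov model of duodenal-ulcer healing.

States, in order: active ulcer (A), healing (H), scar (S) and recovery (R).
The cohort advances in 2-week cycles under a row-stochastic transition
matrix.  Structural assumptions: an active ulcer must pass through the
healing stage before scarring (A->S and A->R are structural zeros), there is
no death state over the 48-week horizon, and recovered patients may relapse
to the active stage (recurrence).

Outputs are per-cycle state occupancy plus accrued quality-adjusted life
years (QALYs) and direct medical costs per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STATES",
    "MarkovSpec",
    "CohortTrace",
    "StateValues",
    "build_transition_matrix",
    "run_cohort",
    "accrue_qalys",
    "accrue_costs",
]

STATES = ("A", "H", "S", "R")

_ROW_TOL = 1e-12
_TRACE_TOL = 1e-9


def build_transition_matrix(
    p_ah: float, p_hs: float, p_sr: float, p_recur: float
) -> np.ndarray:
    """Assemble the 4x4 per-cycle transition matrix.

    Parameters are single-cycle probabilities: active->healing, healing->scar,
    scar->recovery and recovery->active (recurrence).  Each state otherwise
    stays put, so every row sums to one by construction.
    """
    for name, p in (("p_ah", p_ah), ("p_hs", p_hs), ("p_sr", p_sr),
                    ("p_recur", p_recur)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    return np.array(
        [
            [1.0 - p_ah, p_ah, 0.0, 0.0],
            [0.0, 1.0 - p_hs, p_hs, 0.0],
            [0.0, 0.0, 1.0 - p_sr, p_sr],
            [p_recur, 0.0, 0.0, 1.0 - p_recur],
        ]
    )


@dataclass
class MarkovSpec:
    """Cohort-model specification: matrix, horizon and starting vector."""

    transition_matrix: np.ndarray
    n_cycles: int = 24
    cycle_length_weeks: int = 2
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(
            self.initial_distribution, dtype=float
        )
        P = self.transition_matrix
        if P.shape != (len(STATES), len(STATES)):
            raise ValueError(f"transition matrix must be 4x4, got {P.shape}")
        if (P < -_ROW_TOL).any() or (P > 1 + _ROW_TOL).any():
            raise ValueError("transition probabilities outside [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial_distribution.sum(), 1.0, atol=_ROW_TOL):
            raise ValueError("initial distribution must sum to 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class CohortTrace:
    """State-occupancy matrix: row 0 is the initial distribution."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(STATES):
            raise ValueError("occupancy must be (n_cycles+1) x 4")
        if (occ < -_TRACE_TOL).any():
            raise ValueError("negative occupancy")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=_TRACE_TOL):
            raise ValueError("occupancy rows must sum to 1")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def run_cohort(spec: MarkovSpec) -> CohortTrace:
    """Advance the cohort: occupancy[t+1] = occupancy[t] @ P."""
    occ = np.empty((spec.n_cycles + 1, len(STATES)))
    occ[0] = spec.initial_distribution
    P = spec.transition_matrix
    for t in range(spec.n_cycles):
        occ[t + 1] = occ[t] @ P
    return CohortTrace(occ)


@dataclass
class StateValues:
    """Per-state QALY weights and the cost pathway's unit inputs.

    ``utilities`` is ordered (A, H, S, R).  ``drug_cost_per_cycle`` is the
    14-day drug acquisition cost (daily tablets x unit price).  The
    examination and gastroscopy costs are billed as scheduled panels; the
    follow-up fee accrues each cycle a patient has not recovered; the fixed
    programme cost is a per-patient one-off covering the unpriced residual
    direct medical costs (registration, laboratory work, adverse-event
    management).
    """

    utilities: np.ndarray
    drug_cost_per_cycle: float = 0.0
    exam_cost: float = 0.0
    gastroscopy_cost: float = 0.0
    followup_cost_per_cycle: float = 0.0
    fixed_program_cost: float = 0.0

    def __post_init__(self) -> None:
        self.utilities = np.asarray(self.utilities, dtype=float)
        if self.utilities.shape != (len(STATES),):
            raise ValueError("need one utility per state (A, H, S, R)")
        if (self.utilities < 0).any() or (self.utilities > 1).any():
            raise ValueError("utilities must lie in [0, 1]")
        for nm in ("drug_cost_per_cycle", "exam_cost", "gastroscopy_cost",
                   "followup_cost_per_cycle", "fixed_program_cost"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} is negative")


def accrue_qalys(trace: CohortTrace, values: StateValues) -> float:
    """Total QALYs per patient over the horizon.

    Each of the ``n`` cycles contributes occupancy-weighted utility with
    weight 1/n, so a cohort spending the whole horizon in a state of utility
    u accrues exactly u QALYs.  No half-cycle correction and no discounting
    (horizon under one year).
    """
    occ = trace.occupancy
    n = trace.n_cycles
    return float((occ[1:] @ values.utilities).sum() / n)


def accrue_costs(
    trace: CohortTrace,
    values: StateValues,
    treatment_cycles: int = 2,
    retreat_on_recurrence: bool = True,
) -> float:
    """Total direct medical cost per patient over the horizon (¥).

    The pathway bills, per patient:

    * an examination + gastroscopy panel at entry (diagnosis) and another at
      the end of the initial course (``treatment_cycles``, week-4 endoscopic
      assessment) — full cohort;
    * drug cost for each cycle a patient occupies the active state (billed on
      start-of-cycle occupancy).  With ``retreat_on_recurrence`` the billing
      runs over the whole horizon, so persistent and recurrent active disease
      is retreated; otherwise only the initial course is billed;
    * the follow-up fee for every cycle a patient has not recovered;
    * the fixed residual programme cost once.
    """
    occ = trace.occupancy
    n = trace.n_cycles
    if treatment_cycles > n:
        raise ValueError("treatment_cycles exceeds the trace horizon")
    panels = 2.0 * (values.exam_cost + values.gastroscopy_cost)
    drug_horizon = n if retreat_on_recurrence else treatment_cycles
    drug = values.drug_cost_per_cycle * occ[:drug_horizon, 0].sum()
    followup = values.followup_cost_per_cycle * (1.0 - occ[:n, 3]).sum()
    return float(panels + drug + followup + values.fixed_program_cost)
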
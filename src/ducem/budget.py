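"""Budget impact analysis: 3-year payer expenditure projection.

Projects annual insurance-fund expenditure on proton-pump inhibitors (PPIs)
for duodenal ulcer under two scenarios — with and without the new drug
listed — and reports the incremental cost as a share of the fund budget.
Annual expenditure is

    patients_y x consultation_rate x reimbursement_rate
        x sum_d share_{d,y} x course_cost_d .

In the "without" scenario the new drug's share is reallocated to the
incumbent drugs proportionally to their shares.  Flows are undiscounted
nominal ¥ over the short horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DrugMarket", "BIAInputs", "project_expenditure",
           "incremental_share", "run_bia"]


@dataclass(frozen=True)
class DrugMarket:
    """One drug's course cost and market-share trajectory."""

    name: str
    course_cost: float
    shares: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.course_cost < 0:
            raise ValueError(f"{self.name}: negative course cost")
        if any(not 0.0 <= s <= 1.0 for s in self.shares):
            raise ValueError(f"{self.name}: shares outside [0, 1]")


@dataclass(frozen=True)
class BIAInputs:
    base_year: int
    horizon: int
    eligible_patients_per_year: tuple[float, ...]
    consultation_rate: float
    reimbursement_rate: float
    drugs: tuple[DrugMarket, ...]
    new_drug: str
    fund_budget_per_year: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for nm in ("eligible_patients_per_year", "fund_budget_per_year"):
            if len(getattr(self, nm)) != self.horizon:
                raise ValueError(f"{nm} must list one value per horizon year")
        if any(p < 0 for p in self.eligible_patients_per_year):
            raise ValueError("negative patient counts")
        if any(b <= 0 for b in self.fund_budget_per_year):
            raise ValueError("fund budgets must be positive")
        for r in (self.consultation_rate, self.reimbursement_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.new_drug not in {d.name for d in self.drugs}:
            raise ValueError(f"new_drug {self.new_drug!r} not among drugs")
        for d in self.drugs:
            if len(d.shares) != self.horizon:
                raise ValueError(f"{d.name}: one share per horizon year")
        for y in range(self.horizon):
            tot = sum(d.shares[y] for d in self.drugs)
            if tot > 1.0 + 1e-9:
                raise ValueError(f"year {y}: total market share {tot} > 1")

    @classmethod
    def from_dict(cls, doc: dict) -> "BIAInputs":
        drugs = tuple(
            DrugMarket(name, float(d["course_cost"]),
                       tuple(float(s) for s in d["shares"]))
            for name, d in doc["drugs"].items()
        )
        return cls(
            base_year=int(doc["base_year"]),
            horizon=int(doc["horizon"]),
            eligible_patients_per_year=tuple(
                float(v) for v in doc["eligible_patients_per_year"]),
            consultation_rate=float(doc["consultation_rate"]),
            reimbursement_rate=float(doc["reimbursement_rate"]),
            drugs=drugs,
            new_drug=str(doc["new_drug"]),
            fund_budget_per_year=tuple(
                float(v) for v in doc["fund_budget_per_year"]),
        )


def _shares(inputs: BIAInputs, scenario: str) -> dict[str, np.ndarray]:
    shares = {d.name: np.array(d.shares, dtype=float) for d in inputs.drugs}
    if scenario == "with":
        return shares
    if scenario != "without":
        raise ValueError("scenario must be 'with' or 'without'")
    new = shares[inputs.new_drug]
    incumbents = {n: s for n, s in shares.items() if n != inputs.new_drug}
    out = {inputs.new_drug: np.zeros_like(new)}
    total_inc = sum(incumbents.values())
    for n, s in incumbents.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total_inc > 0, s / np.where(total_inc > 0,
                                                        total_inc, 1.0), 0.0)
        out[n] = s + new * frac
    return out


def project_expenditure(inputs: BIAInputs, scenario: str) -> np.ndarray:
    """Annual reimbursed expenditure (¥) for one scenario."""
    shares = _shares(inputs, scenario)
    costs = {d.name: d.course_cost for d in inputs.drugs}
    pats = np.array(inputs.eligible_patients_per_year, dtype=float)
    blended = sum(shares[n] * costs[n] for n in shares)
    return (pats * inputs.consultation_rate * inputs.reimbursement_rate
            * blended)


def incremental_share(incremental: np.ndarray,
                      budgets: np.ndarray) -> np.ndarray:
    """Incremental expenditure as a percentage of the fund budget."""
    budgets = np.asarray(budgets, dtype=float)
    if (budgets <= 0).any():
        raise ValueError("fund budgets must be positive")
    return 100.0 * np.asarray(incremental, dtype=float) / budgets


def run_bia(inputs: BIAInputs) -> pd.DataFrame:
    """Per-year projection table for both scenarios."""
    with_new = project_expenditure(inputs, "with")
    without_new = project_expenditure(inputs, "without")
    inc = with_new - without_new
    years = [inputs.base_year + 1 + y for y in range(inputs.horizon)]
    return pd.DataFrame({
        "year": years,
        "expenditure_without_listing": without_new,
        "expenditure_with_listing": with_new,
        "incremental": inc,
        "incremental_pct_of_budget": incremental_share(
            inc, np.array(inputs.fund_budget_per_year)),
    })
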
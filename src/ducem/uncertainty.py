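"""Deterministic and probabilistic sensitivity analysis.

Deterministic (DSA): each model parameter is moved one-at-a-time to the
bounds of a +/-10% range around its base value and the two-arm cost-utility
model is re-run; the resulting ICUR swing per parameter is displayed as a
tornado table.  Shared parameters (examination, gastroscopy, utilities) move
simultaneously in both arms; drug prices are arm-specific.

Probabilistic (PSA): second-order Monte Carlo.  Costs are sampled from Gamma
and utilities from Beta distributions fitted by the method of moments to the
published mean and standard error (SE = range width / (2 x 1.96)).  By
default the four arm-specific transition probabilities are also sampled,
from Beta distributions with binomial standard errors at the trial
(effective) sample sizes; cost/utility uncertainty alone leaves the adoption
decision essentially certain at any plausible threshold.  Results feed the
cost-effectiveness plane and the acceptability curve (CEAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .economics import CEResult, decide, icur, run_arm

__all__ = [
    "EconParameter",
    "se_from_range",
    "pct_range",
    "gamma_from_mean_se",
    "beta_from_mean_se",
    "table1_parameters",
    "run_dsa",
    "run_psa",
    "ceac",
]

Z95 = 1.96


def se_from_range(low: float, high: float) -> float:
    """Standard error implied by a 95% range: (high - low) / (2 x 1.96)."""
    if high < low:
        raise ValueError(f"range inverted: high={high} < low={low}")
    return (high - low) / (2.0 * Z95)


def pct_range(base: float, pct: float = 0.10) -> tuple[float, float]:
    """Symmetric percentage range around a base value."""
    if not math.isfinite(base):
        raise ValueError("base must be finite")
    return base * (1.0 - pct), base * (1.0 + pct)


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments Gamma fit; returns (shape, rate)."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma fit requires mean > 0 and se > 0")
    shape = mean * mean / (se * se)
    rate = mean / (se * se)
    return shape, rate


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments Beta fit; returns (alpha, beta)."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta fit requires mean in (0, 1)")
    if se <= 0:
        raise ValueError("beta fit requires se > 0")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"se too large for a Beta distribution: need se^2 < mean(1-mean) "
            f"= {mean * (1 - mean):.6g}, got se^2 = {se * se:.6g}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass
class EconParameter:
    """One probabilistic model input (a parameter-table row)."""

    name: str
    base: float
    low: float
    high: float
    family: str  # "gamma" or "beta"
    se: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: base outside [low, high]")
        implied = se_from_range(self.low, self.high)
        if self.se is None:
            self.se = implied
        elif abs(self.se - implied) > 1e-4:
            raise ValueError(
                f"{self.name}: se={self.se} inconsistent with range "
                f"(implied {implied:.6f})"
            )
        if self.family not in ("gamma", "beta"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.family == "beta" and not 0.0 < self.base < 1.0:
            raise ValueError(f"{self.name}: beta base must lie in (0, 1)")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw from the fitted distribution (degenerate if se == 0)."""
        if self.se == 0.0:
            return np.full(size, self.base)
        if self.family == "gamma":
            shape, rate = gamma_from_mean_se(self.base, self.se)
            return rng.gamma(shape, 1.0 / rate, size)
        a, b = beta_from_mean_se(self.base, self.se)
        return rng.beta(a, b, size)


def table1_parameters(cfg: RunConfig, pct: float = 0.10) -> list[EconParameter]:
    """The seven probabilistic cost/utility parameters of the base case."""
    params = []
    for arm in ("anaprazole", "ilaprazole"):
        base = cfg.arms[arm].price_per_tablet
        lo, hi = pct_range(base, pct)
        params.append(EconParameter(f"{arm}_drug_cost", base, lo, hi, "gamma"))
    for nm in ("exam_cost", "gastroscopy_cost"):
        base = getattr(cfg, nm)
        lo, hi = pct_range(base, pct)
        params.append(EconParameter(nm, base, lo, hi, "gamma"))
    for s in "AHS":
        base = cfg.utilities[s]
        lo, hi = pct_range(base, pct)
        params.append(EconParameter(f"utility_{s}", base, lo, hi, "beta"))
    return params


def _evaluate(cfg: RunConfig, values: dict[str, float]) -> CEResult:
    """Re-run the two-arm model with named parameters overridden."""
    util = np.array([
        values.get("utility_A", cfg.utilities["A"]),
        values.get("utility_H", cfg.utilities["H"]),
        values.get("utility_S", cfg.utilities["S"]),
        cfg.utilities["R"],
    ])
    per_arm = {}
    for arm in ("anaprazole", "ilaprazole"):
        a = cfg.arms[arm]
        price = values.get(f"{arm}_drug_cost", a.price_per_tablet)
        per_arm[arm] = run_arm(
            cfg,
            arm,
            utilities=util,
            drug_cost_per_cycle=price * a.tablets_per_day * cfg.days_per_cycle,
            exam_cost=values.get("exam_cost", cfg.exam_cost),
            gastroscopy_cost=values.get("gastroscopy_cost",
                                        cfg.gastroscopy_cost),
            p_ah=values.get(f"{arm}_p_ah"),
            p_hs=values.get(f"{arm}_p_hs"),
        )
    (c1, q1), (c2, q2) = per_arm["anaprazole"], per_arm["ilaprazole"]
    return icur(c1, q1, c2, q2)


def run_dsa(
    cfg: RunConfig, params: list[EconParameter] | None = None
) -> pd.DataFrame:
    """One-way sensitivity analysis; tornado table sorted by |ICUR swing|.

    Returns one row per parameter with the ICUR (¥/QALY) at its low and high
    bound, the absolute swing, and whether the comparison remains
    cost-effective at the configured threshold at both bounds.
    """
    if params is None:
        params = table1_parameters(cfg, cfg.uncertainty.dsa_pct)
    rows = []
    for p in params:
        results = {}
        for tag, v in (("low", p.low), ("high", p.high)):
            try:
                res = _evaluate(cfg, {p.name: v})
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(
                    f"model failed at {p.name} {tag} bound ({v})"
                ) from exc
            results[tag] = res
        rows.append(
            {
                "parameter": p.name,
                "icur_at_low": results["low"].icur,
                "icur_at_high": results["high"].icur,
                "swing": abs(
                    (0.0 if math.isnan(results["high"].icur)
                     else results["high"].icur)
                    - (0.0 if math.isnan(results["low"].icur)
                       else results["low"].icur)
                ),
                "cost_effective_at_low": decide(results["low"], cfg.wtp),
                "cost_effective_at_high": decide(results["high"], cfg.wtp),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("swing", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _transition_parameters(cfg: RunConfig) -> list[tuple[str, float, float]]:
    """(name, base, binomial SE) for the sampled transition probabilities."""
    out = []
    for arm in ("anaprazole", "ilaprazole"):
        a = cfg.arms[arm]
        for nm, p in (("p_ah", a.p_ah), ("p_hs", a.p_hs)):
            se = math.sqrt(p * (1.0 - p) / a.n_effective)
            out.append((f"{arm}_{nm}", p, se))
    return out


def run_psa(
    cfg: RunConfig,
    n_draws: int | None = None,
    seed: int | None = None,
    params: list[EconParameter] | None = None,
) -> pd.DataFrame:
    """Second-order Monte Carlo over the model's parameter distributions.

    Returns one row per draw holding the sampled parameter vector, per-arm
    costs and QALYs, and the incremental quantities.  Deterministic for a
    given seed.
    """
    if n_draws is None:
        n_draws = cfg.uncertainty.n_draws
    if seed is None:
        seed = cfg.uncertainty.seed
    if params is None:
        params = table1_parameters(cfg, cfg.uncertainty.dsa_pct)
    for p in params:
        if p.se > 0:  # validate every distribution before any draw
            if p.family == "gamma":
                gamma_from_mean_se(p.base, p.se)
            else:
                beta_from_mean_se(p.base, p.se)
    rng = np.random.default_rng(seed)
    draws = {p.name: p.sample(rng, n_draws) for p in params}
    if cfg.uncertainty.sample_transitions:
        for nm, base, se in _transition_parameters(cfg):
            a, b = beta_from_mean_se(base, se)
            draws[nm] = rng.beta(a, b, n_draws)
    rows = []
    for i in range(n_draws):
        values = {nm: float(col[i]) for nm, col in draws.items()}
        res = _evaluate(cfg, values)
        rec = {"draw": i, **values,
               "cost_anaprazole": res.cost1, "qalys_anaprazole": res.qalys1,
               "cost_ilaprazole": res.cost2, "qalys_ilaprazole": res.qalys2,
               "delta_cost": res.delta_cost, "delta_qalys": res.delta_qalys}
        rows.append(rec)
    return pd.DataFrame(rows)


def ceac(samples: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of draws whose
    incremental net monetary benefit (wtp x dQALY - dCost) is positive.
    """
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if (wtp_grid < 0).any():
        raise ValueError("willingness-to-pay grid must be non-negative")
    dq = samples["delta_qalys"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": prob})
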
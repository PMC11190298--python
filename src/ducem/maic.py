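"""Anchored matching-adjusted indirect comparison (MAIC).

Individual patient data (IPD) from the anaprazole trial are reweighted so
their baseline covariate means match the published aggregate margins of the
ilaprazole trial.  Weights take the method-of-moments MAIC form
``w_i = exp(alpha' x_i)`` with covariates centred at the target moments;
minimising ``sum_i exp(alpha' x_centred_i)`` (convex) makes the gradient
vanish exactly when the weighted means equal the targets.  Relative effects
are expressed as odds ratios against the common anchor arm (rabeprazole) in
each trial and combined across trials by Bucher's method:

    log OR_AB = log OR_AC - log OR_BC,   se^2 = se_AC^2 + se_BC^2.

The weighted arm's binomial variance uses the effective sample size
ESS = (sum w)^2 / (sum w^2) as its denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .synthetic import ArmProfile

__all__ = [
    "AggregateBaseline",
    "MAICWeights",
    "ComparisonResult",
    "MAICConvergenceError",
    "MAICSingularityError",
    "MATCHED_COVARIATES",
    "estimate_weights",
    "effective_sample_size",
    "balance_table",
    "weighted_outcome_or",
    "aggregate_or",
    "bucher_combine",
]

#: first moments matched by default (age mean plus four proportions)
MATCHED_COVARIATES = ("age", "male", "stage_a1", "hp_positive", "single_ulcer")

Z95 = 1.96


class MAICConvergenceError(RuntimeError):
    """Target moment unattainable (outside the convex hull of the IPD)."""


class MAICSingularityError(RuntimeError):
    """A matched covariate has no variation in the IPD."""


@dataclass(frozen=True)
class AggregateBaseline:
    """Published summary moments of a comparator arm."""

    n: int
    means: dict[str, float]
    age_sd: float | None = None

    @classmethod
    def from_profile(cls, profile: ArmProfile) -> "AggregateBaseline":
        means = {"age": profile.age_mean, **profile.proportions}
        return cls(n=profile.n, means=means, age_sd=profile.age_sd)


@dataclass
class MAICWeights:
    """Per-patient MAIC weights plus diagnostics."""

    weights: np.ndarray
    ess: float
    alpha: np.ndarray = field(default_factory=lambda: np.array([]))
    covariates: tuple[str, ...] = ()

    def rescaled(self, total: float) -> np.ndarray:
        """Weights rescaled to a presentation total (e.g. a matched pseudo-N).
        Never used for variance computation."""
        return self.weights * (total / self.weights.sum())


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size, (sum w)^2 / (sum w^2)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    sw2 = (w * w).sum()
    if sw2 == 0:
        raise ValueError("all weights are zero")
    return float(w.sum() ** 2 / sw2)


def estimate_weights(
    ipd: pd.DataFrame,
    target: AggregateBaseline,
    covariates: tuple[str, ...] = MATCHED_COVARIATES,
) -> MAICWeights:
    """Method-of-moments MAIC weights matching first moments of ``target``.

    Raises :class:`MAICSingularityError` for a zero-variance covariate and
    :class:`MAICConvergenceError` when a target moment lies outside the
    convex hull of the IPD values (naming the covariate in both cases).
    After convergence the weighted means equal the targets to within 1e-6.
    """
    missing = [c for c in covariates if c not in ipd.columns]
    if missing:
        raise KeyError(f"IPD lacks matched covariates: {missing}")
    for c in covariates:
        if c not in target.means or not math.isfinite(target.means[c]):
            raise ValueError(f"target moment for {c!r} missing or non-finite")
    X = ipd[list(covariates)].to_numpy(dtype=float)
    mu = np.array([target.means[c] for c in covariates])
    for j, c in enumerate(covariates):
        col = X[:, j]
        if col.max() == col.min():
            raise MAICSingularityError(
                f"covariate {c!r} has zero variance in the IPD"
            )
        if not col.min() < mu[j] < col.max():
            raise MAICConvergenceError(
                f"target moment for {c!r} ({mu[j]}) lies outside the IPD "
                f"range ({col.min()}, {col.max()})"
            )
    Xc = X - mu
    scale = Xc.std(axis=0, ddof=0)
    Z = Xc / scale

    # minimise log(sum exp(Z a)): same minimiser as sum exp, numerically
    # stable, and its gradient is the weighted covariate mean residual
    def objective(a: np.ndarray) -> tuple[float, np.ndarray]:
        eta = Z @ a
        lse = special.logsumexp(eta)
        return lse, special.softmax(eta) @ Z

    res = optimize.minimize(
        objective, np.zeros(Z.shape[1]), jac=True, method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    eta = Z @ res.x
    w = np.exp(eta - eta.max())
    w *= len(w) / w.sum()  # mean weight 1, presentation only
    bal = np.abs(w @ Xc) / w.sum()
    if bal.max() > 1e-6:
        worst = covariates[int(bal.argmax())]
        raise MAICConvergenceError(
            f"weight solver failed to balance {worst!r} "
            f"(residual {bal.max():.2e})"
        )
    return MAICWeights(weights=w, ess=effective_sample_size(w),
                       alpha=res.x / scale, covariates=tuple(covariates))


def _two_proportion_p(p1: float, n1: float, p2: float, n2: float) -> float:
    """Two-sided pooled two-proportion test (chi-square with 1 df)."""
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _welchless_t_p(m1, s1, n1, m2, s2, n2) -> float:
    """Two-sided pooled-variance two-sample t-test from summary statistics."""
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.pvalue)


def balance_table(
    ipd: pd.DataFrame,
    weights: MAICWeights,
    target: AggregateBaseline,
) -> pd.DataFrame:
    """Before/after covariate balance against the aggregate target.

    Age is tested with a two-sample t-test from summary statistics, binary
    covariates with a pooled two-proportion chi-square test (no continuity
    correction).  "After" tests replace the IPD sample size with the ESS.
    """
    w = weights.weights
    rows = []
    for c in weights.covariates:
        col = ipd[c].to_numpy(dtype=float)
        before = float(col.mean())
        after = float((w @ col) / w.sum())
        tgt = target.means[c]
        if c == "age":
            sd = float(col.std(ddof=1))
            wmean = after
            wsd = math.sqrt(float((w @ (col - wmean) ** 2) / w.sum()))
            tgt_sd = target.age_sd if target.age_sd is not None else sd
            p_before = _welchless_t_p(before, sd, len(col),
                                      tgt, tgt_sd, target.n)
            p_after = _welchless_t_p(after, wsd, weights.ess,
                                     tgt, tgt_sd, target.n)
        else:
            p_before = _two_proportion_p(before, len(col), tgt, target.n)
            p_after = _two_proportion_p(after, weights.ess, tgt, target.n)
        rows.append({"covariate": c, "mean_before": before,
                     "mean_after": after, "target": tgt,
                     "p_before": p_before, "p_after": p_after})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """A relative effect on the log-odds scale with Wald inference."""

    log_or: float
    se_log_or: float

    def __post_init__(self) -> None:
        if not self.se_log_or > 0:
            raise ValueError("se_log_or must be positive")

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z95 * self.se_log_or)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z95 * self.se_log_or)

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.log_or) / self.se_log_or))

    def as_dict(self) -> dict[str, float]:
        return {"or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "log_or": self.log_or, "se_log_or": self.se_log_or,
                "p_value": self.p_value}


def _cells_to_result(a: float, b: float, c: float, d: float,
                     continuity: bool) -> ComparisonResult:
    if min(a, b, c, d) <= 0:
        if not continuity:
            raise ValueError(
                "degenerate 2x2 table (a zero cell); enable the "
                "Haldane-Anscombe continuity correction (continuity=True) "
                "or supply rates strictly inside (0, 1)"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ComparisonResult(log_or, se)


def weighted_outcome_or(
    outcomes: np.ndarray,
    weights: MAICWeights,
    anchor_rate: float,
    anchor_n: int,
    continuity: bool = True,
) -> ComparisonResult:
    """Weighted-arm odds ratio against the within-trial anchor arm.

    The weighted event rate is ``sum(w y) / sum(w)``; its binomial variance
    uses the effective sample size as denominator, the anchor arm's the
    actual ``anchor_n``.
    """
    y = np.asarray(outcomes, dtype=float)
    w = weights.weights
    if y.shape != w.shape:
        raise ValueError("outcomes and weights differ in length")
    if not 0.0 <= anchor_rate <= 1.0 or anchor_n < 1:
        raise ValueError("invalid anchor rate or size")
    pw = float((w @ y) / w.sum())
    ess = weights.ess
    return _cells_to_result(ess * pw, ess * (1 - pw),
                            anchor_n * anchor_rate,
                            anchor_n * (1 - anchor_rate), continuity)


def aggregate_or(
    rate1: float, n1: int, rate0: float, n0: int, continuity: bool = True
) -> ComparisonResult:
    """Odds ratio between two aggregate binomial arms (arm 1 vs arm 0)."""
    for r, n in ((rate1, n1), (rate0, n0)):
        if not 0.0 <= r <= 1.0 or n < 1:
            raise ValueError("invalid aggregate rate or size")
    return _cells_to_result(n1 * rate1, n1 * (1 - rate1),
                            n0 * rate0, n0 * (1 - rate0), continuity)


def bucher_combine(ac: ComparisonResult, bc: ComparisonResult
                   ) -> ComparisonResult:
    """Anchored indirect effect A vs B via the common comparator C."""
    return ComparisonResult(
        ac.log_or - bc.log_or,
        math.sqrt(ac.se_log_or ** 2 + bc.se_log_or ** 2),
    )
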
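"""Seeded synthetic patient-level trial data.

The matching-adjusted indirect comparison needs individual patient data
(IPD) for the anaprazole trial, which is not publicly deposited.  This
module generates synthetic IPD whose covariate margins and outcome rates
match the published baseline table, so the downstream pipeline is fully
testable.  Covariates are drawn independently (only margins are published):
age from a normal distribution truncated to the trial-plausible adult range
(18, 75) with its location calibrated so the *truncated* mean equals the
target, binary covariates from Bernoulli margins.  Binary outcomes (healing
at week 4, any adverse drug reaction) follow a logistic model in the five
covariates whose intercept is calibrated by bisection so the expected
marginal rate equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

__all__ = [
    "ArmProfile",
    "OutcomeModel",
    "COVARIATES",
    "ANAPRAZOLE_PROFILE",
    "ILAPRAZOLE_PROFILE",
    "generate_ipd",
    "summarize_arm",
    "read_ipd",
    "write_ipd",
    "load_profile",
    "save_profile",
]

AGE_BOUNDS = (18.0, 75.0)

#: model covariates, in the order used by the logistic outcome model
COVARIATES = ("age", "male", "stage_a1", "hp_positive", "single_ulcer")

_BINARY = ("male", "stage_a1", "hp_positive", "single_ulcer")


@dataclass(frozen=True)
class ArmProfile:
    """Published summary margins of one trial arm."""

    n: int
    age_mean: float
    age_sd: float
    prop_male: float
    prop_a1: float
    prop_hp: float
    prop_single: float
    healing_rate: float
    adr_rate: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        for nm in ("prop_male", "prop_a1", "prop_hp", "prop_single",
                   "healing_rate", "adr_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")

    @property
    def proportions(self) -> dict[str, float]:
        return {
            "male": self.prop_male,
            "stage_a1": self.prop_a1,
            "hp_positive": self.prop_hp,
            "single_ulcer": self.prop_single,
        }


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic covariate effects (log odds ratios) on the two outcomes.

    Age enters standardised by the profile mean/SD so coefficients are
    comparable across covariates.  Defaults are deliberately neutral (zero
    effects): no covariate-outcome association strengths are published.
    """

    healing: dict[str, float] = field(default_factory=dict)
    adr: dict[str, float] = field(default_factory=dict)

    def coef_vector(self, outcome: str) -> np.ndarray:
        coefs = getattr(self, outcome)
        unknown = set(coefs) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in outcome model: {unknown}")
        return np.array([coefs.get(c, 0.0) for c in COVARIATES])


#: published "before matching" margins of the anaprazole trial arm
ANAPRAZOLE_PROFILE = ArmProfile(
    n=220, age_mean=40.9, age_sd=11.10,
    prop_male=0.6363, prop_a1=0.8230, prop_hp=0.8136, prop_single=0.8227,
    healing_rate=0.879, adr_rate=0.0821,
)

#: published margins of the ilaprazole trial arm
ILAPRAZOLE_PROFILE = ArmProfile(
    n=129, age_mean=37.64, age_sd=11.14,
    prop_male=0.7054, prop_a1=0.7287, prop_hp=0.7674, prop_single=0.7209,
    healing_rate=0.837, adr_rate=0.0698,
)


def _truncnorm(age_mean: float, age_sd: float) -> stats.rv_continuous:
    """Truncated normal whose *truncated* mean equals ``age_mean``.

    Truncation to (18, 75) shifts the mean of a plain normal upward by a
    fraction of a year; the location is re-solved so sample means converge
    to the profile value rather than to a slightly offset one.
    """
    lo, hi = AGE_BOUNDS

    def shift(loc: float) -> float:
        a, b = (lo - loc) / age_sd, (hi - loc) / age_sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=age_sd) - age_mean

    loc = optimize.brentq(shift, lo, hi, xtol=1e-10)
    a, b = (lo - loc) / age_sd, (hi - loc) / age_sd
    return stats.truncnorm(a, b, loc=loc, scale=age_sd)


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-6
                         ) -> float:
    """Bisection for the intercept b0 with mean(expit(b0 + eta)) = target."""
    lo, hi = -40.0, 40.0
    flo = special.expit(lo + eta).mean() - target
    fhi = special.expit(hi + eta).mean() - target
    if flo > 0 or fhi < 0:
        raise ValueError("target rate unreachable for this outcome model")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if special.expit(mid + eta).mean() - target <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_ipd(
    profile: ArmProfile,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    n: int | None = None,
) -> pd.DataFrame:
    """Generate one arm of synthetic IPD, one row per patient.

    Deterministic for a given seed.  ``n`` overrides ``profile.n`` (useful
    for convergence checks at large sample sizes).
    """
    if outcome_model is None:
        outcome_model = OutcomeModel()
    n = profile.n if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    age = _truncnorm(profile.age_mean, profile.age_sd).rvs(
        size=n, random_state=rng
    )
    df = pd.DataFrame({"patient_id": [f"P{i + 1:06d}" for i in range(n)],
                       "age": age})
    for cov, p in profile.proportions.items():
        df[cov] = (rng.random(n) < p).astype(int)

    X = df[list(COVARIATES)].to_numpy(dtype=float)
    X[:, 0] = (X[:, 0] - profile.age_mean) / profile.age_sd  # standardised age
    for outcome, rate in (("healing", profile.healing_rate),
                          ("adr", profile.adr_rate)):
        beta = outcome_model.coef_vector(outcome)
        if rate in (0.0, 1.0) and not beta.any():
            prob = np.full(n, rate)
        else:
            eta = X @ beta
            b0 = _calibrate_intercept(eta, rate)
            prob = special.expit(b0 + eta)
        col = "healed" if outcome == "healing" else "adr"
        df[col] = (rng.random(n) < prob).astype(int)
    return df


def summarize_arm(records: pd.DataFrame) -> ArmProfile:
    """Exact sample moments of an IPD table.

    The healing and ADR rates are the simple event proportions (healed
    cases / total cases; ADR events / total participants).
    """
    if len(records) == 0:
        raise ValueError("cannot summarise an empty IPD table")
    return ArmProfile(
        n=len(records),
        age_mean=float(records["age"].mean()),
        age_sd=float(records["age"].std(ddof=1)) if len(records) > 1 else 1.0,
        prop_male=float(records["male"].mean()),
        prop_a1=float(records["stage_a1"].mean()),
        prop_hp=float(records["hp_positive"].mean()),
        prop_single=float(records["single_ulcer"].mean()),
        healing_rate=float(records["healed"].mean()),
        adr_rate=float(records["adr"].mean()),
    )


_IPD_COLUMNS = ["patient_id", "age", "male", "stage_a1", "hp_positive",
                "single_ulcer", "healed", "adr"]


def write_ipd(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=_IPD_COLUMNS)


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_IPD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IPD file missing columns: {sorted(missing)}")
    if ((df["age"] <= 0) | (df["age"] >= 120)).any():
        raise ValueError("ages outside (0, 120)")
    for c in _IPD_COLUMNS[2:]:
        if not df[c].isin((0, 1)).all():
            raise ValueError(f"column {c} must be binary 0/1")
    return df


def save_profile(profile: ArmProfile, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(profile.__dict__, fh, sort_keys=False)


def load_profile(path) -> ArmProfile:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ArmProfile(**doc)


def profile_with(profile: ArmProfile, **kwargs) -> ArmProfile:
    """Convenience: a copy of ``profile`` with fields replaced."""
    return replace(profile, **kwargs)
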
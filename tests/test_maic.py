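"""MAIC weighting, balance diagnostics, and the anchored Bucher comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from ducem.maic import (
    AggregateBaseline,
    ComparisonResult,
    MAICConvergenceError,
    MAICSingularityError,
    aggregate_or,
    balance_table,
    bucher_combine,
    effective_sample_size,
    estimate_weights,
    weighted_outcome_or,
)
from ducem.maic import MAICWeights


def _ipd(**cols):
    n = len(next(iter(cols.values())))
    base = {"patient_id": [f"P{i}" for i in range(n)]}
    return pd.DataFrame({**base, **cols})


class TestEffectiveSampleSize:
    def test_uniform_weights(self):
        assert effective_sample_size(np.ones(10)) == pytest.approx(10.0)

    def test_single_support_point(self):
        assert effective_sample_size(np.array([1.0, 0, 0, 0])) == pytest.approx(1.0)

    def test_direct_formula(self):
        assert effective_sample_size(np.array([2.0, 1.0, 1.0])) == pytest.approx(16 / 6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.zeros(3))


class TestEstimateWeights:
    def test_prebalanced_ipd_gets_uniform_weights(self):
        ipd = _ipd(x=[0.0, 1.0, 0.0, 1.0])
        target = AggregateBaseline(n=50, means={"x": 0.5})
        w = estimate_weights(ipd, target, covariates=("x",))
        assert np.allclose(w.weights, w.weights[0])
        assert w.ess == pytest.approx(4.0)

    def test_two_patient_closed_form(self):
        # one moment equation: w0*0 + w1*1 = 0.75(w0+w1)  =>  w1 = 3 w0
        ipd = _ipd(x=[0.0, 1.0])
        target = AggregateBaseline(n=10, means={"x": 0.75})
        w = estimate_weights(ipd, target, covariates=("x",))
        assert w.weights[1] / w.weights[0] == pytest.approx(3.0, abs=1e-6)

    def test_matches_dense_grid_oracle(self):
        """Solver weights agree with a dense grid search over the
        single weight-model coefficient on a 20-patient instance."""
        rng = np.random.default_rng(0)
        x = rng.random(20)
        ipd = _ipd(x=x)
        target = AggregateBaseline(n=30, means={"x": 0.62})
        w = estimate_weights(ipd, target, covariates=("x",))
        xc = x - 0.62
        center, span = 0.0, 20.0
        for _ in range(4):  # zoomed grid search down to step ~2e-8
            grid = np.linspace(center - span, center + span, 40_001)
            obj = np.array([np.exp(a * xc).sum() for a in grid])
            center = grid[obj.argmin()]
            span = 2 * (grid[1] - grid[0])
        wg = np.exp(center * xc)
        assert abs((wg @ x) / wg.sum() - (w.weights @ x) / w.weights.sum()) < 1e-8

    def test_centering_invariance(self, anaprazole_ipd, ilaprazole_target):
        shifted = anaprazole_ipd.copy()
        shifted["age"] = shifted["age"] + 100.0
        means = dict(ilaprazole_target.means)
        means["age"] += 100.0
        target = AggregateBaseline(n=ilaprazole_target.n, means=means,
                                   age_sd=ilaprazole_target.age_sd)
        w0 = estimate_weights(anaprazole_ipd, ilaprazole_target)
        w1 = estimate_weights(shifted, target)
        assert np.allclose(w0.weights, w1.weights, rtol=1e-6, atol=1e-9)

    def test_target_outside_hull_names_covariate(self):
        ipd = _ipd(x=[0.2, 0.4, 0.6])
        target = AggregateBaseline(n=10, means={"x": 0.9})
        with pytest.raises(MAICConvergenceError, match="x"):
            estimate_weights(ipd, target, covariates=("x",))

    def test_zero_variance_names_covariate(self):
        ipd = _ipd(x=[1.0, 1.0, 1.0])
        target = AggregateBaseline(n=10, means={"x": 0.5})
        with pytest.raises(MAICSingularityError, match="x"):
            estimate_weights(ipd, target, covariates=("x",))


class TestPublishedBaselineMatch:
    """Weighting the synthetic anaprazole arm to the ilaprazole column."""

    def test_weighted_means_hit_targets(self, anaprazole_ipd, ilaprazole_target,
                                        matched_weights):
        w = matched_weights.weights
        for cov, tgt in ilaprazole_target.means.items():
            wm = (w @ anaprazole_ipd[cov]) / w.sum()
            assert abs(wm - tgt) < 1e-6, cov

    def test_ess_bounds(self, matched_weights, anaprazole_ipd):
        assert 1.0 <= matched_weights.ess <= len(anaprazole_ipd)
        assert matched_weights.ess < 220

    def test_rescaled_counts_reproduce_matched_column(self, anaprazole_ipd,
                                                      matched_weights):
        """Weighted counts rescaled to the matched pseudo-N of 179."""
        w179 = matched_weights.rescaled(179)
        counts = {c: round(float(w179 @ anaprazole_ipd[c]))
                  for c in ("male", "stage_a1", "hp_positive", "single_ulcer")}
        assert counts == {"male": 126, "stage_a1": 130,
                          "hp_positive": 137, "single_ulcer": 129}

    def test_balance_table_pattern(self, anaprazole_ipd, ilaprazole_target,
                                   matched_weights):
        bal = balance_table(anaprazole_ipd, matched_weights, ilaprazole_target)
        bal = bal.set_index("covariate")
        # the published imbalance: single-ulcer proportion differs (p < 0.05)
        assert bal.loc["single_ulcer", "p_before"] < 0.05
        # sex and H. pylori were reported balanced before matching
        assert bal.loc["male", "p_before"] > 0.05
        assert bal.loc["hp_positive", "p_before"] > 0.05
        # after matching every weighted mean equals its target
        assert np.allclose(bal["mean_after"], bal["target"], atol=1e-6)
        assert (bal["p_after"] > 0.999).all()


class TestWeightedOutcomeOR:
    def test_equal_rates_give_unit_or(self):
        w = MAICWeights(weights=np.ones(100), ess=100.0)
        y = np.array([1] * 80 + [0] * 20)
        res = weighted_outcome_or(y, w, anchor_rate=0.8, anchor_n=100)
        assert res.or_ == pytest.approx(1.0)

    def test_direct_odds_arithmetic(self):
        # weighted rate 0.879 at ESS 179 vs anchor 0.800 at n=200
        res = aggregate_or(0.879, 179, 0.800, 200)
        assert res.or_ == pytest.approx((0.879 / 0.121) / (0.800 / 0.200),
                                        rel=1e-12)
        assert res.or_ == pytest.approx(1.816, abs=5e-3)

    def test_matches_bruteforce_table(self, anaprazole_ipd, matched_weights):
        y = anaprazole_ipd["healed"].to_numpy()
        res = weighted_outcome_or(y, matched_weights, 0.853, 218)
        # independent oracle: build the weighted 2x2 table by hand
        w = matched_weights.weights
        pw = (w * y).sum() / w.sum()
        ess = (w.sum()) ** 2 / (w ** 2).sum()
        a, b = ess * pw, ess * (1 - pw)
        c, d = 218 * 0.853, 218 * 0.147
        assert abs(res.log_or - math.log(a * d / (b * c))) < 1e-12
        assert abs(res.se_log_or
                   - math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)) < 1e-12

    def test_degenerate_rate_needs_continuity(self):
        w = MAICWeights(weights=np.ones(10), ess=10.0)
        y = np.ones(10)
        with pytest.raises(ValueError, match="continuity"):
            weighted_outcome_or(y, w, 0.8, 50, continuity=False)
        res = weighted_outcome_or(y, w, 0.8, 50, continuity=True)
        assert math.isfinite(res.log_or)


class TestBucher:
    def test_anchor_cancellation(self):
        x = ComparisonResult(log_or=0.37, se_log_or=0.21)
        res = bucher_combine(x, x)
        assert res.or_ == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form(self):
        ac = ComparisonResult(log_or=0.5, se_log_or=0.2)
        bc = ComparisonResult(log_or=0.2, se_log_or=0.1)
        res = bucher_combine(ac, bc)
        assert res.or_ == pytest.approx(math.exp(0.3))
        assert res.se_log_or == pytest.approx(math.sqrt(0.05))
        # frozen from the closed form exp(0.3 -/+ 1.96 * sqrt(0.05))
        assert res.ci_low == pytest.approx(0.8708641, abs=1e-6)
        assert res.ci_high == pytest.approx(2.0923113, abs=1e-6)
        assert res.ci_low <= res.or_ <= res.ci_high

    def test_fixture_pipeline_reproduces_published_pattern(
            self, cfg, anaprazole_ipd, matched_weights):
        """Efficacy OR near 1 (p > 0.05); safety OR with CI spanning 1."""
        comp = cfg.comparison
        ac = weighted_outcome_or(anaprazole_ipd["healed"].to_numpy(),
                                 matched_weights, comp.anchor1_healing_rate,
                                 comp.anchor1_n)
        bc = aggregate_or(comp.comparator_healing_rate, comp.comparator_n,
                          comp.anchor2_healing_rate, comp.anchor2_n)
        eff = bucher_combine(ac, bc)
        assert 0.5 < eff.or_ < 2.0
        assert eff.p_value > 0.05
        ac_s = weighted_outcome_or(anaprazole_ipd["adr"].to_numpy(),
                                   matched_weights, comp.anchor1_adr_rate,
                                   comp.anchor1_n)
        bc_s = aggregate_or(comp.comparator_adr_rate, comp.comparator_n,
                            comp.anchor2_adr_rate, comp.anchor2_n)
        saf = bucher_combine(ac_s, bc_s)
        assert saf.ci_low < 1.0 < saf.ci_high
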
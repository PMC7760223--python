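"""Hierarchical Bayesian consensus, fallback combiner and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from alidose.consensus import (
    HierarchicalConsensus,
    convergence_check,
    fallback_consensus,
    significance_calls,
)
from alidose.simulate import SimulationConfig, simulate_plate_readings
from alidose.viability import compute_viability_table


def records(y_by_plate, condition="c"):
    rows = []
    for j, ys in enumerate(y_by_plate):
        for y in ys:
            rows.append({"plate_id": f"P{j + 1}", "condition": condition, "viability_pct": y})
    return pd.DataFrame(rows)


def fit_synthetic(truth, seed, **kw):
    cfg = SimulationConfig(seed=seed, condition_truths={"exposure": truth})
    vt = compute_viability_table(simulate_plate_readings(cfg))
    sub = vt[vt.condition == "exposure"]
    params = dict(n_iterations=2000, n_chains=2, seed=seed)
    params.update(kw)
    return HierarchicalConsensus(**params).fit(sub)


class TestHierarchicalModel:
    def test_single_level_reduction_matches_conjugate_posterior(self):
        """With sigma known and tau pinned at 0 the model is a conjugate
        Gaussian update; the MCMC posterior must match the closed form."""
        rng = np.random.default_rng(0)
        y = rng.normal(85, 10, size=20)
        df = records([y])
        m = HierarchicalConsensus(
            n_iterations=4000, n_chains=4, seed=1, sigma_fixed=10.0, tau_fixed=0.0
        ).fit(df)
        draws = m.draws_["c"].ravel()
        prior_prec = 1.0 / 1000.0**2
        prec = 20 / 100.0 + prior_prec
        post_mean = (y.sum() / 100.0 + 100.0 * prior_prec) / prec
        post_sd = prec**-0.5
        assert draws.mean() == pytest.approx(post_mean, abs=4 * post_sd / np.sqrt(500))
        assert draws.std() == pytest.approx(post_sd, rel=0.1)

    def test_identical_observations_concentrate_on_their_value(self):
        m = HierarchicalConsensus(n_iterations=2000, n_chains=2, seed=2).fit(
            records([[85.0] * 5, [85.0] * 5, [85.0] * 5])
        )
        s = m.summaries_["c"]
        assert s.consensus_mean == pytest.approx(85.0, abs=0.5)
        lo, hi = s.consensus_bounds
        assert hi - lo < 2.0

    def test_consensus_within_convex_hull_of_plate_means(self):
        rng = np.random.default_rng(5)
        for k in range(5):
            y_by_plate = [rng.normal(rng.uniform(40, 110), 8, size=4) for _ in range(3)]
            m = HierarchicalConsensus(n_iterations=1500, n_chains=2, seed=k).fit(
                records(y_by_plate)
            )
            means = [np.mean(y) for y in y_by_plate]
            c = m.summaries_["c"].consensus_mean
            assert min(means) - 1.0 <= c <= max(means) + 1.0

    def test_fixed_seed_reproducible(self):
        a = fit_synthetic(85.0, seed=11).summaries_["exposure"]
        b = fit_synthetic(85.0, seed=11).summaries_["exposure"]
        assert a.consensus_mean == b.consensus_mean
        assert a.consensus_bounds == b.consensus_bounds

    def test_strict_rhat_threshold_routes_to_fallback(self):
        # split-R-hat is strictly > 1 for finite stochastic chains, so an
        # impossible threshold must trigger the fallback combination
        m = fit_synthetic(85.0, seed=3, rhat_threshold=1.0)
        s = m.summaries_["exposure"]
        assert not s.converged
        assert s.used_fallback

    def test_bayes_and_fallback_agree_on_well_behaved_data(self):
        hits = 0
        for k in range(10):
            m = fit_synthetic(85.0, seed=100 + k)
            s = m.summaries_["exposure"]
            means = list(s.per_plate_means.values())
            sds = [
                (hi - lo) / (2 * 1.96) for lo, hi in s.per_plate_bounds.values()
            ]
            fb_mean, fb_lo, fb_hi, _ = fallback_consensus(means, sds)
            lo, hi = s.consensus_bounds
            if max(lo, fb_lo) <= min(hi, fb_hi):
                hits += 1
        assert hits >= 9


class TestSignificance:
    def test_low_viability_condition_flagged_below_control(self):
        m = fit_synthetic(39.0, seed=21)
        call = m.significance_calls()[0]
        assert call.flag_less_than_control
        assert call.prob_below_reference > 0.95

    def test_healthy_condition_not_flagged(self):
        m = fit_synthetic(100.0, seed=22)
        call = m.significance_calls()[0]
        assert not call.flag_less_than_control

    def test_pairwise_equality_of_identical_truths(self):
        hits = 0
        for k in range(10):
            cfg = SimulationConfig(
                seed=300 + k, condition_truths={"a": 85.0, "b": 85.0}
            )
            vt = compute_viability_table(simulate_plate_readings(cfg))
            m = HierarchicalConsensus(n_iterations=1500, n_chains=2, seed=k).fit(
                vt[vt.condition.isin(["a", "b"])]
            )
            calls = {c.condition: c for c in m.significance_calls()}
            if calls["a"].pairwise_equality[("a", "b")]:
                hits += 1
        assert hits >= 8

    def test_calls_from_raw_draws(self):
        rng = np.random.default_rng(0)
        draws = {"low": rng.normal(39, 5, (2, 500)), "high": rng.normal(100, 5, (2, 500))}
        calls = {c.condition: c for c in significance_calls(draws)}
        assert calls["low"].flag_less_than_control
        assert not calls["high"].flag_less_than_control
        assert calls["low"].pairwise_equality[("high", "low")] is False


class TestFallbackConsensus:
    def test_homogeneous_plates(self):
        mean, lo, hi, tau = fallback_consensus([80.0, 80.0, 80.0], [2.0, 2.0, 2.0])
        assert mean == pytest.approx(80.0)
        assert tau == 0.0
        assert hi - mean == pytest.approx(1.959964 * 2 / np.sqrt(3), rel=1e-5)

    def test_two_heterogeneous_plates_hand_computation(self):
        # w=1 each: Q=200, C=1, tau2=199; symmetric weights -> consensus 80
        mean, lo, hi, tau = fallback_consensus([70.0, 90.0], [1.0, 1.0])
        assert mean == pytest.approx(80.0)
        assert tau == pytest.approx(np.sqrt(199.0), rel=1e-12)

    def test_zero_uncertainty_limit(self):
        mean, lo, hi, tau = fallback_consensus([70.0, 80.0, 90.0], [0.0, 0.0, 0.0])
        assert mean == pytest.approx(80.0)
        assert tau == pytest.approx(10.0)  # sample sd of the plate means

    def test_single_plate_passthrough(self):
        mean, lo, hi, tau = fallback_consensus([75.0], [3.0])
        assert mean == 75.0
        assert lo == pytest.approx(75.0 - 1.959964 * 3, rel=1e-5)

    def test_matches_statsmodels_dersimonian_laird(self):
        """Independent cross-check of tau2 and the weighted mean."""
        effects = np.array([72.0, 85.0, 91.0])
        sds = np.array([2.0, 3.0, 1.5])
        mean, _, _, tau = fallback_consensus(effects, sds)
        res = combine_effects(effects, sds**2, method_re="dl")
        assert tau**2 == pytest.approx(res.tau2, rel=1e-10)
        df = res.summary_frame()
        assert mean == pytest.approx(df.loc["random effect", "eff"], rel=1e-10)


class TestConvergenceCheck:
    def test_iid_chains_have_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(0, 1, size=(4, 2000))
        out = convergence_check(chains)
        assert 1.0 <= out["rhat"]["param"] <= 1.05
        assert out["ess"]["param"] > 500

    def test_disjoint_constant_chains_fail(self):
        rng = np.random.default_rng(1)
        chains = np.vstack(
            [rng.normal(0, 0.01, 500), rng.normal(100, 0.01, 500)]
        )
        out = convergence_check(chains)
        # rank-normalized split-R-hat saturates, but must sit far above 1.05
        assert out["rhat"]["param"] > 1.5

    def test_duplicated_chain_rhat_near_one(self):
        rng = np.random.default_rng(2)
        one = rng.normal(0, 1, 1000)
        out = convergence_check(np.vstack([one, one]))
        assert out["rhat"]["param"] == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            convergence_check(np.zeros((1, 100)))
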
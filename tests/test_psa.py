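"""Probabilistic sensitivity analysis: sampling, propagation, CEAC."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from tpxcea import (
    DistributionSpec,
    evaluate_strategy,
    padua_point,
    run_psa,
    sample_parameter_set,
    strategy_all,
    strategy_none,
    strategy_ram,
)
from tpxcea.psa import HOSP_BLEED_SPLIT, TX_BLEED_SPLIT, ceac, default_distributions


def degenerate_distributions(base):
    """Every default distribution replaced by a point mass at the default
    parameter value."""
    out = {}
    for name in default_distributions():
        if name == "risks.any_hosp_bleed":
            value = sum(getattr(base.risks, k) for k in HOSP_BLEED_SPLIT)
        elif name == "risks.any_tx_bleed":
            value = sum(getattr(base.risks, k) for k in TX_BLEED_SPLIT)
        else:
            section, key = name.split(".")
            value = getattr(getattr(base, section), key)
        out[name] = DistributionSpec("fixed", (float(value),))
    return out


class TestSampling:
    def test_fixed_specs_return_defaults(self, base_params):
        dists = degenerate_distributions(base_params)
        ps = sample_parameter_set(dists, seed=3, base=base_params)
        for f in dataclasses.fields(ps.risks):
            v, v0 = getattr(ps.risks, f.name), getattr(base_params.risks, f.name)
            if v0 is not None:
                assert float(np.asarray(v)) == pytest.approx(float(v0), rel=1e-12)

    def test_same_seed_same_draws(self, base_params):
        a = sample_parameter_set(default_distributions(), seed=11, base=base_params, size=5)
        b = sample_parameter_set(default_distributions(), seed=11, base=base_params, size=5)
        assert np.array_equal(a.effects.rr_vte, b.effects.rr_vte)
        assert np.array_equal(a.risks.p_advt, b.risks.p_advt)

    def test_rr_vte_sample_mean(self, base_params):
        dists = default_distributions()
        ps = sample_parameter_set(dists, seed=4, base=base_params, size=10_000)
        mu, sigma = dists["effects.rr_vte"].params
        expected = np.exp(mu + sigma**2 / 2)
        se = expected * np.sqrt((np.exp(sigma**2) - 1) / 10_000)
        assert abs(ps.effects.rr_vte.mean() - expected) < 3 * se

    def test_bleed_subtype_ratios_preserved(self, base_params):
        ps = sample_parameter_set(default_distributions(), seed=5, base=base_params, size=100)
        ratio = np.asarray(ps.risks.q_hosp_fatal) / np.asarray(ps.risks.q_hosp_other)
        assert np.allclose(ratio, 0.10 / 0.51)


class TestRunPsa:
    def test_degenerate_psa_equals_deterministic(self, base_params, strategies):
        dists = degenerate_distributions(base_params)
        res = run_psa(strategies[:2], dists=dists, n=1, seed=9, base=base_params)
        det = evaluate_strategy(strategies[0], base_params)
        assert res.mean_cost[strategies[0].label] == pytest.approx(float(det.cost), rel=1e-12)
        assert res.mean_qalys[strategies[0].label] == pytest.approx(float(det.qalys), rel=1e-12)

    def test_seed_reproducibility(self, base_params, strategies):
        a = run_psa(strategies, n=200, seed=42, base=base_params)
        b = run_psa(strategies, n=200, seed=42, base=base_params)
        assert a.to_dict() == b.to_dict()

    def test_incremental_signs_all_vs_none(self, base_params):
        res = run_psa([strategy_none(), strategy_all()], n=1000, seed=2, base=base_params)
        inc = res.incremental["All inpatients"]
        assert inc["d_qalys"]["mean"] > 0
        assert inc["d_cost"]["mean"] < 25  # near zero or cost-saving
        assert inc["d_qalys"]["ci"][0] < inc["d_qalys"]["mean"] < inc["d_qalys"]["ci"][1]


class TestCeac:
    def test_probabilities_sum_to_one(self, base_params, strategies):
        res = run_psa(strategies, n=100, seed=7, base=base_params)
        for probs in res.prob_ce_at.values():
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_strategy_probability_one(self):
        costs = np.random.default_rng(0).normal(100, 10, (50, 1))
        qalys = np.random.default_rng(1).normal(5, 1, (50, 1))
        out = ceac(costs, qalys, ["only"], [0.0, 20_000.0])
        assert all(p["only"] == 1.0 for p in out.values())

    def test_large_lambda_rewards_max_qalys(self):
        rng = np.random.default_rng(3)
        costs = np.column_stack([rng.normal(100, 1, 500), rng.normal(500, 1, 500)])
        qalys = np.column_stack([rng.normal(5, 0.01, 500), rng.normal(6, 0.01, 500)])
        out = ceac(costs, qalys, ["cheap", "effective"], [1e9])
        assert out[1e9]["effective"] == 1.0

    def test_two_strategy_normal_closed_form(self):
        """With independent normal increments the CEAC equals the normal
        probability Phi((lambda*mu_q - mu_c)/sd)."""
        rng = np.random.default_rng(12)
        n = 200_000
        mu_c, sd_c, mu_q, sd_q = -30.0, 60.0, 0.05, 0.02
        lam = 20_000.0
        dc = rng.normal(mu_c, sd_c, n)
        dq = rng.normal(mu_q, sd_q, n)
        costs = np.column_stack([np.zeros(n), dc])
        qalys = np.column_stack([np.zeros(n), dq])
        out = ceac(costs, qalys, ["ref", "new"], [lam])
        expected = norm.cdf((lam * mu_q - mu_c) / np.hypot(lam * sd_q, sd_c))
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(out[lam]["new"] - expected) < 3 * mc_se

    def test_exact_ties_split_equally(self):
        costs = np.zeros((10, 2))
        qalys = np.ones((10, 2))
        out = ceac(costs, qalys, ["a", "b"], [20_000.0])
        assert out[20_000.0]["a"] == pytest.approx(0.5)
        assert out[20_000.0]["b"] == pytest.approx(0.5)
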
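"""Beta-binomial engine: likelihood oracle, fitting, LRT, BH."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom, chi2

from aluedit.bbstat import (
    bb_loglik,
    bh_adjust,
    build_design,
    fit_bb_regression,
    lrt_condition,
    differential_test,
)
from tests._sim import paired_observations


def oracle_bb_loglik(k, n, mu, rho):
    """Term-by-term log-gamma evaluation, independent of the package."""
    total = 0.0
    for ki, ni, mi in zip(k, n, mu):
        a = mi * (1 - rho) / rho
        b = (1 - mi) * (1 - rho) / rho
        total += (
            math.lgamma(ni + 1) - math.lgamma(ki + 1) - math.lgamma(ni - ki + 1)
            + math.lgamma(ki + a) + math.lgamma(ni - ki + b) - math.lgamma(ni + a + b)
            + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        )
    return total


class TestLoglik:
    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(3)
        n = rng.integers(5, 80, size=12)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        beta = np.array([-0.3, 0.7])
        for rho in (0.01, 0.1, 0.45):
            mu = expit(X @ beta)
            assert bb_loglik(k, n, X, beta, rho) == pytest.approx(
                oracle_bb_loglik(k, n, mu, rho), abs=1e-6
            )

    def test_binomial_limit(self):
        rng = np.random.default_rng(4)
        n = rng.integers(5, 60, size=10)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        X = np.ones((10, 1))
        beta = np.array([0.4])
        mu = float(expit(0.4))
        binom_ll = float(binom.logpmf(k, n, mu).sum())
        assert bb_loglik(k, n, X, beta, 1e-12) == pytest.approx(binom_ll, abs=1e-6)

    def test_degenerate_all_successes(self):
        n = np.array([10, 20])
        k = n.copy()
        X = np.ones((2, 1))
        # mu -> 1: probability of k = n tends to 1, log-likelihood to 0
        assert bb_loglik(k, n, X, np.array([30.0]), 1e-12) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_rho_domain_error(self, rho):
        with pytest.raises(ValueError, match="rho"):
            bb_loglik(np.array([1]), np.array([2]), np.ones((1, 1)), np.array([0.0]), rho)


class TestFit:
    def test_recovers_condition_effect(self):
        rng = np.random.default_rng(12)
        obs = paired_observations(
            rng, n_patients=40, trials=100, base_logit=0.0,
            condition_effect=-1.0, rho=0.05,
        )
        fit = fit_bb_regression(obs)
        assert fit.converged
        assert fit.condition_effect == pytest.approx(-1.0, abs=0.25)

    def test_symmetry_gives_null_effect(self):
        rows = []
        for p in range(6):
            for cond in ("tumor", "normal"):
                rows.append(
                    {"k": 12 + p, "n": 50, "condition": cond, "patient_id": f"P{p}"}
                )
        fit = fit_bb_regression(pd.DataFrame(rows))
        assert abs(fit.condition_effect) < 0.05

    def test_binomial_data_rho_near_lower_bound(self):
        rng = np.random.default_rng(9)
        rows = []
        for p in range(12):
            for cond in ("tumor", "normal"):
                rows.append(
                    {
                        "k": int(rng.binomial(200, 0.3)),
                        "n": 200,
                        "condition": cond,
                        "patient_id": f"P{p}",
                    }
                )
        fit = fit_bb_regression(pd.DataFrame(rows))
        assert fit.rho < 0.01

    def test_degenerate_all_zero_flagged(self):
        rows = [
            {"k": 0, "n": 30, "condition": c, "patient_id": f"P{p}"}
            for p in range(3)
            for c in ("tumor", "normal")
        ]
        fit = fit_bb_regression(pd.DataFrame(rows))
        assert fit.degenerate and not fit.converged

    def test_nested_model_loglik_ordering(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            obs = paired_observations(
                rng, n_patients=8, trials=60, condition_effect=rng.normal(),
                patient_sd=0.4, rho=0.05,
            )
            full = fit_bb_regression(obs, include_condition=True)
            reduced = fit_bb_regression(obs, include_condition=False)
            assert full.loglik >= reduced.loglik - 1e-6

    def test_likelihood_invariant_under_patient_relabeling(self):
        rng = np.random.default_rng(33)
        obs = paired_observations(rng, n_patients=6, trials=50, patient_sd=0.5)
        relabeled = obs.copy()
        mapping = {f"P{i:02d}": f"Q{7 - i}" for i in range(1, 7)}
        relabeled["patient_id"] = relabeled.patient_id.map(mapping)
        f1 = fit_bb_regression(obs)
        f2 = fit_bb_regression(relabeled)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)

    def test_invalid_counts_rejected(self):
        bad = pd.DataFrame(
            [{"k": 5, "n": 3, "condition": "tumor", "patient_id": "P1"},
             {"k": 1, "n": 3, "condition": "normal", "patient_id": "P1"}]
        )
        with pytest.raises(ValueError):
            fit_bb_regression(bad)


class TestLRT:
    def test_equal_logliks(self):
        rng = np.random.default_rng(2)
        obs = paired_observations(rng, n_patients=4, trials=30)
        full = fit_bb_regression(obs)
        stat, p = lrt_condition(full, full)
        assert stat == 0.0
        assert p == 1.0

    def test_chi_square_quantile(self):
        # a statistic of 3.841 on 1 df sits at p ~= 0.05
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(6)
        f1 = fit_bb_regression(paired_observations(rng, 4, 30))
        f2 = fit_bb_regression(paired_observations(rng, 4, 31))
        with pytest.raises(ValueError, match="same data"):
            lrt_condition(f1, f2)


class TestBH:
    def test_closed_form(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(17)
        p = rng.random(37)
        # reference step-up: sort, scale by m/rank, enforce monotonicity
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(bh_adjust(p), expected)

    def test_order_preserving(self):
        p = [0.001, 0.5, 0.01, 0.9]
        adjusted = bh_adjust(p)
        assert np.all(np.diff(adjusted[np.argsort(p)]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestUnits:
    def test_adjusted_at_least_raw_and_strict_threshold(self):
        rng = np.random.default_rng(8)
        frames = [
            paired_observations(
                rng, 6, 50, condition_effect=-1.5 if i < 3 else 0.0,
                patient_sd=0.3, unit_id=f"u{i}",
            )
            for i in range(10)
        ]
        result = differential_test(pd.concat(frames, ignore_index=True))
        assert (result.fdr_adjusted_p >= result.p_value - 1e-12).all()
        assert result.significant.equals(result.fdr_adjusted_p < 0.05)

    def test_degenerate_unit_reported_not_dropped(self):
        obs = pd.DataFrame(
            [
                {"unit_id": "dead", "k": 0, "n": 40, "condition": c, "patient_id": f"P{p}"}
                for p in range(3)
                for c in ("tumor", "normal")
            ]
        )
        result = differential_test(obs)
        assert len(result) == 1
        assert result.p_value.iloc[0] == 1.0
        assert bool(result.degenerate.iloc[0])


class TestQuasiLikelihood:
    def test_moment_dispersion_recovers_truth(self):
        from aluedit.bbstat import estimate_dispersion_moment
        from tests._sim import betabinom_draw

        rng = np.random.default_rng(19)
        mu_true, rho_true, trials = 0.3, 0.1, 80
        n = np.full(400, trials)
        k = np.array([betabinom_draw(rng, trials, mu_true, rho_true) for _ in range(400)])
        mu = np.full(400, k.mean() / trials)
        est = estimate_dispersion_moment(k, n, mu, n_params=1)
        assert est == pytest.approx(rho_true, abs=0.03)

    def test_moment_dispersion_binomial_at_lower_bound(self):
        from aluedit.bbstat import RHO_MIN, estimate_dispersion_moment

        rng = np.random.default_rng(20)
        n = np.full(300, 100)
        k = rng.binomial(100, 0.3, size=300)
        est = estimate_dispersion_moment(k, n, np.full(300, 0.3), n_params=1)
        assert est <= 0.005 or est == RHO_MIN

    def test_ql_symmetric_data_null(self):
        from aluedit.bbstat import ql_condition_test

        rows = [
            {"k": 12 + p, "n": 50, "condition": c, "patient_id": f"P{p}"}
            for p in range(6)
            for c in ("tumor", "normal")
        ]
        res = ql_condition_test(pd.DataFrame(rows))
        assert abs(res["condition_effect"]) < 0.05
        assert res["p_value"] > 0.5

    def test_ql_detects_strong_shift(self):
        from aluedit.bbstat import ql_condition_test
        from tests._sim import paired_level_observations

        rng = np.random.default_rng(23)
        obs = paired_level_observations(rng, 10, 80, 0.5, -0.3, rho=0.02)
        assert ql_condition_test(obs)["p_value"] < 1e-4


def test_design_matrix_reference_coding():
    X, names = build_design(
        np.array(["tumor", "normal", "tumor", "normal"]),
        np.array(["P1", "P1", "P2", "P2"]),
    )
    assert names == ["intercept", "condition_tumor", "patient_P2"]
    assert X.shape == (4, 3)
    assert X[:, 1].tolist() == [1.0, 0.0, 1.0, 0.0]
    assert X[:, 2].tolist() == [0.0, 0.0, 1.0, 1.0]
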
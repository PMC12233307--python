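"""Model designs, the closed-form Bayesian linear evidence against a
quadrature oracle, the random-effects selection scheme against a brute-force
reimplementation, and model recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma

import gazeconf as g
from gazeconf.config import EvidenceConfig
from gazeconf.model_selection import (attention_times, invert_participants,
                                      log_evidence_linear, model_design,
                                      posterior_coefficients, rfx_bms)


def _participant_frame(rng, n=30):
    dt1 = rng.uniform(0.5, 4.0, n)
    dt2 = rng.uniform(0.5, 4.0, n)
    return pd.DataFrame({"dt1_s": dt1, "dt2_s": dt2,
                         "C": rng.integers(0, 11, n)})


class TestModelDesign:
    def test_column_counts(self):
        rng = np.random.default_rng(0)
        d = _participant_frame(rng)
        assert model_design(d, "hybrid")[0].shape[1] == 3
        assert model_design(d, "sequential")[0].shape[1] == 2
        assert model_design(d, "parallel")[0].shape[1] == 2

    def test_response_normalized(self):
        d = pd.DataFrame({"dt1_s": [2.0], "dt2_s": [1.0], "C": [7]})
        X, y = model_design(d, "hybrid")
        assert y[0] == pytest.approx(0.7)
        assert X.iloc[0].tolist() == pytest.approx([1.0, 1.0, 1.0 / 3.0])

    def test_zero_total_time_dropped(self):
        d = pd.DataFrame({"dt1_s": [0.0, 2.0], "dt2_s": [0.0, 1.0], "C": [5, 7]})
        X, y = model_design(d, "parallel")
        assert len(y) == 1
        X2, y2 = model_design(d, "sequential")
        assert len(y2) == 2  # no inverse term, nothing to drop


class TestLogEvidence:
    def test_fixed_sd_matches_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        y = 0.8 * x + rng.normal(0, 0.5, 5)
        cfg = EvidenceConfig(prior_sd_alpha=2.0, noise_model="fixed_sd",
                             noise_sd=0.5, standardize_predictors=False)
        ev = log_evidence_linear(x[:, None], y, cfg)
        # dense-grid integration over the single coefficient
        a = np.linspace(-25, 25, 200_001)
        resid = y[:, None] - np.outer(x, a)
        loglik = -0.5 * (resid**2).sum(axis=0) / 0.25 - 2.5 * np.log(2 * np.pi * 0.25)
        prior = np.exp(-0.5 * a**2 / 4.0) / np.sqrt(2 * np.pi * 4.0)
        oracle = np.log(np.trapezoid(np.exp(loglik) * prior, a))
        assert ev == pytest.approx(oracle, abs=1e-3)

    def test_conjugate_posterior_matches_ols_under_diffuse_prior(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = 0.3 + 0.7 * X[:, 1] + rng.normal(0, 0.2, 60)
        cfg = EvidenceConfig(prior_sd_alpha=1e4, standardize_predictors=False)
        mean, _ = posterior_coefficients(pd.DataFrame(X, columns=["const", "x"]), y, cfg)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert mean == pytest.approx(ols, abs=1e-4)

    def test_destandardized_posterior_equals_unstandardized(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"const": np.ones(80), "x": rng.normal(2.0, 3.0, 80)})
        y = 0.2 + 0.5 * X["x"].to_numpy() + rng.normal(0, 0.3, 80)
        diffuse = dict(prior_sd_alpha=1e5, noise_model="fixed_sd", noise_sd=0.3)
        m_std, _ = posterior_coefficients(X, y, EvidenceConfig(standardize_predictors=True, **diffuse))
        m_raw, _ = posterior_coefficients(X, y, EvidenceConfig(standardize_predictors=False, **diffuse))
        assert m_std == pytest.approx(m_raw, rel=1e-3)

    def test_occam_penalty_for_pure_noise_predictor(self):
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(150):
            x = rng.normal(size=40)
            y = x + rng.normal(0, 0.5, 40)
            X1 = pd.DataFrame({"const": np.ones(40), "x": x})
            X2 = X1.assign(junk=rng.normal(size=40))
            diffs.append(log_evidence_linear(X1, y) - log_evidence_linear(X2, y))
        assert np.mean(diffs) > 0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"const": np.ones(20), "x": rng.normal(size=20)})
        y = rng.normal(size=20)
        perm = rng.permutation(20)
        assert log_evidence_linear(X, y) == pytest.approx(
            log_evidence_linear(X.iloc[perm].reset_index(drop=True), y[perm]))

    def test_requires_more_rows_than_columns(self):
        with pytest.raises(ValueError):
            log_evidence_linear(np.ones((2, 3)), np.zeros(2))


def _brute_force_rfx(F, alpha0, tol=1e-10, max_iter=100_000):
    """Independent plain-python reimplementation of the update loop."""
    import math
    n, K = len(F), len(F[0])
    alpha = list(alpha0)
    for _ in range(max_iter):
        counts = [0.0] * K
        for row in F:
            logu = [row[k] + digamma(alpha[k]) - digamma(sum(alpha)) for k in range(K)]
            mx = max(logu)
            u = [math.exp(v - mx) for v in logu]
            s = sum(u)
            for k in range(K):
                counts[k] += u[k] / s
        new = [alpha0[k] + counts[k] for k in range(K)]
        if max(abs(a - b) for a, b in zip(new, alpha)) < tol:
            return new
        alpha = new
    return alpha


class TestRFXBMS:
    def test_identical_evidence_rows_symmetric(self):
        F = np.tile([3.0, 3.0, 3.0], (10, 1))
        res = rfx_bms(F, n_dirichlet_samples=200_000, seed=0)
        assert res.model_frequency == pytest.approx([1 / 3] * 3, abs=1e-9)
        assert res.exceedance_prob == pytest.approx([1 / 3] * 3, abs=0.01)

    def test_decisive_cohort_hand_computed(self):
        F = np.zeros((20, 3))
        F[:, 0] = 1000.0
        res = rfx_bms(F, n_dirichlet_samples=1_000_000, seed=1)
        assert res.dirichlet_alpha == pytest.approx([21.0, 1.0, 1.0], abs=1e-6)
        assert res.model_frequency == pytest.approx([21 / 23, 1 / 23, 1 / 23], abs=1e-6)
        assert res.exceedance_prob[0] == pytest.approx(1.0, abs=1e-4)

    def test_matches_brute_force_loop(self):
        F = [[1.2, -0.3], [0.1, 0.9]]
        res = rfx_bms(np.array(F), alpha0=(1.0, 1.0), tol=1e-10,
                      n_dirichlet_samples=1000, seed=2)
        oracle = _brute_force_rfx(F, [1.0, 1.0])
        assert res.dirichlet_alpha == pytest.approx(oracle, abs=1e-6)

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(6, 3))
        res_a = rfx_bms(F, n_dirichlet_samples=1000, seed=3)
        F2 = F + rng.normal(size=(6, 1))  # per-participant constant shifts
        res_b = rfx_bms(F2, n_dirichlet_samples=1000, seed=3)
        assert res_a.dirichlet_alpha == pytest.approx(res_b.dirichlet_alpha, abs=1e-8)
        assert res_a.exceedance_prob == pytest.approx(res_b.exceedance_prob)

    def test_single_participant_digamma_softmax_fixed_point(self):
        F = np.array([[0.7, -0.4, 0.1]])
        res = rfx_bms(F, n_dirichlet_samples=1000, seed=4)
        alpha = res.dirichlet_alpha
        logu = F[0] + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(logu - logu.max())
        u /= u.sum()
        assert res.assignment[0] == pytest.approx(u, abs=1e-6)
        assert alpha == pytest.approx(1.0 + u, abs=1e-5)

    def test_exceedance_probabilities_sum_to_one(self):
        rng = np.random.default_rng(6)
        res = rfx_bms(rng.normal(size=(8, 3)), n_dirichlet_samples=100_000, seed=7)
        assert res.exceedance_prob.sum() == pytest.approx(1.0)

    def test_nonfinite_evidence_rejected(self):
        with pytest.raises(ValueError):
            rfx_bms(np.array([[np.nan, 0.0]]))


class TestCohortInversion:
    def test_hybrid_cohort_selects_hybrid(self, hybrid_cohort):
        F = invert_participants(hybrid_cohort["att"], hybrid_cohort["kept"])
        res = rfx_bms(F, n_dirichlet_samples=200_000, seed=11)
        assert res.winner() == "hybrid"
        assert res.exceedance_prob[list(res.model_names).index("hybrid")] > 0.95

    def test_alpha_recovery_within_two_standard_errors(self, hybrid_cohort):
        data = hybrid_cohort["att"].merge(
            hybrid_cohort["kept"][["participant_id", "trial_index", "C"]],
            on=["participant_id", "trial_index"])
        means = []
        for _, grp in data.groupby("participant_id"):
            X, y = model_design(grp, "hybrid")
            means.append(posterior_coefficients(X, y)[0])
        M = np.array(means)
        gm = M.mean(axis=0)
        se = M.std(axis=0, ddof=1) / np.sqrt(len(M))
        truth = np.array([0.5, 0.15, 0.3])
        assert np.all(np.abs(gm - truth) < 2 * se + 0.02)

    def test_evidence_table_shape(self, hybrid_cohort):
        F = invert_participants(hybrid_cohort["att"], hybrid_cohort["kept"])
        assert list(F.columns) == ["hybrid", "sequential", "parallel"]
        assert len(F) == hybrid_cohort["cfg"].n_participants
        assert np.isfinite(F.to_numpy()).all()


class TestModelRecovery:
    def test_strong_signal_confusion_diagonal(self):
        cfg = g.GenerativeConfig(n_participants=8, n_trials=80, seed=31)
        table = g.model_recovery(cfg, seed=31, n_dirichlet_samples=50_000)
        assert (table["winner"] == table["generative_model"]).all()
        for _, row in table.iterrows():
            assert row[f"xp_{row['generative_model']}"] > 0.9

    def test_pure_noise_confidence_is_undecided(self):
        from dataclasses import replace
        from gazeconf.config import ConfidenceModelSpec
        cfg = g.GenerativeConfig(
            n_participants=8, n_trials=80, seed=33,
            alpha=ConfidenceModelSpec("hybrid", 0.5, 0.0, 0.0))
        gaze, trials, _ = g.simulate_dataset(cfg)
        kept, _ = g.exclude_trials(trials)
        metrics = g.metrics_table(gaze, kept, cfg.geometry)
        att = attention_times(metrics, kept)
        F = invert_participants(att, kept)
        res = rfx_bms(F, n_dirichlet_samples=100_000, seed=34)
        assert res.exceedance_prob[list(res.model_names).index("hybrid")] < 0.95
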
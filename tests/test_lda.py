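"""RMS-feature and shrinkage-LDA contracts: closed-form feature values,
agreement with the Gaussian discriminant and with an independent LDA
implementation, invariances, and the Bayesian-optimization tuner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from megspeech import ShrinkageLda, RmsLdaDecoder, extract_rms, bayes_opt_tune
from megspeech.epoching import EpochSet
from megspeech.lda import _trial_rms


def epochs_from_trials(trials, labels):
    return EpochSet(trials=list(trials), labels=np.array(labels), phase="overt",
                    fs=1000.0, trial_ids=np.arange(len(trials)),
                    channel_ids=np.arange(trials[0].shape[0]))


class TestExtractRms:
    def test_constant_channel(self):
        es = epochs_from_trials([np.full((2, 100), 3.0)], ["yes"])
        assert extract_rms(es).values[0, 0] == pytest.approx(3.0)

    def test_sine_closed_form(self):
        t = np.arange(1000) / 1000.0
        a = 2.5
        trial = np.vstack([a * np.sin(2 * np.pi * 5 * t)] * 2)  # 5 full periods
        es = epochs_from_trials([trial], ["yes"])
        assert extract_rms(es).values[0, 0] == pytest.approx(a / np.sqrt(2), abs=1e-6)

    def test_matches_direct_loop_oracle(self, rng):
        trial = rng.standard_normal((4, 333))
        es = epochs_from_trials([trial], ["no"])
        got = extract_rms(es).values[0]
        for c in range(4):
            acc = 0.0
            for v in trial[c]:
                acc += v * v
            assert got[c] == pytest.approx(np.sqrt(acc / 333), abs=1e-12)

    @given(scale=st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((3, 64))
        assert np.allclose(_trial_rms(scale * x), abs(scale) * _trial_rms(x),
                           rtol=1e-10, atol=1e-12)

    def test_zero_length_trial_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            _trial_rms(np.empty((3, 0)))


class TestShrinkageLda:
    def _gaussians(self, rng, n=200, d=4, sep=2.0):
        cov = np.eye(d) + 0.3
        L = np.linalg.cholesky(cov)
        X0 = rng.standard_normal((n, d)) @ L.T
        X1 = rng.standard_normal((n, d)) @ L.T + sep
        X = np.vstack([X0, X1])
        y = np.array(["no"] * n + ["yes"] * n)
        return X, y, cov

    def test_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-1, 0.01, (20, 3)), rng.normal(1, 0.01, (20, 3))])
        y = np.array(["no"] * 20 + ["yes"] * 20)
        m = ShrinkageLda(shrinkage=0.1).fit(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_boundary_normal_matches_closed_form(self):
        rng = np.random.default_rng(0)
        X, y, cov = self._gaussians(rng, n=5000, d=2)
        m = ShrinkageLda(shrinkage=0.0).fit(X, y)
        mu0 = X[y == "no"].mean(axis=0)
        mu1 = X[y == "yes"].mean(axis=0)
        expected = np.linalg.solve(cov, mu1 - mu0)
        cos = (m.coef_ @ expected) / np.linalg.norm(m.coef_) / np.linalg.norm(expected)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0

    def test_predictions_match_gaussian_density_oracle(self, rng):
        X, y, _ = self._gaussians(rng, n=100, d=3)
        m = ShrinkageLda(shrinkage=0.3).fit(X, y)
        pts = rng.standard_normal((100, 3)) * 2 + 1
        inv = np.linalg.inv(m.covariance_)
        for p in pts:
            logd = [
                -0.5 * (p - mu) @ inv @ (p - mu) + np.log(pi)
                for mu, pi in zip(m.class_means_, m.priors_)
            ]
            assert m.predict(p[None])[0] == m.classes_[int(np.argmax(logd))]

    def test_boundary_point_has_half_posterior_and_class0(self):
        X = np.array([[-1.0], [-1.1], [1.0], [1.1]])
        y = np.array(["no", "no", "yes", "yes"])
        m = ShrinkageLda(shrinkage=0.0).fit(X, y)
        boundary = -m.intercept_ / m.coef_[0]
        proba = m.predict_proba(np.array([[boundary]]))
        assert proba[0] == pytest.approx([0.5, 0.5], abs=1e-9)
        assert m.predict(np.array([[boundary]]))[0] == m.classes_[0]

    def test_matches_sklearn_at_zero_shrinkage(self, rng):
        X, y, _ = self._gaussians(rng, n=150, d=5)
        ours = ShrinkageLda(shrinkage=0.0).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        assert np.allclose(ours.coef_, ref.coef_[0], rtol=1e-6)
        pts = rng.standard_normal((200, 5))
        assert np.array_equal(ours.predict(pts), ref.predict(pts))

    def test_full_shrinkage_equals_diagonal_lda(self, rng):
        """γ=1 must reduce to an independent per-feature (diagonal
        covariance) Gaussian discriminant."""
        X, y, _ = self._gaussians(rng, n=120, d=4)
        ours = ShrinkageLda(shrinkage=1.0).fit(X, y)
        # independent diagonal implementation
        mu0, mu1 = X[y == "no"].mean(0), X[y == "yes"].mean(0)
        var = (X[y == "no"].var(0) * (y == "no").sum()
               + X[y == "yes"].var(0) * (y == "yes").sum()) / len(y)
        coef = (mu1 - mu0) / var
        assert np.allclose(ours.coef_, coef, rtol=1e-8)

    def test_affine_invariance_of_decision(self, rng):
        X, y, _ = self._gaussians(rng, n=100, d=4)
        pts = rng.standard_normal((50, 4))
        base = ShrinkageLda(shrinkage=0.2, reg_delta=0.0).fit(X, y).predict(pts)
        scaled = ShrinkageLda(shrinkage=0.2, reg_delta=0.0).fit(3.0 * X + 5.0, y) \
            .predict(3.0 * pts + 5.0)
        assert np.array_equal(base, scaled)

    def test_sample_weight_duplication_equivalence(self, rng):
        X, y, _ = self._gaussians(rng, n=30, d=3)
        w = np.ones(len(y))
        w[5] = 2.0
        weighted = ShrinkageLda(shrinkage=0.1).fit(X, y, sample_weight=w)
        dup = ShrinkageLda(shrinkage=0.1).fit(
            np.vstack([X, X[5:6]]), np.concatenate([y, y[5:6]]))
        assert np.allclose(weighted.coef_, dup.coef_, rtol=1e-8)

    def test_reg_delta_zeroes_weak_coefficients(self, rng):
        X, y, _ = self._gaussians(rng, n=200, d=6)
        X[:, 5] = rng.standard_normal(len(y))  # uninformative feature
        m = ShrinkageLda(shrinkage=0.2, reg_delta=0.5).fit(X, y)
        assert m.coef_[5] == 0.0
        assert np.any(m.coef_ != 0)

    def test_shuffled_labels_give_chance_cv(self, rng):
        from megspeech import bayesian_bootstrap_cv
        trials = [rng.standard_normal((4, 60)) for _ in range(60)]
        accs = []
        for rep in range(20):
            labels = np.array(["yes", "no"] * 30)
            rng.shuffle(labels)
            es = epochs_from_trials(trials, labels)
            a = bayesian_bootstrap_cv(es, k=4, n_bootstrap=1,
                                      decoder_factory=RmsLdaDecoder,
                                      seed=rep, uniform_weights=True)
            accs.append(np.nanmean(a))
        mean = np.mean(accs)
        half = 1.96 * np.sqrt(0.25 / (20 * 60))
        assert abs(mean - 0.5) < half + 0.05

    def test_singular_covariance_message(self):
        X = np.zeros((8, 3))
        X[:, 0] = [0, 0.1, 0.2, 0.3, 1, 1.1, 1.2, 1.3]
        y = np.array(["no"] * 4 + ["yes"] * 4)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            ShrinkageLda(shrinkage=0.0).fit(X, y)


class TestBayesOpt:
    bounds = {"x": (0.0, 1.0)}

    def test_concave_objective_recovered(self):
        obj = lambda p: -(p["x"] - 0.63) ** 2
        best, score, trace = bayes_opt_tune(obj, self.bounds, budget=20, seed=0)
        grid = np.linspace(0, 1, 201)
        grid_best = grid[np.argmax(-(grid - 0.63) ** 2)]
        assert abs(best["x"] - grid_best) < 0.05
        assert len(trace) == 20

    def test_budget_one_returns_single_point(self):
        best, score, trace = bayes_opt_tune(lambda p: p["x"], self.bounds,
                                            budget=1, seed=0)
        assert len(trace) == 1
        assert best == trace[0][0]

    def test_beats_random_search_on_average(self):
        def noisy_obj(rng):
            peak = rng.uniform(0.2, 0.8)
            return lambda p: -(p["x"] - peak) ** 2

        wins = 0
        for rep in range(8):
            rng = np.random.default_rng(rep)
            obj = noisy_obj(rng)
            _, bo_score, _ = bayes_opt_tune(obj, self.bounds, budget=12, seed=rep)
            rand = np.random.default_rng(1000 + rep).uniform(0, 1, 12)
            rs_score = max(obj({"x": v}) for v in rand)
            wins += bo_score >= rs_score
        assert wins >= 5

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bayes_opt_tune(lambda p: 0.0, {}, budget=5)

    def test_tune_lda_improves_over_worst_configuration(self):
        from megspeech import FeatureMatrix, tune_lda
        rng = np.random.default_rng(2)
        # informative means, strongly correlated noise: shrinkage matters
        n, d = 80, 10
        L = np.linalg.cholesky(0.9 * np.ones((d, d)) + 0.1 * np.eye(d))
        X = np.abs(rng.standard_normal((n, d)) @ L.T
                   + np.outer(np.tile([1.0, -1.0], n // 2), np.ones(d)) * 0.8) + 1.0
        y = np.tile(["yes", "no"], n // 2)
        fm = FeatureMatrix(values=X, labels=y, channel_ids=np.arange(d))
        best, score, trace = tune_lda(fm, k_folds=4, budget=10, seed=0)
        assert set(best) == {"shrinkage", "reg_delta"}
        assert score >= max(s for _, s in trace) - 1e-12
        assert 0.0 <= best["shrinkage"] <= 1.0
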
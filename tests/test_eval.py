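"""Evaluation-protocol contracts: temporal split arithmetic, Bayesian-
bootstrap CV reduction and weight properties, statistics against textbook
oracles, and end-to-end report determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from megspeech import (
    CvSpec, RmsLdaDecoder, accuracy, anova_tukey, bayesian_bootstrap_cv,
    paired_ttest, temporal_split, ttest_vs_chance, run_full_analysis,
    AnalysisSettings,
)
from megspeech.epoching import EpochSet

from conftest import small_config


def toy_epochs(n=100, n_ch=3, seed=0, sep=1.0):
    rng = np.random.default_rng(seed)
    trials, labels = [], []
    for i in range(n):
        lab = "yes" if rng.random() < 0.5 else "no"
        x = rng.standard_normal((n_ch, 50))
        x[0] += (1 if lab == "yes" else -1) * sep
        trials.append(x.astype(np.float32))
        labels.append(lab)
    return EpochSet(trials=trials, labels=np.array(labels), phase="overt",
                    fs=1000.0, trial_ids=np.arange(n), channel_ids=np.arange(n_ch))


class TestTemporalSplit:
    def test_100_trials_at_07(self):
        es = toy_epochs(100)
        train, test = temporal_split(es, 0.7)
        assert train.trial_ids.tolist() == list(range(70))
        assert test.trial_ids.tolist() == list(range(70, 100))

    def test_160_trials_gives_112_48(self):
        es = toy_epochs(160)
        train, test = temporal_split(es, 0.7)
        assert (train.n_trials, test.n_trials) == (112, 48)

    def test_extreme_fraction(self):
        es = toy_epochs(10)
        train, test = temporal_split(es, 0.999)
        assert (train.n_trials, test.n_trials) == (9, 1)

    def test_temporal_order_never_mixed(self):
        train, test = temporal_split(toy_epochs(57), 0.7)
        assert train.trial_ids.max() < test.trial_ids.min()

    def test_missing_class_in_train_rejected(self):
        es = toy_epochs(20)
        es.labels[:14] = "yes"
        with pytest.raises(ValueError, match="class absent"):
            temporal_split(es, 0.7)


class TestAccuracy:
    @pytest.mark.parametrize("pred, lab, expected", [
        (["yes"] * 4, ["yes"] * 4, 1.0),
        (["yes"] * 4, ["no"] * 4, 0.0),
        (["yes", "yes", "yes", "no"], ["yes", "yes", "yes", "yes"], 0.75),
    ])
    def test_examples(self, pred, lab, expected):
        assert accuracy(pred, lab) == expected

    @given(st.integers(1, 500), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_counting_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 2, n)
        lab = rng.integers(0, 2, n)
        count = sum(1 for p, l in zip(pred, lab) if p == l)
        assert accuracy(pred, lab) == count / n

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])


class TestBayesianBootstrapCv:
    def test_uniform_reduction_equals_plain_kfold(self):
        es = toy_epochs(48, sep=0.6)
        train, _ = temporal_split(es, 0.75)
        via_cv = bayesian_bootstrap_cv(train, k=4, n_bootstrap=1,
                                       decoder_factory=RmsLdaDecoder,
                                       seed=0, uniform_weights=True)
        # manual contiguous-block fourfold CV
        n = train.n_trials
        folds = np.array_split(np.arange(n), 4)
        manual = []
        for hold in folds:
            fit_idx = np.setdiff1d(np.arange(n), hold)
            sub, held = train.subset(fit_idx), train.subset(hold)
            dec = RmsLdaDecoder().fit(sub.trials, sub.labels)
            manual.append(accuracy(dec.predict(held.trials), held.labels))
        assert via_cv[:, 0].tolist() == manual

    def test_dirichlet_weights_properties(self):
        """Flat-Dirichlet bootstrap weights sum to one per repetition and
        have expectation 1/n."""
        rng = np.random.default_rng(0)
        n = 37
        draws = rng.dirichlet(np.ones(n), size=2000)
        assert np.allclose(draws.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(draws.mean(axis=0), 1.0 / n, atol=3e-3)

    def test_matrix_shape_and_range(self):
        es = toy_epochs(40, sep=0.6)
        train, _ = temporal_split(es, 0.8)
        accs = bayesian_bootstrap_cv(train, k=4, n_bootstrap=3,
                                     decoder_factory=RmsLdaDecoder, seed=1)
        assert accs.shape == (4, 3)
        assert np.all((accs >= 0) & (accs <= 1))

    def test_training_fold_size_keeps_40_trials_per_class(self):
        """80 trials/class x 70% train x 75% per CV fit leaves >= 40 trials
        per class in every training fold."""
        es = toy_epochs(160)
        es.labels[:] = np.array(["yes", "no"] * 80)
        train, _ = temporal_split(es, 0.7)
        n = train.n_trials
        folds = np.array_split(np.arange(n), 4)
        for hold in folds:
            fit_idx = np.setdiff1d(np.arange(n), hold)
            labs = train.labels[fit_idx]
            assert (labs == "yes").sum() >= 40
            assert (labs == "no").sum() >= 40

    def test_seeded_reproducibility(self):
        es = toy_epochs(40, sep=0.3)
        train, _ = temporal_split(es, 0.8)
        a = bayesian_bootstrap_cv(train, 4, 2, RmsLdaDecoder, seed=7)
        b = bayesian_bootstrap_cv(train, 4, 2, RmsLdaDecoder, seed=7)
        assert np.array_equal(a, b)


class TestTTests:
    def test_constant_chance_values_give_zero_t(self):
        res = ttest_vs_chance([0.5, 0.5, 0.5])
        assert res.t == 0.0
        assert res.zero_variance

    def test_hand_vector_oracle(self):
        res = ttest_vs_chance([0.6, 0.7, 0.8])
        # mean .7, sd .1 -> t = .2 / (.1/sqrt(3))
        assert res.t == pytest.approx(3.4641016, abs=1e-6)
        assert res.df == 2

    def test_p_matches_quadrature_of_t_density(self):
        res = ttest_vs_chance([0.6, 0.7, 0.8])
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, res.df), res.t, np.inf)
        assert res.p == pytest.approx(2 * tail, abs=1e-6)

    def test_paired_identical_zero(self):
        res = paired_ttest([0.6, 0.7], [0.6, 0.7])
        assert res.t == 0.0

    def test_paired_constant_difference_flagged_infinite(self):
        res = paired_ttest([0.6, 0.7, 0.8, 0.9], [0.5, 0.6, 0.7, 0.8])
        assert np.isinf(res.t) and res.t > 0
        assert res.zero_variance

    def test_paired_matches_scipy_ttest_rel(self, rng):
        a = rng.uniform(0.4, 0.9, 12)
        b = rng.uniform(0.4, 0.9, 12)
        res = paired_ttest(a, b)
        ref_t, ref_p = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref_t, abs=1e-10)
        assert res.p == pytest.approx(ref_p, abs=1e-10)


class TestAnovaTukey:
    def test_identical_group_means_give_zero_f(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        F, p, _ = anova_tukey(g)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_textbook_sums_of_squares_oracle(self):
        groups = {"a": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "b": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "c": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        vals = [np.array(v) for v in groups.values()]
        grand = np.concatenate(vals).mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
        ssw = sum(((v - v.mean()) ** 2).sum() for v in vals)
        k, n = 3, 18
        expected_F = (ssb / (k - 1)) / (ssw / (n - k))
        F, p, tukey = anova_tukey(groups)
        assert F == pytest.approx(expected_F, abs=1e-10)

    def test_tukey_adjusted_never_below_unadjusted(self):
        rng = np.random.default_rng(3)
        groups = {n: rng.normal(m, 1.0, 8) for n, m in
                  [("a", 0.0), ("b", 0.5), ("c", 1.5)]}
        _, _, tukey = anova_tukey(groups)
        for row in tukey:
            x, y = groups[row["group_a"]], groups[row["group_b"]]
            _, p_unadj = stats.ttest_ind(x, y)
            assert row["p_adj"] >= p_unadj - 1e-12

    def test_matches_statsmodels_tukeyhsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        groups = {n: rng.normal(m, 1.0, 10) for n, m in
                  [("a", 0.0), ("b", 0.6), ("c", 1.0)]}
        _, _, tukey = anova_tukey(groups)
        data = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(data, labs)
        ours = {(r["group_a"], r["group_b"]): r["p_adj"] for r in tukey}
        # statsmodels orders pairs lexicographically for sorted group labels
        for (g1, g2), padj in zip([("a", "b"), ("a", "c"), ("b", "c")], ref.pvalues):
            assert ours[(g1, g2)] == pytest.approx(padj, abs=1e-6)

    def test_unequal_group_sizes_allowed(self, rng):
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(1, 1, 9),
                  "c": rng.normal(2, 1, 7)}
        F, p, tukey = anova_tukey(groups)
        assert np.isfinite(F) and len(tukey) == 3

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_tukey({"a": [1.0, 2.0]})


class TestFullAnalysis:
    @pytest.fixture(scope="class")
    def fast_settings(self):
        return AnalysisSettings(
            cv=CvSpec(k_folds=3, n_bootstrap=1, seed=0),
            cnn_params={"learning_rate": 0.003, "max_epochs": 2, "batch_size": 8},
            ica_n_components=10,
            seed=0,
        )

    def test_report_structure_and_determinism(self, fast_settings):
        from megspeech import generate_session
        cfg = small_config(seed=4, n_reps_per_word=10)
        session = generate_session(cfg)
        rep1 = run_full_analysis(session, fast_settings)
        rep2 = run_full_analysis(generate_session(cfg), fast_settings)
        d1, d2 = rep1.to_dict(), rep2.to_dict()
        assert d1["phases"] == d2["phases"]
        assert d1["anova"] == d2["anova"]
        for phase in ("intended", "overt", "post"):
            for dec in ("lda", "cnn"):
                r = rep1.results[phase, dec]
                assert 0.0 <= r.test_accuracy <= 1.0
                assert r.cv_accuracies.shape == (3, 1)
        assert rep1.tost is not None and rep1.tost.df == rep1.n_trials - 2
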
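"""Evaluation protocol and statistics for the yes/no decoders.

The protocol preserves temporal order throughout: the first 70% of trials
(acquisition order) train, the last 30% test; within the training set,
fourfold cross-validation uses contiguous blocks as folds, repeated 10 times
by Bayesian bootstrapping — per repetition, flat-Dirichlet weights over the
training-fold trials enter the decoder fit as example weights, while the
held-out fold is scored unweighted.  Reported statistics: accuracy, t-tests
against the 0.5 chance level, paired decoder comparison, one-way ANOVA with
Tukey HSD across the three speech phases, and the TOST duration-equivalence
check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .epoching import EpochSet, PHASES, epoch_phases
from .lda import RmsLdaDecoder
from .cnn import SpeechCNN
from .preprocess import FilterSpec, lowpass_filter, notch_filter, detect_bad_channels, ica_clean
from .speech_events import (VADConfig, wiener_denoise, detect_voice_activity,
                            label_events, duration_equivalence_tost, TostResult)
from .synth import RawSession

__all__ = [
    "CvSpec",
    "EvalReport",
    "temporal_split",
    "bayesian_bootstrap_cv",
    "accuracy",
    "ttest_vs_chance",
    "paired_ttest",
    "anova_tukey",
    "run_full_analysis",
    "simulate_study",
]

logger = logging.getLogger(__name__)


@dataclass
class CvSpec:
    train_fraction: float = 0.7
    k_folds: int = 4
    n_bootstrap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    zero_variance: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def temporal_split(epochs: EpochSet, train_fraction: float = 0.7) -> tuple[EpochSet, EpochSet]:
    """First ``floor(f·n)`` trials (acquisition order) train, rest test."""
    n = epochs.n_trials
    if n < 10:
        raise ValueError("temporal split needs at least 10 trials")
    n_train = int(np.floor(train_fraction * n))
    train = epochs.subset(np.arange(n_train))
    test = epochs.subset(np.arange(n_train, n))
    if len(np.unique(train.labels)) < 2:
        raise ValueError("temporal split left a class absent from the training set")
    return train, test


def accuracy(predictions, labels) -> float:
    """Proportion of correct predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) == 0:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    return float(np.mean(predictions == labels))


def bayesian_bootstrap_cv(train: EpochSet, k: int, n_bootstrap: int,
                          decoder_factory, seed: int = 0,
                          uniform_weights: bool = False) -> np.ndarray:
    """k-fold CV over contiguous temporal blocks, repeated with Bayesian-
    bootstrap example weights.

    Folds are ``k`` contiguous blocks of the temporally ordered training
    trials.  Per repetition, per-trial weights are drawn flat-Dirichlet over
    the training-fold trials and passed to the decoder fit as
    ``sample_weight``; held-out accuracy is unweighted.  With
    ``uniform_weights=True`` (or implicitly for checking) the weights are
    uniform and one repetition reduces exactly to plain k-fold CV.

    Returns a (k, n_bootstrap) matrix; folds lacking both classes are
    skipped (NaN) with a warning.
    """
    n = train.n_trials
    folds = np.array_split(np.arange(n), k)
    rng = np.random.default_rng(seed)
    accs = np.full((k, n_bootstrap), np.nan)
    for b in range(n_bootstrap):
        for f, hold in enumerate(folds):
            fit_idx = np.setdiff1d(np.arange(n), hold)
            y_fit = train.labels[fit_idx]
            if len(np.unique(y_fit)) < 2 or len(np.unique(train.labels[hold])) < 2:
                warnings.warn(f"fold {f} lacks both classes; skipped", stacklevel=2)
                continue
            if uniform_weights:
                w = np.ones(len(fit_idx))
            else:
                w = rng.dirichlet(np.ones(len(fit_idx)))
                w = w * len(fit_idx)  # scale-invariant for both decoders
            dec = decoder_factory()
            sub = train.subset(fit_idx)
            dec.fit(sub.trials, sub.labels, sample_weight=w)
            held = train.subset(hold)
            accs[f, b] = accuracy(dec.predict(held.trials), held.labels)
    return accs


def ttest_vs_chance(accuracies, chance: float = 0.5) -> TTestResult:
    """One-sample two-sided t-test of decoding accuracies against chance."""
    a = np.asarray(accuracies, dtype=np.float64)
    a = a[~np.isnan(a)]
    if len(a) < 2:
        raise ValueError("need at least 2 accuracy values")
    # a spread at floating-point rounding level counts as zero variance
    if a.std(ddof=1) <= 1e-10 * max(1.0, np.abs(a).max()):
        t = np.inf * np.sign(a.mean() - chance) if a.mean() != chance else 0.0
        return TTestResult(t=float(t), p=0.0 if t != 0 else 1.0, df=len(a) - 1,
                           zero_variance=True)
    t, p = stats.ttest_1samp(a, chance)
    return TTestResult(t=float(t), p=float(p), df=len(a) - 1)


def paired_ttest(acc_a, acc_b) -> TTestResult:
    """Paired comparison of two decoders: one-sample t-test on differences."""
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    return ttest_vs_chance(a - b, chance=0.0)


def anova_tukey(groups: dict[str, np.ndarray]):
    """One-way fixed-effects ANOVA plus Tukey HSD pairwise comparisons
    (Tukey–Kramer for unequal group sizes).

    Returns ``(F, p, tukey)`` where tukey is a list of dicts
    ``{group_a, group_b, mean_diff, p_adj}``.
    """
    names = list(groups)
    vals = [np.asarray(groups[g], dtype=np.float64) for g in names]
    vals = [v[~np.isnan(v)] for v in vals]
    if len(vals) < 2 or any(len(v) < 2 for v in vals):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    if all(v.std(ddof=1) == 0 for v in vals):
        warnings.warn("zero within-group variance in every group", stacklevel=2)
    F, p = stats.f_oneway(*vals)
    res = stats.tukey_hsd(*vals)
    tukey = []
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            tukey.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": float(vals[i].mean() - vals[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return float(F), float(p), tukey


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisSettings:
    """Every tunable of the end-to-end run (logged into the report)."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    vad: VADConfig = field(default_factory=VADConfig)
    cv: CvSpec = field(default_factory=CvSpec)
    lda_params: dict = field(default_factory=lambda: {"shrinkage": 0.2, "reg_delta": 0.0})
    cnn_params: dict = field(default_factory=lambda: {"learning_rate": 0.003,
                                                      "max_epochs": 30,
                                                      "batch_size": 16})
    run_ica: bool = True
    ica_threshold: float = 0.8
    ica_n_components: int | None = None
    ica_decim: int = 20
    run_cv: bool = True
    tost_bound_d: float = 0.3
    decoders: tuple[str, ...] = ("lda", "cnn")
    seed: int = 0


@dataclass
class PhaseDecoderResult:
    cv_accuracies: np.ndarray | None
    cv_mean: float | None
    cv_sd: float | None
    test_accuracy: float
    n_test: int
    binom_p_vs_chance: float
    t_vs_chance: TTestResult | None


@dataclass
class EvalReport:
    """Per-phase, per-decoder results plus the session-level statistics."""

    results: dict          # (phase, decoder) -> PhaseDecoderResult
    anova: dict            # decoder -> {F, p, tukey}
    decoder_comparison: dict   # phase -> paired t LDA vs CNN (on CV accuracies)
    tost: TostResult | None
    n_trials: int
    n_channels: int
    settings: AnalysisSettings
    ica_report: object = None

    def test_accuracy(self, phase: str, decoder: str) -> float:
        return self.results[phase, decoder].test_accuracy

    def to_dict(self) -> dict:
        out = {"n_trials": self.n_trials, "n_channels": self.n_channels,
               "phases": {}, "anova": self.anova,
               "decoder_comparison": {
                   ph: r.as_dict() for ph, r in self.decoder_comparison.items()},
               "tost": asdict(self.tost) if self.tost else None}
        for (phase, dec), r in self.results.items():
            out["phases"].setdefault(phase, {})[dec] = {
                "cv_mean": r.cv_mean, "cv_sd": r.cv_sd,
                "cv_accuracies": (None if r.cv_accuracies is None
                                  else np.asarray(r.cv_accuracies).tolist()),
                "test_accuracy": r.test_accuracy, "n_test": r.n_test,
                "binom_p_vs_chance": r.binom_p_vs_chance,
                "t_vs_chance": r.t_vs_chance.as_dict() if r.t_vs_chance else None,
            }
        return out


def _decoder_factory(name: str, settings: AnalysisSettings, seed: int):
    if name == "lda":
        return lambda: RmsLdaDecoder(**settings.lda_params)
    if name == "cnn":
        return lambda: SpeechCNN(seed=seed, **settings.cnn_params)
    raise ValueError(f"unknown decoder {name!r}")


def preprocess_session(session: RawSession, settings: AnalysisSettings):
    """Filtering → bad channels → (optional) ICA; returns the cleaned
    session and the ICA report (or None)."""
    clean = lowpass_filter(session, settings.filter_spec)
    clean = notch_filter(clean, settings.filter_spec)
    detect_bad_channels(clean)
    ica_report = None
    if settings.run_ica:
        clean, ica_report = ica_clean(
            clean, n_components=settings.ica_n_components,
            threshold=settings.ica_threshold, seed=settings.seed,
            decim=settings.ica_decim,
        )
    return clean, ica_report


def extract_events(session: RawSession, settings: AnalysisSettings):
    """Wiener denoising → VAD → ground-truth overlap labeling."""
    denoised = wiener_denoise(session.audio, session.fs_audio)
    detected = detect_voice_activity(denoised, session.fs_audio, settings.vad)
    return label_events(detected, session.ground_truth_events, session.fs_audio)


def run_full_analysis(session: RawSession,
                      settings: AnalysisSettings | None = None) -> EvalReport:
    """Execute the whole pipeline on one session and collect all statistics.

    Stages: continuous filtering, bad-channel exclusion, ICA artifact
    removal, audio denoising + VAD + labeling, three-phase epoching, then
    per phase and per decoder a temporal 70/30 split with (optionally)
    Bayesian-bootstrapped fourfold CV on the training part and a final
    test-set accuracy, followed by the statistical tests.
    """
    settings = settings or AnalysisSettings()
    ss = np.random.SeedSequence(settings.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    clean, ica_report = preprocess_session(session, settings)
    events = extract_events(session, settings)
    if not events:
        raise RuntimeError("event extraction produced no labeled events")
    phase_sets = epoch_phases(clean, events)

    results: dict = {}
    cv_store: dict = {}
    for phase in PHASES:
        train, test = temporal_split(phase_sets[phase], settings.cv.train_fraction)
        for di, dec_name in enumerate(settings.decoders):
            factory = _decoder_factory(dec_name, settings, seed=stage_seeds[0])
            cv_accs = None
            if settings.run_cv:
                cv_accs = bayesian_bootstrap_cv(
                    train, k=settings.cv.k_folds, n_bootstrap=settings.cv.n_bootstrap,
                    decoder_factory=factory, seed=stage_seeds[1] + 97 * di,
                )
            model = factory()
            model.fit(train.trials, train.labels)
            pred = model.predict(test.trials)
            test_acc = accuracy(pred, test.labels)
            n_correct = int(round(test_acc * test.n_trials))
            binom_p = stats.binomtest(n_correct, test.n_trials, 0.5).pvalue
            flat = None if cv_accs is None else cv_accs[~np.isnan(cv_accs)].ravel()
            results[phase, dec_name] = PhaseDecoderResult(
                cv_accuracies=cv_accs,
                cv_mean=None if flat is None else float(np.mean(flat)),
                cv_sd=None if flat is None else float(np.std(flat, ddof=1)),
                test_accuracy=test_acc,
                n_test=test.n_trials,
                binom_p_vs_chance=float(binom_p),
                t_vs_chance=None if flat is None else ttest_vs_chance(flat),
            )
            if cv_accs is not None:
                cv_store[phase, dec_name] = cv_accs

    anova = {}
    comparison = {}
    if settings.run_cv:
        for dec_name in settings.decoders:
            groups = {ph: cv_store[ph, dec_name].ravel() for ph in PHASES}
            F, p, tukey = anova_tukey(groups)
            anova[dec_name] = {"F": F, "p": p, "tukey": tukey}
        if set(settings.decoders) >= {"lda", "cnn"}:
            for ph in PHASES:
                comparison[ph] = paired_ttest(cv_store[ph, "cnn"].ravel(),
                                              cv_store[ph, "lda"].ravel())

    dur = {lab: np.array([e.duration_s for e in events if e.label == lab])
           for lab in ("yes", "no")}
    tost = None
    if len(dur["yes"]) >= 2 and len(dur["no"]) >= 2:
        tost = duration_equivalence_tost(dur["yes"], dur["no"],
                                         bound_d=settings.tost_bound_d)

    return EvalReport(
        results=results, anova=anova, decoder_comparison=comparison, tost=tost,
        n_trials=phase_sets["overt"].n_trials,
        n_channels=phase_sets["overt"].n_channels,
        settings=settings, ica_report=ica_report,
    )


@dataclass
class StudyResult:
    """Across-session ("participant") statistics of a simulated study."""

    reports: list
    test_accuracy: dict        # (phase, decoder) -> per-session vector
    t_vs_chance: dict          # (phase, decoder) -> TTestResult across sessions
    decoder_comparison: dict   # phase -> TTestResult (CNN - LDA across sessions)
    anova: dict                # decoder -> {F, p, tukey} across phases


def simulate_study(session_configs, settings: AnalysisSettings | None = None) -> StudyResult:
    """Generate + analyze one session per config ("participant") and compute
    the across-session statistics."""
    from .synth import generate_session

    settings = settings or AnalysisSettings()
    reports = [run_full_analysis(generate_session(cfg), settings)
               for cfg in session_configs]
    acc = {}
    for ph in PHASES:
        for dec in settings.decoders:
            acc[ph, dec] = np.array([r.test_accuracy(ph, dec) for r in reports])
    tvc = {k: ttest_vs_chance(v) for k, v in acc.items() if len(v) >= 2}
    comp = {}
    if set(settings.decoders) >= {"lda", "cnn"} and len(reports) >= 2:
        comp = {ph: paired_ttest(acc[ph, "cnn"], acc[ph, "lda"]) for ph in PHASES}
    anova = {}
    if len(reports) >= 2:
        for dec in settings.decoders:
            F, p, tukey = anova_tukey({ph: acc[ph, dec] for ph in PHASES})
            anova[dec] = {"F": F, "p": p, "tukey": tukey}
    return StudyResult(reports=reports, test_accuracy=acc, t_vs_chance=tvc,
                       decoder_comparison=comp, anova=anova)
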
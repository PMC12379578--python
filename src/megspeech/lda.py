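"""Baseline decoder: per-channel RMS amplitude features and a regularized
linear discriminant, with Bayesian-optimization hyperparameter tuning.

The discriminant assumes two Gaussian classes sharing one covariance.  The
pooled within-class covariance is shrunk toward its own diagonal,
``Σ = (1 - γ) Σ̂ + γ diag(Σ̂)``, and discriminant coefficients whose
standardized magnitude falls below a relative threshold δ are zeroed — a
simple sparsifier for noisy sensors.  Both γ and δ are the tunable
hyperparameters searched by :func:`bayes_opt_tune`.

Estimators follow the scikit-learn protocol (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``fit``/``predict``/
``predict_proba``) and accept per-example ``sample_weight`` so they plug
directly into the Bayesian-bootstrap cross-validation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from scipy import stats

from .epoching import EpochSet

__all__ = [
    "FeatureMatrix",
    "extract_rms",
    "ShrinkageLda",
    "RmsLdaDecoder",
    "fit_lda",
    "predict_lda",
    "bayes_opt_tune",
]


@dataclass
class FeatureMatrix:
    """Trial × channel RMS amplitudes with labels."""

    values: np.ndarray
    labels: np.ndarray
    channel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (trials x channels)")
        if np.any(self.values < 0):
            raise ValueError("RMS features must be non-negative")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per trial required")


def _trial_rms(trial: np.ndarray) -> np.ndarray:
    if trial.shape[-1] == 0:
        raise ValueError("zero-length trial has no RMS")
    return np.sqrt(np.mean(np.asarray(trial, dtype=np.float64) ** 2, axis=-1))


def extract_rms(epochs: EpochSet) -> FeatureMatrix:
    """Per-channel root-mean-square amplitude of every trial, each computed
    over that trial's own length."""
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    values = np.stack([_trial_rms(t) for t in epochs.trials])
    return FeatureMatrix(values=values, labels=np.asarray(epochs.labels),
                         channel_ids=epochs.channel_ids)


class ShrinkageLda(BaseEstimator, ClassifierMixin):
    """Two-class LDA with diagonal shrinkage and coefficient thresholding.

    Parameters
    ----------
    shrinkage : float in [0, 1]
        Weight γ of the diagonal target; γ=0 is plain pooled-covariance LDA,
        γ=1 a diagonal (naive-Bayes-like) discriminant.
    reg_delta : float in [0, 1]
        Coefficients whose standardized magnitude ``|w_j|·s_j`` falls below
        ``reg_delta × max_j |w_j|·s_j`` are zeroed (s_j = pooled within-class
        SD of feature j).  0 disables thresholding.
    priors : array-like of 2 or None
        Class priors; None uses the (weighted) empirical frequencies.
    """

    def __init__(self, shrinkage: float = 0.2, reg_delta: float = 0.0, priors=None):
        self.shrinkage = shrinkage
        self.reg_delta = reg_delta
        self.priors = priors

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")
        if not 0 <= self.reg_delta <= 1:
            raise ValueError("reg_delta must lie in [0, 1]")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ShrinkageLda is a two-class discriminant")
        n, p = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("sample weights must be non-negative and not all zero")

        means = np.empty((2, p))
        cov = np.zeros((p, p))
        wsum_c = np.empty(2)
        for k, c in enumerate(self.classes_):
            m = y == c
            if w[m].sum() == 0 or m.sum() < 2:
                raise ValueError(f"class {c!r} needs at least 2 (weighted) trials")
            wc = w[m] / w[m].sum()
            means[k] = wc @ X[m]
            d = X[m] - means[k]
            cov += w[m].sum() * (d.T * wc) @ d
            wsum_c[k] = w[m].sum()
        cov /= w.sum()

        gamma = float(self.shrinkage)
        sigma = (1 - gamma) * cov + gamma * np.diag(np.diag(cov))
        self.class_means_ = means
        self.covariance_ = sigma
        self.priors_ = (np.asarray(self.priors, dtype=np.float64)
                        if self.priors is not None else wsum_c / wsum_c.sum())
        if not np.isclose(self.priors_.sum(), 1.0):
            raise ValueError("priors must sum to 1")

        try:
            sigma_inv_dm = np.linalg.solve(sigma, (means[1] - means[0]))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular shrunken covariance; increase shrinkage gamma"
            ) from err
        coef = sigma_inv_dm
        if self.reg_delta > 0:
            s = np.sqrt(np.diag(cov))
            z = np.abs(coef) * s
            zmax = z.max()
            if zmax > 0:
                coef = np.where(z < self.reg_delta * zmax, 0.0, coef)
        # score_1 - score_0 = coef·x + intercept
        self.coef_ = coef
        self.intercept_ = float(
            -0.5 * coef @ (means[0] + means[1])
            + np.log(self.priors_[1] / self.priors_[0])
        )
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.coef_):
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match fitted {len(self.coef_)}"
            )
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        s = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-s))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        # ties (score exactly 0) resolve to the first class
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class RmsLdaDecoder(BaseEstimator, ClassifierMixin):
    """RMS feature extraction + :class:`ShrinkageLda`, operating directly on
    ragged trial lists so it is interchangeable with the CNN decoder."""

    def __init__(self, shrinkage: float = 0.2, reg_delta: float = 0.0, priors=None):
        self.shrinkage = shrinkage
        self.reg_delta = reg_delta
        self.priors = priors

    @staticmethod
    def _features(trials) -> np.ndarray:
        return np.stack([_trial_rms(t) for t in trials])

    def fit(self, X, y, sample_weight=None):
        self.lda_ = ShrinkageLda(self.shrinkage, self.reg_delta, self.priors)
        self.lda_.fit(self._features(X), y, sample_weight=sample_weight)
        self.classes_ = self.lda_.classes_
        return self

    def predict(self, X):
        return self.lda_.predict(self._features(X))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self._features(X))


def fit_lda(features: FeatureMatrix, shrinkage: float = 0.2,
            reg_delta: float = 0.0, sample_weight=None) -> ShrinkageLda:
    """Functional wrapper over :class:`ShrinkageLda`."""
    return ShrinkageLda(shrinkage=shrinkage, reg_delta=reg_delta).fit(
        features.values, features.labels, sample_weight=sample_weight
    )


def predict_lda(model: ShrinkageLda, features: FeatureMatrix):
    """Labels and posterior probabilities for a fitted discriminant."""
    return model.predict(features.values), model.predict_proba(features.values)


def _expected_improvement(mu, sd, best):
    sd = np.maximum(sd, 1e-12)
    z = (mu - best) / sd
    return (mu - best) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def bayes_opt_tune(objective, bounds: dict[str, tuple[float, float]],
                   budget: int = 20, n_init: int = 5, seed: int = 0,
                   n_candidates: int = 512):
    """Sequential model-based maximization of a black-box objective.

    A Gaussian-process surrogate (Matérn ν=2.5) is fitted to all past
    evaluations; the next point maximizes expected improvement over a random
    candidate set.  Returns ``(best_params, best_score, trace)`` where trace
    is the list of ``(params, score)`` in evaluation order.

    ``objective`` maps a parameter dict to a scalar score (higher is
    better) — typically mean cross-validated accuracy of the LDA decoder
    over ``{shrinkage, reg_delta}``.
    """
    if not bounds:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])

    def sample(n):
        return lo + (hi - lo) * rng.random((n, len(names)))

    X_obs, y_obs, trace = [], [], []

    def evaluate(x):
        params = {k: float(v) for k, v in zip(names, x)}
        score = float(objective(params))
        X_obs.append(x)
        y_obs.append(score)
        trace.append((params, score))

    for x in sample(min(n_init, budget)):
        evaluate(x)
    while len(y_obs) < budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.ones(len(names))),
            normalize_y=True, alpha=1e-6,
            random_state=int(rng.integers(2 ** 31)),
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # kernel hyperparameter optimizer hitting its bound is fine here
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.array(X_obs), np.array(y_obs))
        cand = sample(n_candidates)
        mu, sd = gp.predict(cand, return_std=True)
        evaluate(cand[int(np.argmax(_expected_improvement(mu, sd, max(y_obs))))])

    best = int(np.argmax(y_obs))
    return trace[best][0], y_obs[best], trace


DEFAULT_LDA_SEARCH_SPACE = {"shrinkage": (0.0, 1.0), "reg_delta": (0.0, 0.5)}


def tune_lda(features: FeatureMatrix, k_folds: int = 4,
             search_space: dict[str, tuple[float, float]] | None = None,
             budget: int = 20, seed: int = 0):
    """Tune (shrinkage γ, threshold δ) by Bayesian optimization of mean
    k-fold CV accuracy over contiguous temporal blocks of the training
    features.  Returns ``(best_params, best_score, trace)``."""
    space = search_space or DEFAULT_LDA_SEARCH_SPACE
    X, y = features.values, np.asarray(features.labels)
    folds = np.array_split(np.arange(len(y)), k_folds)

    def objective(params: dict) -> float:
        accs = []
        for hold in folds:
            fit_idx = np.setdiff1d(np.arange(len(y)), hold)
            if len(np.unique(y[fit_idx])) < 2 or len(np.unique(y[hold])) < 2:
                continue
            model = ShrinkageLda(**params).fit(X[fit_idx], y[fit_idx])
            accs.append(np.mean(model.predict(X[hold]) == y[hold]))
        return float(np.mean(accs)) if accs else 0.0

    return bayes_opt_tune(objective, space, budget=budget, seed=seed)
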
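"""Canned desk-scale studies: whole-pipeline chance calibration and
synthetic signal recovery.

Both studies run the complete chain — generation, filtering, bad-channel
exclusion, artifact ICA, Wiener + VAD event extraction, three-phase
epoching, LDA and CNN decoding — at a desk scale chosen to finish in
minutes on one CPU: 64 gradiometers at 1 kHz, 80 repetitions per word.

* Calibration: sessions with all effect sizes zero.  Test accuracies must
  scatter inside the 95% binomial interval around chance, and the fraction
  of (session, phase, decoder) combinations whose test accuracy is
  significantly above chance (exact binomial test) must stay at the nominal
  rate.  The CNN trains for 15 epochs here — at zero effect the calibration
  property does not depend on training length.
* Signal recovery: one session with standardized phase effects
  intended 0.6, overt 1.5, post 0.9.  The expected signature is the overt >
  post > intended accuracy ordering, high overt accuracy for both decoders,
  and a significant one-way ANOVA across phases on the fold-level CV
  accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import AnalysisSettings, CvSpec, run_full_analysis
from .epoching import PHASES
from .synth import SessionConfig, generate_session

__all__ = [
    "calibration_settings",
    "calibration_session_config",
    "recovery_session_config",
    "run_calibration",
    "run_signal_recovery",
    "CalibrationResult",
]

#: desk-scale channel count used by the canned studies
N_CHANNELS = 64


def calibration_session_config(seed: int) -> SessionConfig:
    return SessionConfig(
        n_channels_grad=N_CHANNELS,
        n_reps_per_word=80,
        fs_meg=1000.0,
        effect_size_intended=0.0,
        effect_size_overt=0.0,
        effect_size_post=0.0,
        seed=seed,
    )


def recovery_session_config(seed: int) -> SessionConfig:
    return SessionConfig(
        n_channels_grad=N_CHANNELS,
        n_reps_per_word=80,
        fs_meg=1000.0,
        effect_size_intended=0.6,
        effect_size_overt=1.5,
        effect_size_post=0.9,
        seed=seed,
    )


def calibration_settings(seed: int = 0) -> AnalysisSettings:
    return AnalysisSettings(
        cv=CvSpec(k_folds=4, n_bootstrap=1, seed=seed),
        cnn_params={"learning_rate": 0.003, "max_epochs": 15, "batch_size": 16},
        ica_n_components=16,
        run_cv=False,
        seed=seed,
    )


def recovery_settings(seed: int = 0) -> AnalysisSettings:
    return AnalysisSettings(
        cv=CvSpec(k_folds=4, n_bootstrap=2, seed=seed),
        cnn_params={"learning_rate": 0.003, "max_epochs": 30, "batch_size": 16},
        ica_n_components=16,
        run_cv=True,
        seed=seed,
    )


@dataclass
class CalibrationResult:
    """Chance-level calibration over several zero-effect sessions."""

    accuracies: dict            # (session, phase, decoder) -> test accuracy
    binom_p: dict               # (session, phase, decoder) -> p vs chance
    n_test: int
    n_sessions: int

    @property
    def ci_halfwidth(self) -> float:
        return 1.96 * np.sqrt(0.25 / self.n_test)

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.accuracies.values()))

    @property
    def coverage_violation_rate(self) -> float:
        v = self.values
        return float(np.mean(np.abs(v - 0.5) > self.ci_halfwidth))

    @property
    def significant_rate(self) -> float:
        return float(np.mean(np.array(list(self.binom_p.values())) < 0.05))

    @property
    def mean_accuracy(self) -> float:
        return float(self.values.mean())


def run_calibration(n_sessions: int = 20, seed: int = 0) -> CalibrationResult:
    """Run the zero-effect calibration study."""
    ss = np.random.SeedSequence(seed)
    accs, ps, n_test = {}, {}, 0
    for i, child in enumerate(ss.spawn(n_sessions)):
        session_seed = int(child.generate_state(1)[0] % (2 ** 31))
        session = generate_session(calibration_session_config(session_seed))
        report = run_full_analysis(session, calibration_settings(seed=session_seed))
        for phase in PHASES:
            for dec in ("lda", "cnn"):
                r = report.results[phase, dec]
                accs[i, phase, dec] = r.test_accuracy
                ps[i, phase, dec] = r.binom_p_vs_chance
                n_test = r.n_test
    return CalibrationResult(accuracies=accs, binom_p=ps, n_test=n_test,
                             n_sessions=n_sessions)


def run_signal_recovery(seed: int = 0):
    """Run the fixed-seed signal-recovery analysis; returns the EvalReport."""
    session = generate_session(recovery_session_config(seed=seed + 11))
    return run_full_analysis(session, recovery_settings(seed=seed))
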
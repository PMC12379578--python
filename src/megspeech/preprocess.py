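"""Continuous-data cleaning: zero-phase Butterworth low-pass, power-line
notch bank, bad-channel detection, and ICA removal of ocular/cardiac
artifacts validated against the EOG/ECG reference channels.

Filtering is applied to the continuous recording before epoching so filter
edge effects never fall inside a trial.  All filters act on the MEG channels
only; auxiliary (EOG/ECG) channels pass through untouched so they remain
usable as artifact references for the ICA stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synth import RawSession

__all__ = [
    "FilterSpec",
    "ICAReport",
    "lowpass_filter",
    "notch_filter",
    "detect_bad_channels",
    "ica_clean",
]


@dataclass
class FilterSpec:
    """Low-pass + notch-bank specification.

    Defaults mirror a standard MEG speech-decoding chain: 4th-order
    noncausal (forward-backward) Butterworth low-pass at 250 Hz, and
    second-order IIR notches at the 60 Hz line frequency and its harmonics
    below the low-pass cutoff.
    """

    lowpass_cutoff: float = 250.0
    butter_order: int = 4
    causal: bool = False
    notch_freqs: list[float] | None = None  # None -> 60 Hz + harmonics < cutoff
    notch_bandwidth: float = 1.0
    line_freq: float = 60.0

    def resolved_notches(self, fs: float) -> list[float]:
        if self.notch_freqs is not None:
            freqs = list(self.notch_freqs)
        else:
            freqs = []
            f = self.line_freq
            while f < min(self.lowpass_cutoff, fs / 2):
                freqs.append(f)
                f += self.line_freq
        for f in freqs:
            if f >= fs / 2:
                raise ValueError(f"notch frequency {f} Hz is at or above Nyquist")
        return freqs

    def validate(self, fs: float) -> None:
        if not 0 < self.lowpass_cutoff < fs / 2:
            raise ValueError(
                f"low-pass cutoff {self.lowpass_cutoff} Hz must lie below Nyquist ({fs / 2} Hz)"
            )
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        self.resolved_notches(fs)


@dataclass
class ICAReport:
    """Outcome of the artifact-ICA pass: per-component |correlation| with the
    EOG and ECG references and the rejected component indices."""

    n_components: int
    eog_scores: np.ndarray
    ecg_scores: np.ndarray
    rejected_components: list[int]
    threshold: float
    seed_used: int = 0

    def __post_init__(self) -> None:
        for s in (self.eog_scores, self.ecg_scores):
            if np.any((np.asarray(s) < 0) | (np.asarray(s) > 1 + 1e-9)):
                raise ValueError("component scores must lie in [0, 1]")
        if any(c < 0 or c >= self.n_components for c in self.rejected_components):
            raise ValueError("rejected component index out of range")


def _apply_sos(x: np.ndarray, sos: np.ndarray, causal: bool) -> np.ndarray:
    if causal:
        return signal.sosfilt(sos, x, axis=-1)
    return signal.sosfiltfilt(sos, x, axis=-1)


def lowpass_filter(session: RawSession, spec: FilterSpec | None = None) -> RawSession:
    """Zero-phase (forward-backward) Butterworth low-pass of the MEG channels.

    Output length equals input length; EOG/ECG channels are untouched.
    """
    spec = spec or FilterSpec()
    spec.validate(session.fs)
    sos = signal.butter(spec.butter_order, spec.lowpass_cutoff, btype="low",
                        fs=session.fs, output="sos")
    out = session.copy()
    meg = out.meg_indices()
    x = out.data[meg]
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    out.data[meg] = _apply_sos(x, sos, spec.causal).astype(out.data.dtype)
    return out


def notch_filter(session: RawSession, spec: FilterSpec | None = None) -> RawSession:
    """Second-order IIR notches at the line frequency and harmonics, applied
    forward-backward.  Attenuation at each notch center exceeds 40 dB while
    frequencies >= 5 Hz away are left essentially untouched."""
    spec = spec or FilterSpec()
    spec.validate(session.fs)
    out = session.copy()
    meg = out.meg_indices()
    x = out.data[meg]
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    freqs = spec.resolved_notches(session.fs)
    if freqs:
        # cascade all harmonic notches into one second-order-section stack
        sos = np.vstack([
            signal.tf2sos(*signal.iirnotch(f0, f0 / spec.notch_bandwidth, fs=session.fs))
            for f0 in freqs
        ])
        x = _apply_sos(x, sos, spec.causal)
    out.data[meg] = x.astype(out.data.dtype)
    return out


def detect_bad_channels(session: RawSession, flat_tol: float = 1e-10,
                        noise_z: float = 5.0) -> np.ndarray:
    """Flag flat (variance < ``flat_tol``) and noisy MEG channels.

    The per-channel amplitude statistic is a robust variance (squared scaled
    median absolute deviation about the median), so sparse transients such
    as blinks do not inflate it — only channels that are noisy most of the
    time stand out.  Noisy channels are outliers of its log distribution:
    robust z-score (median / MAD across channels) above ``noise_z``.  The
    mask is stored on the session and honored by epoching; a mask covering
    more than 20% of the MEG channels triggers a corrupt-session warning.
    """
    meg = session.meg_indices()
    if len(meg) < 10:
        raise ValueError("bad-channel detection needs at least 10 MEG channels")
    X = session.data[meg]
    if X.shape[1] > 400_000:  # robust statistics stabilize long before this
        X = X[:, ::4]
    med_t = np.median(X, axis=1, keepdims=True)
    var = (1.4826 * np.median(np.abs(X - med_t), axis=1)) ** 2
    flat = var < flat_tol
    logv = np.where(flat, np.nan,
                    np.log(np.maximum(var.astype(np.float64), 1e-300)))
    med = np.nanmedian(logv)
    mad = np.nanmedian(np.abs(logv - med))
    scale = 1.4826 * mad if mad > 0 else np.nanstd(logv) or 1.0
    z = (logv - med) / scale
    noisy = np.nan_to_num(z, nan=0.0) > noise_z
    mask = np.zeros(session.data.shape[0], dtype=bool)
    mask[meg[flat | noisy]] = True
    if mask[meg].mean() > 0.2:
        warnings.warn(
            f"{mask[meg].sum()} of {len(meg)} MEG channels flagged bad; "
            "the session may be continuously contaminated",
            stacklevel=2,
        )
    session.bad_channel_mask = mask
    return mask


def _abs_corr(sources: np.ndarray, ref: np.ndarray) -> np.ndarray:
    s = sources - sources.mean(axis=1, keepdims=True)
    r = ref - ref.mean()
    denom = np.sqrt((s ** 2).sum(axis=1) * (r ** 2).sum())
    denom[denom == 0] = np.inf
    return np.abs(s @ r) / denom


def ica_clean(session: RawSession, n_components: int | None = None,
              threshold: float = 0.8, seed: int = 0, decim: int = 20,
              max_retries: int = 3) -> tuple[RawSession, ICAReport]:
    """Remove ocular/cardiac components from the MEG channels.

    Fixed-point (negentropy-maximizing) ICA is fitted on the good MEG
    channels, decimated in time for speed; sources are then computed on the
    full-rate data.  Deflation (one component at a time) is used because it
    peels off the strongly non-Gaussian artifact components first and is
    indifferent to the Gaussian background subspace, where a symmetric
    rotation has no stable fixed point.  Components whose absolute temporal
    correlation with the EOG or ECG reference exceeds ``threshold`` are
    subtracted via their back-projection, so cleaned data + removed
    reconstruction equals the input exactly.
    """
    eog = session.channel_indices("eog")
    ecg = session.channel_indices("ecg")
    if len(eog) == 0 or len(ecg) == 0:
        raise ValueError("ICA cleaning requires EOG and ECG reference channels")
    meg = session.meg_indices()
    good = meg[~session.bad_channel_mask[meg]]
    X = np.asarray(session.data[good], dtype=np.float32)
    k = n_components or min(30, len(good))

    last_err: Exception | None = None
    for attempt in range(max_retries):
        ica = FastICA(n_components=k, algorithm="deflation", whiten="unit-variance",
                      random_state=seed + attempt, max_iter=60, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica.fit(X[:, ::decim].T)
                if not np.all(np.isfinite(ica.components_)):
                    raise RuntimeError("non-finite unmixing matrix")
                break
            except (ConvergenceWarning, RuntimeError) as err:  # retry, fresh seed
                last_err = err
    else:
        raise RuntimeError(f"ICA failed to converge after {max_retries} seeds: {last_err}")

    # full-rate sources from the fitted unmixing (components_ includes whitening)
    W = ica.components_.astype(np.float32)
    S = W @ X - (W @ ica.mean_.astype(np.float32))[:, None]
    mixing = ica.mixing_.astype(np.float32)  # (n_good, k)

    eog_scores = _abs_corr(S, np.asarray(session.data[eog[0]], dtype=np.float32))
    ecg_scores = _abs_corr(S, np.asarray(session.data[ecg[0]], dtype=np.float32))
    rejected = sorted(np.where((eog_scores > threshold) | (ecg_scores > threshold))[0].tolist())

    out = session.copy()
    if rejected:
        removal = mixing[:, rejected] @ S[rejected]
        out.data[good] = (X - removal).astype(out.data.dtype)
    report = ICAReport(
        n_components=k,
        eog_scores=eog_scores,
        ecg_scores=ecg_scores,
        rejected_components=rejected,
        threshold=threshold,
        seed_used=seed + attempt,
    )
    return out, report
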
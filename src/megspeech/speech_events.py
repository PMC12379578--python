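"""Acoustic event extraction: Wiener speech denoising, energy-based voice
activity detection (VAD) with hangover, ground-truth overlap labeling, and
the two one-sided tests (TOST) procedure for yes/no duration equivalence.

The VAD is a frame-energy detector with hysteresis: frames above an adaptive
(or fixed) log-energy threshold mark speech, a hangover keeps the detector
active over brief intra-word dips, short gaps are merged and short blips
dropped, and boundaries are refined to sample resolution at the local
envelope threshold crossing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .synth import SpeechEvent

__all__ = [
    "VADConfig",
    "TostResult",
    "wiener_denoise",
    "detect_voice_activity",
    "label_events",
    "duration_equivalence_tost",
]

logger = logging.getLogger(__name__)


@dataclass
class VADConfig:
    frame_len_ms: float = 25.0
    hop_ms: float = 10.0
    energy_threshold_mode: str = "adaptive-percentile"  # or "fixed"
    threshold_db: float = -30.0          # used in fixed mode
    adaptive_percentile: float = 30.0    # noise-floor percentile
    adaptive_margin_db: float = 6.0      # dB above the noise floor
    hangover_frames: int = 5
    min_event_ms: float = 150.0
    min_gap_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.frame_len_ms < self.hop_ms:
            raise ValueError("frame length must be >= hop")
        if self.min_event_ms <= 0:
            raise ValueError("min_event_ms must be positive")
        if self.energy_threshold_mode not in ("adaptive-percentile", "fixed"):
            raise ValueError(f"unknown threshold mode {self.energy_threshold_mode!r}")


def wiener_denoise(audio: np.ndarray, fs: float, noise_percentile: float = 10.0,
                   nperseg: int = 512, oversubtract: float = 2.0) -> np.ndarray:
    """Short-time spectral Wiener filter.

    The noise power spectrum is estimated as the mean periodogram of the
    lowest-energy frames (bottom ``noise_percentile`` percent); because that
    lower tail underestimates the stationary noise level, the estimate is
    inflated by ``oversubtract`` before entering the gain
    ``G = max(0, 1 - βN/P)``, applied per time-frequency bin, and the signal
    re-synthesized by overlap-add.  Output length equals input length.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.ndim != 1:
        raise ValueError("expected a mono waveform")
    if len(audio) < fs:
        raise ValueError("need at least 1 s of audio")
    if not np.any(audio):
        return audio.copy()

    noverlap = nperseg // 2
    f, t, Z = signal.stft(audio, fs=fs, nperseg=nperseg, noverlap=noverlap)
    P = np.abs(Z) ** 2
    frame_energy = P.sum(axis=0)
    k = max(1, int(math.ceil(len(t) * noise_percentile / 100.0)))
    quiet = np.argsort(frame_energy)[:k]
    N = P[:, quiet].mean(axis=1, keepdims=True)
    gain = np.maximum(0.0, 1.0 - oversubtract * N / np.maximum(P, 1e-300))
    _, x = signal.istft(Z * gain, fs=fs, nperseg=nperseg, noverlap=noverlap)
    if len(x) < len(audio):
        x = np.pad(x, (0, len(audio) - len(x)))
    return x[: len(audio)]


def _frame_log_energy(audio: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (len(audio) - frame)) // hop
    idx = np.arange(frame) + hop * np.arange(n_frames)[:, None]
    e = (audio[idx] ** 2).mean(axis=1)
    return 10.0 * np.log10(np.maximum(e, 1e-30))


def detect_voice_activity(audio: np.ndarray, fs: float,
                          cfg: VADConfig | None = None) -> list[tuple[int, int]]:
    """Detect speech segments; returns ``(onset, offset)`` sample pairs
    (0-based, half-open), sorted and non-overlapping."""
    cfg = cfg or VADConfig()
    audio = np.asarray(audio, dtype=np.float64)
    frame = max(int(round(cfg.frame_len_ms * fs / 1000.0)), 1)
    hop = max(int(round(cfg.hop_ms * fs / 1000.0)), 1)
    if len(audio) < frame:
        return []
    logE = _frame_log_energy(audio, frame, hop)

    if cfg.energy_threshold_mode == "fixed":
        thr = cfg.threshold_db
    else:
        thr = np.percentile(logE, cfg.adaptive_percentile) + cfg.adaptive_margin_db

    active = logE > thr
    # hangover: stay active for a few frames after the last energetic frame
    if cfg.hangover_frames > 0 and active.any():
        run = 0
        for i in range(len(active)):
            if active[i]:
                run = cfg.hangover_frames
            elif run > 0:
                active[i] = True
                run -= 1

    # frame runs -> candidate segments in samples
    segs: list[list[int]] = []
    i = 0
    while i < len(active):
        if active[i]:
            j = i
            while j + 1 < len(active) and active[j + 1]:
                j += 1
            segs.append([i * hop, j * hop + frame])
            i = j + 1
        else:
            i += 1

    # merge gaps shorter than min_gap, then drop short events
    min_gap = cfg.min_gap_ms * fs / 1000.0
    merged: list[list[int]] = []
    for s in segs:
        if merged and s[0] - merged[-1][1] < min_gap:
            merged[-1][1] = s[1]
        else:
            merged.append(s)
    min_len = cfg.min_event_ms * fs / 1000.0
    coarse = [s for s in merged if s[1] - s[0] >= min_len]

    # refine boundaries to the sample where the short-time envelope crosses
    # the linear threshold
    lin_thr = 10 ** (thr / 10.0)
    w = max(int(0.005 * fs), 1)
    kernel = np.ones(w) / w
    env = signal.fftconvolve(audio ** 2, kernel, mode="same")
    out: list[tuple[int, int]] = []
    for a, b in coarse:
        lo = max(a - frame, 0)
        hi = min(b + frame, len(audio))
        above = env[lo:hi] > lin_thr
        if above.any():
            a_ref = lo + int(np.argmax(above))
            b_ref = lo + len(above) - int(np.argmax(above[::-1]))
        else:
            a_ref, b_ref = a, min(b, len(audio))
        if out and a_ref < out[-1][1]:
            a_ref = out[-1][1]
        if b_ref - a_ref >= min_len:
            out.append((a_ref, b_ref))
    return out


def label_events(detected: list[tuple[int, int]], ground_truth: list[SpeechEvent],
                 fs_audio: float) -> list[SpeechEvent]:
    """Attach labels to detected segments by maximal temporal overlap with the
    ground-truth events.  Detections overlapping nothing, or tying between
    two truths, are dropped (and logged)."""
    labeled: list[SpeechEvent] = []
    n_dropped = 0
    for a, b in detected:
        overlaps = [(min(b, ev.offset_sample) - max(a, ev.onset_sample), ev)
                    for ev in ground_truth]
        overlaps = [(o, ev) for o, ev in overlaps if o > 0]
        if not overlaps:
            n_dropped += 1
            continue
        overlaps.sort(key=lambda p: p[0], reverse=True)
        if len(overlaps) > 1 and overlaps[0][0] == overlaps[1][0]:
            n_dropped += 1  # ambiguous tie
            continue
        best = overlaps[0][1]
        labeled.append(SpeechEvent(a, b, best.label, (b - a) / fs_audio))
    if n_dropped:
        logger.info("label_events: dropped %d unmatched/ambiguous detections", n_dropped)
    return labeled


@dataclass
class TostResult:
    """Two one-sided tests against symmetric standardized bounds ±bound_d."""

    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    p: float
    df: int
    cohens_d: float
    bound_d: float
    alpha: float
    equivalent: bool


def duration_equivalence_tost(durations_yes, durations_no, bound_d: float = 0.3,
                              alpha: float = 0.05) -> TostResult:
    """Equivalence test for the two duration distributions.

    The raw mean difference is tested against margins ``±bound_d * s_p``
    (pooled SD), i.e. the equivalence bound is expressed as a standardized
    Cohen's d.  Equivalence is declared when both one-sided tests reject,
    equivalently when ``max(p_lower, p_upper) < alpha``.
    """
    x = np.asarray(durations_yes, dtype=np.float64)
    y = np.asarray(durations_no, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 samples per class")
    if bound_d <= 0:
        raise ValueError("bound_d must be positive")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: durations are degenerate")
    sp = math.sqrt(sp2)
    diff = x.mean() - y.mean()
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    d = diff / sp
    margin = bound_d * sp
    t_lower = (diff + margin) / se       # H0: diff <= -margin, reject if large
    t_upper = (diff - margin) / se       # H0: diff >= +margin, reject if small
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    p = max(p_lower, p_upper)
    return TostResult(
        t_lower=float(t_lower), t_upper=float(t_upper),
        p_lower=p_lower, p_upper=p_upper, p=float(p), df=int(df),
        cohens_d=float(d), bound_d=float(bound_d), alpha=float(alpha),
        equivalent=bool(p < alpha),
    )
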
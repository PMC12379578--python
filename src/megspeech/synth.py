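"""Synthetic MEG + audio session generator.

Emulates a self-paced yes/no speech-production MEG session: multichannel
gradiometer (plus optional magnetometer) recordings with 1/f background
noise, power-line contamination, ocular and cardiac artifacts mirrored into
EOG/ECG reference channels, class-dependent spatiotemporal patterns in the
intended / overt / postspeech windows of each utterance, and a synchronized
mono audio track with one voiced burst per utterance.

The generator is the ground-truth oracle for every downstream stage: it
returns the exact event table (onset, offset, label) it injected, so voice
activity detection, epoching and decoding can all be scored against truth.
All randomness flows from ``SessionConfig.seed`` through a single
``numpy.random.SeedSequence``; two calls with equal configs produce
bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SessionConfig",
    "SpeechEvent",
    "RawSession",
    "event_schedule",
    "generate_session",
]

#: valid labels, in class-index order
LABELS = ("yes", "no")


@dataclass(frozen=True)
class SpeechEvent:
    """One utterance, located on the audio sample axis (0-based, half-open)."""

    onset_sample: int
    offset_sample: int
    label: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.offset_sample <= self.onset_sample:
            raise ValueError(
                f"event offset {self.offset_sample} must exceed onset {self.onset_sample}"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")


def _as_pair(x) -> tuple[float, float]:
    if np.isscalar(x):
        return (float(x), float(x))
    x = tuple(float(v) for v in x)
    if len(x) != 2:
        raise ValueError("per-class parameter needs exactly two entries (yes, no)")
    return x


@dataclass
class SessionConfig:
    """Parameters of one synthetic session ("participant").

    Desk-scale defaults: 203 gradiometers at 1 kHz — the decoding feature
    dimension of a 306-channel acquisition after dropping magnetometers and
    one bad sensor, at a sampling rate that keeps CNN training fast.  The
    full acquisition scale (add 102 magnetometers, 4 kHz) stays reachable
    through the same fields.

    Effect sizes are standardized: each phase's class pattern is a focal
    spatial topography (a random ~1/8 subset of sensors, unit RMS over the
    active set) whose per-active-sensor amplitude is
    ``effect_size × noise_sd``.
    """

    n_channels_grad: int = 203
    n_channels_mag: int = 0
    n_aux: int = 2                      # EOG + ECG reference channels
    fs_meg: float = 1000.0
    fs_audio: float = 16000.0
    n_reps_per_word: int = 80
    inter_word_interval: tuple[float, float] = (4.0, 5.0)   # onset-to-onset, s
    word_duration_mean: tuple[float, float] | float = 0.45  # per class, s
    word_duration_sd: tuple[float, float] | float = 0.08
    effect_size_intended: float = 0.6
    effect_size_overt: float = 1.5
    effect_size_post: float = 0.9
    blink_rate_per_min: float = 15.0
    heart_rate_bpm: float = 65.0
    line_freq: float = 60.0
    line_amp: float = 0.5               # line amplitude / noise SD
    blink_amp: float = 8.0              # peak blink amplitude / noise SD
    ecg_amp: float = 3.0                # peak cardiac amplitude / noise SD
    noise_sd: float = 1.0
    audio_snr_db: float = 15.0
    pattern_freq: float = 8.0           # carrier of the injected patterns, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        self.word_duration_mean = _as_pair(self.word_duration_mean)
        self.word_duration_sd = _as_pair(self.word_duration_sd)
        for name in ("n_channels_grad", "n_aux", "fs_meg", "fs_audio", "n_reps_per_word"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_channels_mag < 0:
            raise ValueError("n_channels_mag must be >= 0")
        lo, hi = self.inter_word_interval
        if not (0 < lo <= hi):
            raise ValueError("inter_word_interval must satisfy 0 < lo <= hi")
        if lo < 3.0 * max(self.word_duration_mean):
            raise ValueError(
                "inter-word interval shorter than 3x mean word duration would make "
                "the intended/overt/post windows of consecutive trials overlap"
            )
        for name in ("effect_size_intended", "effect_size_overt", "effect_size_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # highest audio component: 5th harmonic of the higher voiced f0 (150 Hz)
        if self.fs_audio < 2 * 5 * 160.0:
            raise ValueError("fs_audio too low for the synthesized speech band")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RawSession:
    """Continuous multichannel recording plus synchronized audio.

    ``data`` holds one row per entry of ``channel_roles``
    (``grad`` / ``mag`` / ``eog`` / ``ecg``); ``audio`` is a mono waveform at
    ``fs_audio``.  ``ground_truth_events`` is populated by the generator only.
    """

    data: np.ndarray
    channel_roles: list[str]
    fs: float
    audio: np.ndarray
    fs_audio: float
    ground_truth_events: list[SpeechEvent] = field(default_factory=list)
    bad_channel_mask: np.ndarray | None = None
    config: SessionConfig | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_roles):
            raise ValueError("data must be (n_channels, n_samples) matching channel_roles")
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros(self.data.shape[0], dtype=bool)
        expected_audio = self.data.shape[1] * self.fs_audio / self.fs
        if abs(len(self.audio) - expected_audio) > self.fs_audio / self.fs + 1:
            raise ValueError(
                f"audio length {len(self.audio)} inconsistent with MEG length "
                f"{self.data.shape[1]} and the sampling-rate ratio"
            )
        self._check_events()

    def _check_events(self) -> None:
        prev_off = -1
        n_audio = len(self.audio)
        for ev in self.ground_truth_events:
            if ev.onset_sample <= prev_off:
                raise ValueError("ground-truth events must be sorted and non-overlapping")
            if ev.onset_sample < 0 or ev.offset_sample > n_audio:
                raise ValueError("ground-truth event outside the recording")
            prev_off = ev.offset_sample

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == role], dtype=int)

    def meg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r in ("grad", "mag")], dtype=int
        )

    def copy(self) -> "RawSession":
        return RawSession(
            data=self.data.copy(),
            channel_roles=list(self.channel_roles),
            fs=self.fs,
            audio=self.audio.copy(),
            fs_audio=self.fs_audio,
            ground_truth_events=list(self.ground_truth_events),
            bad_channel_mask=None if self.bad_channel_mask is None else self.bad_channel_mask.copy(),
            config=self.config,
        )


# ---------------------------------------------------------------------------
# event scheduling
# ---------------------------------------------------------------------------

def event_schedule(config: SessionConfig, rng: np.random.Generator | None = None) -> list[SpeechEvent]:
    """Draw the utterance schedule: balanced random label order, uniform
    inter-onset gaps, per-class Gaussian durations (truncated at 100 ms).

    The label sequence is a random permutation of ``n_reps_per_word`` copies
    of each word — i.i.d. uniform draws with each class capped at its quota,
    matching a speaker told to randomize rather than alternate, with the run
    stopped once both words reach the quota.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_reps_per_word
    labels = np.array([0] * n + [1] * n)
    rng.shuffle(labels)

    lo, hi = config.inter_word_interval
    gaps = rng.uniform(lo, hi, size=2 * n)
    # lead-in long enough for the intended window of the first trial
    t = 2.0 + max(config.word_duration_mean) + 3 * max(config.word_duration_sd)
    events: list[SpeechEvent] = []
    for i, lab in enumerate(labels):
        dur = rng.normal(config.word_duration_mean[lab], config.word_duration_sd[lab])
        dur = max(float(dur), 0.1)
        onset = int(round(t * config.fs_audio))
        offset = onset + max(int(round(dur * config.fs_audio)), 1)
        events.append(
            SpeechEvent(onset, offset, LABELS[lab], (offset - onset) / config.fs_audio)
        )
        t += gaps[i]
    return events


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit (=sd) standard deviation per
    channel.  Spectrum flattened below 1 Hz so the variance stays finite."""
    from scipy.fft import next_fast_len, rfft, irfft

    nfft = next_fast_len(n_samples)
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    shape = (1.0 / np.sqrt(np.maximum(freqs, 1.0))).astype(np.float32)
    shape[0] = 0.0  # no DC
    for block in range(0, n_channels, 16):
        nb = min(16, n_channels - block)
        white = rng.standard_normal((nb, nfft)).astype(np.float32)
        spec = rfft(white, axis=1) * shape
        x = irfft(spec, n=nfft, axis=1)[:, :n_samples]
        x /= x.std(axis=1, keepdims=True)
        out[block:block + nb] = sd * x
    return out


def _blink_template(fs: float) -> np.ndarray:
    """Biphasic ~300 ms blink: dominant positive lobe with a small rebound."""
    t = np.arange(int(round(0.3 * fs))) / fs
    main = np.exp(-0.5 * ((t - 0.10) / 0.035) ** 2)
    rebound = -0.35 * np.exp(-0.5 * ((t - 0.20) / 0.05) ** 2)
    return (main + rebound).astype(np.float32)


def _qrs_template(fs: float) -> np.ndarray:
    """Triphasic ~80 ms QRS-like complex (Q-R-S deflections)."""
    t = np.arange(int(round(0.08 * fs))) / fs
    q = -0.25 * np.exp(-0.5 * ((t - 0.015) / 0.004) ** 2)
    r = 1.0 * np.exp(-0.5 * ((t - 0.04) / 0.006) ** 2)
    s = -0.3 * np.exp(-0.5 * ((t - 0.062) / 0.005) ** 2)
    return (q + r + s).astype(np.float32)


def _add_template_train(target: np.ndarray, template: np.ndarray,
                        onsets: np.ndarray, gain: float | np.ndarray) -> None:
    """Add ``gain[:, None] * template`` at each onset (rows broadcast)."""
    n = target.shape[-1]
    L = len(template)
    for s in onsets:
        s = int(s)
        if s < 0 or s >= n:
            continue
        seg = template[: n - s]
        if target.ndim == 1:
            target[s:s + len(seg)] += gain * seg
        else:
            target[:, s:s + len(seg)] += np.outer(gain, seg)


def _audio_word(rng: np.random.Generator, label_idx: int, n: int, fs: float) -> np.ndarray:
    """Voiced burst: harmonic stack (distinct f0 per word) + aspiration noise,
    with a fast-attack / fast-release envelope."""
    t = np.arange(n) / fs
    f0 = 150.0 if label_idx == 0 else 110.0
    x = np.zeros(n)
    phase = rng.uniform(0, 2 * np.pi)
    for h in range(1, 6):
        x += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + phase * h)
    x += 0.2 * rng.standard_normal(n)
    attack = min(int(0.02 * fs), max(n // 8, 1))
    env = np.ones(n)
    env[:attack] = np.linspace(0, 1, attack)
    env[-attack:] *= np.linspace(1, 0, attack)
    x *= env
    rms = np.sqrt(np.mean(x ** 2))
    return (x / rms if rms > 0 else x).astype(np.float32)


def meg_window(event: SpeechEvent, fs_meg: float, fs_audio: float) -> tuple[int, int]:
    """Map an audio-domain event to MEG-domain samples: onset rounds down,
    offset rounds up (half-open [onset, offset))."""
    ratio = fs_meg / fs_audio
    onset = int(math.floor(event.onset_sample * ratio))
    offset = int(math.ceil(event.offset_sample * ratio))
    return onset, max(offset, onset + 1)


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def generate_session(config: SessionConfig) -> RawSession:
    """Generate one synthetic session.  Deterministic given ``config.seed``.

    Sensor model: 1/f background noise (per-channel SD ``noise_sd``) + 60 Hz
    line harmonics + blink/cardiac templates on fixed random topographies.
    For each utterance, the class-specific pattern (fixed unit-norm random
    topography per class per phase × half-sine envelope × sinusoidal carrier)
    is injected into the intended (pre-onset), overt (onset→offset) and
    postspeech (post-offset) windows, scaled by the phase effect size in
    units of the sensor noise SD.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_sched, rng_noise, rng_art, rng_topo, rng_audio = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    events = event_schedule(config, rng_sched)

    # recording span: last post window + 2 s pad
    last = events[-1]
    dur_last = last.offset_sample - last.onset_sample
    n_audio = int(last.offset_sample + dur_last + 2.0 * config.fs_audio)
    n_meg = int(round(n_audio * config.fs_meg / config.fs_audio))

    n_grad = config.n_channels_grad
    n_mag = config.n_channels_mag
    n_meg_ch = n_grad + n_mag
    roles = ["grad"] * n_grad + ["mag"] * n_mag + ["eog", "ecg"][: config.n_aux]
    n_ch = len(roles)

    data = np.zeros((n_ch, n_meg), dtype=np.float32)
    data[:n_meg_ch] = _pink_noise(rng_noise, n_meg_ch, n_meg, config.fs_meg, config.noise_sd)

    t_meg = np.arange(n_meg, dtype=np.float64) / config.fs_meg
    # power-line harmonics (pickup falls off with order; capped at the 5th),
    # per-channel random amplitude, common phase
    h = 1
    while h * config.line_freq < config.fs_meg / 2 and h <= 5:
        amp = config.line_amp * config.noise_sd / h
        coeff = (amp * rng_noise.uniform(0.5, 1.5, size=n_meg_ch)).astype(np.float32)
        phase = rng_noise.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * h * config.line_freq * t_meg + phase).astype(np.float32)
        data[:n_meg_ch] += coeff[:, None] * wave
        h += 1

    eog_idx = roles.index("eog") if "eog" in roles else None
    ecg_idx = roles.index("ecg") if "ecg" in roles else None

    # ocular artifacts
    if config.blink_rate_per_min > 0:
        n_blinks = rng_art.poisson(config.blink_rate_per_min * n_meg / config.fs_meg / 60.0)
        blink_onsets = np.sort(rng_art.uniform(0, n_meg - 0.35 * config.fs_meg,
                                               size=n_blinks)).astype(int)
        tpl = _blink_template(config.fs_meg)
        topo = rng_art.standard_normal(n_meg_ch)
        topo /= np.max(np.abs(topo))
        _add_template_train(data[:n_meg_ch], tpl, blink_onsets,
                            (config.blink_amp * config.noise_sd * topo).astype(np.float32))
        if eog_idx is not None:
            _add_template_train(data[eog_idx], tpl, blink_onsets,
                                5.0 * config.blink_amp * config.noise_sd)

    # cardiac artifacts: quasi-regular beat train
    if config.heart_rate_bpm > 0:
        beat = 60.0 / config.heart_rate_bpm
        times, t = [], float(rng_art.uniform(0, beat))
        while t * config.fs_meg < n_meg - 0.1 * config.fs_meg:
            times.append(t)
            t += beat * (1 + 0.02 * rng_art.standard_normal())
        beat_onsets = (np.array(times) * config.fs_meg).astype(int)
        tpl = _qrs_template(config.fs_meg)
        topo = rng_art.standard_normal(n_meg_ch)
        topo /= np.max(np.abs(topo))
        _add_template_train(data[:n_meg_ch], tpl, beat_onsets,
                            (config.ecg_amp * config.noise_sd * topo).astype(np.float32))
        if ecg_idx is not None:
            _add_template_train(data[ecg_idx], tpl, beat_onsets,
                                8.0 * config.ecg_amp * config.noise_sd)

    if eog_idx is not None:
        data[eog_idx] += 0.2 * config.noise_sd * rng_art.standard_normal(n_meg).astype(np.float32)
    if ecg_idx is not None:
        data[ecg_idx] += 0.2 * config.noise_sd * rng_art.standard_normal(n_meg).astype(np.float32)

    # class-specific patterns on the gradiometers, per phase
    effects = {
        "intended": config.effect_size_intended,
        "overt": config.effect_size_overt,
        "post": config.effect_size_post,
    }
    # focal topographies: each class/phase pattern loads a small random
    # subset of sensors (as real sensor-space speech responses do), with
    # unit-RMS amplitude over the active set, so effect size reads as the
    # standardized per-active-sensor amplitude
    n_active = max(4, int(round(n_grad / 8)))
    topos = {}
    for phase in ("intended", "overt", "post"):
        for ci in (0, 1):
            v = np.zeros(n_grad, dtype=np.float32)
            idx = rng_topo.choice(n_grad, size=min(n_active, n_grad), replace=False)
            vals = rng_topo.standard_normal(len(idx))
            vals /= np.sqrt(np.mean(vals ** 2))
            v[idx] = vals
            topos[phase, ci] = v

    for ev in events:
        onset, offset = meg_window(ev, config.fs_meg, config.fs_audio)
        L = offset - onset
        ci = LABELS.index(ev.label)
        windows = {
            "intended": (onset - L, onset),
            "overt": (onset, offset),
            "post": (offset, offset + L),
        }
        tt = np.arange(L) / config.fs_meg
        env = np.sin(np.pi * np.arange(L) / L)
        carrier = np.sin(2 * np.pi * config.pattern_freq * tt)
        wave = (env * carrier).astype(np.float32)
        for phase, (a, b) in windows.items():
            amp = effects[phase] * config.noise_sd
            if amp == 0 or a < 0 or b > n_meg:
                continue
            data[:n_grad, a:b] += amp * np.outer(topos[phase, ci], wave)

    # audio track
    audio = np.zeros(n_audio, dtype=np.float32)
    for ev in events:
        n = ev.offset_sample - ev.onset_sample
        audio[ev.onset_sample:ev.offset_sample] += _audio_word(
            rng_audio, LABELS.index(ev.label), n, config.fs_audio
        )
    noise_rms = 10 ** (-config.audio_snr_db / 20.0)  # word bursts have unit RMS
    audio += (noise_rms * rng_audio.standard_normal(n_audio)).astype(np.float32)

    session = RawSession(
        data=data,
        channel_roles=roles,
        fs=config.fs_meg,
        audio=audio,
        fs_audio=config.fs_audio,
        ground_truth_events=events,
        config=config,
    )
    return session
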
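"""Readers/writers shared by all stages.

A session round-trips through one HDF5 container with datasets ``/meg``,
``/audio``, ``/channel_roles``, ``/fs``, ``/fs_audio``, ``/events`` (and the
bad-channel mask); the event table also round-trips through a plain CSV
(columns ``onset_sample, offset_sample, label, duration_s``; 0-based,
half-open sample indices).  Audio is exportable as 16-bit PCM WAV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import FilterSpec
from .speech_events import VADConfig
from .evaluate import CvSpec, AnalysisSettings
from .synth import RawSession, SessionConfig, SpeechEvent

__all__ = [
    "write_session", "read_session",
    "write_events", "read_events",
    "write_wav",
    "StudyConfig",
]

EVENT_COLUMNS = ["onset_sample", "offset_sample", "label", "duration_s"]


def write_session(session: RawSession, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("meg", data=session.data)
        f.create_dataset("audio", data=session.audio)
        f.create_dataset("channel_roles",
                         data=np.array(session.channel_roles, dtype="S"))
        f.create_dataset("fs", data=float(session.fs))
        f.create_dataset("fs_audio", data=float(session.fs_audio))
        f.create_dataset("bad_channel_mask", data=session.bad_channel_mask)
        ev = session.ground_truth_events
        g = f.create_group("events")
        g.create_dataset("onset_sample", data=np.array([e.onset_sample for e in ev], dtype=np.int64))
        g.create_dataset("offset_sample", data=np.array([e.offset_sample for e in ev], dtype=np.int64))
        g.create_dataset("label", data=np.array([e.label for e in ev], dtype="S"))
        g.create_dataset("duration_s", data=np.array([e.duration_s for e in ev], dtype=np.float64))
        if session.config is not None:
            f.attrs["config_json"] = json.dumps(session.config.to_dict())


def read_session(path) -> RawSession:
    with h5py.File(path, "r") as f:
        for name in ("meg", "audio", "channel_roles", "fs", "fs_audio"):
            if name not in f:
                raise KeyError(f"session container is missing dataset /{name}")
        roles = [r.decode() for r in f["channel_roles"][()]]
        events = []
        if "events" in f:
            g = f["events"]
            for on, off, lab, dur in zip(g["onset_sample"][()], g["offset_sample"][()],
                                         g["label"][()], g["duration_s"][()]):
                events.append(SpeechEvent(int(on), int(off), lab.decode(), float(dur)))
        cfg = None
        if "config_json" in f.attrs:
            d = json.loads(f.attrs["config_json"])
            for key in ("inter_word_interval", "word_duration_mean", "word_duration_sd"):
                if isinstance(d.get(key), list):
                    d[key] = tuple(d[key])
            cfg = SessionConfig(**d)
        mask = f["bad_channel_mask"][()] if "bad_channel_mask" in f else None
        return RawSession(
            data=f["meg"][()], channel_roles=roles, fs=float(f["fs"][()]),
            audio=f["audio"][()], fs_audio=float(f["fs_audio"][()]),
            ground_truth_events=events, bad_channel_mask=mask, config=cfg,
        )


def write_events(events: list[SpeechEvent], path) -> None:
    pd.DataFrame({
        "onset_sample": [e.onset_sample for e in events],
        "offset_sample": [e.offset_sample for e in events],
        "label": [e.label for e in events],
        "duration_s": [e.duration_s for e in events],
    }).to_csv(path, index=False)


def read_events(path) -> list[SpeechEvent]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV is missing columns: {sorted(missing)}")
    for i, row in df.iterrows():
        if row.offset_sample <= row.onset_sample:
            raise ValueError(f"event CSV row {i}: offset <= onset")
        if row.label not in ("yes", "no"):
            raise ValueError(f"event CSV row {i}: unknown label {row.label!r}")
    if not df.onset_sample.is_monotonic_increasing:
        warnings.warn("event CSV rows were not sorted by onset; sorting", stacklevel=2)
        df = df.sort_values("onset_sample").reset_index(drop=True)
    prev_off = -1
    for i, row in df.iterrows():
        if row.onset_sample < prev_off:
            raise ValueError(f"event CSV row {i}: overlaps the previous event")
        prev_off = row.offset_sample
    return [SpeechEvent(int(r.onset_sample), int(r.offset_sample), str(r.label),
                        float(r.duration_s)) for r in df.itertuples()]


def write_wav(audio: np.ndarray, fs: float, path) -> None:
    """Export audio as 16-bit PCM, peak-normalized to 90% full scale."""
    x = np.asarray(audio, dtype=np.float64)
    peak = np.max(np.abs(x)) or 1.0
    wavfile.write(path, int(fs), (0.9 * x / peak * 32767).astype(np.int16))


@dataclasses.dataclass
class StudyConfig:
    """Nested configuration of a full simulated study; round-trips through
    JSON losslessly, with every unset field resolving to the documented
    module default."""

    session: SessionConfig = dataclasses.field(default_factory=SessionConfig)
    settings: AnalysisSettings = dataclasses.field(default_factory=AnalysisSettings)
    n_sessions: int = 1
    seed: int = 0

    def to_json(self, path=None) -> str:
        d = {
            "session": self.session.to_dict(),
            "settings": {
                **{k: v for k, v in dataclasses.asdict(self.settings).items()
                   if k not in ("filter_spec", "vad", "cv")},
                "filter_spec": dataclasses.asdict(self.settings.filter_spec),
                "vad": dataclasses.asdict(self.settings.vad),
                "cv": dataclasses.asdict(self.settings.cv),
            },
            "n_sessions": self.n_sessions,
            "seed": self.seed,
        }
        text = json.dumps(d, indent=2, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "StudyConfig":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists() else str(source)
        d = json.loads(text)
        sd = d.get("session", {})
        for key in ("inter_word_interval", "word_duration_mean", "word_duration_sd"):
            if isinstance(sd.get(key), list):
                sd[key] = tuple(sd[key])
        st = dict(d.get("settings", {}))
        fspec = FilterSpec(**st.pop("filter_spec", {}))
        vad = VADConfig(**st.pop("vad", {}))
        cv = CvSpec(**st.pop("cv", {}))
        if isinstance(st.get("decoders"), list):
            st["decoders"] = tuple(st["decoders"])
        settings = AnalysisSettings(filter_spec=fspec, vad=vad, cv=cv, **st)
        return cls(session=SessionConfig(**sd), settings=settings,
                   n_sessions=d.get("n_sessions", 1), seed=d.get("seed", 0))
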
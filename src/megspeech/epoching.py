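"""Trial segmentation: cut the cleaned MEG recording into intended / overt /
postspeech segments of equal per-trial length, anchored on the acoustic
onset and offset of each utterance, keeping only good gradiometer channels.

For an utterance spanning MEG samples ``[onset, offset)`` of length ``L``:

* overt    = ``[onset, onset + L)``
* intended = ``[onset - L, onset)``
* post     = ``[offset, offset + L)``

Trials whose intended window would reach into the previous trial's post
window, or whose windows leave the recording, are dropped (and counted), so
no two retained segments share a sample.  Trial lengths are preserved as-is
(ragged storage): both decoders — RMS features and a global-average-pooled
CNN — are length-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth import RawSession, SpeechEvent, meg_window

__all__ = ["EpochSet", "epoch_phases", "pool_sessions", "PHASES"]

logger = logging.getLogger(__name__)

PHASES = ("intended", "overt", "post")


@dataclass
class EpochSet:
    """Trials of one phase: a ragged list of (n_channels, n_samples) arrays.

    ``trial_ids`` index into the event table the epochs were cut from;
    ``channel_ids`` are the retained gradiometer rows of the source session.
    """

    trials: list[np.ndarray]
    labels: np.ndarray
    phase: str
    fs: float
    trial_ids: np.ndarray
    channel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if not (len(self.trials) == len(self.labels) == len(self.trial_ids)):
            raise ValueError("trials, labels and trial_ids must have equal length")
        nch = {t.shape[0] for t in self.trials}
        if len(nch) > 1:
            raise ValueError("all trials must share one channel count")
        if self.trials and self.trials[0].shape[0] != len(self.channel_ids):
            raise ValueError("trial channel count must match channel_ids")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def __len__(self) -> int:
        return len(self.trials)

    def lengths(self) -> np.ndarray:
        return np.array([t.shape[1] for t in self.trials], dtype=int)

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return EpochSet(
            trials=[self.trials[i] for i in idx],
            labels=self.labels[idx],
            phase=self.phase,
            fs=self.fs,
            trial_ids=self.trial_ids[idx],
            channel_ids=self.channel_ids,
        )


def epoch_phases(session: RawSession, events: list[SpeechEvent]) -> dict[str, EpochSet]:
    """Cut the three phase segments for each labeled event.

    Only gradiometer channels not flagged bad are retained.  Returns a dict
    with one EpochSet per phase; every trial present appears in all three
    phases with identical segment length.
    """
    grad = session.channel_indices("grad")
    good = grad[~session.bad_channel_mask[grad]]
    if len(good) == 0:
        raise ValueError("no good gradiometer channels to epoch")

    n = session.n_samples
    kept: dict[str, list[np.ndarray]] = {p: [] for p in PHASES}
    labels, trial_ids = [], []
    prev_post_end = -1
    n_dropped = 0
    for i, ev in enumerate(events):
        onset, offset = meg_window(ev, session.fs, session.fs_audio)
        L = offset - onset
        spans = {
            "intended": (onset - L, onset),
            "overt": (onset, offset),
            "post": (offset, offset + L),
        }
        if spans["intended"][0] < 0 or spans["post"][1] > n or spans["intended"][0] < prev_post_end:
            n_dropped += 1
            continue
        for p in PHASES:
            a, b = spans[p]
            kept[p].append(np.asarray(session.data[good, a:b], dtype=np.float32))
        labels.append(ev.label)
        trial_ids.append(i)
        prev_post_end = spans["post"][1]

    if n_dropped:
        logger.info("epoch_phases: dropped %d of %d trials (overlap or bounds)",
                    n_dropped, len(events))
    if not labels:
        raise ValueError("no trials survived epoching")
    labels = np.array(labels)
    trial_ids = np.array(trial_ids)
    return {
        p: EpochSet(trials=kept[p], labels=labels.copy(), phase=p, fs=session.fs,
                    trial_ids=trial_ids.copy(), channel_ids=good.copy())
        for p in PHASES
    }


def pool_sessions(epoch_sets: list[EpochSet]) -> EpochSet:
    """Concatenate same-phase EpochSets from several sessions, preserving
    within-session temporal order and the given session order."""
    if not epoch_sets:
        raise ValueError("nothing to pool")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.phase != first.phase:
            raise ValueError("cannot pool different phases")
        if es.fs != first.fs:
            raise ValueError("cannot pool different sampling rates")
        if es.n_channels != first.n_channels:
            raise ValueError(
                f"channel count mismatch: {es.n_channels} vs {first.n_channels}"
            )
    trials, labels, ids = [], [], []
    offset = 0
    for es in epoch_sets:
        trials.extend(es.trials)
        labels.append(es.labels)
        ids.append(es.trial_ids + offset)
        offset += (es.trial_ids.max() + 1) if len(es.trial_ids) else 0
    return EpochSet(
        trials=trials,
        labels=np.concatenate(labels),
        phase=first.phase,
        fs=first.fs,
        trial_ids=np.concatenate(ids),
        channel_ids=first.channel_ids,
    )
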
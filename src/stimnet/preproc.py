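"""Referencing, artifact screening, and epoch extraction.

A stimulation-mapping session yields, per trial, a half-second
pre-stimulation window ending at stimulation onset and two consecutive
half-second post-stimulation windows beginning 100 ms after stimulation
offset (the buffer absorbs amplifier recovery).  The 30 s pre-session
baseline is tiled into nonoverlapping half-second windows.  Channels with
stimulation-locked amplitude artifact are screened out on the raw (pre
common-average-reference) signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    ReferencingError,
    ScheduleError,
)
from .schedule import SessionSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EpochWindow",
    "WINDOW_SECONDS",
    "BUFFER_SECONDS",
    "common_average_reference",
    "screen_artifact_electrodes",
    "extract_epochs",
    "window_samples",
]

WINDOW_SECONDS = 0.5
BUFFER_SECONDS = 0.1


@dataclass
class Recording:
    """Multichannel recording: ``signal`` [channels x samples] in microvolts."""

    signal: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "raw"  # {"raw", "common_average"}

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.signal[self.labels.index(label)]

    def subset(self, labels: list[str]) -> "Recording":
        idx = [self.labels.index(lb) for lb in labels]
        return Recording(
            signal=self.signal[idx].copy(),
            fs=self.fs,
            labels=list(labels),
            reference=self.reference,
        )


@dataclass(frozen=True)
class EpochWindow:
    """Half-open sample span [start, stop) with its role in the trial layout.

    ``trial_index`` is None for baseline windows.  Roles: ``baseline``,
    ``pre`` (ends at stimulation onset), ``post100`` (begins 100 ms after
    stimulation offset), ``post600`` (immediately after post100).
    """

    trial_index: int | None
    role: str
    start: int
    stop: int

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    def extract(self, rec: Recording) -> np.ndarray:
        return rec.signal[:, self.start : self.stop]


def window_samples(fs: float, seconds: float = WINDOW_SECONDS) -> int:
    """Samples per analysis window: round(seconds * fs)."""
    return int(round(seconds * fs))


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the per-sample mean across channels.

    Output column means are zero by construction; the reference flag flips
    to ``common_average``.
    """
    if rec.reference != "raw":
        raise ReferencingError(f"recording already referenced: {rec.reference}")
    if rec.n_channels < 2:
        raise ReferencingError("common average reference needs >= 2 channels")
    referenced = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return replace(rec, signal=referenced, reference="common_average")


def _trial_spans(
    schedule: SessionSchedule, fs: float
) -> list[tuple[int, int, int, int]]:
    """Per trial: (pre_start, onset, post_start, post_stop) in samples."""
    n_win = window_samples(fs)
    n_buf = int(round(BUFFER_SECONDS * fs))
    spans = []
    for trial in schedule.trials:
        onset = int(round(trial.onset * fs))
        offset = int(round((trial.onset + trial.duration) * fs))
        post_start = offset + n_buf
        spans.append((onset - n_win, onset, post_start, post_start + 2 * n_win))
    return spans


def screen_artifact_electrodes(
    rec: Recording,
    schedule: SessionSchedule,
    alpha: float = 0.05,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Discard channels whose raw post-stimulation amplitude is elevated.

    For each non-stimulated channel, the mean absolute voltage of the
    pre-stimulation window is compared with that of the post-stimulation
    epoch (both half-second response windows) by a paired t test across
    trials.  A channel is discarded when p < ``alpha`` (uncorrected,
    two-sided) *and* its mean post amplitude exceeds its mean pre amplitude:
    suppression is not grounds for removal.  Zero-variance paired
    differences are assigned p = 1.

    Must run on the raw (pre-referencing) recording; the stimulated pair is
    exempt from screening and retained.
    """
    if rec.reference != "raw":
        raise ReferencingError("screening must run on the raw recording")
    if len(schedule.trials) < 2:
        raise InsufficientDataError("artifact screening needs >= 2 trials")
    spans = _trial_spans(schedule, rec.fs)
    for pre_start, _, _, post_stop in spans:
        if pre_start < 0 or post_stop > rec.n_samples:
            raise ScheduleError("trial extends outside the recording")

    stim_labels = set()
    for trial in schedule.trials:
        stim_labels.update(trial.stim_pair)

    kept: list[str] = []
    discarded: list[str] = []
    pvals: dict[str, float] = {}
    for ci, label in enumerate(rec.labels):
        if label in stim_labels:
            kept.append(label)
            continue
        pre_amp = np.array(
            [np.mean(np.abs(rec.signal[ci, s[0] : s[1]])) for s in spans]
        )
        post_amp = np.array(
            [np.mean(np.abs(rec.signal[ci, s[2] : s[3]])) for s in spans]
        )
        diffs = post_amp - pre_amp
        if np.allclose(np.std(diffs), 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(post_amp, pre_amp).pvalue)
        pvals[label] = p
        if p < alpha and post_amp.mean() > pre_amp.mean():
            discarded.append(label)
        else:
            kept.append(label)
    if discarded:
        logger.info("screened out %d channel(s): %s", len(discarded), discarded)
    return kept, discarded, pvals


def extract_epochs(
    rec: Recording, schedule: SessionSchedule
) -> list[EpochWindow]:
    """Tile the baseline and cut per-trial pre/post100/post600 windows.

    The stimulation epoch and the 100 ms buffer after stimulation offset
    never fall inside any returned window.  Trials whose post600 window
    would run past the end of the recording are dropped with a logged
    warning.
    """
    fs = rec.fs
    n_win = window_samples(fs)
    windows: list[EpochWindow] = []

    b0 = int(round(schedule.baseline_span[0] * fs))
    b1 = int(round(schedule.baseline_span[1] * fs))
    b1 = min(b1, rec.n_samples)
    n_base = (b1 - b0) // n_win
    for w in range(n_base):
        start = b0 + w * n_win
        windows.append(EpochWindow(None, "baseline", start, start + n_win))

    for ti, (pre_start, onset, post_start, post_stop) in enumerate(
        _trial_spans(schedule, fs)
    ):
        if pre_start < 0:
            raise ScheduleError(f"trial {ti} pre window starts before recording")
        if post_stop > rec.n_samples:
            logger.warning(
                "trial %d post600 window extends past recording end; dropped", ti
            )
            continue
        windows.append(EpochWindow(ti, "pre", pre_start, onset))
        windows.append(EpochWindow(ti, "post100", post_start, post_start + n_win))
        windows.append(
            EpochWindow(ti, "post600", post_start + n_win, post_stop)
        )
    return windows
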
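"""Core in-memory containers shared across the pipeline.

Recordings are plain numpy arrays plus geometry; word-level events travel
as pandas DataFrames in a BIDS-events-like dialect (columns ``onset``,
``duration``, ``word``, ``sentence_id``, ``subject``, onsets in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("onset", "duration", "word", "sentence_id", "subject")


@dataclass
class Recording:
    """A continuous multi-sensor recording for one subject.

    Attributes
    ----------
    signal : ndarray, shape (n_samples, n_sensors)
    sampling_rate_hz : float
    sensor_positions : ndarray, shape (n_sensors, 2)
        2-D sensor layout, normalized to the unit square.
    subject_id : str
    """

    signal: np.ndarray
    sampling_rate_hz: float
    sensor_positions: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (samples x sensors)")
        if self.sensor_positions.shape != (self.signal.shape[1], 2):
            raise ValueError(
                f"sensor_positions shape {self.sensor_positions.shape} does not "
                f"match {self.signal.shape[1]} sensors")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_sensors(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[0] / self.sampling_rate_hz


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the events-table contract and return the table unchanged.

    Onsets must be non-decreasing and each sentence_id must group a
    contiguous run of rows.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    onsets = events["onset"].to_numpy(dtype=float)
    if len(onsets) and (np.diff(onsets) < 0).any():
        raise ValueError("event onsets must be non-decreasing")
    sid = events["sentence_id"].to_numpy()
    if len(sid):
        changes = np.flatnonzero(sid[1:] != sid[:-1]) + 1
        blocks = [sid[0], *sid[changes]]
        if len(blocks) != len(set(blocks)):
            raise ValueError("sentence_id must group contiguous rows")
    return events


@dataclass
class EpochSet:
    """Word-aligned windows of brain activity.

    ``X`` has shape (n_epochs, t, n_sensors); row ``i`` is the window for
    ``words[i]`` in sentence ``sentence_ids[i]`` of ``subject_ids[i]``.
    """

    X: np.ndarray
    words: list[str]
    sentence_ids: list
    subject_ids: list[str]
    sampling_rate_hz: float
    tmin_s: float = 0.0
    window_s: float = 3.0
    baseline_s: float = 0.5
    n_dropped: int = 0
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        n = self.X.shape[0] if self.X.size else len(self.words)
        if not (len(self.words) == len(self.sentence_ids) == len(self.subject_ids) == n):
            raise ValueError("epoch metadata lengths disagree")

    def __len__(self) -> int:
        return len(self.words)

    @property
    def n_times(self) -> int:
        return self.X.shape[1] if self.X.ndim == 3 else 0

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset (boolean mask) or reorder (integer index array) epochs."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return EpochSet(
            X=self.X[idx] if self.X.size else self.X,
            words=[self.words[i] for i in idx],
            sentence_ids=[self.sentence_ids[i] for i in idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            sampling_rate_hz=self.sampling_rate_hz,
            tmin_s=self.tmin_s,
            window_s=self.window_s,
            baseline_s=self.baseline_s,
            onsets=self.onsets[idx] if self.onsets.size else self.onsets,
        )


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets that share sampling rate and window geometry."""
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if (s.sampling_rate_hz, s.window_s, s.tmin_s) != (
                first.sampling_rate_hz, first.window_s, first.tmin_s):
            raise ValueError("epoch sets have incompatible geometry")
    return EpochSet(
        X=np.concatenate([s.X for s in sets], axis=0),
        words=sum((s.words for s in sets), []),
        sentence_ids=sum((list(s.sentence_ids) for s in sets), []),
        subject_ids=sum((s.subject_ids for s in sets), []),
        sampling_rate_hz=first.sampling_rate_hz,
        tmin_s=first.tmin_s,
        window_s=first.window_s,
        baseline_s=first.baseline_s,
        n_dropped=sum(s.n_dropped for s in sets),
        onsets=np.concatenate([s.onsets for s in sets])
        if all(s.onsets.size for s in sets) else np.empty(0),
    )
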
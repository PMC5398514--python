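"""Core in-memory containers for multichannel fNIRS decoding.

A :class:`Recording` is one subject's channels x samples matrix of
oxygenated-hemoglobin (HbO) concentration change, already preprocessed
(filtered and converted via the modified Beer-Lambert law), together with
its stimulus events.  A :class:`Dataset` bundles the recordings of one
experiment with exactly two condition labels and the a-priori channel
inclusion list shared by every subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ChannelMismatchError,
    DatasetValidationError,
    EventOutOfBoundsError,
    MissingConditionTrialsError,
    UnknownConditionError,
)

logger = logging.getLogger("nirsmvpa")


@dataclass(frozen=True)
class Event:
    """A stimulus presentation: onset in seconds from recording start."""

    onset_s: float
    condition: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.onset_s) or self.onset_s < 0:
            raise EventOutOfBoundsError(
                f"event onset {self.onset_s!r} must be finite and >= 0"
            )


@dataclass(frozen=True)
class TimeWindow:
    """Analysis window relative to stimulus onset, in seconds.

    The window is half-open: samples with onset + start_s <= t < onset + end_s
    are included.  It must span at least two samples (the baseline sample
    plus one more) at the recording's sampling rate.
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise DatasetValidationError(
                f"window [{self.start_s}, {self.end_s}) requires 0 <= start < end"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def n_samples(self, sample_rate_hz: float) -> int:
        """Number of samples the window covers at a given rate (half-open)."""
        i0 = int(np.ceil(self.start_s * sample_rate_hz - 1e-9))
        i1 = int(np.ceil(self.end_s * sample_rate_hz - 1e-9))
        return i1 - i0


@dataclass
class Recording:
    """One subject's HbO time series plus events.

    hbo is channels x samples; sample index 0 is t = 0 and sample i is at
    t = i / sample_rate_hz seconds.
    """

    subject_id: str
    hbo: np.ndarray
    channel_ids: list[str]
    sample_rate_hz: float
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        if self.sample_rate_hz <= 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: sample_rate_hz must be > 0"
            )
        if self.hbo.shape[0] != len(self.channel_ids):
            raise DatasetValidationError(
                f"subject {self.subject_id}: {len(self.channel_ids)} channel ids "
                f"but hbo has {self.hbo.shape[0]} rows"
            )
        if self.hbo.shape[1] < 1:
            raise DatasetValidationError(
                f"subject {self.subject_id}: recording has no samples"
            )
        for ev in self.events:
            if ev.onset_s >= self.duration_s:
                raise EventOutOfBoundsError(
                    f"subject {self.subject_id}: event onset {ev.onset_s} s is "
                    f"outside the {self.duration_s} s recording"
                )

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise ChannelMismatchError(
                f"subject {self.subject_id}: channel {channel_id!r} not present "
                f"(has {self.channel_ids})"
            ) from None

    def events_for(self, condition: str) -> list[Event]:
        return [ev for ev in self.events if ev.condition == condition]


@dataclass
class Dataset:
    """A two-condition experiment: recordings + shared channel inclusion.

    analysis_window carries the config's default decoding window; operations
    accept an explicit window that overrides it.
    """

    recordings: list[Recording]
    conditions: list[str]
    included_channels: list[str]
    analysis_window: TimeWindow | None = None

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise DatasetValidationError(
                f"this decoder supports exactly 2 conditions, got "
                f"{self.conditions!r}; multi-condition designs are out of scope"
            )
        if len(set(self.conditions)) != 2:
            raise DatasetValidationError("condition labels must be distinct")
        if len(self.recordings) < 2:
            raise DatasetValidationError(
                "leave-one-out decoding requires at least 2 subjects"
            )
        if len(set(self.subject_ids)) != len(self.recordings):
            raise DatasetValidationError("duplicate subject ids")
        for rec in self.recordings:
            for ch in self.included_channels:
                rec.channel_index(ch)  # raises ChannelMismatchError
            for ev in rec.events:
                if ev.condition not in self.conditions:
                    raise UnknownConditionError(
                        f"subject {rec.subject_id}: unknown condition "
                        f"{ev.condition!r} (declared: {self.conditions})"
                    )
            for cond in self.conditions:
                if not rec.events_for(cond):
                    raise MissingConditionTrialsError(
                        f"subject {rec.subject_id} has no trials for condition "
                        f"{cond!r}"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return [rec.subject_id for rec in self.recordings]

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    @property
    def n_channels(self) -> int:
        return len(self.included_channels)

    def recording(self, subject_id: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id:
                return rec
        raise DatasetValidationError(f"unknown subject {subject_id!r}")


def drop_invalid_subjects(
    recordings: list[Recording], conditions: list[str]
) -> list[Recording]:
    """Return the recordings that have >= 1 event in every condition.

    Subjects failing the invariant are logged and excluded; mirrors the
    practice of deciding inclusion once, before any decoding is run.
    """
    kept: list[Recording] = []
    for rec in recordings:
        missing = [c for c in conditions if not rec.events_for(c)]
        if missing:
            logger.warning(
                "dropping subject %s: no trials for condition(s) %s",
                rec.subject_id,
                ", ".join(missing),
            )
        else:
            kept.append(rec)
    return kept
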
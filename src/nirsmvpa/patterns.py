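"""Event-locked multichannel pattern extraction.

The atom of decoding is a trial's *multichannel pattern*: for every included
channel, HbO is averaged over an a-priori window after stimulus onset after
re-baselining each channel to the first sample inside that window,

    x_chan = (1/t) * sum_i (HbO_chan,i - HbO_chan,1),   i = 1..t,

and the per-channel values are stacked, in the dataset's channel order, into
a vector of dimension n (the number of channels).  Trial patterns are then
averaged within subject and condition to give the subject-level pattern for
that condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import Dataset, Event, Recording, TimeWindow
from .errors import NonFiniteDataError, TrialOutOfBoundsError

logger = logging.getLogger("nirsmvpa")


@dataclass(frozen=True)
class TrialPattern:
    """Windowed, baseline-corrected HbO vector for one trial."""

    subject_id: str
    condition: str
    trial_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )

    @property
    def n_channels(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SubjectConditionPattern:
    """Per-subject mean pattern for one condition; r trials averaged."""

    subject_id: str
    condition: str
    values: np.ndarray
    r: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        if self.r < 1:
            raise ValueError("r (number of averaged trials) must be >= 1")


def window_sample_slice(
    onset_s: float, window: TimeWindow, sample_rate_hz: float
) -> slice:
    """Sample indices covered by the window shifted to a stimulus onset.

    Half-open rule: indices i with onset + start <= i/fs < onset + end.
    Fractional boundaries resolve by this rule; no interpolation.
    """
    i0 = int(np.ceil((onset_s + window.start_s) * sample_rate_hz - 1e-9))
    i1 = int(np.ceil((onset_s + window.end_s) * sample_rate_hz - 1e-9))
    return slice(i0, i1)


def extract_trial_pattern(
    recording: Recording,
    event: Event,
    window: TimeWindow,
    included_channels: Sequence[str],
    trial_index: int = 0,
) -> TrialPattern:
    """Windowed baseline-corrected average per channel for one trial.

    The baseline is the first sample *inside* the shifted window (not the
    stimulus-onset sample; for a window starting at 6 s those differ).

    Raises
    ------
    TrialOutOfBoundsError
        If the shifted window does not lie fully inside the recording, or
        covers fewer than two samples.
    NonFiniteDataError
        If any sample inside the window is NaN/inf.
    """
    sl = window_sample_slice(event.onset_s, window, recording.sample_rate_hz)
    t = sl.stop - sl.start
    if sl.start < 0 or sl.stop > recording.n_samples or t < 2:
        raise TrialOutOfBoundsError(
            f"subject {recording.subject_id}, trial {trial_index} "
            f"(onset {event.onset_s} s): window samples [{sl.start}, {sl.stop}) "
            f"not inside recording of {recording.n_samples} samples"
        )
    rows = [recording.channel_index(ch) for ch in included_channels]
    seg = recording.hbo[rows, sl]
    if not np.all(np.isfinite(seg)):
        ch_bad, s_bad = np.argwhere(~np.isfinite(seg))[0]
        raise NonFiniteDataError(
            f"subject {recording.subject_id}, trial {trial_index}: non-finite "
            f"sample in channel {included_channels[ch_bad]!r} at window "
            f"sample {s_bad}"
        )
    values = (seg - seg[:, :1]).mean(axis=1)
    return TrialPattern(
        subject_id=recording.subject_id,
        condition=event.condition,
        trial_index=trial_index,
        values=values,
    )


def average_condition_patterns(
    trials: Sequence[TrialPattern],
) -> SubjectConditionPattern:
    """Element-wise mean of one subject's trial patterns for one condition."""
    if not trials:
        raise ValueError("cannot average an empty list of trial patterns")
    subjects = {t.subject_id for t in trials}
    conditions = {t.condition for t in trials}
    if len(subjects) != 1 or len(conditions) != 1:
        raise ValueError(
            f"mixed subjects {subjects} or conditions {conditions}: condition "
            "averaging is per subject, per condition"
        )
    lengths = {t.n_channels for t in trials}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent pattern lengths {lengths}")
    stacked = np.vstack([t.values for t in trials])
    return SubjectConditionPattern(
        subject_id=trials[0].subject_id,
        condition=trials[0].condition,
        values=stacked.mean(axis=0),
        r=len(trials),
    )


def extract_all_trial_patterns(
    dataset: Dataset, window: TimeWindow
) -> tuple[dict[str, list[TrialPattern]], dict[str, int]]:
    """All in-bounds trial patterns per subject, plus exclusion counts.

    Trials whose shifted window extends past the recording are excluded with
    a logged warning (silent inclusion of truncated windows would bias the
    baseline-corrected average); the per-subject exclusion count is returned
    so results can report it.
    """
    per_subject: dict[str, list[TrialPattern]] = {}
    excluded: dict[str, int] = {}
    for rec in dataset.recordings:
        pats: list[TrialPattern] = []
        n_excl = 0
        for idx, ev in enumerate(rec.events):
            try:
                pats.append(
                    extract_trial_pattern(
                        rec, ev, window, dataset.included_channels, trial_index=idx
                    )
                )
            except TrialOutOfBoundsError as exc:
                n_excl += 1
                logger.warning("excluding out-of-bounds trial: %s", exc)
        per_subject[rec.subject_id] = pats
        excluded[rec.subject_id] = n_excl
    return per_subject, excluded


def subject_condition_patterns(
    dataset: Dataset, window: TimeWindow
) -> tuple[list[SubjectConditionPattern], dict[str, int]]:
    """Per-subject, per-condition mean patterns for a whole dataset."""
    from .errors import MissingConditionTrialsError

    per_subject, excluded = extract_all_trial_patterns(dataset, window)
    out: list[SubjectConditionPattern] = []
    for sid in dataset.subject_ids:
        for cond in dataset.conditions:
            trials = [p for p in per_subject[sid] if p.condition == cond]
            if not trials:
                raise MissingConditionTrialsError(
                    f"subject {sid}: every trial of condition {cond!r} fell "
                    "outside the recording; cannot form a condition average"
                )
            out.append(average_condition_patterns(trials))
    return out, excluded
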
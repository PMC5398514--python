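"""Exhaustive channel-subset decoding and per-channel informativeness.

With ~10 channels the full combinatorial analysis is cheap: for every subset
of k channels (2 <= k <= n) the pattern vectors are restricted to those
channels and the complete leave-one-subject-out infant-level decoding is
re-run.  A channel's informativeness at size k is its mean accuracy over the
C(n-1, k-1) subsets it participates in.

Size-2 subsets are geometrically degenerate: the Pearson correlation of two
2-vectors is always +/-1 (or undefined when a vector is constant).  They are
still computed, for comparability with full subset maps, but carry a logged
warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset, TimeWindow
from .decoding import loo_infant_correct
from .patterns import subject_condition_patterns

logger = logging.getLogger("nirsmvpa")


@dataclass
class SubsetReport:
    """Per-subset infant-level accuracies plus per-subject outcomes."""

    table: pd.DataFrame  # size, channels, accuracy, n_subjects, n_excluded
    outcomes: pd.DataFrame  # size, channels, subject_id, correct
    metadata: dict = field(default_factory=dict)

    @property
    def sizes(self) -> list[int]:
        return sorted(self.table["size"].unique().tolist())


def enumerate_subsets(
    channel_ids: Sequence[str], k: int
) -> list[tuple[str, ...]]:
    """All C(n, k) channel subsets, each in channel order, lexicographic.

    Order follows the position of channels in channel_ids (the dataset's
    canonical order), so enumeration is deterministic.
    """
    n = len(channel_ids)
    if not 2 <= k <= n:
        raise ValueError(f"subset size {k} out of range [2, {n}]")
    return list(itertools.combinations(channel_ids, k))


def subset_decoding(
    dataset: Dataset,
    sizes: Sequence[int],
    window: TimeWindow | None = None,
) -> SubsetReport:
    """Infant-level LOO decoding for every channel subset of the given sizes.

    A subject whose restricted pattern is constant for some subset (Pearson r
    undefined) is excluded from that subset's accuracy; the exclusion count is
    recorded per subset rather than failing the whole map.
    """
    if window is None:
        window = dataset.analysis_window
    n = dataset.n_channels
    sizes = sorted(set(int(k) for k in sizes))
    for k in sizes:
        if not 2 <= k <= n:
            raise ValueError(f"subset size {k} out of range [2, {n}]")
    if 2 in sizes:
        logger.warning(
            "size-2 subsets are degenerate: Pearson r over 2 channels is "
            "always +/-1; interpret size-2 accuracies with caution"
        )

    subj_patterns, _ = subject_condition_patterns(dataset, window)
    cond_a, cond_b = dataset.conditions
    sids = dataset.subject_ids
    pa = np.vstack(
        [
            next(p.values for p in subj_patterns
                 if p.subject_id == s and p.condition == cond_a)
            for s in sids
        ]
    )
    pb = np.vstack(
        [
            next(p.values for p in subj_patterns
                 if p.subject_id == s and p.condition == cond_b)
            for s in sids
        ]
    )
    col = {ch: j for j, ch in enumerate(dataset.included_channels)}

    rows = []
    outcome_rows = []
    for k in sizes:
        for subset in enumerate_subsets(dataset.included_channels, k):
            idx = [col[ch] for ch in subset]
            correct = loo_infant_correct(pa[:, idx], pb[:, idx])
            valid = ~np.isnan(correct)
            accuracy = float(correct[valid].mean()) if valid.any() else np.nan
            label = "+".join(subset)
            rows.append(
                {
                    "size": k,
                    "channels": label,
                    "accuracy": accuracy,
                    "n_subjects": int(valid.sum()),
                    "n_excluded": int((~valid).sum()),
                }
            )
            for s, c, v in zip(sids, correct, valid):
                outcome_rows.append(
                    {
                        "size": k,
                        "channels": label,
                        "subject_id": s,
                        "correct": int(c) if v else np.nan,
                    }
                )
    return SubsetReport(
        table=pd.DataFrame(rows),
        outcomes=pd.DataFrame(outcome_rows),
        metadata={
            "window": {"start_s": window.start_s, "end_s": window.end_s},
            "channels": list(dataset.included_channels),
            "conditions": list(dataset.conditions),
            "n_subjects": dataset.n_subjects,
            "sizes": sizes,
        },
    )


def channel_informativeness(report: SubsetReport, k: int) -> pd.DataFrame:
    """Per-channel mean accuracy over all size-k subsets containing it.

    Returns columns channel, mean_accuracy, n_subsets; for n channels each
    channel appears in exactly C(n-1, k-1) subsets of size k.
    """
    if k not in report.sizes:
        raise ValueError(f"size {k} not present in report (has {report.sizes})")
    sub = report.table[report.table["size"] == k]
    channels = report.metadata["channels"]
    rows = []
    for ch in channels:
        mask = sub["channels"].str.split("+").apply(lambda s: ch in s)
        accs = sub.loc[mask, "accuracy"]
        rows.append(
            {
                "channel": ch,
                "mean_accuracy": float(accs.mean()),
                "n_subsets": int(mask.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "size", k)
    return out


def informativeness_table(report: SubsetReport) -> pd.DataFrame:
    """channel_informativeness stacked over every size in the report."""
    return pd.concat(
        [channel_informativeness(report, k) for k in report.sizes],
        ignore_index=True,
    )
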
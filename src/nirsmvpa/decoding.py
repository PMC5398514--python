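"""Leave-one-subject-out correlation decoding.

The group model for a test subject is the per-condition mean of the other
N-1 subjects' condition patterns.  Infant-level decoding assigns the test
subject's two unlabeled condition averages the label permutation whose
summed Fisher r-to-z transformed Pearson correlations with the group model
is larger:

    S_correct = z(corr(G_A, U_A)) + z(corr(G_B, U_B))
    S_swapped = z(corr(G_B, U_A)) + z(corr(G_A, U_B))

Trial-level decoding labels a single trial pattern by its larger Fisher-z
correlation with the two group-model patterns.  Ties score 0 (incorrect)
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset, TimeWindow
from .errors import (
    DatasetValidationError,
    DegeneratePatternError,
    InsufficientSubjectsError,
)
from .patterns import SubjectConditionPattern, subject_condition_patterns, \
    extract_all_trial_patterns, average_condition_patterns

logger = logging.getLogger("nirsmvpa")

#: clamp applied before arctanh so r = +/-1 maps to a large finite z
FISHER_EPS = 1e-7


def fisher_z(r):
    """Fisher r-to-z (hyperbolic arctangent) transform, clamped.

    arctanh(+/-1) is infinite; correlations are clamped to 1 - 1e-7 in
    magnitude, which preserves ordering while keeping sums finite.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite correlation passed to fisher_z")
    out = np.arctanh(np.clip(r, -1 + FISHER_EPS, 1 - FISHER_EPS))
    return out if out.ndim else float(out)


def pearson_r(u, v) -> float:
    """Pearson correlation across channels of two pattern vectors.

    Raises DegeneratePatternError when either vector is constant (zero
    variance across channels), where the correlation is undefined.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"pattern length mismatch: {u.size} vs {v.size}")
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.sqrt((uc @ uc) * (vc @ vc))
    if denom == 0:
        raise DegeneratePatternError(
            "constant pattern vector: Pearson correlation undefined"
        )
    return float(np.clip((uc @ vc) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# vectorised internals (shared with the subset and permutation analyses)

def _row_standardize(a: np.ndarray) -> np.ndarray:
    """Center and L2-normalise rows; zero-variance rows become NaN rows."""
    a = a - a.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(a, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a / norm
    out[norm.ravel() == 0] = np.nan
    return out


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between two (m, n) arrays; NaN where degenerate."""
    return np.clip(
        np.einsum("ij,ij->i", _row_standardize(a), _row_standardize(b)),
        -1.0,
        1.0,
    )


def loo_infant_correct(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Vectorised leave-one-out infant-level decisions.

    pa, pb: (N, n) arrays of per-subject condition patterns for the two
    conditions.  Returns a float (N,) array of 0/1 decisions (ties -> 0);
    entries are NaN where any involved vector is degenerate.
    """
    n_subj = pa.shape[0]
    ga = (pa.sum(axis=0) - pa) / (n_subj - 1)
    gb = (pb.sum(axis=0) - pb) / (n_subj - 1)
    s_correct = fisher_z(np.nan_to_num(_row_corr(ga, pa))) + fisher_z(
        np.nan_to_num(_row_corr(gb, pb))
    )
    s_swapped = fisher_z(np.nan_to_num(_row_corr(gb, pa))) + fisher_z(
        np.nan_to_num(_row_corr(ga, pb))
    )
    bad = (
        np.isnan(_row_corr(ga, pa))
        | np.isnan(_row_corr(gb, pb))
        | np.isnan(_row_corr(gb, pa))
        | np.isnan(_row_corr(ga, pb))
    )
    out = (s_correct > s_swapped).astype(float)
    out[bad] = np.nan
    return out


# ---------------------------------------------------------------------------
# public types

@dataclass(frozen=True)
class GroupModel:
    """Per-condition mean pattern over the N-1 non-test subjects."""

    excluded_subject_id: str
    condition_means: dict[str, np.ndarray]
    n_contributing: int

    def vector(self, condition: str) -> np.ndarray:
        return self.condition_means[condition]


@dataclass(frozen=True)
class DecodingOutcome:
    """Binary decoding decision for one unit (a subject or a trial)."""

    unit_id: str
    subject_id: str
    correct: int
    correlations: dict[str, float]
    condition: str | None = None


@dataclass
class DecodingResult:
    level: str  # "infant" | "trial"
    outcomes: list[DecodingOutcome]
    overall_accuracy: float
    per_condition_accuracy: dict[str, float] = field(default_factory=dict)
    per_subject_accuracy: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations

def build_group_model(
    subject_patterns: Sequence[SubjectConditionPattern], test_subject: str
) -> GroupModel:
    """Unweighted mean of the non-test subjects' condition patterns."""
    subjects = sorted({p.subject_id for p in subject_patterns})
    if test_subject not in subjects:
        raise DatasetValidationError(f"unknown test subject {test_subject!r}")
    others = [s for s in subjects if s != test_subject]
    if not others:
        raise InsufficientSubjectsError(
            "group model needs at least one non-test subject"
        )
    conditions = sorted({p.condition for p in subject_patterns})
    means: dict[str, np.ndarray] = {}
    for cond in conditions:
        vecs = [
            p.values
            for p in subject_patterns
            if p.condition == cond and p.subject_id != test_subject
        ]
        if len(vecs) != len(others):
            raise DatasetValidationError(
                f"condition {cond!r}: expected one pattern per non-test "
                f"subject ({len(others)}), found {len(vecs)}"
            )
        means[cond] = np.vstack(vecs).mean(axis=0)
    return GroupModel(
        excluded_subject_id=test_subject,
        condition_means=means,
        n_contributing=len(others),
    )


def decode_infant(
    model: GroupModel, test_patterns: dict[str, np.ndarray]
) -> DecodingOutcome:
    """Label a test subject's two condition averages by max summed Fisher-z.

    test_patterns maps the *true* condition of each unlabeled average to its
    vector; correctness is whether the identity labeling beats the swap.
    """
    cond_a, cond_b = sorted(model.condition_means)
    ga, gb = model.vector(cond_a), model.vector(cond_b)
    ua, ub = test_patterns[cond_a], test_patterns[cond_b]
    r_aa, r_bb = pearson_r(ga, ua), pearson_r(gb, ub)
    r_ba, r_ab = pearson_r(gb, ua), pearson_r(ga, ub)
    s_correct = fisher_z(r_aa) + fisher_z(r_bb)
    s_swapped = fisher_z(r_ba) + fisher_z(r_ab)
    if s_correct == s_swapped:
        logger.warning(
            "subject %s: tied label permutations (S=%.6f); scoring incorrect",
            model.excluded_subject_id,
            s_correct,
        )
    return DecodingOutcome(
        unit_id=model.excluded_subject_id,
        subject_id=model.excluded_subject_id,
        correct=int(s_correct > s_swapped),
        correlations={
            f"z_{cond_a}_{cond_a}": fisher_z(r_aa),
            f"z_{cond_b}_{cond_b}": fisher_z(r_bb),
            f"z_{cond_b}_{cond_a}": fisher_z(r_ba),
            f"z_{cond_a}_{cond_b}": fisher_z(r_ab),
        },
    )


def decode_trial(model: GroupModel, trial) -> DecodingOutcome:
    """Label one trial pattern by its larger Fisher-z group correlation.

    arctanh is monotone, so this equals the raw-r comparison; the Fisher-z
    values are what is recorded.
    """
    true_cond = trial.condition
    other = next(c for c in model.condition_means if c != true_cond)
    z_true = fisher_z(pearson_r(model.vector(true_cond), trial.values))
    z_other = fisher_z(pearson_r(model.vector(other), trial.values))
    if z_true == z_other:
        logger.warning(
            "subject %s trial %d: tied correlations (z=%.6f); scoring incorrect",
            trial.subject_id,
            trial.trial_index,
            z_true,
        )
    return DecodingOutcome(
        unit_id=f"{trial.subject_id}/trial{trial.trial_index}",
        subject_id=trial.subject_id,
        condition=true_cond,
        correct=int(z_true > z_other),
        correlations={f"z_{true_cond}": z_true, f"z_{other}": z_other},
    )


def aggregate_accuracy(
    outcomes: Sequence[DecodingOutcome],
    level: str,
    conditions: Sequence[str] | None = None,
) -> dict:
    """Accuracy summaries from binary outcomes.

    Infant level: overall = mean(correct) over subjects.  Trial level:
    within-subject per-condition means first, then unweighted means across
    subjects (so subjects with more trials do not get more weight); a
    subject's accuracy is the mean of its per-condition accuracies and the
    overall accuracy is the mean of the per-subject accuracies.
    Also reports the integer-rounded (round-half-away-from-zero is not
    needed: values are non-negative) percentage.
    """
    if not outcomes:
        raise ValueError("cannot aggregate an empty outcome list")
    if level == "infant":
        overall = float(np.mean([o.correct for o in outcomes]))
        return {
            "overall_accuracy": overall,
            "overall_percent": int(np.floor(overall * 100 + 0.5)),
            "per_condition_accuracy": {},
            "per_subject_accuracy": {o.subject_id: float(o.correct) for o in outcomes},
        }
    if level != "trial":
        raise ValueError(f"unknown level {level!r}")
    if conditions is None:
        conditions = sorted({o.condition for o in outcomes})
    subjects = sorted({o.subject_id for o in outcomes})
    per_subj_cond: dict[str, dict[str, float]] = {}
    for sid in subjects:
        per_subj_cond[sid] = {}
        for cond in conditions:
            vals = [
                o.correct
                for o in outcomes
                if o.subject_id == sid and o.condition == cond
            ]
            if vals:
                per_subj_cond[sid][cond] = float(np.mean(vals))
    per_condition = {
        cond: float(
            np.mean([d[cond] for d in per_subj_cond.values() if cond in d])
        )
        for cond in conditions
    }
    per_subject = {
        sid: float(np.mean(list(d.values()))) for sid, d in per_subj_cond.items()
    }
    overall = float(np.mean(list(per_subject.values())))
    return {
        "overall_accuracy": overall,
        "overall_percent": int(np.floor(overall * 100 + 0.5)),
        "per_condition_accuracy": per_condition,
        "per_subject_accuracy": per_subject,
    }


def run_loo(
    dataset: Dataset, level: str = "infant", window: TimeWindow | None = None
) -> DecodingResult:
    """Full leave-one-subject-out decoding of a dataset.

    Builds N group models, each excluding one subject, and decodes either
    that subject's two condition averages (infant level) or each of its
    in-bounds trials (trial level).
    """
    if level not in ("infant", "trial"):
        raise ValueError(f"level must be 'infant' or 'trial', got {level!r}")
    if window is None:
        window = dataset.analysis_window
    if window is None:
        raise ValueError("no analysis window: pass window= or set it on the dataset")

    subj_patterns, excluded = subject_condition_patterns(dataset, window)
    outcomes: list[DecodingOutcome] = []
    if level == "infant":
        for sid in dataset.subject_ids:
            model = build_group_model(subj_patterns, sid)
            test = {
                p.condition: p.values
                for p in subj_patterns
                if p.subject_id == sid
            }
            outcomes.append(decode_infant(model, test))
    else:
        per_subject_trials, _ = extract_all_trial_patterns(dataset, window)
        for sid in dataset.subject_ids:
            model = build_group_model(subj_patterns, sid)
            for trial in per_subject_trials[sid]:
                outcomes.append(decode_trial(model, trial))
    agg = aggregate_accuracy(outcomes, level, conditions=dataset.conditions)
    return DecodingResult(
        level=level,
        outcomes=outcomes,
        overall_accuracy=agg["overall_accuracy"],
        per_condition_accuracy=agg["per_condition_accuracy"],
        per_subject_accuracy=agg["per_subject_accuracy"],
        metadata={
            "window": {"start_s": window.start_s, "end_s": window.end_s},
            "channels": list(dataset.included_channels),
            "conditions": list(dataset.conditions),
            "n_subjects": dataset.n_subjects,
            "excluded_trials": excluded,
            "overall_percent": agg["overall_percent"],
            "tie_policy": "ties score 0",
            "trial_aggregation": "within-subject per-condition means, then "
            "unweighted means across subjects",
        },
    )


def univariate_contrast(
    dataset: Dataset, window: TimeWindow | None = None
) -> pd.DataFrame:
    """Per-channel paired t-test between the two condition means.

    For each channel, the per-subject difference of windowed condition-mean
    values is tested against zero (two-sided, df = N-1); the Bonferroni flag
    uses alpha = 0.05 / n_channels.  This is the standard single-channel
    contrast the multivariate decoder is compared against.
    """
    if window is None:
        window = dataset.analysis_window
    if dataset.n_subjects < 3:
        raise InsufficientSubjectsError(
            "paired t-test needs at least 3 subjects"
        )
    subj_patterns, _ = subject_condition_patterns(dataset, window)
    cond_a, cond_b = dataset.conditions
    mat = {
        cond: np.vstack(
            [
                next(
                    p.values
                    for p in subj_patterns
                    if p.subject_id == sid and p.condition == cond
                )
                for sid in dataset.subject_ids
            ]
        )
        for cond in (cond_a, cond_b)
    }
    n_ch = dataset.n_channels
    alpha = 0.05 / n_ch
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_rel(mat[cond_a], mat[cond_b], axis=0)
    diffs = mat[cond_a] - mat[cond_b]
    rows = []
    for j, ch in enumerate(dataset.included_channels):
        t_j = float(tt.statistic[j])
        p_j = float(tt.pvalue[j])
        if not np.isfinite(t_j):
            # zero-variance differences: t is 0 (no effect) or +/-inf
            d_mean = float(diffs[:, j].mean())
            if d_mean == 0:
                t_j, p_j = 0.0, 1.0
            else:
                t_j, p_j = float(np.sign(d_mean)) * np.inf, 0.0
        rows.append(
            {
                "channel": ch,
                "t": t_j,
                "df": dataset.n_subjects - 1,
                "p": p_j,
                "bonferroni_significant": bool(p_j < alpha),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha_bonferroni"] = alpha
    return df
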
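"""Permutation-based significance testing for decoding accuracy.

The leave-one-out procedure introduces dependencies between the N test
subjects, so a parametric binomial test on the accuracy is not valid.
Instead an empirical null is built by shuffling condition labels across
trials *within each subject* (preserving each subject's per-condition trial
counts), recomputing the condition averages, and re-running the complete
leave-one-out decoding; the p-value uses the add-one estimator

    p = (1 + #{null >= observed}) / (1 + M),

which cannot be zero.  Each permutation draws from its own seed substream,
so extending M leaves earlier draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, TimeWindow
from .decoding import _row_corr, fisher_z, loo_infant_correct
from .patterns import extract_all_trial_patterns

__all__ = ["PermutationResult", "permutation_null"]


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    n_permutations: int
    p_value: float
    seed: int
    level: str
    per_condition: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _condition_means(trials, labels, conditions):
    """(N, n) per-subject mean pattern arrays for each of the 2 conditions."""
    mats = []
    for cond in conditions:
        rows = []
        for t_mat, lab in zip(trials, labels):
            mask = lab == cond
            rows.append(t_mat[mask].mean(axis=0))
        mats.append(np.vstack(rows))
    return mats


def _infant_accuracy(pa, pb) -> float:
    correct = loo_infant_correct(pa, pb)
    return float(np.nanmean(correct))


def _trial_accuracies(trials, labels, pa, pb, conditions):
    """Grand and per-condition trial-level accuracies for one labeling.

    Within-subject per-condition means first; a subject's accuracy is the
    mean of its per-condition accuracies; grand = mean over subjects.
    """
    n_subj = pa.shape[0]
    ga_all = (pa.sum(axis=0) - pa) / (n_subj - 1)
    gb_all = (pb.sum(axis=0) - pb) / (n_subj - 1)
    cond_a, cond_b = conditions
    per_subject = []
    per_cond_lists: dict[str, list[float]] = {cond_a: [], cond_b: []}
    for s in range(n_subj):
        t_mat, lab = trials[s], labels[s]
        ga = np.broadcast_to(ga_all[s], t_mat.shape)
        gb = np.broadcast_to(gb_all[s], t_mat.shape)
        za = fisher_z(np.nan_to_num(_row_corr(np.ascontiguousarray(ga), t_mat)))
        zb = fisher_z(np.nan_to_num(_row_corr(np.ascontiguousarray(gb), t_mat)))
        correct = np.where(lab == cond_a, za > zb, zb > za).astype(float)
        cond_accs = []
        for cond in conditions:
            mask = lab == cond
            if mask.any():
                acc = float(correct[mask].mean())
                per_cond_lists[cond].append(acc)
                cond_accs.append(acc)
        per_subject.append(float(np.mean(cond_accs)))
    per_cond = {c: float(np.mean(v)) for c, v in per_cond_lists.items()}
    return float(np.mean(per_subject)), per_cond


def permutation_null(
    dataset: Dataset,
    level: str = "infant",
    window: TimeWindow | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Empirical null distribution and p-value for LOO decoding accuracy.

    Parameters
    ----------
    level : "infant" or "trial"; at trial level the observed statistic is the
        grand-mean trial accuracy, and per-condition p-values are computed
        against per-condition nulls.
    n_permutations : number of within-subject label shuffles (M >= 1).
    seed : master seed; permutation i draws from SeedSequence(seed, (i,)).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if level not in ("infant", "trial"):
        raise ValueError(f"level must be 'infant' or 'trial', got {level!r}")
    if window is None:
        window = dataset.analysis_window
    conditions = list(dataset.conditions)

    per_subject, _ = extract_all_trial_patterns(dataset, window)
    trials = []
    labels = []
    for sid in dataset.subject_ids:
        pats = per_subject[sid]
        for cond in conditions:
            if not any(p.condition == cond for p in pats):
                from .errors import MissingConditionTrialsError

                raise MissingConditionTrialsError(
                    f"subject {sid}: no in-bounds trials for condition {cond!r}"
                )
        trials.append(np.vstack([p.values for p in pats]))
        labels.append(np.array([p.condition for p in pats]))

    def statistic(labeling):
        pa, pb = _condition_means(trials, labeling, conditions)
        if level == "infant":
            return _infant_accuracy(pa, pb), None
        return _trial_accuracies(trials, labeling, pa, pb, conditions)

    if level == "infant":
        observed, _ = statistic(labels)
        obs_per_cond = None
    else:
        observed, obs_per_cond = statistic(labels)

    null = np.empty(n_permutations)
    null_per_cond = {c: np.empty(n_permutations) for c in conditions}
    for i in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        perm = [rng.permutation(lab) for lab in labels]
        for lab, p_lab in zip(labels, perm):
            # within-subject shuffle preserves per-condition trial counts
            assert sorted(lab) == sorted(p_lab)
        stat, per_cond = statistic(perm)
        null[i] = stat
        if per_cond is not None:
            for c in conditions:
                null_per_cond[c][i] = per_cond[c]

    m = n_permutations
    p_value = float((1 + np.sum(null >= observed)) / (1 + m))
    per_condition = {}
    if level == "trial":
        per_condition = {
            c: {
                "observed_accuracy": obs_per_cond[c],
                "p_value": float(
                    (1 + np.sum(null_per_cond[c] >= obs_per_cond[c])) / (1 + m)
                ),
                "null_mean": float(null_per_cond[c].mean()),
            }
            for c in conditions
        }
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        n_permutations=m,
        p_value=p_value,
        seed=seed,
        level=level,
        per_condition=per_condition,
        metadata={
            "scheme": "within-subject condition-label shuffle preserving "
            "per-condition trial counts",
            "p_formula": "(1 + #{null >= observed}) / (1 + M)",
            "window": {"start_s": window.start_s, "end_s": window.end_s},
            "conditions": conditions,
        },
    )
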
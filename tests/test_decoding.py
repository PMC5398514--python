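"""Group models, Fisher-z correlation decisions, aggregation, univariate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nirsmvpa import (
    DecodingOutcome,
    SubjectConditionPattern,
    TimeWindow,
    aggregate_accuracy,
    build_group_model,
    decode_infant,
    decode_trial,
    fisher_z,
    pearson_r,
    run_loo,
    univariate_contrast,
)
from nirsmvpa.errors import (
    DegeneratePatternError,
    InsufficientSubjectsError,
)
from nirsmvpa.patterns import TrialPattern


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_is_half_log_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0))

    def test_unit_correlation_clamped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))
        assert fisher_z(-1.0) == pytest.approx(-z)

    def test_strictly_increasing(self):
        r = np.linspace(-1, 1, 201)
        assert np.all(np.diff(fisher_z(r)) > 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(np.nan)


class TestPearson:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.normal(size=(2, 8))
            assert pearson_r(u, v) == pytest.approx(
                stats.pearsonr(u, v).statistic
            )

    def test_constant_vector_raises(self):
        with pytest.raises(DegeneratePatternError):
            pearson_r([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def _scp(sid, cond, values):
    return SubjectConditionPattern(sid, cond, np.asarray(values, float), r=1)


class TestGroupModel:
    def test_mean_of_non_test_subjects(self):
        pats = [
            _scp("s1", "A", [1, 0, 0]),
            _scp("s2", "A", [1, 0, 0]),
            _scp("s3", "A", [0, 1, 0]),
            _scp("s1", "B", [0, 0, 1]),
            _scp("s2", "B", [0, 0, 1]),
            _scp("s3", "B", [0, 0, 1]),
        ]
        model = build_group_model(pats, "s3")
        assert np.allclose(model.vector("A"), [1, 0, 0])
        assert model.n_contributing == 2

    def test_two_subjects_model_is_the_other(self):
        pats = [
            _scp("s1", "A", [1, 2, 3]),
            _scp("s2", "A", [4, 5, 7]),
            _scp("s1", "B", [3, 2, 1]),
            _scp("s2", "B", [9, 5, 4]),
        ]
        model = build_group_model(pats, "s2")
        assert np.allclose(model.vector("A"), [1, 2, 3])
        assert np.allclose(model.vector("B"), [3, 2, 1])

    def test_single_subject_rejected(self):
        pats = [_scp("s1", "A", [1, 0]), _scp("s1", "B", [0, 1])]
        with pytest.raises(InsufficientSubjectsError):
            build_group_model(pats, "s1")

    def test_unknown_test_subject_rejected(self):
        pats = [_scp("s1", "A", [1, 0]), _scp("s1", "B", [0, 1])]
        with pytest.raises(Exception, match="sX"):
            build_group_model(pats, "sX")

    def test_held_out_subject_never_contributes(self):
        """Perturbing the held-out subject's data leaves its model unchanged."""
        rng = np.random.default_rng(1)
        base = [
            _scp(f"s{i}", c, rng.normal(size=5))
            for i in range(1, 5)
            for c in ("A", "B")
        ]
        model1 = build_group_model(base, "s1")
        perturbed = [
            _scp(p.subject_id, p.condition, p.values + 99.0)
            if p.subject_id == "s1"
            else p
            for p in base
        ]
        model2 = build_group_model(perturbed, "s1")
        for c in ("A", "B"):
            assert np.array_equal(model1.vector(c), model2.vector(c))


def _model(ga, gb, sid="test"):
    from nirsmvpa.decoding import GroupModel

    return GroupModel(
        excluded_subject_id=sid,
        condition_means={"A": np.asarray(ga, float), "B": np.asarray(gb, float)},
        n_contributing=2,
    )


class TestDecodeInfant:
    def test_self_match_is_correct(self):
        m = _model([1, 0, 0.2], [0, 0.1, 1])
        out = decode_infant(m, {"A": m.vector("A"), "B": m.vector("B")})
        assert out.correct == 1

    def test_swapped_patterns_incorrect(self):
        m = _model([1, 0, 0.2], [0, 0.1, 1])
        out = decode_infant(m, {"A": m.vector("B"), "B": m.vector("A")})
        assert out.correct == 0

    def test_known_instance(self):
        m = _model([1, 0, 0], [0, 0, 1])
        out = decode_infant(
            m, {"A": np.array([0.9, 0.05, 0.05]), "B": np.array([0.1, 0.1, 0.8])}
        )
        assert out.correct == 1

    def test_matches_bruteforce_enumeration(self):
        """Max-sum decision equals exhaustive enumeration of both labelings
        with scipy's correlation as the independent reference."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(3, 11)
            ga, gb, ua, ub = rng.normal(size=(4, n))
            m = _model(ga, gb)
            out = decode_infant(m, {"A": ua, "B": ub})
            z = lambda u, v: np.arctanh(
                np.clip(stats.pearsonr(u, v).statistic, -1 + 1e-7, 1 - 1e-7)
            )
            s_id = z(ga, ua) + z(gb, ub)
            s_sw = z(gb, ua) + z(ga, ub)
            assert out.correct == int(s_id > s_sw)

    def test_degenerate_vector_raises(self):
        m = _model([1, 0, 0], [0, 0, 1])
        with pytest.raises(DegeneratePatternError):
            decode_infant(m, {"A": np.ones(3), "B": np.array([0.0, 1, 0])})


class TestDecodeTrial:
    def test_exact_match_correct(self):
        m = _model([1, 0, 0.3], [0, 0.3, 1])
        trial = TrialPattern("s1", "A", 0, m.vector("A"))
        assert decode_trial(m, trial).correct == 1

    def test_tie_scores_zero(self):
        # trial [0,1,0] correlates -0.5 with both [1,0,0] and [0,0,1]
        m = _model([1, 0, 0], [0, 0, 1])
        trial = TrialPattern("s1", "A", 0, np.array([0.0, 1.0, 0.0]))
        assert decode_trial(m, trial).correct == 0

    def test_known_instance(self):
        m = _model([1, 0, 0], [0, 0, 1])
        trial = TrialPattern("s1", "A", 0, np.array([0.7, 0.2, 0.1]))
        assert decode_trial(m, trial).correct == 1

    def test_matches_raw_correlation_comparison(self):
        """The Fisher-z decision equals the raw-r decision (arctanh monotone),
        checked against scipy's correlation on random instances."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = rng.integers(3, 11)
            ga, gb, t = rng.normal(size=(3, n))
            m = _model(ga, gb)
            trial = TrialPattern("s1", "A", 0, t)
            r_true = stats.pearsonr(ga, t).statistic
            r_other = stats.pearsonr(gb, t).statistic
            assert decode_trial(m, trial).correct == int(r_true > r_other)


class TestAggregation:
    @pytest.mark.parametrize(
        "n_correct, n_total, percent",
        [(17, 19, 89), (13, 18, 72), (19, 19, 100)],
    )
    def test_infant_percent_rounding(self, n_correct, n_total, percent):
        outcomes = [
            DecodingOutcome(f"s{i}", f"s{i}", int(i < n_correct), {})
            for i in range(n_total)
        ]
        agg = aggregate_accuracy(outcomes, "infant")
        assert agg["overall_percent"] == percent
        assert agg["overall_accuracy"] == pytest.approx(n_correct / n_total)

    def test_trial_level_subjects_weighted_equally(self):
        # s1: 4/4 on A, s2: 0/1 on A -> condition A accuracy 0.5, not 4/5
        outcomes = [
            DecodingOutcome(f"s1/t{i}", "s1", 1, {}, condition="A")
            for i in range(4)
        ]
        outcomes += [DecodingOutcome("s2/t0", "s2", 0, {}, condition="A")]
        outcomes += [
            DecodingOutcome("s1/t9", "s1", 1, {}, condition="B"),
            DecodingOutcome("s2/t9", "s2", 1, {}, condition="B"),
        ]
        agg = aggregate_accuracy(outcomes, "trial", conditions=["A", "B"])
        assert agg["per_condition_accuracy"]["A"] == pytest.approx(0.5)
        assert agg["per_condition_accuracy"]["B"] == pytest.approx(1.0)
        assert agg["overall_accuracy"] == pytest.approx((1.0 + 0.5) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_accuracy([], "infant")


class TestRunLoo:
    def test_identical_subjects_decode_perfectly(self, tiny_dataset):
        res = run_loo(tiny_dataset, "infant")
        assert res.overall_accuracy == 1.0
        assert len(res.outcomes) == 3

    def test_one_model_per_subject(self, tiny_dataset):
        res = run_loo(tiny_dataset, "infant")
        assert sorted(o.unit_id for o in res.outcomes) == ["s1", "s2", "s3"]

    def test_trial_level_counts(self, tiny_dataset):
        res = run_loo(tiny_dataset, "trial")
        assert len(res.outcomes) == 12  # 3 subjects x 4 trials
        assert set(res.per_condition_accuracy) == {"A", "B"}

    def test_label_swap_symmetry(self, small_synthetic):
        """Relabeling A<->B everywhere leaves every decision unchanged."""
        import copy

        ds = small_synthetic
        swapped = copy.deepcopy(ds)
        for rec in swapped.recordings:
            rec.events = [
                type(ev)(ev.onset_s, "A" if ev.condition == "B" else "B")
                for ev in rec.events
            ]
        res = run_loo(ds, "infant")
        res_sw = run_loo(swapped, "infant")
        for o, osw in zip(res.outcomes, res_sw.outcomes):
            assert o.correct == osw.correct


@settings(deadline=None, max_examples=40)
@given(
    seed=st.integers(0, 10_000),
    a=st.floats(min_value=0.1, max_value=5),
    b=st.floats(min_value=-10, max_value=10),
)
def test_affine_invariance_of_decisions(seed, a, b):
    """Replacing a test vector by a*v + b*1 changes no correlation decision."""
    rng = np.random.default_rng(seed)
    ga, gb, ua, ub = rng.normal(size=(4, 6))
    m = _model(ga, gb)
    out = decode_infant(m, {"A": ua, "B": ub})
    out_aff = decode_infant(m, {"A": a * ua + b, "B": ub})
    assert out.correct == out_aff.correct


class TestUnivariateContrast:
    def test_zero_difference_gives_t_zero(self, tiny_dataset):
        # channel c2 carries identical values in both conditions
        table = univariate_contrast(tiny_dataset)
        row = table[table.channel == "c2"].iloc[0]
        assert row.t == 0.0
        assert not row.bonferroni_significant

    def test_bonferroni_threshold_is_alpha_over_n_channels(self, tiny_dataset):
        table = univariate_contrast(tiny_dataset)
        assert table.attrs["alpha_bonferroni"] == pytest.approx(0.05 / 3)

    def test_matches_closed_form_paired_t(self, small_synthetic):
        table = univariate_contrast(small_synthetic)
        from nirsmvpa.patterns import subject_condition_patterns

        pats, _ = subject_condition_patterns(
            small_synthetic, small_synthetic.analysis_window
        )
        cond_a, cond_b = small_synthetic.conditions
        for j, ch in enumerate(small_synthetic.included_channels):
            diffs = np.array(
                [
                    next(
                        p.values[j]
                        for p in pats
                        if p.subject_id == sid and p.condition == cond_a
                    )
                    - next(
                        p.values[j]
                        for p in pats
                        if p.subject_id == sid and p.condition == cond_b
                    )
                    for sid in small_synthetic.subject_ids
                ]
            )
            n = diffs.size
            t_ref = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
            row = table[table.channel == ch].iloc[0]
            assert row.t == pytest.approx(t_ref)
            assert row.df == n - 1

    def test_planted_constant_difference_flagged(self, tiny_dataset):
        # c1 carries a constant +~0.9 condition difference across subjects
        table = univariate_contrast(tiny_dataset)
        row = table[table.channel == "c1"].iloc[0]
        assert row.bonferroni_significant
        assert row.t > 0 and not np.isfinite(row.t) or row.t > 10

    def test_too_few_subjects_rejected(self, tiny_dataset):
        from nirsmvpa import Dataset

        ds2 = Dataset(
            recordings=tiny_dataset.recordings[:2],
            conditions=tiny_dataset.conditions,
            included_channels=tiny_dataset.included_channels,
            analysis_window=tiny_dataset.analysis_window,
        )
        with pytest.raises(InsufficientSubjectsError):
            univariate_contrast(ds2)
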
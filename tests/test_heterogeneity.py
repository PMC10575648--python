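"""Heterogeneity indices (EHI, CV, NU), group tests, tumor contrast,
cohort aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lungelast as le
from conftest import lobar_dist

percents = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    min_size=5, max_size=5,
)


class TestPercentInBand:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2.0] * 4, 100.0),
            ([10.0] * 4, 0.0),
            ([0.5, 1.0, 2.0, 3.0, 4.0], 60.0),  # inclusive bounds
        ],
    )
    def test_hand_values(self, values, expected):
        assert le.percent_in_band(lobar_dist(values)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            le.percent_in_band(lobar_dist([]))


class TestEHI:
    def test_equal_percentages_give_zero(self):
        assert le.ehi([20.0] * 5) == 0.0

    def test_hand_value(self):
        # E_max 30, mean of rest 10: |1 - 70/90| = 2/9
        assert le.ehi([30.0, 10.0, 10.0, 10.0, 10.0]) == pytest.approx(
            2.0 / 9.0, abs=1e-12
        )

    def test_fully_diseased_max_lobe(self):
        assert le.ehi([100.0, 50.0, 50.0, 50.0, 50.0]) == pytest.approx(1.0)

    def test_all_lobes_fully_diseased_is_homogeneous(self):
        assert le.ehi([100.0] * 5) == 0.0

    def test_needs_two_lobes_with_data(self):
        with pytest.raises(ValueError):
            le.ehi([40.0, math.nan, math.nan, math.nan, math.nan])

    def test_empty_lobes_dropped(self):
        assert le.ehi([30.0, 10.0, 10.0, math.nan, 10.0]) == pytest.approx(
            abs(1 - 70.0 / 90.0)
        )

    @settings(deadline=None, max_examples=200)
    @given(percents)
    def test_range_and_permutation_invariance(self, p):
        value = le.ehi(p)
        assert 0.0 <= value <= 1.0
        assert le.ehi(list(reversed(p))) == pytest.approx(value, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(percents)
    def test_zero_iff_max_equals_rest_mean(self, p):
        arr = np.asarray(p)
        e_max = arr.max()
        rest = np.delete(arr, arr.argmax()).mean()
        if abs(e_max - rest) < 1e-9 and rest < 99.0:
            assert le.ehi(p) == pytest.approx(0.0, abs=1e-6)
        elif e_max - rest > 1e-6 and rest < 99.0:
            assert le.ehi(p) > 0.0


class TestCoefficientOfVariation:
    def test_constant_distribution(self):
        assert le.coefficient_of_variation(lobar_dist([4.0, 4.0, 4.0])) == 0.0

    def test_hand_values(self):
        assert le.coefficient_of_variation(
            lobar_dist([1.0, 2.0, 3.0])
        ) == pytest.approx(50.0, abs=1e-12)
        assert le.coefficient_of_variation(
            lobar_dist([2.0, 4.0])
        ) == pytest.approx(100.0 * math.sqrt(2.0) / 3.0, abs=1e-12)

    def test_scale_invariance(self):
        base = lobar_dist([1.0, 2.0, 5.0, 0.5])
        for c in (0.1, 3.0, 42.0):
            scaled = lobar_dist(base.values * c)
            assert le.coefficient_of_variation(scaled) == pytest.approx(
                le.coefficient_of_variation(base), rel=1e-12
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            le.coefficient_of_variation(lobar_dist([1.0]))
        with pytest.raises(ValueError):
            le.coefficient_of_variation(lobar_dist([-2.0, 0.0]))


class TestNonUniformity:
    def test_constant_distribution(self):
        assert le.non_uniformity(lobar_dist([3.0] * 10)) == pytest.approx(0.0)

    def test_engineered_mean_one_p95_three(self):
        # 18 values at 7/9 plus two at 3: mean 1, p95 exactly 3
        values = [7.0 / 9.0] * 18 + [3.0, 3.0]
        assert le.non_uniformity(lobar_dist(values)) == pytest.approx(
            2.0, abs=1e-12
        )

    def test_uniform_1_to_100(self):
        d = lobar_dist(np.arange(1.0, 101.0))
        expected = (95.05 - 50.5) / 50.5
        assert le.non_uniformity(d) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        base = lobar_dist(np.arange(1.0, 41.0))
        scaled = lobar_dist(base.values * 7.3)
        assert le.non_uniformity(scaled) == pytest.approx(
            le.non_uniformity(base), rel=1e-12
        )


class TestCompareGroups:
    def test_identical_groups(self):
        c = le.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.statistic == 0.0
        assert c.pvalue == 1.0

    def test_pooled_t_hand_value(self):
        c = le.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert c.test_type == "t_equal_var"
        assert c.statistic == pytest.approx(-3.674, abs=1e-3)
        assert c.pvalue == pytest.approx(0.0214, abs=1e-3)

    def test_unequal_variances_select_welch(self):
        c = le.compare_groups([1, 2, 3, 4, 5], [1, 2, 3, 4, 50])
        assert c.f_pvalue < 0.05
        assert c.test_type == "t_welch"

    def test_mann_whitney_option(self):
        c = le.compare_groups([1, 2, 3], [4, 5, 6], method="mann_whitney")
        assert c.test_type == "mann_whitney"
        assert 0.0 <= c.pvalue <= 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            le.compare_groups([1.0], [2.0, 3.0])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
    )
    def test_symmetry_and_branch_invariant(self, a, b):
        ca = le.compare_groups(a, b)
        cb = le.compare_groups(b, a)
        assert ca.pvalue == pytest.approx(cb.pvalue, rel=1e-9, abs=1e-12)
        assert ca.statistic == pytest.approx(-cb.statistic, rel=1e-9, abs=1e-12)
        assert ca.f_statistic == pytest.approx(cb.f_statistic, rel=1e-9)
        # the branch choice follows the F-test at alpha
        if not np.array_equal(np.sort(a), np.sort(b)):
            expected = "t_equal_var" if ca.f_pvalue >= ca.alpha else "t_welch"
            assert ca.test_type == expected


class TestHolm:
    def test_monotone_and_bounded(self):
        p = [0.01, 0.04, 0.03, 0.5]
        adj = le.heterogeneity.holm_correction(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        # smallest raw p gets the full multiplicity factor
        assert adj[0] == pytest.approx(0.04)


class TestTumorContrast:
    def make_lobar(self, means, n=50):
        return [lobar_dist(np.full(n, m), label=i + 1)
                for i, m in enumerate(means)]

    def test_identical_lobes(self):
        lobar = self.make_lobar([2.0] * 5)
        c = le.tumor_contrast(lobar, [3])
        assert c.absolute_difference == pytest.approx(0.0)
        assert not c.tumor_lobe_is_stiffest

    def test_hand_arithmetic(self):
        lobar = self.make_lobar([4.0, 2.0, 2.0, 2.0, 2.0])
        c = le.tumor_contrast(lobar, [1])
        assert c.absolute_difference == pytest.approx(2.0)
        assert c.relative_difference == pytest.approx(2.0 / 2.4 * 100.0)
        assert c.tumor_lobe_is_stiffest

    def test_two_tumor_lobes_pool_voxels(self):
        # unequal lobe sizes: pooling != mean of the two lobar means
        lobar = [
            lobar_dist(np.full(10, 6.0), label=1),
            lobar_dist(np.full(90, 2.0), label=2),
            lobar_dist(np.full(50, 3.0), label=3),
            lobar_dist(np.full(50, 3.0), label=4),
            lobar_dist(np.full(50, 3.0), label=5),
        ]
        c = le.tumor_contrast(lobar, [1, 2])
        pooled = (10 * 6.0 + 90 * 2.0) / 100.0
        assert c.tumor_mean == pytest.approx(pooled)
        assert c.absolute_difference == pytest.approx(abs(pooled - 3.0))

    def test_all_lobes_tumorous_rejected(self):
        lobar = self.make_lobar([2.0] * 5)
        with pytest.raises(ValueError):
            le.tumor_contrast(lobar, [1, 2, 3, 4, 5])


@pytest.fixture(scope="module")
def subjects():
    out = []
    for i, preset in enumerate([
        "none", "none", "mild", "mild",
        "moderate_severe", "moderate_severe",
    ]):
        spec = le.severity_preset(preset, grid_shape=(32, 32, 32),
                                  seed=100 + i)
        ph = le.generate_phantom(spec)
        out.append(le.subject_report(
            ph.elasticity_truth, ph.hu_exhale, ph.lobe_labels,
            subject_id=f"s{i}", severity=preset,
        ))
    return out


class TestSubjectAndCohort:
    def test_subject_report_fields(self, subjects):
        r = subjects[0]
        assert len(r.lobar_means) == 5
        assert r.ehi >= 0.0
        assert all(c > 0 for c in r.cv)
        assert all(u >= 0 for u in r.nu)
        assert r.to_dict()["subject_id"] == "s0"

    def test_severity_ordering_visible(self, subjects):
        by = lambda g: [s.ehi for s in subjects if s.severity == g]
        assert np.mean(by("moderate_severe")) > np.mean(by("none"))

    def test_cohort_tables_shape(self, subjects):
        rep = le.cohort_report(subjects, holm=True)
        assert len(rep.lobar_elasticity) == 3 * 5
        assert set(rep.ehi_summary["group"]) == {
            "none", "mild", "moderate_severe"}
        assert "pvalue_holm" in rep.comparisons.columns
        # 3 pairs x 3 metrics + all-COPD-vs-none x 2 metrics
        assert len(rep.comparisons) == 11

    def test_single_subject_degenerates(self, subjects):
        rep = le.cohort_report(subjects[:1])
        assert math.isnan(rep.ehi_summary["sd_ehi"].iloc[0])

    def test_two_identical_subjects_in_different_groups(self, subjects):
        import dataclasses
        a = subjects[0]
        b = dataclasses.replace(a, subject_id="twin", severity="mild")
        rep = le.cohort_report([a, b])
        subj_level = rep.comparisons[
            rep.comparisons["metric"].isin(["ehi", "whole_lung_elasticity"])
        ]
        assert (subj_level["pvalue"] == 1.0).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            le.cohort_report([])

    def test_copd_unknown_only_in_pooled_contrast(self, subjects):
        import dataclasses
        extra = dataclasses.replace(subjects[2], subject_id="unk",
                                    severity="copd_unknown")
        rep = le.cohort_report(subjects + [extra])
        pooled = rep.comparisons[rep.comparisons["group_a"] == "all_copd"]
        assert (pooled["n_a"] == 5).all()          # 2 mild + 2 ms + 1 unknown
        named = rep.comparisons[
            (rep.comparisons["group_a"] != "all_copd")
            & (rep.comparisons["metric"] != "pooled_lobe_cv")
        ]
        assert (named["n_a"] <= 2).all()  # copd_unknown not in named groups
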
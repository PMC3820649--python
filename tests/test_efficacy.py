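"""Efficacy layer: t-test vs permutation oracle, normalization, PF calls,
mortality, baseline-anchored timecourses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrodens import (GroupMeasurements, PfCallCriteria, attenuation,
                       classify_pf, compare_to_vehicle, mortality,
                       normalize_to_control, pf_incidence, students_t_test,
                       timecourse_summarize)
from fibrodens.efficacy import DegenerateVarianceError, NormalizationError


def permutation_p(x, y):
    """Exact two-sided permutation p on |mean difference| over all splits."""
    pooled = list(x) + list(y)
    nx = len(x)
    obs = abs(np.mean(x) - np.mean(y))
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(np.mean(a) - np.mean(b)) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def gm(name, values, vehicle=""):
    return GroupMeasurements(group=name, values=np.asarray(values, float),
                             matched_vehicle=vehicle)


class TestStudentsTTest:
    def test_identical_samples_t_zero_p_one(self):
        t, df, p = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 4 and p == pytest.approx(1.0)

    def test_zero_pooled_variance(self):
        with pytest.raises(DegenerateVarianceError):
            students_t_test([0.0, 0.0], [1.0, 1.0])

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            students_t_test([1.0], [1.0, 2.0])

    def test_separated_groups_agree_with_permutation_oracle(self):
        """x={1,2,3} vs y={4,5,6}: pooled t gives p < 0.05 exactly when the
        exact permutation p over all C(6,3) splits is at its 0.1 floor."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, df, p = students_t_test(x, y)
        assert df == 4 and t < 0
        pp = permutation_p(x, y)
        assert pp == pytest.approx(2 / 20)
        assert (p < 0.05) == (pp <= 0.1)

    def test_rank_agreement_with_permutation_oracle(self):
        """Across tiny 2-to-4-element group pairs of increasing separation,
        the t p-value and the exact permutation p-value rank the instances
        the same way."""
        instances = [
            ([1.0, 2.0], [2.5, 3.0, 4.0]),
            ([1.0, 2.0, 3.0], [3.0, 4.0, 5.0]),
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
            ([1.0, 1.5, 2.0, 2.5], [7.0, 7.5, 8.0, 8.5]),
        ]
        t_ps = [students_t_test(x, y)[2] for x, y in instances]
        perm_ps = [permutation_p(x, y) for x, y in instances]
        for i, j in itertools.combinations(range(len(instances)), 2):
            if t_ps[i] < t_ps[j]:
                assert perm_ps[i] <= perm_ps[j]
            elif t_ps[i] > t_ps[j]:
                assert perm_ps[i] >= perm_ps[j]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=8),
           st.lists(st.floats(-100, 100), min_size=2, max_size=8))
    def test_symmetry(self, x, y):
        try:
            t_xy, df_xy, p_xy = students_t_test(x, y)
        except DegenerateVarianceError:
            return
        t_yx, df_yx, p_yx = students_t_test(y, x)
        assert math.isclose(t_xy, -t_yx, abs_tol=1e-12)
        assert df_xy == df_yx
        assert math.isclose(p_xy, p_yx, rel_tol=1e-12)


class TestNormalization:
    def test_drug_equals_vehicle(self):
        v = gm("veh", [3.0, 4.0, 5.0])
        d = gm("drug", [3.0, 4.0, 5.0], "veh")
        assert normalize_to_control(d, v) == pytest.approx(100.0)
        assert attenuation(d, v) == pytest.approx(0.0)

    def test_half_of_control(self):
        v = gm("veh", [8.0, 12.0])
        d = gm("drug", [5.0, 5.0], "veh")
        assert normalize_to_control(d, v) == pytest.approx(50.0)

    def test_constructed_seventy_percent_attenuation(self):
        """Vehicle all at the 12-point ceiling; drug totals averaging 3.6:
        normalized mean 30% of control, attenuation 70%."""
        v = gm("veh", [12.0] * 10)
        d = gm("drug", [4, 4, 4, 4, 4, 4, 3, 3, 3, 3], "veh")
        assert normalize_to_control(d, v) == pytest.approx(30.0)
        assert attenuation(d, v) == pytest.approx(70.0)

    def test_zero_drug_full_attenuation(self):
        assert attenuation(gm("d", [0.0, 0.0]), gm("v", [5.0, 7.0])) == 100.0

    def test_nonpositive_vehicle_mean(self):
        with pytest.raises(NormalizationError):
            normalize_to_control(gm("d", [1.0]), gm("v", [0.0, 0.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 50), min_size=1, max_size=6),
           st.lists(st.floats(0.1, 50), min_size=1, max_size=6),
           st.floats(0.01, 100))
    def test_scale_invariance(self, drug_vals, veh_vals, c):
        base = normalize_to_control(gm("d", drug_vals), gm("v", veh_vals))
        scaled = normalize_to_control(gm("d", [c * v for v in drug_vals]),
                                      gm("v", [c * v for v in veh_vals]))
        assert math.isclose(base, scaled, rel_tol=1e-9)
        assert math.isclose(base + attenuation(gm("d", drug_vals),
                                               gm("v", veh_vals)), 100.0)

    def test_compare_to_vehicle_bundle(self):
        v = gm("veh", [12.0, 12.0, 11.0, 12.0])
        d = gm("drug", [4.0, 3.0, 5.0, 2.0], "veh")
        res = compare_to_vehicle(d, v)
        assert res.attenuation_percent == pytest.approx(
            100 - res.normalized_mean_percent)
        assert res.degrees_of_freedom == 6
        assert res.p_two_sided < 0.05
        assert res.n_drug == res.n_vehicle == 4


class TestPfClassification:
    @pytest.mark.parametrize("total,v200,expected", [
        (12, 85.0, True),    # both criteria met
        (12, 4.0, False),    # CT below the cut: conjunction fails
        (11, 85.0, False),   # histology below the 12-point cut
    ])
    def test_dual_criterion(self, total, v200, expected):
        assert classify_pf(total, v200, PfCallCriteria()) is expected

    def test_incidence(self):
        assert pf_incidence([True] * 9 + [False]) == pytest.approx(90.0)
        assert pf_incidence([False] * 5) == 0.0
        assert pf_incidence([True] * 3 + [False] * 4) == pytest.approx(300 / 7)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pf_incidence([])


class TestMortality:
    def _survival(self, deaths_by_group):
        rows = []
        for group, death_weeks in deaths_by_group.items():
            for i, dw in enumerate(death_weeks):
                rows.append({"animal_id": f"{group}-{i}", "group": group,
                             "death_week": dw})
        return pd.DataFrame(rows)

    def test_half_vs_none(self):
        surv = self._survival({
            "amd3100": [5, 8, 12, 15, 19] + [None] * 5,
            "msx122": [None] * 10,
        })
        assert mortality(surv, "amd3100", 20) == pytest.approx(50.0)
        assert mortality(surv, "msx122", 20) == 0.0

    def test_all_dead(self):
        surv = self._survival({"g": [1, 2, 3]})
        assert mortality(surv, "g", 20) == 100.0

    def test_deaths_after_horizon_not_counted(self):
        surv = self._survival({"g": [25, None]})
        assert mortality(surv, "g", 20) == 0.0

    def test_unknown_group(self):
        with pytest.raises(ValueError):
            mortality(self._survival({"g": [None]}), "nope", 20)


class TestTimecourse:
    def _table(self, by_day, assay="CXCL12_BALF", reference=None):
        rows = []
        for day, vals in by_day.items():
            for i, v in enumerate(vals):
                row = {"assay": assay, "day": day, "animal_id": f"a{i}", "value": v}
                if reference is not None:
                    row["reference"] = reference[day][i]
                rows.append(row)
        return pd.DataFrame(rows)

    def test_day0_anchored_to_one(self):
        points = timecourse_summarize(self._table({0: [2.0, 2.0, 2.0]}),
                                      "CXCL12_BALF")
        assert points[0].day == 0
        assert points[0].relative_level == 1.0
        assert not points[0].significant_vs_day0

    def test_flat_series_all_one_no_flags(self):
        tbl = self._table({d: [3.0, 3.0, 3.0] for d in (0, 1, 3, 7, 14, 28)})
        points = timecourse_summarize(tbl, "CXCL12_BALF")
        assert all(p.relative_level == 1.0 for p in points)
        assert not any(p.significant_vs_day0 for p in points)

    def test_doubled_day28(self):
        tbl = self._table({0: [1.0, 2.0, 3.0], 28: [2.0, 4.0, 6.0]})
        points = timecourse_summarize(tbl, "CXCL12_BALF")
        day28 = next(p for p in points if p.day == 28)
        assert day28.relative_level == pytest.approx(2.0)

    def test_reference_normalization(self):
        """Each replicate divided by its paired actin reference first."""
        tbl = self._table({0: [2.0, 4.0], 7: [8.0, 16.0]},
                          assay="CXCR4_mRNA",
                          reference={0: [2.0, 4.0], 7: [4.0, 8.0]})
        points = timecourse_summarize(tbl, "CXCR4_mRNA")
        day7 = next(p for p in points if p.day == 7)
        assert day7.relative_level == pytest.approx(2.0)

    def test_clear_rise_is_flagged(self):
        tbl = self._table({0: [1.0, 1.1, 0.9], 14: [3.0, 3.2, 2.9]})
        points = timecourse_summarize(tbl, "CXCL12_BALF")
        day14 = next(p for p in points if p.day == 14)
        assert day14.significant_vs_day0 and day14.p_vs_day0 < 0.05

    def test_missing_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            timecourse_summarize(self._table({7: [1.0, 2.0]}), "CXCL12_BALF")

    def test_single_replicate_day_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            timecourse_summarize(self._table({0: [1.0, 2.0], 7: [5.0]}),
                                 "CXCL12_BALF")
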
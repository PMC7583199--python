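"""ROI means, time-point summaries and the paired t-test protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oximap as om
from oximap.quantify import per_subject_values, roi_table


def make_map(sto2, valid=None):
    sto2 = np.asarray(sto2, dtype=float)
    valid = np.ones(sto2.shape, dtype=bool) if valid is None else valid
    vals = np.where(valid, sto2, np.nan)
    return om.StO2Map(vals, valid, np.zeros(sto2.shape, dtype=bool), provenance=(0, 1))


class TestRoiMean:
    def test_constant_field(self):
        m = make_map(np.full((31, 31), 42.0))
        roi = om.RoiSpec(center=(15, 15), side_px=11)
        assert om.roi_mean(m, roi) == pytest.approx(42.0)

    def test_half_zero_half_hundred(self):
        field = np.zeros((21, 22))
        field[:, 11:] = 100.0
        m = make_map(field)
        roi = om.RoiSpec(center=(10, 10), side_px=21)  # cols 0..20: 11 zeros, 10 hundreds
        expected = 100.0 * (10 * 21) / (21 * 21)
        assert om.roi_mean(m, roi) == pytest.approx(expected)

    def test_out_of_bounds(self):
        m = make_map(np.full((20, 20), 10.0))
        with pytest.raises(om.GeometryError):
            om.roi_mean(m, om.RoiSpec(center=(1, 10), side_px=5))

    def test_insufficient_valid_pixels(self):
        valid = np.zeros((21, 21), dtype=bool)
        valid[:4] = True  # well under half the ROI
        m = make_map(np.full((21, 21), 60.0), valid=valid)
        with pytest.raises(om.InsufficientDataError):
            om.roi_mean(m, om.RoiSpec(center=(10, 10), side_px=21))

    def test_even_side_rejected(self):
        with pytest.raises(om.ValidationError):
            om.RoiSpec(center=(5, 5), side_px=10)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_bounded_by_roi_extremes(self, seed):
        rng = np.random.default_rng(seed)
        m = make_map(rng.uniform(0, 100, (15, 15)))
        roi = om.RoiSpec(center=(7, 7), side_px=7)
        mean = om.roi_mean(m, roi)
        patch = m.sto2_pct[4:11, 4:11]
        assert patch.min() <= mean <= patch.max()


class TestSummaries:
    def test_constant_subjects(self):
        assert om.summarize_timepoint([50.0, 50.0, 50.0]) == (50.0, 0.0)

    def test_two_subject_closed_form(self):
        mean, sd = om.summarize_timepoint([10.0, 20.0])
        assert mean == pytest.approx(15.0)
        assert sd == pytest.approx(math.sqrt(50.0), abs=1e-12)

    def test_single_subject_rejected(self):
        with pytest.raises(om.ValidationError):
            om.summarize_timepoint([50.0])


class TestPairedTTest:
    def test_closed_form_example(self):
        """d = [1,2,3]: t = 2*sqrt(3), df = 2, p = 1 - t/sqrt(t^2+2)."""
        res = om.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        t_expected = 2.0 * math.sqrt(3.0)
        p_expected = 1.0 - t_expected / math.sqrt(t_expected**2 + 2.0)
        assert res.t == pytest.approx(t_expected, abs=1e-10)
        assert res.df == 2
        assert res.p == pytest.approx(p_expected, abs=1e-10)
        assert res.p == pytest.approx(0.0742, abs=5e-5)

    def test_antisymmetry(self):
        a, b = [50.1, 52.0, 49.0], [15.0, 20.5, 11.2]
        r1, r2 = om.paired_t_test(a, b), om.paired_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_degenerate_zero_differences(self):
        res = om.paired_t_test([3.0, 3.0, 4.0], [3.0, 3.0, 4.0])
        assert res.degenerate and res.p == 1.0

    def test_constant_nonzero_differences(self):
        res = om.paired_t_test([4.0, 5.0, 6.0], [3.0, 4.0, 5.0])
        assert res.degenerate and res.p == 0.0 and math.isinf(res.t)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 99999), n=st.integers(3, 12))
    def test_matches_textbook_formula(self, seed, n):
        """Agreement with mean(d)/(sd(d)/sqrt(n)) and the t CDF to 1e-10."""
        rng = np.random.default_rng(seed)
        a = rng.normal(50, 5, n)
        b = rng.normal(40, 5, n)
        res = om.paired_t_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        p_oracle = 2.0 * stats.t.sf(abs(t_oracle), n - 1)
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)
        assert res.df == n - 1


@pytest.fixture(scope="module")
def table():
    maps = {}
    rng = np.random.default_rng(0)
    for s in ("pig1", "pig2"):
        for tp, level in zip(om.quantify.TIMEPOINTS, (52.0, 51.0, 16.0, 12.0)):
            maps[(s, tp)] = make_map(rng.normal(level, 0.5, (48, 48)).clip(0, 100))
    return roi_table(maps, om.default_roi_specs((48, 48), side_px=9))


class TestProtocolTables:

    def test_three_rois_per_image(self, table):
        counts = table.groupby(["subject", "timepoint"]).size()
        assert (counts == 3).all() and len(counts) == 8

    def test_per_subject_pooling(self, table):
        values = per_subject_values(table, mode="per_subject")
        assert values.shape == (2, 4)
        one = table[(table.subject == "pig1") & (table.timepoint == "post_ligation_1min")]
        assert values.loc["pig1", "post_ligation_1min"] == pytest.approx(one.sto2_mean.mean())

    def test_pooled_mode_keeps_rois(self, table):
        values = per_subject_values(table, mode="pooled")
        assert values.shape == (6, 4)

    def test_pairwise_tests_structure(self, table):
        tests = om.pairwise_tests(per_subject_values(table))
        assert list(tests["comparison"]) == [
            "pre_anastomosis vs post_anastomosis",
            "post_anastomosis vs post_ligation_1min",
            "post_ligation_1min vs post_ligation_30min",
        ]
        assert tests["df"].tolist() == [1, 1, 1]

    def test_report_text_mentions_all_timepoints(self, table):
        values = per_subject_values(table)
        text = om.quantify.report_text(
            om.summarize_experiment(values), om.pairwise_tests(values)
        )
        for tp in om.quantify.TIMEPOINTS:
            assert tp in text
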
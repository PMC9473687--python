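"""LC-MS quantification: filtering, normalization, region summaries and tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titinsplice.errors import ConfigurationError, NormalizationError
from titinsplice.proteomics import (
    GelLanes,
    compare_region,
    count_covered_exons,
    filter_low_abundance,
    gel_isoform_fractions,
    normalize_to_constitutive,
    summarize_region,
)

from conftest import make_table

GROUPS2 = {"c1": "control", "c2": "control", "k1": "knockout", "k2": "knockout"}


def two_group_table(values_by_pid, exons_by_pid, n_loci=None):
    rows = []
    for pid, vals in values_by_pid.items():
        rows.append((pid, exons_by_pid[pid], (n_loci or {}).get(pid, 1), vals))
    return make_table(rows, GROUPS2)


class TestFilterLowAbundance:
    def test_boundary_value_is_kept(self):
        vals = {
            "p1": {"c1": 1.0e7, "c2": 1.0e7, "k1": 9e9, "k2": 9e9},
            "p2": {"c1": 1.5e7, "c2": 1.5e7, "k1": 1.0, "k2": 1.0},
            "p3": {"c1": 2.0e7, "c2": 2.0e7, "k1": 1.0, "k2": 1.0},
        }
        exons = {p: {1} for p in vals}
        out = filter_low_abundance(two_group_table(vals, exons), "control", 1.5e7)
        assert list(out.abundances.index) == ["p2", "p3"]

    def test_threshold_zero_retains_everything(self):
        vals = {"p1": {"c1": 0.0, "c2": 0.0, "k1": 1.0, "k2": 1.0}}
        out = filter_low_abundance(two_group_table(vals, {"p1": {1}}), "control", 0.0)
        assert len(out.peptides) == 1

    def test_all_missing_control_counts_as_below(self):
        vals = {"p1": {"c1": np.nan, "c2": np.nan, "k1": 1e9, "k2": 1e9}}
        out = filter_low_abundance(two_group_table(vals, {"p1": {1}}), "control", 1.0)
        assert len(out.peptides) == 0

    def test_unknown_control_group_is_configuration_error(self):
        vals = {"p1": {"c1": 1.0, "c2": 1.0, "k1": 1.0, "k2": 1.0}}
        with pytest.raises(ConfigurationError):
            filter_low_abundance(two_group_table(vals, {"p1": {1}}), "sham", 1.0)

    @given(
        st.lists(st.floats(min_value=0, max_value=1e9), min_size=1, max_size=8),
        st.floats(min_value=0, max_value=5e8),
        st.floats(min_value=0, max_value=5e8),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_shrinks_retained_set(self, medians, t1, t2):
        lo, hi = sorted([t1, t2])
        vals = {
            f"p{i}": {"c1": m, "c2": m, "k1": 1.0, "k2": 1.0} for i, m in enumerate(medians)
        }
        table = two_group_table(vals, {f"p{i}": {1} for i in range(len(medians))})
        kept_lo = set(filter_low_abundance(table, "control", lo).abundances.index)
        kept_hi = set(filter_low_abundance(table, "control", hi).abundances.index)
        assert kept_hi <= kept_lo


class TestCountCoveredExons:
    def test_union_of_exon_sets(self):
        vals = {
            "p1": {"c1": 1, "c2": 1, "k1": 1, "k2": 1},
            "p2": {"c1": 1, "c2": 1, "k1": 1, "k2": 1},
        }
        table = two_group_table(vals, {"p1": {1, 2}, "p2": {2, 3}})
        assert count_covered_exons(table) == 3

    def test_empty_table_is_zero(self):
        vals = {"p1": {"c1": 0.0, "c2": 0.0, "k1": 0.0, "k2": 0.0}}
        table = two_group_table(vals, {"p1": {1}})
        assert count_covered_exons(filter_low_abundance(table, "control", 1.0)) == 0


def region_table(const=(4.0, 6.0), target=10.0):
    """Two constitutive peptides (exons 256, 300) + one target peptide (exon 70)."""
    vals = {
        "t": {s: target for s in GROUPS2},
        "n1": {s: const[0] for s in GROUPS2},
        "n2": {s: const[1] for s in GROUPS2},
    }
    return two_group_table(vals, {"t": {70}, "n1": {256}, "n2": {300}})


class TestNormalizeToConstitutive:
    def test_toy_division_by_constitutive_mean(self):
        out = normalize_to_constitutive(region_table(), (256, 363))
        assert out.abundances.loc["t"].tolist() == pytest.approx([2.0] * 4)

    def test_constitutive_mean_is_one_per_sample(self):
        out = normalize_to_constitutive(region_table(), (256, 363))
        member = out.region_members((256, 363))
        means = out.abundances.loc[member].mean(axis=0)
        assert means.tolist() == pytest.approx([1.0] * 4)

    def test_idempotent(self):
        once = normalize_to_constitutive(region_table(), (256, 363))
        twice = normalize_to_constitutive(once, (256, 363))
        pd.testing.assert_frame_equal(once.abundances, twice.abundances)

    def test_missing_constitutive_sample_names_the_sample(self):
        vals = {
            "t": {"c1": 1, "c2": 1, "k1": 1, "k2": 1},
            "n1": {"c1": 4, "c2": 4, "k1": np.nan, "k2": 4},
        }
        table = two_group_table(vals, {"t": {70}, "n1": {256}})
        with pytest.raises(NormalizationError, match="k1"):
            normalize_to_constitutive(table, (256, 363))

    def test_scale_invariance_of_downstream_summary(self):
        table = region_table()
        scaled = table.subset(np.ones(3, dtype=bool))
        scaled.abundances["k1"] *= 7.3  # per-sample rescaling cancels in normalization
        a = summarize_region(normalize_to_constitutive(table), (70, 79), "control", "knockout")
        b = summarize_region(normalize_to_constitutive(scaled), (70, 79), "control", "knockout")
        assert a.mean_b == pytest.approx(b.mean_b, rel=1e-12)
        assert a.percent_difference == pytest.approx(b.percent_difference, abs=1e-10)


class TestSummarizeRegion:
    def test_noiseless_effect_recovered_exactly(self):
        vals = {
            "t": {"c1": 10.0, "c2": 10.0, "k1": 11.8, "k2": 11.8},
            "n1": {s: 5.0 for s in GROUPS2},
        }
        table = two_group_table(vals, {"t": {72}, "n1": {256}})
        norm = normalize_to_constitutive(table)
        rs = summarize_region(norm, (70, 79), "control", "knockout")
        assert rs.percent_difference == pytest.approx(18.0)

    def test_identical_groups_give_zero_difference(self):
        rs = summarize_region(normalize_to_constitutive(region_table()), (70, 79), "control", "knockout")
        assert rs.percent_difference == pytest.approx(0.0)

    def test_undetected_reference_region_is_flagged(self):
        vals = {
            "t": {"c1": np.nan, "c2": np.nan, "k1": 3.0, "k2": 3.0},
            "n1": {s: 1.0 for s in GROUPS2},
        }
        table = two_group_table(vals, {"t": {55}, "n1": {256}})
        rs = summarize_region(table, (52, 69), "control", "knockout")
        assert rs.undefined_reference
        assert math.isnan(rs.percent_difference)
        assert rs.n_peptides_b == 1

    def test_strict_vs_any_membership(self):
        vals = {
            "inside": {s: 1.0 for s in GROUPS2},
            "straddle": {s: 1.0 for s in GROUPS2},
        }
        table = two_group_table(vals, {"inside": {71}, "straddle": {69, 70}})
        strict = summarize_region(table, (70, 79), "control", "knockout", membership="strict")
        anyov = summarize_region(table, (70, 79), "control", "knockout", membership="any")
        assert strict.n_peptides_a == 1
        assert anyov.n_peptides_a == 2

    def test_multi_locus_peptides_excluded_by_default(self):
        vals = {"dup": {s: 1.0 for s in GROUPS2}, "uni": {s: 1.0 for s in GROUPS2}}
        table = two_group_table(vals, {"dup": {71}, "uni": {72}}, n_loci={"dup": 2})
        rs = summarize_region(table, (70, 79), "control", "knockout")
        assert rs.n_peptides_a == 1


class TestCompareRegion:
    def test_bonferroni_adjusted_threshold(self):
        rs = compare_region(
            normalize_to_constitutive(region_table()), (70, 79), "control", "knockout",
            n_regions_tested=2, alpha=0.05,
        )
        assert rs.alpha_adjusted == 0.025

    def test_identical_groups_not_significant(self):
        vals = {
            f"p{i}": {"c1": v, "c2": v, "k1": v, "k2": v}
            for i, v in enumerate([1.0, 2.0, 3.0])
        }
        vals["n1"] = {s: 1.0 for s in GROUPS2}
        exons = {f"p{i}": {71} for i in range(3)}
        exons["n1"] = {256}
        rs = compare_region(two_group_table(vals, exons), (70, 79), "control", "knockout")
        assert rs.t_statistic == pytest.approx(0.0)
        assert rs.p_value == pytest.approx(1.0)
        assert rs.significant is False

    def test_matches_reference_t_test_on_fixed_toy(self):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        a = [1.0, 2.0, 3.0]
        b = [2.0, 4.0, 6.0]
        vals = {}
        exons = {}
        for i, (va, vb) in enumerate(zip(a, b)):
            vals[f"p{i}"] = {"c1": va, "c2": va, "k1": vb, "k2": vb}
            exons[f"p{i}"] = {71}
        vals["n1"] = {s: 1.0 for s in GROUPS2}
        exons["n1"] = {256}
        rs = compare_region(two_group_table(vals, exons), (70, 79), "control", "knockout")
        t_ref, p_ref, _ = sm_ttest(np.log(b), np.log(a), usevar="pooled")
        assert rs.t_statistic == pytest.approx(t_ref, abs=1e-8)
        assert rs.p_value == pytest.approx(p_ref, abs=1e-8)

    def test_nonpositive_values_excluded_with_count(self):
        vals = {
            "z": {"c1": 0.0, "c2": 0.0, "k1": 1.0, "k2": 1.0},
            "p1": {"c1": 1.0, "c2": 2.0, "k1": 2.0, "k2": 3.0},
            "p2": {"c1": 2.0, "c2": 1.0, "k1": 4.0, "k2": 3.0},
            "p3": {"c1": 1.5, "c2": 1.5, "k1": 3.0, "k2": 3.5},
        }
        exons = {p: {71} for p in vals}
        exons["n1"] = {256}
        vals["n1"] = {s: 1.0 for s in GROUPS2}
        rs = compare_region(two_group_table(vals, exons), (70, 79), "control", "knockout")
        assert rs.n_excluded_nonpositive == 1
        assert np.isfinite(rs.p_value)


class TestGelIsoformFractions:
    @pytest.mark.parametrize(
        "bands,expected",
        [
            ((2.0, 2.0, 0.0), (0.5, 0.5, 0.0)),
            ((0.0, 5.0, 0.0), (0.0, 1.0, 0.0)),
            ((3.0, 6.0, 1.0), (0.3, 0.6, 0.1)),
        ],
    )
    def test_fraction_arithmetic(self, bands, expected):
        lanes = GelLanes(long_t1=[bands[0]], short_t1=[bands[1]], t2=[bands[2]])
        out = gel_isoform_fractions(lanes)
        row = out.iloc[0]
        assert (row["frac_long_t1"], row["frac_short_t1"], row["frac_t2"]) == pytest.approx(expected)
        assert row[["frac_long_t1", "frac_short_t1", "frac_t2"]].sum() == pytest.approx(1.0)

    def test_empty_lane_rejected(self):
        with pytest.raises(ValueError):
            gel_isoform_fractions(GelLanes([0.0], [0.0], [0.0]))
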
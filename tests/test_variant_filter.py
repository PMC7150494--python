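"""Post-calling filter engine: rule boundaries, attribution, rescue, modes."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aasig.variants import (
    AF_RULE,
    POP_RULE,
    READ_LEVEL_RULES,
    FilterThresholds,
    apply_af_window,
    apply_population_filter,
    apply_read_level_filters,
    filter_variants,
    intersect_callsets,
)

from conftest import make_record


class TestIntersectCallsets:
    def test_common_key_kept(self):
        a = [make_record(pos=100)]
        b = [make_record(pos=100), make_record(pos=5, chrom="chr2", ref="C", alt="G")]
        assert [r.key for r in intersect_callsets(a, b)] == [a[0].key]

    def test_empty_input_yields_empty(self):
        assert intersect_callsets([], [make_record()]) == []

    def test_identical_sets_are_identity(self):
        a = [make_record(pos=100 + i) for i in range(5)]
        assert intersect_callsets(a, list(a)) == a

    def test_features_come_from_first_set(self):
        a = [make_record(pos=100, baseq_median_varreads=30.0)]
        b = [make_record(pos=100, baseq_median_varreads=99.0)]
        (kept,) = intersect_callsets(a, b)
        assert kept.baseq_median_varreads == 30.0

    def test_duplicate_key_is_error(self):
        dup = [make_record(pos=7), make_record(pos=7)]
        with pytest.raises(ValueError, match="chr1:7"):
            intersect_callsets(dup, [])


# (overrides, expected failing rule or None) -- boundary semantics per rule
RULE_CASES = [
    ({"dist_to_end_median": 5.0}, READ_LEVEL_RULES[0]),
    ({"dist_to_end_median": 9.99}, READ_LEVEL_RULES[0]),
    ({"dist_to_end_median": 10.0}, None),          # "less than 10" is strict
    ({"dist_to_end_mad": 2.9}, READ_LEVEL_RULES[1]),
    ({"dist_to_end_mad": 3.0}, None),
    ({"frac_low_mapq": 0.11}, READ_LEVEL_RULES[2]),
    ({"frac_low_mapq": 0.10}, None),               # "greater than 10%" is strict
    ({"mapq_median_varreads": 39.0}, READ_LEVEL_RULES[3]),
    ({"mapq_median_varreads": 40.0}, None),
    ({"baseq_median_varreads": 19.0}, READ_LEVEL_RULES[4]),
    ({"baseq_median_varreads": 20.0}, None),
    # rule 6 fires only when variant-read bias is low AND all-read bias is not
    ({"strand_frac_varreads": 0.01, "strand_frac_allreads": 0.25}, READ_LEVEL_RULES[5]),
    ({"strand_frac_varreads": 0.01, "strand_frac_allreads": 0.15}, None),
    ({"strand_frac_varreads": 0.02, "strand_frac_allreads": 0.25}, None),
    ({"repeat_len_adjacent": 12}, READ_LEVEL_RULES[6]),   # "12 or more" inclusive
    ({"repeat_len_adjacent": 11}, None),
    ({"nearby_variant_max": 3}, READ_LEVEL_RULES[7]),     # "greater than 2" strict
    ({"nearby_variant_max": 2}, None),
]


class TestReadLevelFilters:
    @pytest.mark.parametrize("overrides,expected_rule", RULE_CASES)
    def test_rule_boundaries(self, overrides, expected_rule):
        report = apply_read_level_filters([make_record(**overrides)])
        if expected_rule is None:
            assert len(report.retained) == 1
        else:
            assert len(report.retained) == 0
            assert report.rejections[expected_rule] == 1

    def test_pass_all_record_retained(self):
        report = apply_read_level_filters([make_record()])
        assert len(report.retained) == 1
        assert report.n_removed == 0

    def test_multi_failing_counted_under_lowest_rule(self):
        v = make_record(dist_to_end_median=1.0, mapq_median_varreads=10.0)
        report = apply_read_level_filters([v])
        assert report.rejections[READ_LEVEL_RULES[0]] == 1
        assert report.rejections[READ_LEVEL_RULES[3]] == 0

    def test_missing_field_names_variant_and_field(self):
        v = make_record()
        v.baseq_median_varreads = None
        with pytest.raises(ValueError, match="chr1:1000.*baseq_median_varreads"):
            apply_read_level_filters([v])

    def test_partition_invariant(self):
        variants = [make_record(pos=100 * i + 1) for i in range(10)]
        variants += [make_record(pos=5000 + i, dist_to_end_median=3.0) for i in range(4)]
        report = apply_read_level_filters(variants)
        assert len(report.retained) + report.n_removed == len(variants)

    def test_determinism(self):
        variants = [make_record(pos=i + 1, mapq_median_varreads=30.0 + i) for i in range(20)]
        r1 = apply_read_level_filters(variants)
        r2 = apply_read_level_filters(variants)
        assert r1.rejections == r2.rejections
        assert [v.key for v in r1.retained] == [v.key for v in r2.retained]


class TestAFWindow:
    @pytest.mark.parametrize(
        "af,kept",
        [(0.50, True), (0.26, True), (0.74, True),
         (0.25, False), (0.75, False), (0.80, False), (0.10, False)],
    )
    def test_strict_window(self, af, kept):
        report = apply_af_window([make_record(allele_freq=af)])
        assert (len(report.retained) == 1) is kept
        assert report.rejections[AF_RULE] == (0 if kept else 1)

    def test_out_of_range_af_rejected_at_construction(self):
        with pytest.raises(ValueError, match="allele_freq"):
            make_record(allele_freq=1.5)


class TestPopulationFilter:
    def test_common_variant_removed(self):
        report = apply_population_filter([make_record(pop_freqs={"exac": 0.01})])
        assert report.retained == []
        assert report.rejections[POP_RULE] == 1

    def test_cutoff_is_inclusive(self):
        removed = apply_population_filter([make_record(pop_freqs={"exac": 0.001})])
        kept = apply_population_filter([make_record(pop_freqs={"exac": 0.0009})])
        assert removed.retained == [] and len(kept.retained) == 1

    def test_absent_from_all_databases_retained(self):
        report = apply_population_filter([make_record(pop_freqs={})])
        assert len(report.retained) == 1

    @pytest.mark.parametrize("flag", ["clinvar_pathogenic", "cosmic_urinary"])
    def test_pathogenicity_rescue(self, flag):
        v = make_record(pop_freqs={"exac": 0.01}, **{flag: True})
        report = apply_population_filter([v])
        assert len(report.retained) == 1
        assert report.rescued_count == 1

    def test_rescue_can_be_disabled(self):
        v = make_record(pop_freqs={"exac": 0.01}, clinvar_pathogenic=True)
        report = apply_population_filter([v], rescue=False)
        assert report.retained == [] and report.rescued_count == 0

    def test_negative_frequency_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            make_record(pop_freqs={"exac": -0.1})


class TestFullFilter:
    def test_low_coverage_mode_is_af_identity(self):
        variants = [make_record(pos=100, allele_freq=0.9),
                    make_record(pos=200, allele_freq=0.1)]
        full = filter_variants(variants, af_window=True)
        lowcov = filter_variants(variants, af_window=False)
        assert full.retained == []
        assert lowcov.retained == variants
        assert lowcov.rejections[AF_RULE] == 0

    def test_combined_partition(self):
        variants = [
            make_record(pos=100),
            make_record(pos=200, dist_to_end_median=1.0),
            make_record(pos=300, allele_freq=0.9),
            make_record(pos=400, pop_freqs={"kaviar": 0.5}),
        ]
        report = filter_variants(variants)
        assert len(report.retained) + report.n_removed == len(variants)
        assert len(report.retained) == 1

    @given(
        field=st.sampled_from(
            ["dist_end_median_min", "mapq_median_min", "baseq_median_min"]
        ),
        scale=st.floats(min_value=0.3, max_value=1.0),
        data=st.data(),
    )
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_loosening_a_threshold_is_monotone(self, field, scale, data):
        """Lowering any removal cutoff never shrinks the retained set."""
        variants = [
            make_record(
                pos=100 * i + 1,
                dist_to_end_median=data.draw(st.floats(0.1, 60)),
                mapq_median_varreads=data.draw(st.floats(1, 60)),
                baseq_median_varreads=data.draw(st.floats(1, 40)),
            )
            for i in range(8)
        ]
        tight = FilterThresholds()
        loose = dataclasses.replace(tight, **{field: getattr(tight, field) * scale})
        kept_tight = {v.key for v in apply_read_level_filters(variants, tight).retained}
        kept_loose = {v.key for v in apply_read_level_filters(variants, loose).retained}
        assert kept_tight <= kept_loose

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="af_low"):
            FilterThresholds(af_low=0.8, af_high=0.7)
        with pytest.raises(ValueError, match="strictly positive"):
            FilterThresholds(mapq_median_min=0)
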
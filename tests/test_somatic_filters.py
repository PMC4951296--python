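import dataclasses
import itertools

import pytest

from exoncnv.somatic_filters import (
    RULE_ORDER,
    FilterParams,
    VariantRecord,
    apply_somatic_filters,
    classify_substitution,
    first_failing_rule,
    read_variant_table,
    write_variant_table,
)


def make_variant(**overrides) -> VariantRecord:
    base = dict(
        chrom="chr1",
        pos=100,
        ref="C",
        alt="T",
        kind="SNV",
        tumor_depth=50,
        normal_depth=50,
        tumor_alt=10,
        normal_alt=0,
        genotype_quality=60.0,
        region_class="exonic",
        in_germline_db=False,
        in_cosmic=False,
    )
    base.update(overrides)
    return VariantRecord(**base)


def oracle_passes(v: VariantRecord, p: FilterParams) -> bool:
    """Independent single-expression re-statement of the whole cascade."""
    return (
        v.region_class in ("exonic", "splice")
        and v.tumor_depth >= p.min_depth
        and v.normal_depth >= p.min_depth
        and v.normal_alt < p.max_normal_alt
        and v.tumor_alt > p.min_tumor_alt
        and v.genotype_quality >= p.min_gq
        and (
            v.kind == "SNV"
            or (
                v.tumor_alt >= p.min_indel_reads
                and v.tumor_depth > 0
                and v.tumor_alt / v.tumor_depth >= p.min_indel_fraction
            )
        )
        and (not v.in_germline_db or v.in_cosmic)
    )


class TestCascade:
    def test_clean_somatic_snv_passes_all_rules(self):
        passing, report = apply_somatic_filters([make_variant()])
        assert len(passing) == 1 and report.n_passing == 1

    def test_shallow_tumor_fails_coverage_floor(self):
        # the 10x minimum applies to tumor and matched normal alike
        v = make_variant(tumor_depth=9, tumor_alt=4)
        assert first_failing_rule(v, FilterParams()) == "coverage"
        v = make_variant(normal_depth=9)
        assert first_failing_rule(v, FilterParams()) == "coverage"

    def test_three_read_deletion_rejected(self):
        # 3 supporting reads is below the 4-read indel floor; in cascade
        # order the strict tumor-alt count rule (> 3) trips first
        v = make_variant(kind="deletion", ref="CTT", alt="C", tumor_alt=3)
        _, report = apply_somatic_filters([v])
        assert report.n_passing == 0
        assert first_failing_rule(v, FilterParams()) == "tumor_alt"

    def test_indel_fraction_floor(self):
        v = make_variant(kind="deletion", ref="CTT", alt="C",
                         tumor_depth=200, tumor_alt=5)
        assert first_failing_rule(v, FilterParams()) == "indel_support"
        ok = make_variant(kind="deletion", ref="CTT", alt="C",
                          tumor_depth=50, tumor_alt=5)
        assert first_failing_rule(ok, FilterParams()) is None

    def test_normal_alt_strictness_at_boundary(self):
        assert first_failing_rule(make_variant(normal_alt=3), FilterParams()) == "normal_alt"
        assert first_failing_rule(make_variant(normal_alt=2), FilterParams()) is None

    def test_genotype_quality_boundary_inclusive(self):
        assert first_failing_rule(make_variant(genotype_quality=40.0), FilterParams()) is None
        assert (
            first_failing_rule(make_variant(genotype_quality=39.9), FilterParams())
            == "genotype_quality"
        )

    def test_cosmic_rescues_germline_flagged_site(self):
        rejected = make_variant(in_germline_db=True)
        rescued = make_variant(in_germline_db=True, in_cosmic=True)
        assert first_failing_rule(rejected, FilterParams()) == "germline_db"
        assert first_failing_rule(rescued, FilterParams()) is None

    def test_intronic_variant_dropped_first(self):
        v = make_variant(region_class="other", tumor_depth=9)
        assert first_failing_rule(v, FilterParams()) == "region"

    def test_report_conserves_totals(self, rng):
        variants = [random_variant(rng) for _ in range(500)]
        _, report = apply_somatic_filters(variants)
        assert (
            report.n_input
            == report.n_passing + report.n_malformed + sum(report.rejected.values())
        )

    def test_cascade_idempotent(self, rng):
        variants = [random_variant(rng) for _ in range(500)]
        passing, _ = apply_somatic_filters(variants)
        again, report = apply_somatic_filters(passing)
        assert again == passing and report.n_passing == len(passing)

    def test_matches_single_expression_oracle(self, rng):
        params = FilterParams()
        variants = [random_variant(rng) for _ in range(10_000)]
        passing, _ = apply_somatic_filters(variants, params)
        expected = [v for v in variants if oracle_passes(v, params)]
        assert passing == expected

    @pytest.mark.parametrize(
        "field,relaxed",
        [
            ("min_depth", 5),
            ("max_normal_alt", 6),
            ("min_tumor_alt", 1),
            ("min_gq", 20.0),
            ("min_indel_reads", 2),
            ("min_indel_fraction", 0.01),
        ],
    )
    def test_relaxing_one_threshold_never_shrinks_passing_set(
        self, rng, field, relaxed
    ):
        variants = [random_variant(rng) for _ in range(2_000)]
        strict_pass, _ = apply_somatic_filters(variants, FilterParams())
        loose = dataclasses.replace(FilterParams(), **{field: relaxed})
        loose_pass, _ = apply_somatic_filters(variants, loose)
        assert set(v.key() for v in strict_pass) <= set(v.key() for v in loose_pass)

    def test_malformed_record_counted_separately(self):
        bad = make_variant(tumor_alt=60)  # exceeds tumor_depth
        passing, report = apply_somatic_filters([bad, make_variant()])
        assert report.n_malformed == 1 and len(passing) == 1
        assert bad.key() in report.malformed_keys


def random_variant(rng) -> VariantRecord:
    kind = ("SNV", "insertion", "deletion")[int(rng.integers(0, 3))]
    td = int(rng.integers(0, 60))
    nd = int(rng.integers(0, 60))
    ref, alt = ("C", "T") if kind == "SNV" else (("CAA", "C") if kind == "deletion" else ("C", "CAA"))
    return VariantRecord(
        chrom="chr1",
        pos=int(rng.integers(1, 1_000_000)),
        ref=ref,
        alt=alt,
        kind=kind,
        tumor_depth=td,
        normal_depth=nd,
        tumor_alt=int(rng.integers(0, td + 1)),
        normal_alt=int(rng.integers(0, nd + 1)),
        genotype_quality=round(float(rng.uniform(0, 100)), 1),
        region_class=("exonic", "splice", "other")[int(rng.integers(0, 3))],
        in_germline_db=bool(rng.random() < 0.3),
        in_cosmic=bool(rng.random() < 0.15),
    )


class TestSubstitutionClass:
    def test_canonical_pairs(self):
        assert classify_substitution("C", "T") == "transition"
        assert classify_substitution("C", "A") == "transversion"

    def test_exhaustive_enumeration_counts(self):
        results = [
            classify_substitution(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        ]
        assert results.count("transition") == 4
        assert results.count("transversion") == 8

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("C", "C")

    def test_indel_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("CA", "C")


def test_variant_table_round_trip(tmp_path, rng):
    variants = [random_variant(rng) for _ in range(50)] + [
        make_variant(gene="TP53", effect="missense")
    ]
    path = tmp_path / "v.tsv"
    write_variant_table(variants, path)
    assert read_variant_table(path) == variants
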
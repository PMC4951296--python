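import numpy as np
import pytest

from exoncnv.regions import GenomicInterval, ReferenceSequence, merge_capture_regions
from exoncnv.somatic_filters import VariantRecord
from exoncnv.summaries import (
    QPCRMeasurement,
    cpg_context_bases,
    cpg_context_mask,
    cpg_context_rates,
    mutation_rate,
    qpcr_fold_change,
    qpcr_fold_table,
    recurrence_matrix,
)


def brute_force_cpg_mask(seq: str) -> list[bool]:
    """Dinucleotide-scan oracle: flag both bases of every CG."""
    flags = [False] * len(seq)
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            flags[i] = True
            flags[i + 1] = True
    return flags


def make_snv(chrom, pos, ref, alt, **kw):
    base = dict(
        kind="SNV", tumor_depth=50, normal_depth=50, tumor_alt=10, normal_alt=0,
        genotype_quality=60.0, region_class="exonic",
    )
    base.update(kw)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **base)


class TestMutationRate:
    @pytest.mark.parametrize(
        "n,bases,rate", [(0, 5_000_000, 0.0), (100, 1_000_000, 100.0), (7, 3_500_000, 2.0)]
    )
    def test_forced_arithmetic(self, n, bases, rate):
        assert mutation_rate(n, bases) == pytest.approx(rate)

    def test_linear_in_count_inverse_in_target(self):
        assert mutation_rate(10, 1_000_000) == pytest.approx(2 * mutation_rate(5, 1_000_000))
        assert mutation_rate(10, 2_000_000) == pytest.approx(mutation_rate(10, 1_000_000) / 2)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(1, 0)


class TestCpGContext:
    def test_cg_free_sequence_has_no_context(self):
        assert cpg_context_mask("ATATAT").sum() == 0
        ref = ReferenceSequence({"c": "ATATAT"})
        regions = merge_capture_regions([GenomicInterval("c", 0, 6)])
        assert cpg_context_rates([], ref, regions) is None

    def test_hand_enumerated_dinucleotide(self):
        # AACGTT: the C (index 2) and G (index 3) are CpG context
        mask = cpg_context_mask("AACGTT")
        assert list(np.nonzero(mask)[0]) == [2, 3]

    def test_mask_matches_brute_force_scan(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=500))
            assert list(cpg_context_mask(seq)) == brute_force_cpg_mask(seq)

    def test_context_spans_region_boundary(self):
        # CG straddles the region edge: the in-target G still counts
        ref = ReferenceSequence({"c": "AACGTT"})
        regions = merge_capture_regions([GenomicInterval("c", 3, 6)])
        assert cpg_context_bases(ref, regions) == 1

    def test_rates_forced_arithmetic(self):
        # target of 4 CpG-context bases; 1 C>T transition at a CpG C
        ref = ReferenceSequence({"c": "ACGACGAA"})
        regions = merge_capture_regions([GenomicInterval("c", 0, 8)])
        assert cpg_context_bases(ref, regions) == 4
        variants = [
            make_snv("c", 2, "C", "T"),   # CpG transition (pos 1-based)
            make_snv("c", 2, "C", "A"),   # CpG transversion
            make_snv("c", 7, "A", "T"),   # not CpG context: ignored
        ]
        ti, tv = cpg_context_rates(variants, ref, regions)
        mb = 4 / 1e6
        assert ti == pytest.approx(1 / mb)
        assert tv == pytest.approx(1 / mb)

    def test_variant_outside_reference_raises(self):
        ref = ReferenceSequence({"c": "ACGT"})
        regions = merge_capture_regions([GenomicInterval("c", 0, 4)])
        with pytest.raises(IndexError):
            cpg_context_rates([make_snv("c", 99, "C", "T")], ref, regions)


class TestRecurrence:
    def test_single_sample_single_gene(self):
        matrix, freq = recurrence_matrix(
            {"s1": [make_snv("c", 5, "C", "T", gene="TP53", effect="missense")]}
        )
        assert matrix.loc["TP53", "s1"] == "missense"
        assert freq.loc["TP53", "overall"] == 1.0

    def test_category_precedence_stop_gain_wins(self):
        vs = [
            make_snv("c", 5, "C", "T", gene="TP53", effect="missense"),
            make_snv("c", 9, "G", "A", gene="TP53", effect="stop-gain"),
        ]
        matrix, _ = recurrence_matrix({"s1": vs})
        assert matrix.loc["TP53", "s1"] == "stop-gain"

    def test_indel_category(self):
        v = VariantRecord(
            chrom="c", pos=5, ref="CA", alt="C", kind="deletion",
            tumor_depth=50, normal_depth=50, tumor_alt=10, normal_alt=0,
            genotype_quality=60.0, region_class="exonic", gene="KMT2D",
        )
        matrix, _ = recurrence_matrix({"s1": [v]})
        assert matrix.loc["KMT2D", "s1"] == "indel"

    def test_hand_counted_frequency(self):
        samples = {
            f"s{i}": (
                [make_snv("c", 5, "C", "T", gene="TP53", effect="missense")]
                if i < 3
                else []
            )
            for i in range(10)
        }
        matrix, freq = recurrence_matrix(samples)
        assert freq.loc["TP53", "overall"] == pytest.approx(0.3)

    def test_frequencies_invariant_to_sample_order(self):
        a = {"s1": [make_snv("c", 5, "C", "T", gene="G1", effect="missense")], "s2": []}
        b = dict(reversed(a.items()))
        _, fa = recurrence_matrix(a)
        _, fb = recurrence_matrix(b)
        assert fa.loc["G1", "overall"] == fb.loc["G1", "overall"]

    def test_group_split(self):
        samples = {
            "t1": [make_snv("c", 5, "C", "T", gene="G", effect="missense")],
            "t2": [],
            "n1": [],
            "n2": [],
        }
        groups = {"t1": "smoker", "t2": "smoker", "n1": "never", "n2": "never"}
        _, freq = recurrence_matrix(samples, groups)
        assert freq.loc["G", "smoker"] == 0.5
        assert freq.loc["G", "never"] == 0.0


class TestQPCR:
    def test_identical_cts_give_unit_fold(self):
        t = QPCRMeasurement("s", "tumor", 27.0, 25.0)
        n = QPCRMeasurement("s", "normal", 27.0, 25.0)
        assert qpcr_fold_change(t, n) == 1.0

    def test_one_cycle_earlier_doubles(self):
        t = QPCRMeasurement("s", "tumor", 26.0, 25.0)
        n = QPCRMeasurement("s", "normal", 27.0, 25.0)
        assert qpcr_fold_change(t, n) == pytest.approx(2.0)

    def test_independent_power_computation(self):
        # ddCt = -2.322 -> fold 2^2.322 = 5.0
        t = QPCRMeasurement("s", "tumor", 24.678, 25.0)
        n = QPCRMeasurement("s", "normal", 27.0, 25.0)
        assert qpcr_fold_change(t, n) == pytest.approx(5.0, abs=0.01)

    def test_self_fold_is_exactly_one(self, rng):
        for _ in range(10):
            ct_t, ct_r = rng.uniform(15, 35, 2)
            t = QPCRMeasurement("s", "tumor", float(ct_t), float(ct_r))
            n = QPCRMeasurement("s", "normal", float(ct_t), float(ct_r))
            assert qpcr_fold_change(t, n) == 1.0

    def test_mismatched_pair_rejected(self):
        t = QPCRMeasurement("s1", "tumor", 27.0, 25.0)
        n = QPCRMeasurement("s2", "normal", 27.0, 25.0)
        with pytest.raises(ValueError, match="mismatched"):
            qpcr_fold_change(t, n)
        with pytest.raises(ValueError):
            qpcr_fold_change(n, t)

    def test_fold_table_pairs_by_sample(self):
        ms = [
            QPCRMeasurement("a", "tumor", 26.0, 25.0),
            QPCRMeasurement("a", "normal", 27.0, 25.0),
            QPCRMeasurement("b", "tumor", 27.0, 25.0),
            QPCRMeasurement("b", "normal", 27.0, 25.0),
        ]
        folds = qpcr_fold_table(ms).set_index("sample")["fold_change"]
        assert folds["a"] == pytest.approx(2.0)
        assert folds["b"] == pytest.approx(1.0)

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            QPCRMeasurement("s", "tumor", -1.0, 25.0)
        with pytest.raises(ValueError):
            QPCRMeasurement("s", "blood", 25.0, 25.0)
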
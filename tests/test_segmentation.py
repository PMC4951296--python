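import numpy as np
import pandas as pd
import pytest

from exoncnv.ploidy_purity import CorrectedCopySeries
from exoncnv.regions import GenomicInterval
from exoncnv.segmentation import (
    CopyNumberSegment,
    GeneCall,
    annotate_genes,
    call_segments,
    cohort_cna_matrix,
    segment,
)


def make_cn(values, chrom="chr1"):
    ivs = tuple(
        GenomicInterval(chrom, i * 100, i * 100 + 80) for i in range(len(values))
    )
    return CorrectedCopySeries(
        intervals=ivs, copy_number=np.asarray(values, dtype=float), purity=1.0
    )


def exhaustive_single_breakpoint(values, min_regions=3):
    """Oracle: best single split by the pooled-SE t statistic, by enumeration."""
    x = np.asarray(values, float)
    n = len(x)
    best_k, best_t = None, -np.inf
    for k in range(min_regions, n - min_regions + 1):
        left, right = x[:k], x[k:]
        dm = abs(left.mean() - right.mean())
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        pooled = ss / (n - 2)
        se = np.sqrt(pooled * (1 / len(left) + 1 / len(right)))
        t = np.inf if se == 0 and dm > 0 else (0.0 if dm == 0 else dm / se)
        if t > best_t:
            best_t, best_k = t, k
    return best_k, best_t


class TestSegment:
    def test_constant_series_single_segment(self):
        segs = segment(make_cn([2.0] * 100), threshold=5.0)
        assert len(segs) == 1
        assert segs[0].n_regions == 100
        assert segs[0].mean_cn == pytest.approx(2.0)

    def test_noiseless_step_exact_breakpoint(self):
        values = [2.0] * 50 + [4.0] * 50
        segs = segment(make_cn(values), threshold=5.0)
        assert [s.n_regions for s in segs] == [50, 50]
        assert [s.mean_cn for s in segs] == [2.0, 4.0]
        k, t = exhaustive_single_breakpoint(values)
        assert k == 50 and t == np.inf

    def test_noisy_step_matches_exhaustive_oracle(self, rng):
        values = np.concatenate(
            [rng.normal(2.0, 0.15, 60), rng.normal(4.0, 0.15, 40)]
        )
        segs = segment(make_cn(values), threshold=5.0)
        k, _ = exhaustive_single_breakpoint(values)
        assert segs[0].n_regions == k

    def test_false_positive_rate_under_null(self):
        # pure-noise diploid profile should stay one segment nearly always
        single = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            depths_t = r.poisson(80.0, size=200)
            depths_n = np.maximum(r.poisson(80.0, size=200), 1)
            cn = 2.0 * depths_t / depths_n
            single += len(segment(make_cn(cn), threshold=5.0)) == 1
        assert single >= 95

    def test_partition_invariant_across_chromosomes(self, rng):
        ivs = tuple(
            GenomicInterval("chr1" if i < 120 else "chr2", (i % 120) * 100, (i % 120) * 100 + 80)
            for i in range(200)
        )
        values = rng.normal(2.0, 0.3, 200)
        cn = CorrectedCopySeries(intervals=ivs, copy_number=values, purity=1.0)
        segs = segment(cn, threshold=3.0)
        assert sum(s.n_regions for s in segs) == 200
        # segments never span a chromosome boundary
        for s in segs:
            assert s.interval.chrom in ("chr1", "chr2")

    def test_deterministic(self, rng):
        values = rng.normal(2.0, 0.5, 300)
        a = segment(make_cn(values))
        b = segment(make_cn(values))
        assert a == b

    def test_empty_series(self):
        assert segment(make_cn([])) == []

    def test_integer_cn_rounds_half_up(self):
        segs = segment(make_cn([2.5] * 10))
        assert segs[0].integer_cn == 3


class TestCalls:
    def test_rule_table_oracle(self):
        def oracle(c, baseline=2, amp_min=5, del_max=0):
            if c <= del_max:
                return "deletion"
            if c >= amp_min:
                return "amplification"
            if c < baseline:
                return "loss"
            if c == baseline:
                return "neutral"
            return "gain"

        segs = [
            CopyNumberSegment(GenomicInterval("chr1", i * 10, i * 10 + 5), 3, float(c), c)
            for i, c in enumerate([0, 1, 2, 3, 4, 5, 6, 2, 0, 1] * 2)
        ]
        called = call_segments(segs)
        assert [s.call for s in called] == [oracle(s.integer_cn) for s in segs]

    @pytest.mark.parametrize(
        "cn,expected", [(2, "neutral"), (6, "amplification"), (0, "deletion")]
    )
    def test_single_calls(self, cn, expected):
        seg = CopyNumberSegment(GenomicInterval("chr1", 0, 10), 3, float(cn), cn)
        assert call_segments([seg])[0].call == expected

    def test_ploidy_relative_baseline(self):
        seg = CopyNumberSegment(GenomicInterval("chr1", 0, 10), 3, 3.0, 3)
        assert call_segments([seg], baseline_cn=3)[0].call == "neutral"
        assert call_segments([seg], baseline_cn=2)[0].call == "gain"


class TestGeneAnnotation:
    def _segs(self):
        return call_segments(
            [
                CopyNumberSegment(GenomicInterval("chr1", 0, 1000), 5, 2.0, 2),
                CopyNumberSegment(GenomicInterval("chr1", 1000, 2000), 5, 6.0, 6),
            ]
        )

    def test_contained_gene_gets_segment_call(self):
        calls, n = annotate_genes(self._segs(), [GenomicInterval("chr1", 1200, 1400, "G")])
        assert n == 0
        assert calls[0] == GeneCall("G", 6, "amplification", 200)

    def test_straddling_gene_takes_majority_overlap(self):
        # 60% in the first segment, 40% in the second
        gene = GenomicInterval("chr1", 700, 1200, "G")
        calls, _ = annotate_genes(self._segs(), [gene])
        assert calls[0].call == "neutral" and calls[0].overlap_bases == 300

    def test_gene_outside_all_segments_is_counted(self):
        calls, n = annotate_genes(self._segs(), [GenomicInterval("chr2", 0, 100, "G")])
        assert calls == [] and n == 1


class TestCohortMatrix:
    def test_single_sample(self):
        calls = {"s1": [GeneCall("FGF19", 6, "amplification", 100)]}
        matrix, freq = cohort_cna_matrix(calls, {"s1": "A"})
        assert matrix.shape == (1, 1)
        assert matrix.loc["FGF19", "s1"] == "amplification"
        assert freq.loc["FGF19", "A"] == 1.0

    def test_group_frequencies_hand_count(self):
        calls = {}
        groups = {}
        for i in range(5):
            s = f"a{i}"
            call = "amplification" if i < 2 else "neutral"
            calls[s] = [GeneCall("FGF19", 6 if i < 2 else 2, call, 100)]
            groups[s] = "A"
        for i in range(5):
            s = f"b{i}"
            calls[s] = [GeneCall("FGF19", 2, "neutral", 100)]
            groups[s] = "B"
        _, freq = cohort_cna_matrix(calls, groups)
        assert freq.loc["FGF19", "A"] == pytest.approx(0.4)
        assert freq.loc["FGF19", "B"] == 0.0

    def test_empty_gene_list(self):
        matrix, freq = cohort_cna_matrix({"s1": []}, {"s1": "A"})
        assert matrix.empty and freq.empty

    def test_missing_group_tag_raises(self):
        with pytest.raises(ValueError, match="group"):
            cohort_cna_matrix({"s1": []}, {})
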
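"""Copy-number segmentation, integer calls, and gene-level annotation.

Corrected per-region copy numbers are partitioned into runs of constant
copy state by recursive binary segmentation: at each step the candidate
breakpoint maximizing the two-sample statistic

    |mean_L - mean_R| / (s_p * sqrt(1/n_L + 1/n_R))

(s_p the pooled standard deviation) is placed, accepted when the statistic
reaches ``threshold`` and both sides keep at least ``min_regions`` regions,
and the two halves are segmented recursively. Chromosomes are processed
independently. Segments carry the mean copy number of their member regions,
the nearest integer state, and a categorical call relative to a baseline
(diploid by default; pass round(psi) for ploidy-relative calling):
deletion / loss / neutral / gain / amplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ploidy_purity import CorrectedCopySeries
from .regions import GenomicInterval

__all__ = [
    "CopyNumberSegment",
    "GeneCall",
    "segment",
    "call_segments",
    "annotate_genes",
    "cohort_cna_matrix",
    "CALL_CATEGORIES",
]

CALL_CATEGORIES = ("deletion", "loss", "neutral", "gain", "amplification")


@dataclass(frozen=True)
class CopyNumberSegment:
    """A run of consecutive capture regions sharing one copy state."""

    interval: GenomicInterval
    n_regions: int
    mean_cn: float
    integer_cn: int
    call: str | None = None


@dataclass(frozen=True)
class GeneCall:
    """Copy-number call assigned to a gene from its best-overlapping segment."""

    gene: str
    integer_cn: int
    call: str
    overlap_bases: int


def _split_statistics(x: np.ndarray, min_regions: int) -> np.ndarray:
    """Statistic of every admissible breakpoint k (split after index k-1).

    Returns an array indexed by k in [min_regions, n - min_regions];
    entries outside that range are -inf. A zero pooled variance with a
    nonzero mean difference yields +inf (a noiseless step).
    """
    n = len(x)
    stats = np.full(n + 1, -np.inf)
    if n < 2 * min_regions:
        return stats
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])
    ks = np.arange(min_regions, n - min_regions + 1)
    n_l = ks.astype(float)
    n_r = n - n_l
    sum_l = csum[ks]
    sum_r = csum[n] - sum_l
    mean_l = sum_l / n_l
    mean_r = sum_r / n_r
    ss_l = csq[ks] - sum_l * mean_l
    ss_r = (csq[n] - csq[ks]) - sum_r * mean_r
    dof = n - 2
    pooled_var = np.maximum(ss_l + ss_r, 0.0) / dof if dof > 0 else np.zeros_like(ss_l)
    se = np.sqrt(pooled_var * (1.0 / n_l + 1.0 / n_r))
    dm = np.abs(mean_l - mean_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, dm / se, np.where(dm > 0, np.inf, 0.0))
    stats[ks] = t
    return stats


def _segment_block(
    x: np.ndarray, offset: int, threshold: float, min_regions: int
) -> list[tuple[int, int]]:
    """Recursive binary segmentation of one block; returns [start, end) index runs."""
    stats = _split_statistics(x, min_regions)
    k = int(np.argmax(stats))
    if not stats[k] >= threshold:
        return [(offset, offset + len(x))]
    left = _segment_block(x[:k], offset, threshold, min_regions)
    right = _segment_block(x[k:], offset + k, threshold, min_regions)
    return left + right


def segment(
    cn: CorrectedCopySeries,
    threshold: float = 5.0,
    min_regions: int = 3,
) -> list[CopyNumberSegment]:
    """Segment corrected copy numbers into constant-state runs per chromosome.

    Parameters
    ----------
    cn : CorrectedCopySeries
        Genomically ordered per-region copy numbers.
    threshold : float
        Minimum breakpoint statistic to accept a split. Default 5.
    min_regions : int
        Minimum regions on each side of an accepted breakpoint (and hence
        per segment). Default 3.

    Returns
    -------
    list of CopyNumberSegment
        Segments in genomic order; their member counts sum to ``len(cn)``
        (the segmentation partitions the region sequence).
    """
    if len(cn) == 0:
        return []
    if min_regions < 1:
        raise ValueError("min_regions must be >= 1")
    segments: list[CopyNumberSegment] = []
    ivs = cn.intervals
    values = np.asarray(cn.copy_number, dtype=float)
    # contiguous chromosome blocks, preserving input order
    block_start = 0
    for i in range(1, len(ivs) + 1):
        if i == len(ivs) or ivs[i].chrom != ivs[block_start].chrom:
            x = values[block_start:i]
            for lo, hi in _segment_block(x, block_start, threshold, min_regions):
                mean_cn = float(values[lo:hi].mean())
                segments.append(
                    CopyNumberSegment(
                        interval=GenomicInterval(
                            ivs[lo].chrom, ivs[lo].start, ivs[hi - 1].end
                        ),
                        n_regions=hi - lo,
                        mean_cn=mean_cn,
                        integer_cn=max(0, int(math.floor(mean_cn + 0.5))),
                    )
                )
            block_start = i
    return segments


def call_segments(
    segments: Sequence[CopyNumberSegment],
    baseline_cn: int = 2,
    amp_min: int = 5,
    del_max: int = 0,
) -> list[CopyNumberSegment]:
    """Label segments as deletion/loss/neutral/gain/amplification.

    Deletion takes precedence over loss (integer CN <= ``del_max``),
    amplification over gain (integer CN >= ``amp_min``); otherwise the
    integer copy number is compared against ``baseline_cn``.
    """
    out = []
    for seg in segments:
        c = seg.integer_cn
        if c <= del_max:
            call = "deletion"
        elif c >= amp_min:
            call = "amplification"
        elif c < baseline_cn:
            call = "loss"
        elif c == baseline_cn:
            call = "neutral"
        else:
            call = "gain"
        out.append(replace(seg, call=call))
    return out


def annotate_genes(
    segments: Sequence[CopyNumberSegment],
    genes: Iterable[GenomicInterval],
) -> tuple[list[GeneCall], int]:
    """Assign each gene the call of the segment it overlaps most.

    Ties break toward the earlier segment. Genes overlapping no segment
    are omitted; the second return value counts them.
    """
    calls: list[GeneCall] = []
    n_unassigned = 0
    for gene in genes:
        best_seg = None
        best_overlap = 0
        for seg in segments:
            ov = gene.overlap_bases(seg.interval)
            if ov > best_overlap:
                best_overlap = ov
                best_seg = seg
        if best_seg is None:
            n_unassigned += 1
            continue
        if best_seg.call is None:
            raise ValueError("segments must be called before gene annotation")
        calls.append(
            GeneCall(
                gene=gene.name or f"{gene.chrom}:{gene.start}-{gene.end}",
                integer_cn=best_seg.integer_cn,
                call=best_seg.call,
                overlap_bases=best_overlap,
            )
        )
    return calls, n_unassigned


def cohort_cna_matrix(
    sample_calls: Mapping[str, Sequence[GeneCall]],
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample call matrix plus per-group alteration frequencies.

    Parameters
    ----------
    sample_calls : mapping of sample label -> gene calls
        Labels must be unique (a mapping enforces this; duplicate labels in
        the underlying data must be resolved upstream).
    groups : mapping of sample label -> group tag

    Returns
    -------
    (matrix, frequencies)
        ``matrix`` holds call categories (``"neutral"`` where a gene was
        not called in a sample); ``frequencies`` is genes x groups with
        the fraction of samples in each group whose call is non-neutral.
    """
    samples = list(sample_calls)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample labels")
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"samples without a group tag: {missing}")
    genes: list[str] = []
    for calls in sample_calls.values():
        for gc in calls:
            if gc.gene not in genes:
                genes.append(gc.gene)
    matrix = pd.DataFrame("neutral", index=genes, columns=samples, dtype=object)
    for sample, calls in sample_calls.items():
        for gc in calls:
            matrix.loc[gc.gene, sample] = gc.call
    group_names = sorted(set(groups[s] for s in samples))
    freq = pd.DataFrame(0.0, index=genes, columns=group_names)
    for g in group_names:
        members = [s for s in samples if groups[s] == g]
        altered = (matrix[members] != "neutral").sum(axis=1)
        freq[g] = altered / len(members)
    return matrix, freq


def write_segment_table(
    segments: Sequence[CopyNumberSegment], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "chrom": [s.interval.chrom for s in segments],
            "start": [s.interval.start for s in segments],
            "end": [s.interval.end for s in segments],
            "n_regions": [s.n_regions for s in segments],
            "mean_cn": [s.mean_cn for s in segments],
            "integer_cn": [s.integer_cn for s in segments],
            "call": [s.call if s.call is not None else "" for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_segment_table(path: str | Path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        CopyNumberSegment(
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            n_regions=int(r.n_regions),
            mean_cn=float(r.mean_cn),
            integer_cn=int(r.integer_cn),
            call=str(r.call) if isinstance(r.call, str) and r.call else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_call_table(calls: Sequence[GeneCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "integer_cn": [c.integer_cn for c in calls],
            "call": [c.call for c in calls],
            "overlap_bases": [c.overlap_bases for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
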
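"""Mutation-rate and CpG-context statistics, recurrence matrices, and
delta-delta-Ct qPCR fold changes.

Per-sample mutation burden is expressed per megabase of the (merged,
GC-filtered) capture target. CpG-context rates use as denominator only the
CpG-dinucleotide bases inside the target: a base is CpG-context when it is
the C of a 5'-CG-3' dinucleotide on the reference strand, or the G
immediately following such a C — both positions of the hypermutable
dinucleotide count.

Gene x sample recurrence matrices mirror the usual oncoprint layout, with
a fixed category precedence (stop-gain > indel > missense) resolving
multi-hit cells.

qPCR copy-number verification uses the comparative threshold-cycle method:
dCt = Ct_target - Ct_reference within each tissue, ddCt = dCt_tumor -
dCt_normal, fold difference = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import CaptureRegionSet, ReferenceSequence
from .somatic_filters import VariantRecord, classify_substitution

__all__ = [
    "QPCRMeasurement",
    "mutation_rate",
    "cpg_context_mask",
    "cpg_context_bases",
    "cpg_context_rates",
    "recurrence_matrix",
    "qpcr_fold_change",
    "qpcr_fold_table",
]

# multi-hit cells resolve to the most disruptive category
_CATEGORY_PRECEDENCE = {"stop-gain": 3, "indel": 2, "missense": 1, "none": 0}


@dataclass(frozen=True)
class QPCRMeasurement:
    """One tissue's qPCR threshold cycles for a target and a housekeeping
    reference assay (RNase-P style)."""

    sample: str
    tissue: str  # "tumor" or "normal"
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor|normal, got {self.tissue!r}")
        for v in (self.ct_target, self.ct_reference):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"Ct values must be positive and finite: {v}")


def mutation_rate(n_mutations: int, target_bases: int) -> float:
    """Mutations per megabase of target: n / (target_bases / 1e6)."""
    if target_bases <= 0:
        raise ValueError("target size must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be >= 0")
    return n_mutations / (target_bases / 1e6)


def cpg_context_mask(sequence: str) -> np.ndarray:
    """Boolean per-base mask of CpG context over a nucleotide string.

    Position i is flagged when sequence[i:i+2] == "CG" (the C) or
    sequence[i-1:i+1] == "CG" (the G).
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    if len(arr) < 2:
        return mask
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    mask[:-1] |= cg
    mask[1:] |= cg
    return mask


def cpg_context_bases(ref: ReferenceSequence, regions: CaptureRegionSet) -> int:
    """Count CpG-context bases within the capture target.

    Context is evaluated on the whole chromosome, so a CG dinucleotide
    straddling a region boundary still marks the in-target base.
    """
    masks = {chrom: cpg_context_mask(ref.sequence(chrom)) for chrom in ref.chroms}
    total = 0
    for iv in regions:
        total += int(masks[iv.chrom][iv.start : iv.end].sum())
    return total


def cpg_context_rates(
    variants: Iterable[VariantRecord],
    ref: ReferenceSequence,
    regions: CaptureRegionSet,
) -> tuple[float, float] | None:
    """(transition, transversion) rates per Mb of CpG context in the target.

    Only SNVs whose 1-based position falls on a CpG-context base are
    counted. Returns ``None`` when the target contains no CpG-context
    bases (the rates are undefined).
    """
    denom_bases = cpg_context_bases(ref, regions)
    if denom_bases == 0:
        return None
    masks = {chrom: cpg_context_mask(ref.sequence(chrom)) for chrom in ref.chroms}
    n_ti = n_tv = 0
    for v in variants:
        if v.kind != "SNV":
            continue
        if v.chrom not in masks:
            raise KeyError(f"variant chrom {v.chrom!r} absent from reference")
        idx = v.pos - 1
        if idx >= ref.length(v.chrom):
            raise IndexError(f"variant {v.key()} outside reference bounds")
        if not masks[v.chrom][idx]:
            continue
        if classify_substitution(v.ref, v.alt) == "transition":
            n_ti += 1
        else:
            n_tv += 1
    mb = denom_bases / 1e6
    return n_ti / mb, n_tv / mb


def _variant_category(v: VariantRecord) -> str:
    if v.kind in ("insertion", "deletion"):
        return "indel"
    return v.effect if v.effect in ("missense", "stop-gain") else "missense"


def recurrence_matrix(
    sample_variants: Mapping[str, Sequence[VariantRecord]],
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample mutation-event matrix and per-gene frequencies.

    Each cell holds one of {none, missense, stop-gain, indel}; when a
    sample carries several events in a gene the most disruptive category
    wins. Genes are sorted by descending overall mutation frequency.
    Variants without a gene label are ignored.

    Returns
    -------
    (matrix, frequencies)
        ``frequencies`` has one column per group (plus ``"overall"``),
        each the fraction of that group's samples mutated in the gene.
    """
    samples = list(sample_variants)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    groups = groups or {s: "all" for s in samples}
    cells: dict[tuple[str, str], str] = {}
    genes: list[str] = []
    for sample, variants in sample_variants.items():
        for v in variants:
            if v.gene is None:
                continue
            cat = _variant_category(v)
            cur = cells.get((v.gene, sample), "none")
            if _CATEGORY_PRECEDENCE[cat] > _CATEGORY_PRECEDENCE[cur]:
                cells[(v.gene, sample)] = cat
            if v.gene not in genes:
                genes.append(v.gene)
    matrix = pd.DataFrame("none", index=genes, columns=samples, dtype=object)
    for (gene, sample), cat in cells.items():
        matrix.loc[gene, sample] = cat
    mutated = matrix != "none"
    overall = mutated.sum(axis=1) / max(1, len(samples))
    order = overall.sort_values(ascending=False, kind="stable").index
    matrix = matrix.loc[order]
    mutated = mutated.loc[order]
    group_names = sorted(set(groups[s] for s in samples))
    freq = pd.DataFrame(index=matrix.index)
    for g in group_names:
        members = [s for s in samples if groups.get(s) == g]
        freq[g] = mutated[members].sum(axis=1) / len(members)
    freq["overall"] = mutated.sum(axis=1) / max(1, len(samples))
    return matrix, freq


def qpcr_fold_change(tumor: QPCRMeasurement, normal: QPCRMeasurement) -> float:
    """Comparative-Ct fold difference of a matched tumor/normal pair.

    fold = 2^-(dCt_tumor - dCt_normal) with dCt = Ct_target - Ct_reference.
    """
    if tumor.tissue != "tumor" or normal.tissue != "normal":
        raise ValueError("expected a (tumor, normal) measurement pair")
    if tumor.sample != normal.sample:
        raise ValueError(
            f"mismatched pair: {tumor.sample!r} vs {normal.sample!r}"
        )
    dct_t = tumor.ct_target - tumor.ct_reference
    dct_n = normal.ct_target - normal.ct_reference
    return float(2.0 ** (-(dct_t - dct_n)))


def read_qpcr_table(path: str | Path) -> list[QPCRMeasurement]:
    """Read a Ct TSV with columns ``sample tissue ct_target ct_reference``."""
    df = pd.read_csv(path, sep="\t")
    return [
        QPCRMeasurement(
            str(r.sample), str(r.tissue), float(r.ct_target), float(r.ct_reference)
        )
        for r in df.itertuples(index=False)
    ]


def qpcr_fold_table(measurements: Sequence[QPCRMeasurement]) -> pd.DataFrame:
    """Pair tumor/normal measurements by sample id and compute fold changes."""
    by_sample: dict[str, dict[str, QPCRMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample, {})[m.tissue] = m
    rows = []
    for sample, pair in by_sample.items():
        if "tumor" not in pair or "normal" not in pair:
            raise ValueError(f"sample {sample!r} lacks a tumor/normal pair")
        rows.append(
            {"sample": sample, "fold_change": qpcr_fold_change(pair["tumor"], pair["normal"])}
        )
    return pd.DataFrame(rows, columns=["sample", "fold_change"])
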
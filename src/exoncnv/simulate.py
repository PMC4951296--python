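"""Synthetic tumor/normal exome data with known ground truth.

Everything the pipeline consumes can be generated here: a toy reference
with block-wise GC heterogeneity and CG-rich islands, a capture design
tiling it, per-region tumor/normal depth tables drawn from a GC-biased
Poisson model, candidate variant tables with planted rule violations, and
qPCR Ct tables — all fully determined by a single integer seed, together
with the ground truth (copy-number segments, purity, ploidy, expected
ratios, per-variant pass/fail labels) the outputs were generated from.

Generative model
----------------
* Normal depth per region:  Poisson(base_coverage x g(gc)), with the
  unimodal GC-bias curve g(gc) = max(0.1, 1 - curvature * (gc - 0.4)^2),
  so g(0.4) = 1 and coverage falls off at extreme GC — the reason the
  pipeline excludes GC-rich regions in the first place.
* Tumor depth per region:   Poisson(base_coverage x g(gc) x r), where
  r = (alpha * c + 2 * (1 - alpha)) / 2 is the admixture-model expected
  ratio for true copy number c and purity alpha.
* Somatic variant allele counts: Binomial(depth, v) with
  v = alpha * m / (alpha * c + 2 * (1 - alpha)) for m mutated copies.
* qPCR: the tumor target Ct is shifted by -log2(true copy ratio) relative
  to the normal, with the housekeeping reference constant per tissue.

Defaults mimic a single exome-sequenced tumor/normal pair: ~5,000 capture
regions of 120 bp tiling a 1 Mb two-chromosome toy genome, 97x mean
coverage, a copy-number profile with a triploid block, a single-copy loss
and a short 6-copy focal amplification carrying an FGF19-like gene, and a
200-variant plan covering every filter rule.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .depth_ratio import DepthRecord, write_depth_table
from .regions import (
    CaptureRegionSet,
    GenomicInterval,
    ReferenceSequence,
    gc_fraction,
    merge_capture_regions,
    write_bed,
)
from .somatic_filters import (
    FilterParams,
    VariantRecord,
    first_failing_rule,
    write_variant_table,
)
from .summaries import QPCRMeasurement, cpg_context_mask

__all__ = [
    "TruthSegment",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "default_variant_plan",
    "gc_bias",
    "simulate_reference",
    "simulate_depths",
    "simulate_variants",
    "simulate_qpcr",
    "simulate_all",
]


@dataclass(frozen=True)
class TruthSegment:
    """A true copy-number segment of the simulated tumor genome."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid segment coordinates")


def default_variant_plan() -> dict[str, int]:
    """200 planted variants covering every cascade rule and CpG context."""
    return {
        "somatic_snv": 50,
        "somatic_indel": 10,
        "cpg_transition": 20,
        "cpg_transversion": 10,
        "germline_in_normal": 30,
        "germline_db": 10,
        "cosmic_rescue": 10,
        "region_fail": 10,
        "coverage_fail": 10,
        "normal_alt_fail": 10,
        "tumor_alt_fail": 10,
        "gq_fail": 10,
        "indel_fraction_fail": 10,
    }


@dataclass
class SimulationConfig:
    """Knobs of the simulated study; defaults emulate one ~1 Mb exome pair.

    ``truth_segments`` and ``genes`` default to a fixed profile on the
    default genome: chr1 carries a triploid block, a 6-copy focal
    amplification (with the FGF19-analog gene inside) and a single-copy
    loss (with the TP53-analog inside); chr2 is diploid with a neutral
    control gene.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    gc_levels: tuple[float, ...] = (0.35, 0.45, 0.55)
    gc_block_size: int = 20_000
    n_cpg_islands: int = 10
    cpg_island_length: int = 800
    capture_length: int = 120
    capture_spacing: int = 80
    base_coverage: float = 97.0
    gc_curvature: float = 2.0
    overdispersion: float = 0.0
    purity: float = 1.0
    truth_segments: list[TruthSegment] | None = None
    genes: list[GenomicInterval] | None = None
    variant_plan: dict[str, int] | None = None
    mutated_copies: int = 1
    filter_params: FilterParams = field(default_factory=FilterParams)
    qpcr_copy_ratios: dict[str, float] = field(
        default_factory=lambda: {"S1": 1.0, "S2": 2.0, "S3": 4.0}
    )
    qpcr_noise_sd: float = 0.05
    qpcr_reference_ct: float = 25.0
    qpcr_target_ct_normal: float = 28.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if self.truth_segments is None:
            self.truth_segments = self._default_segments()
        if self.genes is None:
            self.genes = self._default_genes()

    def _default_segments(self) -> list[TruthSegment]:
        # fixed fractional layout so any chr1 length gets the same profile
        segs: list[TruthSegment] = []
        for chrom, length in self.chrom_lengths.items():
            if chrom == next(iter(self.chrom_lengths)):
                for f0, f1, c in (
                    (0.00, 0.33, 2),
                    (0.33, 0.53, 3),
                    (0.53, 0.57, 6),
                    (0.57, 0.77, 1),
                    (0.77, 1.00, 2),
                ):
                    segs.append(
                        TruthSegment(chrom, int(f0 * length), int(f1 * length), c)
                    )
            else:
                segs.append(TruthSegment(chrom, 0, length, 2))
        return segs

    def _default_genes(self) -> list[GenomicInterval]:
        first = next(iter(self.chrom_lengths))
        length = self.chrom_lengths[first]
        genes = [
            GenomicInterval(first, int(0.545 * length), int(0.555 * length), "FGF19L"),
            GenomicInterval(first, int(0.65 * length), int(0.66 * length), "TP53L"),
        ]
        others = [c for c in self.chrom_lengths if c != first]
        if others:
            c2 = others[0]
            l2 = self.chrom_lengths[c2]
            genes.append(GenomicInterval(c2, int(0.25 * l2), int(0.26 * l2), "KRT5L"))
        return genes


@dataclass
class GroundTruth:
    """What the simulation actually planted, for scoring recovery."""

    segments: list[TruthSegment]
    purity: float
    ploidy: float
    expected_ratios: np.ndarray
    variant_labels: list[dict]
    qpcr_copy_ratios: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "segments": [asdict(s) for s in self.segments],
            "purity": self.purity,
            "ploidy": self.ploidy,
            "expected_ratios": [float(x) for x in self.expected_ratios],
            "variant_labels": self.variant_labels,
            "qpcr_copy_ratios": self.qpcr_copy_ratios,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass
class SimulatedDataset:
    """In-memory bundle of everything one simulation produced."""

    config: SimulationConfig
    reference: ReferenceSequence
    cpg_islands: list[GenomicInterval]
    capture_regions: CaptureRegionSet
    genes: list[GenomicInterval]
    depths: list[DepthRecord]
    variants: list[VariantRecord]
    qpcr: list[QPCRMeasurement]
    truth: GroundTruth


class _SegmentLookup:
    """Midpoint -> true copy number lookup over the truth segments."""

    def __init__(self, segments: Sequence[TruthSegment]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        for chrom in {s.chrom for s in segments}:
            segs = sorted(
                (s for s in segments if s.chrom == chrom), key=lambda s: s.start
            )
            self._by_chrom[chrom] = (
                [s.start for s in segs],
                [s.end for s in segs],
                [s.copy_number for s in segs],
            )

    def copy_number(self, chrom: str, pos: int, default: int = 2) -> int:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return default
        starts, ends, cns = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return cns[i]
        return default


def _truth_ploidy(
    segments: Sequence[TruthSegment], chrom_lengths: Mapping[str, int]
) -> float:
    """Length-weighted mean copy number over the genome (uncovered = 2)."""
    total = sum(chrom_lengths.values())
    covered = sum(s.end - s.start for s in segments)
    weighted = sum((s.end - s.start) * s.copy_number for s in segments)
    return (weighted + 2 * (total - covered)) / total


def gc_bias(gc: float, curvature: float) -> float:
    """Unimodal GC coverage-bias curve: g(0.4) = 1, floor 0.1."""
    return max(0.1, 1.0 - curvature * (gc - 0.4) ** 2)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceSequence, list[GenomicInterval], CaptureRegionSet, list[GenomicInterval]]:
    """Build the toy reference, CpG-island BED, capture design, and genes.

    Chromosome sequences are drawn block-wise with GC targets cycling
    through ``gc_levels``; CpG islands are CG-rich overwrites (expected GC
    around 0.88) recorded as intervals; capture regions tile each
    chromosome at the configured length/spacing.
    """
    rng = rng or np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    islands: list[GenomicInterval] = []
    capture: list[GenomicInterval] = []
    for chrom, length in config.chrom_lengths.items():
        if config.capture_length > length:
            raise ValueError(
                f"capture regions of {config.capture_length} bp do not fit "
                f"in {chrom} ({length} bp)"
            )
        blocks = []
        levels = config.gc_levels
        for bi, start in enumerate(range(0, length, config.gc_block_size)):
            n = min(config.gc_block_size, length - start)
            blocks.append(_random_sequence(n, levels[bi % len(levels)], rng))
        arr = np.concatenate(blocks)

        n_islands = max(
            1, round(config.n_cpg_islands * length / sum(config.chrom_lengths.values()))
        ) if config.n_cpg_islands else 0
        for _ in range(n_islands):
            ilen = config.cpg_island_length
            if ilen >= length:
                raise ValueError("CpG island longer than chromosome")
            start = int(rng.integers(0, length - ilen))
            island = np.empty(ilen, dtype=np.uint8)
            i = 0
            while i < ilen:
                if rng.random() < 0.6 and i + 1 < ilen:
                    island[i] = ord("C")
                    island[i + 1] = ord("G")
                    i += 2
                else:
                    island[i] = rng.choice(
                        _BASES, p=[0.15, 0.35, 0.35, 0.15]
                    )
                    i += 1
            arr[start : start + ilen] = island
            islands.append(GenomicInterval(chrom, start, start + ilen))

        seqs[chrom] = arr.tobytes().decode("ascii")

        step = config.capture_length + config.capture_spacing
        for start in range(0, length - config.capture_length + 1, step):
            capture.append(GenomicInterval(chrom, start, start + config.capture_length))

    ref = ReferenceSequence(seqs)
    regions = merge_capture_regions(capture)
    return ref, sorted(islands), regions, list(config.genes or [])


def expected_ratio(copy_number: float, purity: float) -> float:
    """Admixture-model expected tumor:normal ratio for copy number c."""
    return (purity * copy_number + 2.0 * (1.0 - purity)) / 2.0


def simulate_depths(
    segments: Sequence[TruthSegment],
    regions: CaptureRegionSet,
    ref: ReferenceSequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[DepthRecord], np.ndarray]:
    """Draw per-region tumor/normal depths; also return expected ratios.

    With ``overdispersion`` gamma > 0 the Poisson means are themselves
    gamma-distributed (negative-binomial marginal), emulating library
    noise beyond counting statistics.
    """
    rng = rng or np.random.default_rng(config.seed)
    lookup = _SegmentLookup(segments)
    records: list[DepthRecord] = []
    exp_ratios = np.empty(len(regions))
    for j, iv in enumerate(regions):
        gc = gc_fraction(iv, ref)
        g = gc_bias(0.4 if np.isnan(gc) else gc, config.gc_curvature)
        c = lookup.copy_number(iv.chrom, (iv.start + iv.end) // 2)
        r = expected_ratio(c, config.purity)
        exp_ratios[j] = r
        lam_n = config.base_coverage * g
        lam_t = config.base_coverage * g * r
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            lam_n = rng.gamma(shape, lam_n / shape)
            lam_t = rng.gamma(shape, lam_t / shape) if lam_t > 0 else 0.0
        records.append(
            DepthRecord(
                iv,
                float(rng.poisson(lam_t)),
                float(rng.poisson(lam_n)),
            )
        )
    return records, exp_ratios


class _PositionSampler:
    """Draw distinct (chrom, position) pairs from per-chrom pools."""

    def __init__(self, pools: list[tuple[str, np.ndarray]], rng: np.random.Generator):
        self._chroms = [c for c, p in pools]
        self._pools = [p for c, p in pools]
        lens = [len(p) for p in self._pools]
        self._offsets = np.cumsum([0] + lens)
        self._perm = rng.permutation(int(self._offsets[-1]))
        self._next = 0

    def draw(self) -> tuple[str, int]:
        if self._next >= len(self._perm):
            raise ValueError("variant plan exceeds available target positions")
        flat = int(self._perm[self._next])
        self._next += 1
        i = int(np.searchsorted(self._offsets, flat, side="right")) - 1
        return self._chroms[i], int(self._pools[i][flat - self._offsets[i]])


def _target_position_pools(
    ref: ReferenceSequence, regions: CaptureRegionSet
) -> tuple[list[tuple[str, np.ndarray]], list[tuple[str, np.ndarray]]]:
    """(CpG-C positions, non-CpG-context positions) inside the capture target."""
    cpg_c: list[tuple[str, np.ndarray]] = []
    plain: list[tuple[str, np.ndarray]] = []
    for chrom in ref.chroms:
        seq = ref.sequence(chrom)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        context = cpg_context_mask(seq)
        c_of_cg = np.zeros(len(arr), dtype=bool)
        if len(arr) >= 2:
            c_of_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        acgt = np.isin(arr, _BASES)
        in_target = np.zeros(len(arr), dtype=bool)
        for iv in regions:
            if iv.chrom == chrom:
                in_target[iv.start : iv.end] = True
        cpg_c.append((chrom, np.nonzero(c_of_cg & in_target)[0]))
        plain.append((chrom, np.nonzero(~context & acgt & in_target)[0]))
    return cpg_c, plain


def simulate_variants(
    segments: Sequence[TruthSegment],
    ref: ReferenceSequence,
    regions: CaptureRegionSet,
    genes: Sequence[GenomicInterval],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], list[dict]]:
    """Plant candidate variants per the category plan, with truth labels.

    Pass-category variants draw realistic allele counts from the
    purity-admixture VAF model; each fail category is constructed to break
    exactly one cascade rule (e.g. tumor depth 9, normal alt reads 3,
    genotype quality 39, indel fraction 0.04). Labels record, for every
    record, the first failing rule actually implied by its fields under
    ``config.filter_params`` — so even a stochastic borderline draw is
    labelled consistently.
    """
    rng = rng or np.random.default_rng(config.seed)
    plan = dict(config.variant_plan or default_variant_plan())
    lookup = _SegmentLookup(segments)
    cpg_pool, plain_pool = _target_position_pools(ref, regions)
    cpg_sampler = _PositionSampler(cpg_pool, rng)
    plain_sampler = _PositionSampler(plain_pool, rng)

    gene_list = list(genes)

    def gene_at(chrom: str, pos0: int) -> str | None:
        for g in gene_list:
            if g.chrom == chrom and g.start <= pos0 < g.end:
                return g.name
        return None

    def base_depths(c: int) -> tuple[int, int, float]:
        r = expected_ratio(c, config.purity)
        td = int(rng.poisson(config.base_coverage * r))
        nd = int(rng.poisson(config.base_coverage))
        vaf = (
            config.purity
            * config.mutated_copies
            / (config.purity * c + 2.0 * (1.0 - config.purity))
        )
        return td, nd, vaf

    def snv_alleles(chrom: str, pos0: int) -> tuple[str, str]:
        refb = ref.sequence(chrom)[pos0]
        alts = [b for b in "ACGT" if b != refb]
        return refb, alts[int(rng.integers(0, 3))]

    variants: list[VariantRecord] = []
    labels: list[dict] = []

    def emit(v: VariantRecord, category: str) -> None:
        rule = first_failing_rule(v, config.filter_params)
        variants.append(v)
        labels.append(
            {
                "key": v.key(),
                "category": category,
                "should_pass": rule is None,
                "first_failing_rule": rule,
            }
        )

    for category, count in plan.items():
        for _ in range(count):
            use_cpg = category in ("cpg_transition", "cpg_transversion")
            chrom, pos0 = (cpg_sampler if use_cpg else plain_sampler).draw()
            c = lookup.copy_number(chrom, pos0)
            td, nd, vaf = base_depths(c)
            td = max(td, config.filter_params.min_depth)
            nd = max(nd, config.filter_params.min_depth)
            kind = "SNV"
            if use_cpg:
                refb = "C"
                altb = "T" if category == "cpg_transition" else (
                    "A" if rng.random() < 0.5 else "G"
                )
            else:
                refb, altb = snv_alleles(chrom, pos0)
            t_alt = int(rng.binomial(td, min(1.0, vaf)))
            n_alt = int(rng.binomial(nd, 0.002))
            gq = float(np.round(rng.uniform(50.0, 99.0), 1))
            region_class = "exonic" if rng.random() < 0.8 else "splice"
            in_db = False
            in_cosmic = False

            if category == "somatic_indel":
                kind = "deletion" if rng.random() < 0.5 else "insertion"
                refb, altb = _indel_alleles(ref, chrom, pos0, kind, rng)
                # guarantee the planted indel clears the support rule
                floor = max(
                    config.filter_params.min_indel_reads,
                    config.filter_params.min_tumor_alt + 1,
                    int(np.ceil(config.filter_params.min_indel_fraction * td)),
                )
                t_alt = max(t_alt, floor)
            elif category == "germline_in_normal":
                t_alt = int(rng.binomial(td, 0.5))
                n_alt = int(rng.binomial(nd, 0.5))
                in_db = True
            elif category == "germline_db":
                in_db = True
            elif category == "cosmic_rescue":
                in_db = True
                in_cosmic = True
            elif category == "region_fail":
                region_class = "other"
            elif category == "coverage_fail":
                td = config.filter_params.min_depth - 1
                t_alt = min(t_alt, td)
            elif category == "normal_alt_fail":
                n_alt = config.filter_params.max_normal_alt
                nd = max(nd, n_alt)
            elif category == "tumor_alt_fail":
                t_alt = config.filter_params.min_tumor_alt
            elif category == "gq_fail":
                gq = float(np.round(rng.uniform(0.0, config.filter_params.min_gq - 1.0), 1))
            elif category == "indel_fraction_fail":
                kind = "deletion"
                refb, altb = _indel_alleles(ref, chrom, pos0, kind, rng)
                td = max(td, 100)
                t_alt = max(
                    config.filter_params.min_indel_reads,
                    config.filter_params.min_tumor_alt + 1,
                )
                if t_alt / td >= config.filter_params.min_indel_fraction:
                    td = int(
                        np.ceil(t_alt / config.filter_params.min_indel_fraction)
                    ) + 1

            # pass categories must clear the alt-count rules by construction
            if category in ("somatic_snv", "cpg_transition", "cpg_transversion",
                            "cosmic_rescue", "germline_db"):
                t_alt = max(t_alt, config.filter_params.min_tumor_alt + 1)
            t_alt = min(t_alt, td)
            n_alt = min(n_alt, nd)

            emit(
                VariantRecord(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref=refb,
                    alt=altb,
                    kind=kind,
                    tumor_depth=td,
                    normal_depth=nd,
                    tumor_alt=t_alt,
                    normal_alt=n_alt,
                    genotype_quality=gq,
                    region_class=region_class,
                    in_germline_db=in_db,
                    in_cosmic=in_cosmic,
                    gene=gene_at(chrom, pos0),
                    effect="stop-gain" if rng.random() < 0.2 else "missense",
                ),
                category,
            )
    return variants, labels


def _indel_alleles(
    ref: ReferenceSequence,
    chrom: str,
    pos0: int,
    kind: str,
    rng: np.random.Generator,
) -> tuple[str, str]:
    seq = ref.sequence(chrom)
    anchor = seq[pos0]
    ins = "".join("ACGT"[int(rng.integers(0, 4))] for _ in range(2))
    if kind == "insertion":
        return anchor, anchor + ins
    tail = seq[pos0 + 1 : pos0 + 3]
    tail = tail if len(tail) == 2 else tail + "A" * (2 - len(tail))
    return anchor + tail, anchor


def simulate_qpcr(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[QPCRMeasurement]:
    """Ct tables for the configured per-sample true copy ratios.

    The tumor target Ct sits log2(k) cycles below the normal target Ct for
    a true copy ratio k, plus Gaussian cycle noise (sd
    ``qpcr_noise_sd``, 0 for noise-free tables); reference (housekeeping)
    Ct is constant per tissue.
    """
    rng = rng or np.random.default_rng(config.seed)
    out: list[QPCRMeasurement] = []
    for sample, k in config.qpcr_copy_ratios.items():
        if k <= 0:
            raise ValueError(f"true copy ratio for {sample!r} must be > 0")
        noise = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd else 0.0
        out.append(
            QPCRMeasurement(
                sample, "normal", config.qpcr_target_ct_normal, config.qpcr_reference_ct
            )
        )
        out.append(
            QPCRMeasurement(
                sample,
                "tumor",
                config.qpcr_target_ct_normal - float(np.log2(k)) + noise,
                config.qpcr_reference_ct,
            )
        )
    return out


def simulate_all(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Run every generator under one seed; optionally write all files.

    When ``outdir`` is given, writes: reference.fa, capture.bed,
    cpg_islands.bed, genes.bed, depths.tsv, variants.tsv, qpcr.tsv and
    truth.json. Outputs are byte-identical for a fixed config.
    """
    ss = np.random.SeedSequence(config.seed)
    r_ref, r_depth, r_var, r_qpcr = [np.random.default_rng(s) for s in ss.spawn(4)]
    ref, islands, regions, genes = simulate_reference(config, r_ref)
    depths, exp_ratios = simulate_depths(
        config.truth_segments, regions, ref, config, r_depth
    )
    variants, labels = simulate_variants(
        config.truth_segments, ref, regions, genes, config, r_var
    )
    qpcr = simulate_qpcr(config, r_qpcr)
    truth = GroundTruth(
        segments=list(config.truth_segments),
        purity=config.purity,
        ploidy=_truth_ploidy(config.truth_segments, config.chrom_lengths),
        expected_ratios=exp_ratios,
        variant_labels=labels,
        qpcr_copy_ratios=dict(config.qpcr_copy_ratios),
    )
    ds = SimulatedDataset(
        config=config,
        reference=ref,
        cpg_islands=islands,
        capture_regions=regions,
        genes=genes,
        depths=depths,
        variants=variants,
        qpcr=qpcr,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref.write_fasta(outdir / "reference.fa")
        write_bed(regions, outdir / "capture.bed")
        write_bed(islands, outdir / "cpg_islands.bed")
        write_bed(genes, outdir / "genes.bed")
        write_depth_table(depths, outdir / "depths.tsv")
        write_variant_table(variants, outdir / "variants.tsv")
        _write_qpcr_table(qpcr, outdir / "qpcr.tsv")
        truth.to_json(outdir / "truth.json")
    return ds


def _write_qpcr_table(measurements: Sequence[QPCRMeasurement], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample": m.sample,
                "tissue": m.tissue,
                "ct_target": m.ct_target,
                "ct_reference": m.ct_reference,
            }
            for m in measurements
        ]
    ).to_csv(path, sep="\t", index=False)
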
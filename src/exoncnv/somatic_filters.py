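"""Somatic SNV/indel filter cascade over tumor/normal candidate variants.

Candidate somatic calls (already aligned, called and annotated upstream)
are pushed through a fixed-order rule cascade; each record is rejected by
the first rule it fails, and the report keeps a per-rule tally so the
cascade is auditable. The rules, in order:

1. region        — keep only exonic / canonical-splice variants
2. coverage      — >= 10x in both tumor and matched normal
3. normal_alt    — fewer than 3 alt-supporting reads in the normal
4. tumor_alt     — more than 3 alt-supporting reads in the tumor
5. genotype_quality — Phred-scaled genotype confidence >= 40.0 (tumor)
6. indel_support — indels only: >= 4 supporting reads and an alt
                   fraction >= 0.05 of tumor depth
7. germline_db   — drop known germline polymorphisms (dbSNP / 1000
                   Genomes / GWAS membership flag) unless the site is in
                   COSMIC, which rescues known somatic hotspots

The "< 3 in normal / more than 3 in tumor" thresholds are alt-supporting
read counts, applied strictly. Database membership is consumed as two
boolean flags set at load time from user-supplied site lists; the cascade
never touches the databases themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "FilterParams",
    "FilterReport",
    "RULE_ORDER",
    "apply_somatic_filters",
    "first_failing_rule",
    "classify_substitution",
    "read_variant_table",
    "write_variant_table",
]

RULE_ORDER = (
    "region",
    "coverage",
    "normal_alt",
    "tumor_alt",
    "genotype_quality",
    "indel_support",
    "germline_db",
)

VARIANT_KINDS = ("SNV", "insertion", "deletion")
REGION_CLASSES = ("exonic", "splice", "other")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class VariantRecord:
    """One candidate somatic variant with tumor/normal support and annotation.

    ``pos`` is 1-based (VCF convention). ``gene`` and ``effect`` are
    optional annotation columns consumed as-is (functional annotation is
    upstream's job).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str
    tumor_depth: int
    normal_depth: int
    tumor_alt: int
    normal_alt: int
    genotype_quality: float
    region_class: str
    in_germline_db: bool = False
    in_cosmic: bool = False
    gene: str | None = None
    effect: str | None = None

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.key()}: pos must be >= 1")
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"{self.key()}: unknown kind {self.kind!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"{self.key()}: unknown region class {self.region_class!r}"
            )
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError(f"{self.key()}: tumor_alt exceeds tumor_depth")
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(f"{self.key()}: normal_alt exceeds normal_depth")

    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the somatic filter cascade (defaults as documented)."""

    min_depth: int = 10
    max_normal_alt: int = 3  # normal_alt must be strictly below this
    min_tumor_alt: int = 3  # tumor_alt must be strictly above this
    min_gq: float = 40.0
    min_indel_reads: int = 4
    min_indel_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "max_normal_alt",
            "min_tumor_alt",
            "min_gq",
            "min_indel_reads",
            "min_indel_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    """Per-rule rejection audit; counts always conserve the input total."""

    n_input: int = 0
    n_passing: int = 0
    n_malformed: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )
    malformed_keys: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        rows = [("input", self.n_input)]
        rows += [(f"rejected_{rule}", self.rejected[rule]) for rule in RULE_ORDER]
        rows += [("malformed", self.n_malformed), ("passing", self.n_passing)]
        pd.DataFrame(rows, columns=["rule", "count"]).to_csv(
            path, sep="\t", index=False
        )


def first_failing_rule(v: VariantRecord, params: FilterParams) -> str | None:
    """Name of the first cascade rule ``v`` fails, or None if it passes."""
    if v.region_class not in ("exonic", "splice"):
        return "region"
    if v.tumor_depth < params.min_depth or v.normal_depth < params.min_depth:
        return "coverage"
    if not v.normal_alt < params.max_normal_alt:
        return "normal_alt"
    if not v.tumor_alt > params.min_tumor_alt:
        return "tumor_alt"
    if v.genotype_quality < params.min_gq:
        return "genotype_quality"
    if v.kind in ("insertion", "deletion"):
        if v.tumor_alt < params.min_indel_reads:
            return "indel_support"
        if v.tumor_depth == 0 or v.tumor_alt / v.tumor_depth < params.min_indel_fraction:
            return "indel_support"
    if v.in_germline_db and not v.in_cosmic:
        return "germline_db"
    return None


def apply_somatic_filters(
    variants: Iterable[VariantRecord],
    params: FilterParams | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the fixed-order cascade; return passing records and the audit.

    Malformed records (violating the type invariants, e.g. alt reads
    exceeding depth) are rejected outright and counted separately from the
    rule tallies.
    """
    params = params or FilterParams()
    report = FilterReport()
    passing: list[VariantRecord] = []
    for v in variants:
        report.n_input += 1
        try:
            v.validate()
        except ValueError:
            report.n_malformed += 1
            report.malformed_keys.append(v.key())
            continue
        rule = first_failing_rule(v, params)
        if rule is None:
            passing.append(v)
            report.n_passing += 1
        else:
            report.rejected[rule] += 1
    return passing, report


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion.

    Transitions swap within the purines {A, G} or within the pyrimidines
    {C, T}; every other substitution is a transversion. Raises for
    identical alleles or non-single-base input (indels have no
    transition/transversion class).
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("substitution classification requires single bases")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT allele in {ref}>{alt}")
    both = {ref, alt}
    if both <= _PURINES or both <= _PYRIMIDINES:
        return "transition"
    return "transversion"


_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "kind",
    "tumor_depth",
    "normal_depth",
    "tumor_alt",
    "normal_alt",
    "genotype_quality",
    "region_class",
    "in_germline_db",
    "in_cosmic",
    "gene",
    "effect",
]


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read the flat variant TSV (see ``write_variant_table`` for columns)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = set(_VARIANT_COLUMNS[:13]) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                kind=str(r.kind),
                tumor_depth=int(r.tumor_depth),
                normal_depth=int(r.normal_depth),
                tumor_alt=int(r.tumor_alt),
                normal_alt=int(r.normal_alt),
                genotype_quality=float(r.genotype_quality),
                region_class=str(r.region_class),
                in_germline_db=_as_bool(r.in_germline_db),
                in_cosmic=_as_bool(r.in_cosmic),
                gene=str(r.gene) if hasattr(r, "gene") and pd.notna(r.gene) else None,
                effect=str(r.effect)
                if hasattr(r, "effect") and pd.notna(r.effect)
                else None,
            )
        )
    return records


def write_variant_table(
    variants: Sequence[VariantRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "kind": v.kind,
                "tumor_depth": v.tumor_depth,
                "normal_depth": v.normal_depth,
                "tumor_alt": v.tumor_alt,
                "normal_alt": v.normal_alt,
                "genotype_quality": v.genotype_quality,
                "region_class": v.region_class,
                "in_germline_db": v.in_germline_db,
                "in_cosmic": v.in_cosmic,
                "gene": v.gene if v.gene is not None else "",
                "effect": v.effect if v.effect is not None else "",
            }
            for v in variants
        ],
        columns=_VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
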
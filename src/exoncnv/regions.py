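"""Capture-region bookkeeping: intervals, merging, GC content, high-GC exclusion.

Exome copy-number calling aggregates read depth over the capture design, so
the first stage of the pipeline normalises that design into a clean interval
set: overlapping (or book-ended) capture probes are merged into disjoint
regions, and regions whose sequence is GC-rich — CpG islands in particular —
are removed, because PCR amplification, hybrid capture and sequencing are all
biased at high GC and would contaminate the tumor:normal depth ratio.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "CaptureRegionSet",
    "ReferenceSequence",
    "ExclusionReport",
    "merge_capture_regions",
    "gc_fraction",
    "exclude_high_gc",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome) name; must be non-empty.
    start : int
        0-based inclusive start offset.
    end : int
        0-based exclusive end offset; must be > ``start``.
    name : str, optional
        Free-text label (gene name, probe id); ignored for ordering
        and equality.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bases(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CaptureRegionSet:
    """A sorted, disjoint collection of capture regions.

    Produced by :func:`merge_capture_regions`; ``total_bases`` equals the
    size of the per-base union of the member intervals.
    """

    intervals: tuple[GenomicInterval, ...]
    total_bases: int

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


class ReferenceSequence:
    """In-memory reference genome: a mapping of chrom name to an upper-case
    nucleotide string over ``{A, C, G, T, N}``.

    Use :meth:`from_fasta` to load a FASTA file (multi-record, wrapped
    lines are fine) or construct directly from a dict of strings.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequence":
        from pyfaidx import Fasta

        with Fasta(str(path)) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        """Return the bases covered by ``interval``, bounds-checked."""
        if interval.chrom not in self._seqs:
            raise KeyError(f"unknown chrom {interval.chrom!r}")
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise IndexError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chrom length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def merge_capture_regions(
    intervals: Iterable[GenomicInterval],
) -> CaptureRegionSet:
    """Merge capture intervals into their per-base union.

    Intervals sharing at least one base are merged; book-ended (touching)
    intervals are merged too, since capture probes tile contiguously.
    The result is sorted by ``(chrom, start)`` and disjoint.

    Parameters
    ----------
    intervals : iterable of GenomicInterval

    Returns
    -------
    CaptureRegionSet
        Sorted, disjoint union with ``total_bases`` set.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(
                    prev.chrom, prev.start, iv.end, prev.name
                )
        else:
            merged.append(iv)
    total = sum(len(iv) for iv in merged)
    return CaptureRegionSet(tuple(merged), total)


def gc_fraction(interval: GenomicInterval, ref: ReferenceSequence) -> float:
    """GC fraction of ``interval``: (#G + #C) / (#non-N bases).

    Returns ``nan`` when every base is N (undefined GC content).
    """
    seq = ref.fetch(interval)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_valid = int((arr != ord("N")).sum())
    if n_valid == 0:
        return float("nan")
    gc = int(((arr == ord("G")) | (arr == ord("C"))).sum())
    return gc / n_valid


@dataclass
class ExclusionReport:
    """Audit of :func:`exclude_high_gc`: which regions were removed and why.

    ``removed`` holds ``(interval, cause)`` pairs with cause in
    ``{"high_gc", "cpg_island"}``; a region failing both checks is
    attributed to ``high_gc`` (the check runs first).
    """

    removed: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = collections.Counter(cause for _, cause in self.removed)
        return {"high_gc": c.get("high_gc", 0), "cpg_island": c.get("cpg_island", 0)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tcause\n")
            for iv, cause in self.removed:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cause}\n")


def exclude_high_gc(
    regions: CaptureRegionSet,
    ref: ReferenceSequence,
    gc_threshold: float = 0.65,
    cpg_islands: Sequence[GenomicInterval] | None = None,
) -> tuple[CaptureRegionSet, ExclusionReport]:
    """Remove GC-rich regions and regions overlapping CpG islands.

    A region is removed when its :func:`gc_fraction` exceeds
    ``gc_threshold`` or when it overlaps any supplied CpG-island interval
    by at least one base. Regions whose GC is undefined (all N) are kept
    unless they hit an island.

    Parameters
    ----------
    regions : CaptureRegionSet
        Merged capture regions.
    ref : ReferenceSequence
    gc_threshold : float
        Maximum allowed GC fraction, in ``(0, 1]``. Default 0.65.
    cpg_islands : sequence of GenomicInterval, optional
        Island annotation (e.g. from a BED file); regions touching any
        island are excluded regardless of their own GC.

    Returns
    -------
    (CaptureRegionSet, ExclusionReport)
        Surviving regions and the per-cause audit.
    """
    if not (0.0 < gc_threshold <= 1.0):
        raise ValueError(f"gc_threshold must be in (0, 1], got {gc_threshold}")
    islands = list(cpg_islands) if cpg_islands else []
    kept: list[GenomicInterval] = []
    report = ExclusionReport()
    for iv in regions:
        gc = gc_fraction(iv, ref)
        if not np.isnan(gc) and gc > gc_threshold:
            report.removed.append((iv, "high_gc"))
            continue
        if any(iv.overlaps(isl) for isl in islands):
            report.removed.append((iv, "cpg_island"))
            continue
        kept.append(iv)
    total = sum(len(iv) for iv in kept)
    return CaptureRegionSet(tuple(kept), total), report


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 into a list of intervals (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = fields[3] if len(fields) > 3 else None
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (BED4 when a name is present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
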
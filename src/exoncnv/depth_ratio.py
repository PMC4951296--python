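"""Per-region tumor/normal depth collection and ratio computation.

The tumor:normal depth ratio r_j over a capture region is, in expectation,
proportional to the tumor copy state of that region once purity is accounted
for. This module turns a per-region depth table into a ratio series, dropping
regions whose normal coverage is too shallow to give a stable denominator.

Library-size normalization (rescaling ratios so that total tumor and normal
depth match) is OFF by default: the downstream mode-of-density ploidy rule
(modal ratio x 2 = overall ploidy) reads absolute tumor DNA content out of
the ratios, which rescaling would erase. Enable it only when the two
libraries were sequenced to clearly different depths and ploidy is supplied
externally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval

__all__ = [
    "DepthRecord",
    "RatioSeries",
    "compute_ratios",
    "read_depth_table",
    "write_depth_table",
    "write_ratio_table",
    "read_ratio_table",
]


@dataclass(frozen=True)
class DepthRecord:
    """Mean per-base coverage of one capture region in tumor and normal."""

    interval: GenomicInterval
    tumor_depth: float
    normal_depth: float

    def __post_init__(self) -> None:
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError(
                f"negative depth at {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )


@dataclass(frozen=True)
class RatioSeries:
    """Ordered per-region depth ratios r_j.

    Attributes
    ----------
    records : tuple of (GenomicInterval, float)
        Ratios in genomic order.
    n_excluded : int
        Regions dropped for insufficient normal depth.
    scale_factor : float
        Library-normalization multiplier applied to every ratio
        (1.0 when normalization is disabled).
    """

    records: tuple[tuple[GenomicInterval, float], ...]
    n_excluded: int
    scale_factor: float

    @property
    def values(self) -> np.ndarray:
        return np.array([r for _, r in self.records], dtype=float)

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(iv for iv, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)


def compute_ratios(
    depths: Iterable[DepthRecord],
    min_normal_depth: float = 10.0,
    normalize_libraries: bool = False,
) -> RatioSeries:
    """Compute r_j = scale x tumor_depth_j / normal_depth_j per region.

    Regions with ``normal_depth < min_normal_depth`` are dropped and
    counted in ``n_excluded``. Zero tumor depth yields ratio 0 (a legal
    value signalling deep deletion). With ``normalize_libraries`` the
    scale factor is (sum normal depth) / (sum tumor depth) over all input
    records, so equal-size libraries are unchanged.

    Raises
    ------
    ValueError
        If no region survives the normal-depth floor.
    """
    records = list(depths)
    scale = 1.0
    if normalize_libraries:
        tot_t = sum(d.tumor_depth for d in records)
        tot_n = sum(d.normal_depth for d in records)
        if tot_t <= 0:
            raise ValueError("cannot normalize: total tumor depth is zero")
        scale = tot_n / tot_t
    kept: list[tuple[GenomicInterval, float]] = []
    n_excluded = 0
    for d in records:
        if d.normal_depth < min_normal_depth:
            n_excluded += 1
            continue
        kept.append((d.interval, scale * d.tumor_depth / d.normal_depth))
    if not kept:
        raise ValueError(
            "no usable regions: every region fell below the normal-depth floor"
        )
    return RatioSeries(tuple(kept), n_excluded, scale)


def read_depth_table(path: str | Path) -> list[DepthRecord]:
    """Read a TSV with header ``chrom start end tumor_depth normal_depth``."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "tumor_depth", "normal_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return [
        DepthRecord(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            float(row.tumor_depth),
            float(row.normal_depth),
        )
        for row in df.itertuples(index=False)
    ]


def write_depth_table(records: Sequence[DepthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in records],
            "start": [d.interval.start for d in records],
            "end": [d.interval.end for d in records],
            "tumor_depth": [d.tumor_depth for d in records],
            "normal_depth": [d.normal_depth for d in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_ratio_table(series: RatioSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv, _ in series.records],
            "start": [iv.start for iv, _ in series.records],
            "end": [iv.end for iv, _ in series.records],
            "ratio": [r for _, r in series.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ratio_table(path: str | Path) -> RatioSeries:
    df = pd.read_csv(path, sep="\t")
    records = tuple(
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), float(r.ratio))
        for r in df.itertuples(index=False)
    )
    return RatioSeries(records, n_excluded=0, scale_factor=1.0)
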
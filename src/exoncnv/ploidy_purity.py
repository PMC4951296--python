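"""Ratio-density estimation, ploidy from the modal ratio, and purity correction.

Model
-----
A tumor sample is a mixture of malignant cells (fraction alpha, the purity)
and diploid normal cells (fraction 1 - alpha). For a region with tumor copy
number c, the expected tumor:normal depth ratio is

    r = (alpha * c + 2 * (1 - alpha)) / 2.

The most common copy state in the genome dominates the ratio distribution,
so the mode of a kernel-density estimate of the ratios anchors the overall
tumor ploidy: psi = 2 x modal ratio (a modal ratio of 1.05 implies ploidy
2.1). Inverting the admixture map converts each ratio into a continuous
copy number:

    c_j = (2 * r_j - 2 * (1 - alpha)) / alpha,

clipped below at zero because sampling noise can push ratios beneath the
contamination floor.

Purity is primarily a user input. As an optional extension,
:func:`estimate_purity_from_peaks` reads alpha off the density itself:
consecutive integer copy states are separated by alpha / 2 in ratio space,
so twice the median spacing between adjacent density peaks estimates alpha.
Resolving those peaks requires deep coverage — the per-region ratio noise
sd (about r * sqrt(2 / depth) near r = 1) must stay well under the peak
spacing alpha / 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal, stats

from .depth_ratio import RatioSeries
from .regions import GenomicInterval

__all__ = [
    "RatioDensity",
    "PloidyPurityModel",
    "CorrectedCopySeries",
    "estimate_density",
    "find_mode",
    "estimate_ploidy",
    "correct_copy_number",
    "estimate_purity_from_peaks",
    "MIN_RATIOS_FOR_DENSITY",
]

MIN_RATIOS_FOR_DENSITY = 30


@dataclass(frozen=True)
class RatioDensity:
    """Gaussian-kernel density of depth ratios on an even grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("density grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass(frozen=True)
class PloidyPurityModel:
    """Modal ratio, overall ploidy psi = 2 x mode, and purity alpha."""

    mode: float
    ploidy: float
    purity: float

    def __post_init__(self) -> None:
        if self.mode <= 0:
            raise ValueError("modal ratio must be positive")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    def to_json(self, path: str | Path, bandwidth: float | None = None) -> None:
        payload = {
            "mode": self.mode,
            "ploidy": self.ploidy,
            "purity": self.purity,
        }
        if bandwidth is not None:
            payload["bandwidth"] = bandwidth
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class CorrectedCopySeries:
    """Continuous per-region copy numbers aligned to the input ratio order."""

    intervals: tuple[GenomicInterval, ...]
    copy_number: np.ndarray
    purity: float

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.copy_number):
            raise ValueError("intervals and copy numbers must align")

    def __len__(self) -> int:
        return len(self.intervals)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, (3n/4)^(-1/5) x sample sd."""
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        # degenerate sample: fall back to a sliver of the value scale
        center = float(abs(values[0])) if n else 1.0
        return max(1e-3, 1e-2 * center)
    return (3.0 * n / 4.0) ** (-0.2) * sd


def estimate_density(
    ratios: RatioSeries,
    bandwidth: float | None = None,
    grid_points: int = 512,
) -> RatioDensity:
    """Gaussian KDE of the depth ratios on [0, max ratio + 3 x bandwidth].

    Bandwidth defaults to Silverman's rule; pass a value to override.
    Refuses series shorter than ``MIN_RATIOS_FOR_DENSITY`` — the mode of a
    density built from a handful of ratios is too unstable to anchor ploidy.
    """
    vals = ratios.values
    if len(vals) < MIN_RATIOS_FOR_DENSITY:
        raise ValueError(
            f"need >= {MIN_RATIOS_FOR_DENSITY} ratios for a reliable density "
            f"mode, got {len(vals)}"
        )
    h = float(bandwidth) if bandwidth is not None else silverman_bandwidth(vals)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, float(vals.max()) + 3.0 * h, grid_points)
    sd = float(np.std(vals, ddof=1))
    if sd > 0:
        kde = stats.gaussian_kde(vals, bw_method=h / sd)
        dens = kde(grid)
    else:
        # all ratios identical: evaluate the kernel sum directly
        dens = stats.norm.pdf(grid, loc=vals[0], scale=h)
    return RatioDensity(grid=grid, density=dens, bandwidth=h)


def find_mode(density: RatioDensity) -> float:
    """Grid value of the global density maximum (ties break to smaller ratio)."""
    return float(density.grid[int(np.argmax(density.density))])


def estimate_ploidy(mode: float) -> float:
    """Overall tumor ploidy from the modal ratio: psi = 2 x mode."""
    if mode <= 0:
        raise ValueError(f"modal ratio must be positive, got {mode}")
    return 2.0 * mode


def correct_copy_number(ratios: RatioSeries, purity: float) -> CorrectedCopySeries:
    """Invert the admixture map: c_j = (2 r_j - 2 (1 - alpha)) / alpha.

    Values are clipped below at 0; noise can push ratios under the
    contamination floor 1 - alpha, which would otherwise imply negative
    copy number.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    r = ratios.values
    c = (2.0 * r - 2.0 * (1.0 - purity)) / purity
    return CorrectedCopySeries(
        intervals=ratios.intervals,
        copy_number=np.clip(c, 0.0, None),
        purity=purity,
    )


def estimate_purity_from_peaks(
    density: RatioDensity,
    min_peak_fraction: float = 0.1,
) -> float | None:
    """Estimate purity from the spacing of ratio-density peaks.

    Local maxima at least ``min_peak_fraction`` of the global maximum are
    detected; adjacent integer copy states sit alpha / 2 apart in ratio
    space, so alpha-hat = 2 x median spacing of adjacent peaks (capped at
    1). Returns ``None`` when fewer than two peaks are found — a single
    peak carries no spacing information.

    This estimator goes beyond the core mode-to-ploidy rule; it assumes at
    least two integer copy states are common enough, and coverage deep
    enough, for their ratio clusters to resolve as separate peaks.
    """
    top = float(density.density.max())
    if top <= 0:
        return None
    peaks, _ = signal.find_peaks(
        density.density,
        height=min_peak_fraction * top,
        prominence=0.02 * top,
    )
    if len(peaks) < 2:
        return None
    spacings = np.diff(density.grid[peaks])
    return float(min(1.0, 2.0 * np.median(spacings)))


def write_density_table(density: RatioDensity, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame({"ratio": density.grid, "density": density.density}).to_csv(
        path, sep="\t", index=False
    )


def write_copy_number_table(
    cn: CorrectedCopySeries, ratios: RatioSeries, path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in cn.intervals],
            "start": [iv.start for iv in cn.intervals],
            "end": [iv.end for iv in cn.intervals],
            "ratio": ratios.values,
            "copy_number": cn.copy_number,
        }
    ).to_csv(path, sep="\t", index=False)


def read_copy_number_table(path: str | Path) -> CorrectedCopySeries:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    ivs = tuple(
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    )
    return CorrectedCopySeries(
        intervals=ivs,
        copy_number=df["copy_number"].to_numpy(dtype=float),
        purity=1.0,
    )
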
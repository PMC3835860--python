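"""Debris size-frequency spectra and ocean-coverage estimates.

Net-caught microplastic enters the spectrum with measured per-particle
cross-sectional areas; visually observed macrodebris enters through its
recorded longest dimension, treated as the diameter of a circle. The
spectrum reports, per area bin, the numeric density (items per m^2 of sea
surface) and the share of total cross-sectional area — numerically the
small particles dominate while the rare large items carry most of the
area. Coverage is the summed two-dimensional debris area as a percentage
of the sea-surface area surveyed; because visual size classes only bound
an item's diameter, coverage is reported as a (min, max) range built from
the class lower and upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SizeSpectrum",
    "SizeClassBounds",
    "circle_area",
    "build_spectrum",
    "coverage_percent",
    "class_bound_coverage",
]

CM2_PER_M2 = 1e4
M2_PER_KM2 = 1e6


@dataclass(frozen=True)
class SizeSpectrum:
    """Per-bin numeric density (m^-2) and fraction of total debris area."""

    area_bin_edges_cm2: np.ndarray
    numeric_density_per_m2: np.ndarray
    area_fraction: np.ndarray


@dataclass(frozen=True)
class SizeClassBounds:
    """Diameter bounds (cm) of the visual size classes.

    small 2-10 cm, medium 10-30 cm, large 30 cm up to a configurable cap
    (the large class is open-ended in the field protocol).
    """

    small: tuple[float, float] = (2.0, 10.0)
    medium: tuple[float, float] = (10.0, 30.0)
    large_cap_cm: float = 100.0

    def __post_init__(self) -> None:
        if self.large_cap_cm <= self.medium[1]:
            raise ValueError("large_cap_cm must exceed the medium upper bound")
        if not (self.small[0] < self.small[1] == self.medium[0] < self.medium[1]):
            raise ValueError("size classes must be contiguous and increasing")

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "small": self.small,
            "medium": self.medium,
            "large": (self.medium[1], self.large_cap_cm),
        }


def circle_area(diameter_cm: float) -> float:
    """Cross-sectional area (cm^2) of an item assumed circular."""
    d = np.asarray(diameter_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    out = np.pi * d**2 / 4.0
    return float(out) if out.ndim == 0 else out


def build_spectrum(
    micro_areas_cm2: Sequence[float],
    micro_densities_per_m2: Sequence[float],
    macro_diameters_cm: Sequence[float] = (),
    macro_densities_per_m2: Sequence[float] = (),
    bin_edges_cm2: Sequence[float] | None = None,
) -> SizeSpectrum:
    """Combined micro + macro size spectrum over cross-sectional area bins.

    Each item carries a numeric density weight (items m^-2, e.g. 1/area
    surveyed); macro items are converted to areas via ``circle_area``.
    Default bins are log-spaced over 1e-3 to 1e4 cm^2. Items outside the
    bin range are clipped into the end bins so density and area are
    conserved.
    """
    micro_areas = np.asarray(micro_areas_cm2, dtype=float)
    micro_dens = np.asarray(micro_densities_per_m2, dtype=float)
    macro_diam = np.asarray(macro_diameters_cm, dtype=float)
    macro_dens = np.asarray(macro_densities_per_m2, dtype=float)
    if micro_areas.shape != micro_dens.shape or macro_diam.shape != macro_dens.shape:
        raise ValueError("areas/diameters and densities must align")
    if np.any(micro_dens < 0) or np.any(macro_dens < 0):
        raise ValueError("densities must be >= 0")

    macro_areas = circle_area(macro_diam) if macro_diam.size else np.empty(0)
    areas = np.concatenate([micro_areas, macro_areas])
    dens = np.concatenate([micro_dens, macro_dens])

    if bin_edges_cm2 is None:
        edges = np.geomspace(1e-3, 1e4, 36)
    else:
        edges = np.asarray(bin_edges_cm2, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    idx = np.clip(np.searchsorted(edges, areas, side="right") - 1, 0, len(edges) - 2)
    nbins = len(edges) - 1
    numeric = np.bincount(idx, weights=dens, minlength=nbins)
    area_density = np.bincount(idx, weights=dens * areas, minlength=nbins)
    total_area = area_density.sum()
    frac = area_density / total_area if total_area > 0 else np.zeros(nbins)
    return SizeSpectrum(
        area_bin_edges_cm2=edges, numeric_density_per_m2=numeric, area_fraction=frac
    )


def coverage_percent(total_debris_area_m2: float, surveyed_area_km2: float) -> float:
    """Percent of sea surface physically covered by debris."""
    if surveyed_area_km2 <= 0:
        raise ValueError("surveyed_area_km2 must be > 0")
    if total_debris_area_m2 < 0:
        raise ValueError("total debris area must be >= 0")
    return 100.0 * total_debris_area_m2 / (surveyed_area_km2 * M2_PER_KM2)


def class_bound_coverage(
    counts_per_class: Mapping[str, int],
    bounds: SizeClassBounds,
    surveyed_km2: float,
) -> tuple[float, float]:
    """(min, max) coverage percent from size-class bounds.

    The minimum assumes every item sits at its class's lower-bound
    diameter, the maximum at its upper bound (the open large class uses
    the configurable cap); diameters convert to areas as circles.
    """
    class_bounds = bounds.bounds()
    unknown = set(counts_per_class) - set(class_bounds)
    if unknown:
        raise ValueError(f"unknown size classes: {sorted(unknown)}")
    lo_area = 0.0
    hi_area = 0.0
    for cls, count in counts_per_class.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        if count == 0:
            continue
        d_lo, d_hi = class_bounds[cls]
        lo_area += count * circle_area(d_lo) / CM2_PER_M2
        hi_area += count * circle_area(d_hi) / CM2_PER_M2
    return (
        coverage_percent(lo_area, surveyed_km2),
        coverage_percent(hi_area, surveyed_km2),
    )
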
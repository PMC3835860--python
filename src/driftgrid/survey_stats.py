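"""Concentration normalization, mass corrections, ratios, and rank statistics.

A manta net samples the two-dimensional air-sea interface, so
concentrations are preferentially expressed per square metre of sea
surface; when a volumetric form is needed the depth sampled is taken to be
the 0.2 m vertical dimension of the net opening. Zooplankton dry masses
are corrected upward by 20% for biomass lost to preservation, and the
plastic-to-plankton ratio (microplastic dry mass / zooplankton dry mass)
converts directly into the zooplankton bycatch of a hypothetical
neuston-filtering remediation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NET_DEPTH_M",
    "ZOOP_PRESERVATION_FACTOR",
    "RatioResult",
    "SummaryStats",
    "RankTestResults",
    "areal_concentration",
    "volumetric_concentration",
    "zoop_corrected_mass",
    "removal_equivalents",
    "summarize",
    "anomaly",
    "spearman_rho",
    "rank_tests",
    "theil_sen",
]

NET_DEPTH_M = 0.2
ZOOP_PRESERVATION_FACTOR = 1.20


@dataclass(frozen=True)
class RatioResult:
    """Removal equivalents implied by a plastic-to-plankton mass ratio."""

    ratio: float
    zoop_removed_mg_per_g: float
    carbon_removed_mg_per_g: float
    carbon_fraction: float


@dataclass(frozen=True)
class SummaryStats:
    """Median, tail percentiles, CV and a bootstrap CI for the median."""

    median: float
    p5: float
    p95: float
    cv_percent: float
    boot_ci_lo: float
    boot_ci_hi: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class RankTestResults:
    """Mann-Whitney (2 groups) or Kruskal-Wallis (k groups) with post-hoc."""

    statistic: float
    p_value: float
    test: str
    pairwise: tuple[PairwiseComparison, ...]


def areal_concentration(count: float, volume_m3: float) -> float:
    """Particles per square metre of sea surface.

    The area swept is volume / depth with depth fixed at 0.2 m, so the
    areal concentration is ``count / (volume_m3 / 0.2)``.
    """
    if volume_m3 <= 0:
        raise ValueError("volume_m3 must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (volume_m3 / NET_DEPTH_M)


def volumetric_concentration(count: float, volume_m3: float) -> float:
    """Particles per cubic metre filtered."""
    if volume_m3 <= 0:
        raise ValueError("volume_m3 must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / volume_m3


def zoop_corrected_mass(raw_mg: float) -> float:
    """Apply the +20% preservation-loss correction to a zooplankton dry mass."""
    if raw_mg < 0:
        raise ValueError("raw_mg must be >= 0")
    return raw_mg * ZOOP_PRESERVATION_FACTOR


def removal_equivalents(ratio: float, carbon_fraction: float = 0.40) -> RatioResult:
    """Zooplankton (and carbon) removed per gram of plastic filtered out.

    For each gram of plastic removed by surface filtration, 1000 / ratio
    milligrams of zooplankton dry biomass comes with it; the carbon
    equivalent assumes a fixed carbon content of zooplankton dry mass
    (default 0.40).
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if not 0 < carbon_fraction <= 1:
        raise ValueError("carbon_fraction must be in (0, 1]")
    zoop = 1000.0 / ratio
    return RatioResult(
        ratio=ratio,
        zoop_removed_mg_per_g=zoop,
        carbon_removed_mg_per_g=zoop * carbon_fraction,
        carbon_fraction=carbon_fraction,
    )


def summarize(
    values: Sequence[float], n_boot: int = 1000, seed: int = 0
) -> SummaryStats:
    """Median, 5th/95th percentiles, CV%, and a percentile-bootstrap CI.

    Percentiles use linear interpolation (type 7). The 95% CI is a
    percentile bootstrap of the median over ``n_boot`` resamples of the
    observations, seeded for reproducibility.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    med = float(np.median(x))
    p5, p95 = (float(v) for v in np.percentile(x, [5, 95]))
    mean = float(np.mean(x))
    cv = 100.0 * float(np.std(x, ddof=1)) / mean if x.size > 1 and mean != 0 else 0.0
    if x.size > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        boot_medians = np.median(x[idx], axis=1)
        lo, hi = (float(v) for v in np.percentile(boot_medians, [2.5, 97.5]))
    else:
        lo = hi = med
    return SummaryStats(
        median=med, p5=p5, p95=p95, cv_percent=cv, boot_ci_lo=lo, boot_ci_hi=hi,
        n=int(x.size),
    )


def anomaly(values: Sequence[float]) -> np.ndarray:
    """Deviation of each measurement from the series mean; sums to zero."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    return x - x.mean()


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def rank_tests(groups: dict[str, Sequence[float]], alpha: float = 0.05) -> RankTestResults:
    """Nonparametric location comparison across groups.

    Two groups: two-sided Mann-Whitney U (normal approximation with tie
    correction). Three or more: Kruskal-Wallis, followed by all pairwise
    two-sided rank-sum comparisons with Holm family-wise adjustment —
    the same decision structure as a Nemenyi-type post-hoc.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")

    names = list(arrays)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw_stats, raw_p = [], []
    for a, b in pairs:
        u, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided",
                                  method="asymptotic")
        raw_stats.append(float(u))
        raw_p.append(float(p))
    adjusted = multipletests(raw_p, alpha=alpha, method="holm")[1]
    pairwise = tuple(
        PairwiseComparison(a, b, s, p, float(padj))
        for (a, b), s, p, padj in zip(pairs, raw_stats, raw_p, adjusted)
    )

    if len(groups) == 2:
        return RankTestResults(
            statistic=raw_stats[0], p_value=raw_p[0], test="mann-whitney",
            pairwise=pairwise,
        )
    h, p = stats.kruskal(*arrays.values())
    return RankTestResults(
        statistic=float(h), p_value=float(p), test="kruskal-wallis", pairwise=pairwise
    )


def theil_sen(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Theil-Sen single-median line: median pairwise slope, median residual intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.all(x == x[0]):
        raise ValueError("need at least two distinct x values")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return float(slope), float(intercept)
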
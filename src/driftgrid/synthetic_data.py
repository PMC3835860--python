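"""Synthetic debris fields, net tows, particles, and visual sightings.

The generator emulates the statistical structure a surface-debris survey
produces: right-skewed (exponential) microplastic concentrations with
optional spatial autocorrelation along a 1-D cruise track, wind-suppressed
surface availability, Poisson particle counts per tow, exponential particle
cross-sectional areas, lognormal zooplankton biomass, and visually sighted
macrodebris whose perpendicular distances decay half-normally before being
recorded in seven pre-determined distance bins.

The spatial model is a Gaussian copula: a stationary Gaussian process with
squared-exponential correlation is normal-score transformed so the marginal
concentration is exactly exponential with the requested rate. Concentration
marginals are the only distributional feature a sparse tow survey pins
down, so the copula is a modelling stand-in, not an inference about the
ocean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FieldConfig",
    "SightingConfig",
    "TowRecord",
    "SightingRecord",
    "TransectSegment",
    "DISTANCE_BIN_EDGES_M",
    "SIZE_CLASSES",
    "COLOR_CLASSES",
    "SIZE_CLASS_DIAMETER_CM",
    "gaussian_process_track",
    "gen_concentrations",
    "gen_tows",
    "gen_sightings",
    "gen_particles",
]

# Closed distance-bin edges in metres; sightings past the last edge fall in
# the open ">600 m" bin, which is generated but flagged (detection at the
# horizon is not modelled).
DISTANCE_BIN_EDGES_M: tuple[float, ...] = (0.0, 10.0, 50.0, 100.0, 200.0, 300.0, 600.0)
SIZE_CLASSES: tuple[str, ...] = ("small", "medium", "large")
COLOR_CLASSES: tuple[str, ...] = ("white", "high-vis", "low-vis")
# Diameter ranges (cm) by size class; the open-ended large class is capped
# at 100 cm for simulation purposes.
SIZE_CLASS_DIAMETER_CM: dict[str, tuple[float, float]] = {
    "small": (2.0, 10.0),
    "medium": (10.0, 30.0),
    "large": (30.0, 100.0),
}

# Manta-net geometry: rectangular 0.86 x 0.2 m mouth towed ~900 m over
# ground, sampling the two-dimensional air-sea interface.
MANTA_WIDTH_M = 0.86
MANTA_DEPTH_M = 0.2
TOW_LENGTH_M = 900.0
TOW_AREA_M2 = MANTA_WIDTH_M * TOW_LENGTH_M
KM_PER_DEG_LAT = 111.19


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class FieldConfig:
    """Configuration of the synthetic surface-concentration field.

    Parameters
    ----------
    n_stations:
        Number of tows along the track (>= 2).
    track_spacing_km:
        Along-track distance between consecutive tows.
    marginal_rate:
        Rate of the exponential concentration marginal, in 1/(particles m^-2).
        Default 1.44, the maximum-likelihood rate of the combined survey data.
    spatial_range_km:
        Range of the squared-exponential latent correlation; 0 gives a pure
        nugget (white-noise) field.
    wind_mean_ms, wind_sd_ms:
        Mean and SD of per-tow true wind speed (m/s), truncated at 0.
    wind_decay_per_ms:
        Exponential decay of surface availability per m/s of wind above the
        mean; 0 disables the wind effect.
    seed:
        Seed for the generator's random stream.
    """

    n_stations: int = 119
    track_spacing_km: float = 90.0
    marginal_rate: float = 1.44
    spatial_range_km: float = 0.0
    wind_mean_ms: float = 5.0
    wind_sd_ms: float = 2.0
    wind_decay_per_ms: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marginal_rate <= 0:
            raise ConfigurationError("marginal_rate must be > 0")
        if self.spatial_range_km < 0:
            raise ConfigurationError("spatial_range_km must be >= 0")
        if self.n_stations < 2:
            raise ConfigurationError("n_stations must be >= 2")
        if self.track_spacing_km <= 0:
            raise ConfigurationError("track_spacing_km must be > 0")
        if self.wind_sd_ms < 0:
            raise ConfigurationError("wind_sd_ms must be >= 0")


def _default_densities() -> dict[tuple[str, str], float]:
    # Small debris numerically dominant; color split roughly even. Totals
    # give a few thousand sightings over ~1,300 km of transect, matching the
    # scale of a basin-crossing visual survey.
    by_size = {"small": 8.0, "medium": 3.0, "large": 1.0}
    by_color = {"white": 0.3, "high-vis": 0.3, "low-vis": 0.4}
    return {
        (s, c): by_size[s] * by_color[c] for s in SIZE_CLASSES for c in COLOR_CLASSES
    }


def _default_sigmas() -> dict[tuple[str, str], float]:
    # Larger and brighter objects are detectable farther out.
    by_size = {"small": 80.0, "medium": 160.0, "large": 300.0}
    by_color = {"white": 1.0, "high-vis": 1.2, "low-vis": 0.8}
    return {
        (s, c): by_size[s] * by_color[c] for s in SIZE_CLASSES for c in COLOR_CLASSES
    }


@dataclass(frozen=True)
class SightingConfig:
    """Configuration of the synthetic visual-observation survey.

    ``true_density_per_km2`` and ``hn_sigma_m`` are keyed by
    (size class, color class); ``hn_sigma_m`` is the half-normal detection
    scale. Transect geometry is one-sided. Items are generated out to
    ``horizon_m``; those past the last closed bin edge land in the open
    ">600 m" bin and are flagged.
    """

    true_density_per_km2: dict[tuple[str, str], float] = field(
        default_factory=_default_densities
    )
    hn_sigma_m: dict[tuple[str, str], float] = field(default_factory=_default_sigmas)
    segment_lengths_km: Sequence[float] = field(default_factory=lambda: (50.0,) * 26)
    distance_bin_edges_m: Sequence[float] = DISTANCE_BIN_EDGES_M
    horizon_m: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segment_lengths_km:
            raise ConfigurationError("segment_lengths_km must be non-empty")
        if any(length <= 0 for length in self.segment_lengths_km):
            raise ConfigurationError("segment lengths must be > 0")
        edges = np.asarray(self.distance_bin_edges_m, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("distance_bin_edges_m must be strictly increasing")
        for group, density in self.true_density_per_km2.items():
            if density < 0:
                raise ConfigurationError(f"density for {group} must be >= 0")
        for group, sigma in self.hn_sigma_m.items():
            if sigma <= 0:
                raise ConfigurationError(f"sigma for {group} must be > 0")
        if self.horizon_m < edges[-1]:
            raise ConfigurationError("horizon_m must reach the last bin edge")


@dataclass(frozen=True)
class TowRecord:
    """One surface (manta) net tow."""

    tow_id: str
    lat: float
    lon: float
    gear: str
    volume_m3: float
    count: int
    plastic_dry_mg: float
    zoop_dry_mg_raw: float
    wind_ms: float
    region: str
    diel: str


@dataclass(frozen=True)
class SightingRecord:
    """One visually detected debris item, distance recorded only by bin."""

    sighting_id: str
    segment_id: str
    size_class: str
    color_class: str
    bin_index: int
    bin_label: str
    diameter_cm: float
    beyond_truncation: bool


@dataclass(frozen=True)
class TransectSegment:
    """One surveyed track segment."""

    segment_id: str
    length_km: float


def gaussian_process_track(
    positions_km: np.ndarray, range_km: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a zero-mean, unit-variance stationary GP on a 1-D track.

    Correlation is squared-exponential, corr(d) = exp(-(d/range)^2); a
    range of 0 degenerates to white noise. The implied semivariogram is
    gamma(h) = 1 - exp(-(h/range)^2), the "Gaussian" variogram model with
    range parameter ``range_km``.
    """
    positions_km = np.asarray(positions_km, dtype=float)
    n = len(positions_km)
    if range_km == 0:
        return rng.standard_normal(n)
    d = np.abs(positions_km[:, None] - positions_km[None, :])
    cov = np.exp(-((d / range_km) ** 2))
    cov[np.diag_indices_from(cov)] += 1e-10  # jitter for Cholesky
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def _regions(n: int) -> list[str]:
    # Eastern third California Current, middle transition, western gyre --
    # a coarse sketch of a coast-to-gyre track.
    thirds = np.array_split(np.arange(n), 3)
    labels = ["CC", "TR", "NPSG"]
    out = [""] * n
    for label, idx in zip(labels, thirds):
        for i in idx:
            out[i] = label
    return out


def _field(
    config: FieldConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent true concentrations, winds, and wind-suppressed concentrations."""
    n = config.n_stations
    positions_km = np.arange(n) * config.track_spacing_km
    z = gaussian_process_track(positions_km, config.spatial_range_km, rng)
    u = stats.norm.cdf(z)
    # Clip away the copula tails so the exponential quantile stays finite.
    u = np.clip(u, 1e-12, 1 - 1e-12)
    conc_true = stats.expon.ppf(u, scale=1.0 / config.marginal_rate)
    wind = np.maximum(0.0, rng.normal(config.wind_mean_ms, config.wind_sd_ms, n))
    suppression = np.exp(
        -config.wind_decay_per_ms * np.maximum(0.0, wind - config.wind_mean_ms)
    )
    return conc_true, wind, conc_true * suppression


def gen_concentrations(config: FieldConfig) -> np.ndarray:
    """Observed (wind-suppressed) surface concentrations, particles m^-2.

    The same field ``gen_tows`` builds, before the Poisson count layer —
    useful for checking the marginal distribution directly.
    """
    return _field(config, np.random.default_rng(config.seed))[2]


def gen_tows(config: FieldConfig) -> list[TowRecord]:
    """Generate surface tows along a 1-D track.

    The latent log-field is a stationary GP with squared-exponential
    correlation, normal-score transformed so the marginal true
    concentration is exponential(``marginal_rate``). The observed
    concentration is suppressed by wind above the mean,
    ``latent * exp(-wind_decay_per_ms * max(0, wind - wind_mean))``,
    and particle counts are Poisson given concentration x tow area.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stations
    positions_km = np.arange(n) * config.track_spacing_km
    _, wind, conc_obs = _field(config, rng)

    counts = rng.poisson(conc_obs * TOW_AREA_M2)
    # Per-particle dry mass ~ Exp(1 mg): tow plastic mass is a Gamma(count)
    # sum, zero when the tow caught nothing.
    plastic_mg = np.where(counts > 0, rng.gamma(np.maximum(counts, 1), 1.0), 0.0)
    # Zooplankton dry biomass per tow: lognormal, median ~300 mg.
    zoop_mg = rng.lognormal(mean=np.log(300.0), sigma=0.8, size=n)

    lat0 = 32.0
    lons = -125.0 - positions_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat0)))
    regions = _regions(n)
    diel_cycle = ("N", "D", "D", "C")  # tows every 6 h: 0300/0900/1500/2100

    volume = TOW_AREA_M2 * MANTA_DEPTH_M
    return [
        TowRecord(
            tow_id=f"T{i:04d}",
            lat=lat0,
            lon=float(lons[i]),
            gear="manta",
            volume_m3=volume,
            count=int(counts[i]),
            plastic_dry_mg=float(plastic_mg[i]),
            zoop_dry_mg_raw=float(zoop_mg[i]),
            wind_ms=float(wind[i]),
            region=regions[i],
            diel=diel_cycle[i % 4],
        )
        for i in range(n)
    ]


def bin_label(edges: Sequence[float], index: int) -> str:
    """Categorical label for a distance bin; the last index is open-ended."""
    edges = list(edges)
    if index < len(edges) - 1:
        return f"{edges[index]:g}-{edges[index + 1]:g}"
    return f">{edges[-1]:g}"


def gen_sightings(
    config: SightingConfig,
) -> tuple[list[SightingRecord], list[TransectSegment]]:
    """Generate a one-sided visual transect survey.

    Per group and segment, the number of items present out to the horizon
    is Poisson(density x segment length x horizon width); perpendicular
    distances are uniform, and each item is detected with half-normal
    probability g(x) = exp(-x^2 / (2 sigma^2)). Detected items are binned;
    those beyond the last closed edge are flagged ``beyond_truncation``.
    """
    rng = np.random.default_rng(config.seed)
    edges = np.asarray(config.distance_bin_edges_m, dtype=float)
    horizon_km = config.horizon_m / 1000.0

    segments = [
        TransectSegment(segment_id=f"S{i:03d}", length_km=float(length))
        for i, length in enumerate(config.segment_lengths_km)
    ]

    sightings: list[SightingRecord] = []
    counter = 0
    for seg in segments:
        for (size_class, color_class), density in sorted(
            config.true_density_per_km2.items()
        ):
            sigma = config.hn_sigma_m[(size_class, color_class)]
            n_true = rng.poisson(density * seg.length_km * horizon_km)
            if n_true == 0:
                continue
            x = rng.uniform(0.0, config.horizon_m, n_true)
            detected = rng.uniform(size=n_true) < np.exp(-(x**2) / (2 * sigma**2))
            lo, hi = SIZE_CLASS_DIAMETER_CM[size_class]
            for xi in x[detected]:
                idx = min(int(np.searchsorted(edges, xi, side="right")) - 1, len(edges) - 1)
                beyond = xi >= edges[-1]
                sightings.append(
                    SightingRecord(
                        sighting_id=f"V{counter:05d}",
                        segment_id=seg.segment_id,
                        size_class=size_class,
                        color_class=color_class,
                        bin_index=idx,
                        bin_label=bin_label(edges, idx),
                        diameter_cm=float(rng.uniform(lo, hi)),
                        beyond_truncation=bool(beyond),
                    )
                )
                counter += 1
    return sightings, segments


def gen_particles(n: int, area_rate_per_cm2: float = 100.0, seed: int = 0) -> np.ndarray:
    """Exponential particle cross-sectional areas (cm^2).

    The default rate of 100 cm^-2 puts the modal histogram bin at the
    smallest sizes with mean area 0.01 cm^2, the scale at which net-caught
    microplastic is most abundant.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if area_rate_per_cm2 <= 0:
        raise ValueError("area_rate_per_cm2 must be > 0")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / area_rate_per_cm2, size=n)
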
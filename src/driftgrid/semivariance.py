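"""Empirical semivariograms and variogram-model fitting.

The semivariogram gamma(h) describes how half the expected squared
difference between measurements grows with their separation h; a sill
marks the distance beyond which pairs are no longer correlated. Because
surface-debris concentrations are strongly right-skewed, the classical
moment estimator is complemented by the Cressie-Hawkins robust estimator,
which averages |z_i - z_j|^(1/2) before raising to the fourth power and
applying a bias-correcting denominator.

Coordinates are geographic; pairwise separations are great-circle
(haversine) distances on a sphere of radius 6371 km. Fitted families are
a straight line gamma(h) = a + b h (slope may be negative — a diagnostic
of an artifact-prone variogram rather than a valid spatial model) and the
Gaussian model gamma(h) = tau2 + sigma2 (1 - exp(-(h/phi)^2)), whose
practical range (where gamma reaches ~95% of the sill) is phi * sqrt(3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EARTH_RADIUS_KM",
    "SpatialSample",
    "Semivariogram",
    "VariogramModel",
    "pairwise_distances",
    "empirical_semivariogram",
    "fit_variogram",
    "gaussian_model",
]

EARTH_RADIUS_KM = 6371.0

Estimator = Literal["classical", "robust"]
Family = Literal["linear", "gaussian"]


@dataclass(frozen=True)
class SpatialSample:
    """Geo-referenced measurements: (lat, lon) in decimal degrees plus values."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "values", values)
        if not (lats.shape == lons.shape == values.shape) or lats.ndim != 1:
            raise ValueError("lats, lons, values must be equal-length 1-D arrays")
        if lats.size < 2:
            raise ValueError("need at least 2 points")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(np.abs(lats) > 90) or np.any(np.abs(lons) > 360):
            raise ValueError("invalid coordinates")


@dataclass(frozen=True)
class Semivariogram:
    """Binned empirical semivariance with pair counts."""

    bin_centers_km: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    estimator: str


@dataclass(frozen=True)
class VariogramModel:
    """A fitted variogram model.

    Gaussian: nugget tau2, partial sill sigma2, range phi (practical range
    phi*sqrt(3)). Linear: intercept and slope. ``objective`` is the
    weighted sum of squared residuals at the optimum.
    """

    family: str
    nugget: float | None = None
    partial_sill: float | None = None
    range_phi: float | None = None
    slope: float | None = None
    intercept: float | None = None
    objective: float = np.nan

    @property
    def practical_range_km(self) -> float | None:
        if self.range_phi is None:
            return None
        return self.range_phi * np.sqrt(3.0)

    def predict(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "linear":
            return self.intercept + self.slope * h
        return gaussian_model(h, self.nugget, self.partial_sill, self.range_phi)


def gaussian_model(h: np.ndarray, nugget: float, partial_sill: float, phi: float) -> np.ndarray:
    """gamma(h) = tau2 + sigma2 (1 - exp(-(h/phi)^2))."""
    h = np.asarray(h, dtype=float)
    return nugget + partial_sill * (1.0 - np.exp(-((h / phi) ** 2)))


def _haversine_matrix(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    lat = np.radians(lats)
    lon = np.radians(lons)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances(sample: SpatialSample) -> np.ndarray:
    """Great-circle distances (km) for all unordered pairs, condensed order."""
    full = _haversine_matrix(sample.lats, sample.lons)
    iu = np.triu_indices(len(sample.lats), k=1)
    return full[iu]


def empirical_semivariogram(
    sample: SpatialSample,
    bin_edges_km: Sequence[float] | None = None,
    estimator: Estimator = "robust",
    n_bins: int = 15,
) -> Semivariogram:
    """Binned empirical semivariogram.

    Classical: gamma(h) = (1 / 2|N(h)|) * sum (z_i - z_j)^2.
    Robust (Cressie-Hawkins):
    gamma(h) = (mean |z_i - z_j|^(1/2))^4 / (2 (0.457 + 0.494/|N(h)|)).

    Default binning is ``n_bins`` equal-width bins from 0 to half the
    maximum pairwise distance; bins holding no pairs are omitted.
    """
    if estimator not in ("classical", "robust"):
        raise ValueError("estimator must be 'classical' or 'robust'")
    d = pairwise_distances(sample)
    iu = np.triu_indices(len(sample.values), k=1)
    diff = np.abs(sample.values[iu[0]] - sample.values[iu[1]])

    if bin_edges_km is None:
        max_h = d.max() / 2.0
        if max_h <= 0:
            raise ValueError("all points are coincident; cannot bin distances")
        edges = np.linspace(0.0, max_h, n_bins + 1)
    else:
        edges = np.asarray(bin_edges_km, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges_km must be strictly increasing")

    which = np.searchsorted(edges, d, side="right") - 1
    # include pairs exactly at the top edge in the last bin
    which[d == edges[-1]] = len(edges) - 2
    valid = (which >= 0) & (which < len(edges) - 1)

    centers, gammas, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = valid & (which == b)
        m = int(mask.sum())
        if m == 0:
            continue
        dd = diff[mask]
        if estimator == "classical":
            g = float(np.sum(dd**2) / (2.0 * m))
        else:
            g = float(np.mean(np.sqrt(dd)) ** 4 / (2.0 * (0.457 + 0.494 / m)))
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(g)
        counts.append(m)
    if not gammas:
        raise ValueError("no pairs fall within the given bin edges")
    return Semivariogram(
        bin_centers_km=np.asarray(centers),
        gamma=np.asarray(gammas),
        pair_counts=np.asarray(counts),
        estimator=estimator,
    )


def fit_variogram(emp: Semivariogram, family: Family = "gaussian") -> VariogramModel:
    """Weighted least-squares variogram-model fit (weights = pair counts).

    The Gaussian fit is multi-started over a log-spaced grid of range
    values to avoid local minima; parameters are bounded non-negative
    (phi > 0).
    """
    h = np.asarray(emp.bin_centers_km, dtype=float)
    g = np.asarray(emp.gamma, dtype=float)
    w = np.sqrt(np.asarray(emp.pair_counts, dtype=float))

    if family == "linear":
        if len(h) < 3:
            raise ValueError("linear fit needs >= 3 bins")
        slope, intercept = np.polyfit(h, g, 1, w=w)
        resid = w * (intercept + slope * h - g)
        return VariogramModel(
            family="linear", slope=float(slope), intercept=float(intercept),
            objective=float(np.sum(resid**2)),
        )
    if family != "gaussian":
        raise ValueError("family must be 'linear' or 'gaussian'")
    if len(h) < 4:
        raise ValueError("gaussian fit needs >= 4 bins")

    sill0 = max(g.max(), 1e-12)
    hmax = h.max()

    def residuals(params: np.ndarray) -> np.ndarray:
        nugget, psill, phi = params
        return w * (gaussian_model(h, nugget, psill, phi) - g)

    best = None
    for phi0 in np.geomspace(0.05 * hmax, 2.0 * hmax, 8):
        try:
            sol = least_squares(
                residuals,
                x0=[0.1 * sill0, sill0, phi0],
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=1e-8, ftol=1e-8, gtol=1e-8,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            "gaussian variogram fit failed to converge from all starts; "
            f"bins={len(h)}, gamma range=({g.min():.3g}, {g.max():.3g})"
        )
    nugget, psill, phi = best.x
    return VariogramModel(
        family="gaussian", nugget=float(nugget), partial_sill=float(psill),
        range_phi=float(phi), objective=float(2 * best.cost),
    )
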
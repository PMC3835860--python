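"""Semivariogram estimators and variogram-model fitting."""

import numpy as np
import pytest

from driftgrid.semivariance import (
    SpatialSample,
    Semivariogram,
    empirical_semivariogram,
    fit_variogram,
    gaussian_model,
    pairwise_distances,
)

# Cressie-Hawkins denominator constant for a single pair
CH_ONE_PAIR = 2.0 * (0.457 + 0.494)


def _track_sample(values, spacing_km=10.0, lat=30.0):
    n = len(values)
    km_per_deg = 111.19 * np.cos(np.radians(lat))
    lons = np.arange(n) * spacing_km / km_per_deg
    return SpatialSample(lats=np.full(n, lat), lons=lons, values=np.asarray(values))


def test_pairwise_distances_basic():
    s = SpatialSample(lats=np.array([0.0, 0.0]), lons=np.array([0.0, 1.0]),
                      values=np.array([0.0, 1.0]))
    d = pairwise_distances(s)
    # one degree of longitude at the equator: 2 pi R / 360
    assert d[0] == pytest.approx(2 * np.pi * 6371.0 / 360.0, abs=0.01)

    same = SpatialSample(lats=np.array([10.0, 10.0]), lons=np.array([20.0, 20.0]),
                         values=np.array([1.0, 2.0]))
    assert pairwise_distances(same)[0] == pytest.approx(0.0, abs=1e-9)


def test_pairwise_distance_symmetry():
    rng = np.random.default_rng(0)
    lats, lons = rng.uniform(-60, 60, 5), rng.uniform(-180, 180, 5)
    a = SpatialSample(lats=lats, lons=lons, values=np.zeros(5))
    b = SpatialSample(lats=lats[::-1], lons=lons[::-1], values=np.zeros(5))
    assert np.allclose(sorted(pairwise_distances(a)), sorted(pairwise_distances(b)))


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        SpatialSample(lats=np.array([95.0, 0.0]), lons=np.array([0.0, 1.0]),
                      values=np.array([0.0, 1.0]))


def test_two_point_worked_examples():
    """z = {0, 1} in a single bin: classical 0.5, robust 1/(2(0.457+0.494))."""
    s = _track_sample([0.0, 1.0])
    edges = [0.0, 20.0]
    classical = empirical_semivariogram(s, edges, "classical")
    assert classical.gamma[0] == pytest.approx(0.5)
    robust = empirical_semivariogram(s, edges, "robust")
    assert robust.gamma[0] == pytest.approx(1.0 / CH_ONE_PAIR)
    assert robust.gamma[0] == pytest.approx(0.5257, abs=2e-4)
    assert classical.pair_counts[0] == 1


def test_constant_field_zero_gamma():
    s = _track_sample(np.full(20, 3.7))
    for est in ("classical", "robust"):
        emp = empirical_semivariogram(s, estimator=est)
        assert np.allclose(emp.gamma, 0.0)


def test_pair_count_budget():
    n = 25
    s = _track_sample(np.random.default_rng(1).normal(size=n))
    emp = empirical_semivariogram(s, estimator="classical")
    assert emp.pair_counts.sum() <= n * (n - 1) / 2
    assert np.all(emp.pair_counts >= 1)
    assert np.all(emp.gamma >= 0)


def test_quadratic_scale_equivariance():
    """Doubling z multiplies gamma by 4 for both estimators."""
    rng = np.random.default_rng(2)
    z = rng.exponential(size=40)
    s1, s2 = _track_sample(z), _track_sample(2 * z)
    for est, tol in (("classical", 1e-12), ("robust", 1e-9)):
        g1 = empirical_semivariogram(s1, estimator=est).gamma
        g2 = empirical_semivariogram(s2, estimator=est).gamma
        np.testing.assert_allclose(g2, 4.0 * g1, rtol=max(tol, 1e-9))


def test_white_noise_flat_near_variance():
    """Nugget-only data: gamma is flat and averages near the sample variance."""
    rng = np.random.default_rng(3)
    z = rng.normal(size=400)
    emp = empirical_semivariogram(_track_sample(z), estimator="classical")
    var = z.var(ddof=1)
    assert abs(np.average(emp.gamma, weights=emp.pair_counts) - var) < 0.15 * var
    assert emp.gamma.max() - emp.gamma.min() < 0.6 * var


def test_robust_close_to_classical_on_gaussian():
    """On large Gaussian samples the two estimators agree within 15%."""
    rng = np.random.default_rng(4)
    z = rng.normal(size=600)
    s = _track_sample(z)
    edges = np.linspace(0, 1500, 8)
    gc = empirical_semivariogram(s, edges, "classical").gamma
    gr = empirical_semivariogram(s, edges, "robust").gamma
    assert np.all(np.abs(gr - gc) / gc < 0.15)


def test_robust_resists_outlier_better():
    """A single outlier perturbs the robust estimate less than the classical."""
    rng = np.random.default_rng(5)
    z = rng.normal(size=200)
    z_out = z.copy()
    z_out[50] += 30.0
    edges = np.linspace(0, 1000, 6)
    base_c = empirical_semivariogram(_track_sample(z), edges, "classical").gamma
    base_r = empirical_semivariogram(_track_sample(z), edges, "robust").gamma
    out_c = empirical_semivariogram(_track_sample(z_out), edges, "classical").gamma
    out_r = empirical_semivariogram(_track_sample(z_out), edges, "robust").gamma
    dev_c = np.abs(out_c - base_c) / base_c
    dev_r = np.abs(out_r - base_r) / base_r
    assert dev_r.mean() < dev_c.mean()


def test_linear_fit_recovers_exact_line():
    h = np.linspace(10, 100, 6)
    emp = Semivariogram(bin_centers_km=h, gamma=1.5 - 0.002 * h,
                        pair_counts=np.full(6, 20), estimator="classical")
    fit = fit_variogram(emp, "linear")
    assert fit.slope == pytest.approx(-0.002, abs=1e-9)
    assert fit.intercept == pytest.approx(1.5, abs=1e-7)


def test_gaussian_fit_self_inverse():
    """Noise-free points from a known Gaussian model are recovered within 1%."""
    nugget, psill, phi = 0.2, 1.3, 45.0
    h = np.linspace(5, 200, 12)
    emp = Semivariogram(bin_centers_km=h, gamma=gaussian_model(h, nugget, psill, phi),
                        pair_counts=np.full(12, 50), estimator="classical")
    fit = fit_variogram(emp, "gaussian")
    assert fit.nugget == pytest.approx(nugget, rel=0.01, abs=0.005)
    assert fit.partial_sill == pytest.approx(psill, rel=0.01)
    assert fit.range_phi == pytest.approx(phi, rel=0.01)
    assert fit.practical_range_km == pytest.approx(phi * np.sqrt(3), rel=0.01)


def test_fit_requires_enough_bins():
    h = np.array([10.0, 20.0, 30.0])
    emp = Semivariogram(bin_centers_km=h, gamma=np.ones(3),
                        pair_counts=np.ones(3, dtype=int), estimator="classical")
    with pytest.raises(ValueError):
        fit_variogram(emp, "gaussian")
    fit_variogram(emp, "linear")  # 3 bins suffice for the line
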
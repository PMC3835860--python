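"""Detection-function fitting, ESW, correction factors, densities."""

import numpy as np
import pytest
from scipy import stats

from driftgrid.distance_sampling import (
    BinnedDistances,
    bootstrap_density_ci,
    densities,
    esw,
    fit_detection,
    half_normal_esw,
    pool_sparse_groups,
    select_by_aic,
)
from driftgrid.synthetic_data import DISTANCE_BIN_EDGES_M, SightingConfig, gen_sightings

EDGES = np.asarray(DISTANCE_BIN_EDGES_M)
W = 600.0


def _simulate_halfnormal_counts(sigma, n, seed):
    """Bin counts from true half-normal perpendicular distances within W."""
    rng = np.random.default_rng(seed)
    x = np.abs(rng.normal(0.0, sigma, size=4 * n))
    x = x[x <= W][:n]
    counts, _ = np.histogram(x, bins=EDGES)
    return counts


def test_uniform_fit_closed_form_loglik():
    counts = np.array([5, 20, 25, 50, 50, 150])
    binned = BinnedDistances(EDGES, counts)
    fit = fit_detection(binned, "uniform", W)
    widths = np.diff(EDGES)
    expected = float(np.sum(counts * np.log(widths / W)))
    assert fit.loglik == pytest.approx(expected, rel=1e-12)
    assert fit.aic == pytest.approx(-2 * expected)
    assert fit.esw_m == pytest.approx(W, rel=1e-8)


def test_half_normal_parameter_recovery():
    """sigma recovered within 10% from binned counts at n = 2000."""
    sigma_true = 150.0
    errs = []
    for seed in range(5):
        counts = _simulate_halfnormal_counts(sigma_true, 2000, seed)
        fit = fit_detection(BinnedDistances(EDGES, counts), "half_normal", W)
        errs.append(abs(fit.params[0] - sigma_true) / sigma_true)
    assert np.median(errs) < 0.10
    assert max(errs) < 0.15


def test_esw_closed_form_vs_quadrature():
    """Half-normal ESW = sigma sqrt(pi/2) erf(W / sigma sqrt(2))."""
    for sigma in (50.0, 100.0, 300.0):
        counts = _simulate_halfnormal_counts(sigma, 1500, 1)
        fit = fit_detection(BinnedDistances(EDGES, counts), "half_normal", W)
        sigma_hat = fit.params[0]
        assert fit.esw_m == pytest.approx(half_normal_esw(sigma_hat, W), abs=1e-6)
    assert half_normal_esw(100.0, 600.0) == pytest.approx(125.33, abs=0.01)


def test_esw_monotone_in_sigma():
    esws = [half_normal_esw(s, W) for s in (50, 100, 200, 400, 800)]
    assert np.all(np.diff(esws) > 0)
    assert all(0 < e <= W for e in esws)


def test_aic_prefers_generating_family():
    """Model selection picks the right family at n = 5000 over 20 seeds."""
    hits_uniform, hits_hn = 0, 0
    rng_master = np.random.default_rng(100)
    for _ in range(20):
        seed = int(rng_master.integers(2**31))
        # uniform truth
        x = np.random.default_rng(seed).uniform(0, W, 5000)
        counts_u, _ = np.histogram(x, bins=EDGES)
        fits = [fit_detection(BinnedDistances(EDGES, counts_u), fam, W, seed=seed)
                for fam in ("uniform", "half_normal")]
        if select_by_aic(fits).family == "uniform":
            hits_uniform += 1
        # half-normal truth, sigma = 120 m
        counts_h = _simulate_halfnormal_counts(120.0, 5000, seed)
        fits = [fit_detection(BinnedDistances(EDGES, counts_h), fam, W, seed=seed)
                for fam in ("uniform", "half_normal")]
        if select_by_aic(fits).family == "half_normal":
            hits_hn += 1
    assert hits_uniform >= 19
    assert hits_hn == 20


def test_hazard_rate_fit_runs_and_is_plausible():
    counts = _simulate_halfnormal_counts(150.0, 3000, 7)
    fit = fit_detection(BinnedDistances(EDGES, counts), "hazard_rate", W, seed=7)
    assert np.isfinite(fit.loglik)
    assert 0 < fit.esw_m <= W
    assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)


def test_fit_requires_enough_sightings_and_flags_degenerate():
    with pytest.raises(ValueError):
        fit_detection(BinnedDistances(EDGES, [1, 0, 0, 2, 0, 1]), "half_normal", W)
    fit = fit_detection(BinnedDistances(EDGES, [50, 0, 0, 0, 0, 0]), "half_normal", W)
    assert fit.degenerate


def test_densities_corrections():
    counts = _simulate_halfnormal_counts(100.0, 1000, 3)
    fit_narrow = fit_detection(BinnedDistances(EDGES, counts), "half_normal", W)
    # same ESW in every group -> CF = 1
    same = densities({"a": fit_narrow, "b": fit_narrow}, {"a": 100, "b": 50}, 10.0)
    for gd in same:
        assert gd.correction_factor == pytest.approx(1.0)

    counts_wide = _simulate_halfnormal_counts(200.0, 1000, 3)
    fit_wide = fit_detection(BinnedDistances(EDGES, counts_wide), "half_normal", W)
    two = {g.group: g for g in densities(
        {"n": fit_narrow, "w": fit_wide}, {"n": 100, "w": 100}, 10.0)}
    ratio = fit_wide.esw_m / fit_narrow.esw_m
    assert two["n"].correction_factor == pytest.approx(ratio)
    assert two["w"].correction_factor == pytest.approx(1.0)
    # density_g = n_g / (L * ESW_g) algebraically
    assert two["n"].density_per_km2 == pytest.approx(
        100 / (10.0 * fit_narrow.esw_m / 1000.0)
    )


def test_uniform_detection_reduces_to_naive_density():
    """Under uniform detection the density is exactly count / (L x W)."""
    counts = np.array([10, 40, 50, 100, 100, 300])
    fit = fit_detection(BinnedDistances(EDGES, counts), "uniform", W)
    (gd,) = densities({"all": fit}, {"all": int(counts.sum())}, 25.0)
    assert gd.density_per_km2 == pytest.approx(counts.sum() / (25.0 * W / 1000.0))
    assert gd.correction_factor == pytest.approx(1.0)


def test_pool_sparse_groups():
    counts = {
        ("small", "white"): np.array([5, 20, 10, 5, 3, 2]),
        ("small", "low-vis"): np.array([1, 2, 0, 0, 0, 0]),
        ("large", "white"): np.array([0, 1, 0, 1, 0, 0]),
    }
    pooled = pool_sparse_groups(counts, min_n=10)
    assert ("small", "white") in pooled
    assert "small" in pooled and "large" in pooled
    np.testing.assert_array_equal(pooled["small"], counts[("small", "low-vis")])
    total_before = sum(c.sum() for c in counts.values())
    total_after = sum(np.asarray(c).sum() for c in pooled.values())
    assert total_before == total_after


def _one_group_survey(seed, density=25.0, sigma=150.0, n_segments=30, seg_km=4.0):
    cfg = SightingConfig(
        true_density_per_km2={("medium", "white"): density},
        hn_sigma_m={("medium", "white"): sigma},
        segment_lengths_km=[seg_km] * n_segments,
        seed=seed,
    )
    return gen_sightings(cfg)


def test_bootstrap_ci_reproducible_and_ordered():
    sightings, segments = _one_group_survey(5)
    ci1 = bootstrap_density_ci(segments, sightings, n_boot=150, seed=9)
    ci2 = bootstrap_density_ci(segments, sightings, n_boot=150, seed=9)
    assert ci1 == ci2
    lo, hi = ci1[("medium", "white")]
    assert 0 < lo < hi


def test_bootstrap_ci_narrows_with_more_segments():
    s_small, seg_small = _one_group_survey(2, n_segments=12)
    s_big, seg_big = _one_group_survey(2, n_segments=96)
    lo1, hi1 = bootstrap_density_ci(seg_small, s_small, n_boot=150, seed=1)[
        ("medium", "white")]
    lo2, hi2 = bootstrap_density_ci(seg_big, s_big, n_boot=150, seed=1)[
        ("medium", "white")]
    assert (hi2 - lo2) < (hi1 - lo1)
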
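"""Omega estimation, the XtX quadratic form, closed-form Bayes factors,
and covariate collapsing."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolscan import covscan, simulate
from poolscan.covscan import (
    OmegaMatrix,
    bayes_factor,
    collapse_covariates,
    estimate_omega,
    matrix_correlation,
    standardize_freqs,
    xtx,
)


def _random_pd(rng, n, scale=1.0):
    a = rng.normal(0, scale, (n, n))
    return a @ a.T + 0.2 * np.eye(n)


# ----------------------------------------------------------- standardize


def test_standardize_two_pop_arithmetic():
    z, keep = standardize_freqs(np.array([[0.9, 0.1]]))
    assert keep.all()
    np.testing.assert_allclose(z[0], [0.8, -0.8])


def test_standardize_skips_fixed_sites_and_zeroes_identical_pops():
    freqs = np.array([[0.4, 0.4, 0.4], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
    z, keep = standardize_freqs(freqs)
    assert keep.tolist() == [True, False, False]
    np.testing.assert_allclose(z[0], 0.0, atol=1e-12)


def test_standardized_depth_weighted_mean_is_zero():
    rng = np.random.default_rng(0)
    freqs = rng.uniform(0.1, 0.9, (200, 6))
    depths = rng.integers(30, 120, (200, 6))
    z, keep = standardize_freqs(freqs, depths)
    pi = (freqs * depths).sum(1) / depths.sum(1)
    wz = (z * depths[keep]).sum(1) / np.sqrt(pi[keep] * (1 - pi[keep]))
    np.testing.assert_allclose(wz, 0.0, atol=1e-9)


# ----------------------------------------------------------------- omega


def test_omega_moment_estimate_recovers_identity():
    rng = np.random.default_rng(1)
    z = rng.standard_normal((5000, 4))
    om = estimate_omega(z)
    off = om.matrix[~np.eye(4, dtype=bool)]
    assert np.all(np.abs(off) < 3 * np.sqrt(1.0 / 5000))
    assert np.all(np.abs(np.diag(om.matrix) - 1) < 3 * np.sqrt(2.0 / 5000))


def test_omega_invariant_to_duplicating_the_snp_set():
    rng = np.random.default_rng(2)
    z = rng.standard_normal((400, 5))
    a = estimate_omega(z)
    b = estimate_omega(np.vstack([z, z]))
    np.testing.assert_allclose(a.matrix, b.matrix)


def test_omega_thinning_on_low_ld_data_changes_little():
    rng = np.random.default_rng(3)
    z = rng.standard_normal((4000, 5))
    pos = np.arange(4000) * 200  # SNPs 200 bp apart, one contig
    contigs = np.repeat("C1", 4000)
    thick = estimate_omega(z)
    thin = estimate_omega(z, contigs, pos, thin_bp=1000)
    assert thin.n_snps == 800
    assert matrix_correlation(thick.matrix, thin.matrix) > 0.99


def test_omega_warns_when_snps_scarce():
    rng = np.random.default_rng(4)
    with pytest.warns(UserWarning, match="unstable"):
        estimate_omega(rng.standard_normal((10, 5)))


# ---------------------------------------------------- matrix correlation


def test_matrix_correlation_limits_and_hand_case():
    rng = np.random.default_rng(5)
    A = _random_pd(rng, 4)
    assert matrix_correlation(A, A) == pytest.approx(1.0)
    assert matrix_correlation(A, -A) == pytest.approx(-1.0)
    B1 = np.array([[1.0, 2.0], [2.0, 3.0]])
    B2 = np.array([[2.0, 1.0], [1.0, 7.0]])
    # upper triangles (1,2,3) vs (2,1,7): r = 5 / sqrt(2 * 186/9)
    assert matrix_correlation(B1, B2) == pytest.approx(
        5.0 / np.sqrt(2.0 * 186.0 / 9.0)
    )
    with pytest.raises(ValueError):
        matrix_correlation(np.ones((3, 3)), A[:3, :3])


# ------------------------------------------------------------------- xtx


def test_xtx_quadratic_form_cases():
    om = OmegaMatrix(np.eye(3), 100)
    assert xtx(np.zeros(3), om) == 0.0
    assert xtx(np.ones(3), om) == pytest.approx(3.0)


def test_xtx_invariant_to_population_relabeling():
    rng = np.random.default_rng(6)
    om = _random_pd(rng, 6)
    z = rng.standard_normal(6)
    perm = rng.permutation(6)
    a = xtx(z, OmegaMatrix(om, 100))
    b = xtx(z[perm], OmegaMatrix(om[np.ix_(perm, perm)], 100))
    assert a == pytest.approx(b)


def test_xtx_null_mean_matches_population_count():
    rng = np.random.default_rng(7)
    npop, S = 11, 4000
    om = _random_pd(rng, npop, scale=0.3)
    z = rng.multivariate_normal(np.zeros(npop), om, size=S)
    vals = xtx(z, OmegaMatrix(om, S))
    se = np.sqrt(2.0 * npop / S)
    assert abs(vals.mean() - npop) < 3 * se


def test_xtx_dimension_mismatch():
    with pytest.raises(ValueError):
        xtx(np.ones(4), OmegaMatrix(np.eye(3), 10))


# ---------------------------------------------------------- bayes factor


def test_bayes_factor_point_null_prior_is_one():
    rng = np.random.default_rng(8)
    om = OmegaMatrix(_random_pd(rng, 5), 100)
    z = rng.standard_normal(5)
    c = rng.standard_normal(5)
    assert bayes_factor(z, c, om, prior_var=0.0) == pytest.approx(1.0)


def test_bayes_factor_matches_multivariate_normal_evidence_ratio():
    # independent oracle: BF = N(z; 0, Omega + v * (c c^T scaled)) / N(z; 0, Omega)
    rng = np.random.default_rng(9)
    npop, v = 6, 1.7
    om = _random_pd(rng, npop)
    z = rng.standard_normal(npop)
    c = rng.standard_normal(npop)
    cz = (c - c.mean()) / c.std()
    got = bayes_factor(z, c, OmegaMatrix(om, 100), prior_var=v)
    num = stats.multivariate_normal.pdf(z, cov=om + v * np.outer(cz, cz))
    den = stats.multivariate_normal.pdf(z, cov=om)
    assert got == pytest.approx(num / den, rel=1e-9)


def test_bayes_factor_masks_populations_missing_the_covariate():
    rng = np.random.default_rng(10)
    om = _random_pd(rng, 5)
    z = rng.standard_normal(5)
    c = np.array([1.0, np.nan, 2.0, 3.0, np.nan])
    got = bayes_factor(z, c, OmegaMatrix(om, 100))
    idx = [0, 2, 3]
    manual = bayes_factor(
        z[idx], c[idx], OmegaMatrix(om[np.ix_(idx, idx)], 100)
    )
    assert got == pytest.approx(manual, rel=1e-12)
    with pytest.raises(ValueError, match="constant"):
        bayes_factor(z, np.array([2.0, 2.0, 2.0, np.nan, np.nan]),
                     OmegaMatrix(om, 100))


def test_bayes_factor_flags_covariate_driven_spikes():
    cov_vals = [0.1, 0.9, 0.2, 1.4, 0.5, 1.9]
    cfg = simulate.SimConfig(
        n_pops=6,
        genome=[("C1", 120_000)],
        n_spiked_regions=3,
        spike_effect=0.25,
        spike_covariate="salinity",
        covariates={"salinity": cov_vals},
        seed=23,
    )
    positions, freqs, truth = simulate.gen_frequencies(cfg)
    table = simulate.gen_poolseq(positions, freqs, cfg)
    from poolscan.pooldata import allele_freqs

    fmat, depth = allele_freqs(table)
    z, keep = standardize_freqs(fmat, depth)
    om = estimate_omega(z)
    bf = bayes_factor(z, np.array(cov_vals), om)
    pos = positions.loc[keep, "pos"].to_numpy()
    spiked = np.zeros(len(pos), dtype=bool)
    for reg in truth.spiked_regions:
        spiked |= (pos >= reg.start) & (pos < reg.end)
    assert np.log(bf[spiked]).mean() > np.log(bf[~spiked]).mean() + 1.0
    # the strongest signals live inside the spiked regions
    top = np.argsort(bf)[-10:]
    assert spiked[top].mean() >= 0.8


# ------------------------------------------------------------ covariates


def test_collapse_merges_identical_and_keeps_orthogonal():
    idx = [f"P{i}" for i in range(6)]
    rng = np.random.default_rng(11)
    a = rng.normal(size=6)
    b = rng.normal(size=6)
    df = pd.DataFrame({"a": a, "a_copy": a * 2.0 + 1.0, "b": b}, index=idx)
    cs = collapse_covariates(df, corr_threshold=0.8, add_dummies=False)
    assert cs.names == ["a", "b"]
    assert cs.groups["a"] == ["a", "a_copy"]
    # orthogonal covariates below threshold stay separate
    assert cs.groups["b"] == ["b"]


def test_dummy_variables_one_per_population():
    idx = [f"P{i:02d}" for i in range(11)]
    df = pd.DataFrame({"x": np.arange(11.0)}, index=idx)
    cs = collapse_covariates(df)
    assert len(cs.dummies) == 11
    for name in cs.dummies:
        col = cs.values[name]
        assert col.sum() == 1.0
        assert set(col.unique()) == {0.0, 1.0}


def test_sparsely_observed_covariate_dropped():
    idx = [f"P{i}" for i in range(6)]
    ph = [7.0, np.nan, np.nan, np.nan, np.nan, 8.0]  # observed twice
    df = pd.DataFrame({"ph": ph, "x": np.arange(6.0)}, index=idx)
    with pytest.warns(UserWarning, match="dropped"):
        cs = collapse_covariates(df, add_dummies=False)
    assert cs.names == ["x"]
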
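"""Interaction model, genotype-permutation null, SAMseq FDR, strata, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_interaction_instance, statsmodels_ols
from sexqtl import sexinteraction as sx
from sexqtl.sexinteraction import PermutationNull


def _balanced_design(n_per_cell=5):
    """Every (dosage, sex) cell populated with n_per_cell samples."""
    d = np.repeat([0.0, 1.0, 2.0, 0.0, 1.0, 2.0], n_per_cell)
    s = np.repeat([0.0, 0.0, 0.0, 1.0, 1.0, 1.0], n_per_cell)
    return d, s


def test_interaction_beta_exact_without_noise():
    """Male slope 0, female slope 1, zero noise: beta_int is exactly 1."""
    d, s = _balanced_design()
    y = d * s  # female slope 1, male slope 0
    res = sx.fit_interaction_model(d, s, y)
    assert res.testable
    assert res.beta_int == pytest.approx(1.0, abs=1e-10)


def test_interaction_fit_matches_statsmodels():
    rng = np.random.default_rng(21)
    for _ in range(50):
        n = int(rng.integers(30, 300))
        d, s, y = random_interaction_instance(rng, n)
        res = sx.fit_interaction_model(d, s, y)
        assert res.testable
        X = np.column_stack([np.ones(n), d, s, d * s])
        beta, se, t, p = statsmodels_ols(X, y)
        assert res.beta_int == pytest.approx(beta[3], abs=1e-8)
        assert res.se_int == pytest.approx(se[3], abs=1e-8)
        assert res.p_intercept == pytest.approx(p[0], abs=1e-8)
        assert res.p_snp == pytest.approx(p[1], abs=1e-8)
        assert res.p_sex == pytest.approx(p[2], abs=1e-8)
        assert res.p_int == pytest.approx(p[3], abs=1e-8)


def test_single_sex_untestable():
    d, _ = _balanced_design()
    res = sx.fit_interaction_model(d, np.zeros_like(d), d)
    assert not res.testable and "single-sex" in res.reason


def test_opposite_direction_effects_detected():
    """Male slope +0.3, female slope -0.3: beta_int ~ -0.6, strata opposite."""
    rng = np.random.default_rng(22)
    d, s = _balanced_design(n_per_cell=60)
    y = 0.3 * d * (1 - s) - 0.3 * d * s + rng.normal(0, 0.3, d.size)
    res = sx.fit_interaction_model(d, s, y)
    assert res.beta_int == pytest.approx(-0.6, abs=0.1)
    strata = sx.stratified_fit(d, y, s)
    assert strata["male"].beta > 0 > strata["female"].beta


def test_stratified_fit_equal_betas_for_identical_strata():
    rng = np.random.default_rng(23)
    d_half = rng.binomial(2, 0.4, 50).astype(float)
    y_half = 0.5 * d_half + rng.normal(0, 1, 50)
    d = np.concatenate([d_half, d_half])
    y = np.concatenate([y_half, y_half])
    s = np.concatenate([np.zeros(50), np.ones(50)])
    strata = sx.stratified_fit(d, y, s)
    assert strata["male"].beta == pytest.approx(strata["female"].beta, abs=1e-12)


def test_stratified_fit_flags_missing_stratum():
    d = np.repeat([0.0, 1.0, 2.0], 5)
    y = np.arange(15, dtype=float)
    strata = sx.stratified_fit(d, y, np.zeros(15))
    assert strata["male"].ok
    assert not strata["female"].ok and "no samples" in strata["female"].reason


def _null_block(rng, n=120, n_snps=3, n_probes=4):
    dosages = pd.DataFrame(
        {f"rs{i}": rng.binomial(2, 0.4, n).astype(float)
         for i in range(n_snps)},
        index=[f"s{j}" for j in range(n)])
    sex = pd.Series((rng.random(n) < 0.5).astype(int), index=dosages.index)
    expr = pd.DataFrame(rng.normal(0, 1, (n_probes, n)),
                        index=[f"p{k}" for k in range(n_probes)],
                        columns=dosages.index)
    return dosages, sex, expr


def test_permutation_null_deterministic_given_seed():
    rng = np.random.default_rng(24)
    dosages, sex, expr = _null_block(rng)
    a = sx.build_permutation_null(dosages, sex, expr, n_perm=200, seed=5)
    b = sx.build_permutation_null(dosages, sex, expr, n_perm=200, seed=5)
    assert np.array_equal(a.abs_t, b.abs_t)
    c = sx.build_permutation_null(dosages, sex, expr, n_perm=200, seed=6)
    assert not np.array_equal(a.abs_t, c.abs_t)


def test_permutation_shuffle_shared_across_probes_of_one_snp():
    """Two probes with identical expression rows get identical null columns."""
    rng = np.random.default_rng(25)
    dosages, sex, expr = _null_block(rng, n_probes=2)
    expr.iloc[1] = expr.iloc[0]
    null = sx.build_permutation_null(dosages, sex, expr, n_perm=150, seed=1,
                                     pairs=[("rs0", "p0"), ("rs0", "p1")])
    assert np.allclose(null.abs_t[:, 0], null.abs_t[:, 1], atol=1e-10)


def test_small_n_perm_rejected():
    rng = np.random.default_rng(26)
    dosages, sex, expr = _null_block(rng)
    with pytest.raises(ValueError, match="n_perm"):
        sx.build_permutation_null(dosages, sex, expr, n_perm=50)


def test_permutation_pvalue_add_one_estimator():
    null = PermutationNull(pairs=[("rs0", "p0")],
                           abs_t=np.array([[1.0], [2.0], [3.0], [4.0]]),
                           n_perm=4, seed=0)
    # obs 2.5: 2 of 4 permuted stats >= 2.5 -> (1+2)/(1+4)
    assert sx.permutation_pvalues([2.5], null)[0] == pytest.approx(3 / 5)
    # obs above everything: floor at 1/(n_perm+1)
    assert sx.permutation_pvalues([9.0], null)[0] == pytest.approx(1 / 5)


def test_null_statistic_distribution_matches_observed_under_null():
    """Permuted |t*| and observed |t| agree in distribution on null data."""
    passed = 0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        dosages, sex, expr = _null_block(rng, n=150, n_snps=5, n_probes=30)
        obs = []
        for snp in dosages.columns:
            for probe in expr.index:
                r = sx.fit_interaction_model(dosages[snp], sex, expr.loc[probe])
                obs.append(abs(r.t_int))
        null = sx.build_permutation_null(dosages, sex, expr, n_perm=150,
                                         seed=seed)
        ks = stats.ks_2samp(np.array(obs), null.abs_t.ravel())
        if ks.pvalue > 0.01:
            passed += 1
    assert passed >= 18


def test_permutation_fdr_zero_when_observed_dominates():
    rng = np.random.default_rng(27)
    null = PermutationNull(
        pairs=[("rs0", f"p{i}") for i in range(10)],
        abs_t=rng.uniform(0, 1, (200, 10)), n_perm=200, seed=0)
    obs = np.full(10, 5.0)
    obs[0] = 6.0
    fdr = sx.permutation_fdr(obs, null)
    assert np.allclose(fdr, 0.0)


def test_permutation_fdr_monotone_in_threshold():
    rng = np.random.default_rng(28)
    m = 100
    null = PermutationNull(
        pairs=[("rs0", f"p{i}") for i in range(m)],
        abs_t=np.abs(rng.standard_normal((300, m))), n_perm=300, seed=0)
    obs = np.abs(rng.standard_normal(m))
    fdr = sx.permutation_fdr(obs, null)
    order = np.argsort(obs)
    assert (np.diff(fdr[order]) <= 1e-12).all()
    assert ((fdr >= 0) & (fdr <= 1)).all()


def test_permutation_fdr_rejects_empty():
    null = PermutationNull(pairs=[], abs_t=np.empty((100, 0)), n_perm=100,
                           seed=0)
    with pytest.raises(ValueError, match="empty"):
        sx.permutation_fdr(np.array([]), null)


def test_r2_identity_and_allele_flip_symmetry():
    rng = np.random.default_rng(29)
    d = rng.binomial(2, 0.3, 500).astype(float)
    assert sx.compute_r2(d, d).r2 == pytest.approx(1.0)
    assert sx.compute_r2(d, 2.0 - d).r2 == pytest.approx(1.0)
    e = rng.binomial(2, 0.3, 500).astype(float)
    assert sx.compute_r2(d, e).r2 == pytest.approx(sx.compute_r2(e, d).r2)


def test_r2_independent_snps_near_zero():
    rng = np.random.default_rng(30)
    a = rng.binomial(2, 0.3, 10_000).astype(float)
    b = rng.binomial(2, 0.4, 10_000).astype(float)
    assert sx.compute_r2(a, b).r2 < 0.01


def test_r2_monomorphic_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        sx.compute_r2(np.zeros(50), np.ones(50))
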
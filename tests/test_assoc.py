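"""Kernel machine score test: weights, kernels, Q statistic, mixture p-value."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from padnet import assoc
from padnet.assoc import (
    KernelSpec,
    NullModel,
    bonferroni,
    build_kernel,
    compute_weights,
    fit_null_logistic,
    linear_score_statistic,
    pvalue_mixture_chisq,
    score_statistic,
)


# ---------------------------------------------------------------- weights


def test_flat_weights_all_one():
    w = compute_weights(np.array([0.05, 0.2, 0.5]), KernelSpec(weight_scheme="flat"))
    np.testing.assert_array_equal(w, np.ones(3))


def test_beta_weight_closed_form_at_half():
    """Beta(1,25) density at 0.5 is 25 * 0.5^24; the weight is its square."""
    w = compute_weights(np.array([0.5]), KernelSpec())
    expected = (25 * 0.5**24) ** 2
    assert w[0] == pytest.approx(expected, rel=1e-12)


def test_beta_weights_decreasing_in_maf():
    mafs = np.linspace(0.01, 0.5, 50)
    w = compute_weights(mafs, KernelSpec())
    assert (np.diff(w) < 0).all()


def test_weight_maf_domain():
    with pytest.raises(ValueError):
        compute_weights(np.array([0.0]), KernelSpec())
    with pytest.raises(ValueError):
        compute_weights(np.array([0.6]), KernelSpec())


# ---------------------------------------------------------------- kernels


def test_linear_kernel_single_snp_outer_product(rng):
    z = rng.binomial(2, 0.3, 10).astype(float)[:, None]
    K = build_kernel(z, np.array([1.0]), KernelSpec(weight_scheme="flat"))
    np.testing.assert_allclose(K, np.outer(z, z))


def test_linear_kernel_psd_and_symmetric(rng):
    Z = rng.binomial(2, 0.3, size=(15, 6)).astype(float)
    w = compute_weights(np.full(6, 0.3), KernelSpec())
    K = build_kernel(Z, w, KernelSpec())
    np.testing.assert_allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-10


def test_kernels_match_elementwise_loops(rng):
    """3 samples x 2 SNPs: every kernel entry equals a hand double loop."""
    Z = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 0.0]])
    w = np.array([0.7, 1.3])
    K_lin = build_kernel(Z, w, KernelSpec())
    K_ibs = build_kernel(Z, w, KernelSpec(kind="ibs"))
    rho = 2.0
    K_gau = build_kernel(Z, w, KernelSpec(kind="gaussian", gaussian_rho=rho))
    for i in range(3):
        for j in range(3):
            lin = sum(w[k] * Z[i, k] * Z[j, k] for k in range(2))
            ibs = sum(w[k] * (2 - abs(Z[i, k] - Z[j, k])) for k in range(2)) / (
                2 * w.sum()
            )
            gau = np.exp(-sum((Z[i, k] - Z[j, k]) ** 2 for k in range(2)) / rho)
            assert K_lin[i, j] == pytest.approx(lin)
            assert K_ibs[i, j] == pytest.approx(ibs)
            assert K_gau[i, j] == pytest.approx(gau)


# -------------------------------------------------------------- null model


def test_intercept_only_fit_is_case_fraction():
    y = np.array([1] * 1926 + [0] * 2938)
    null = fit_null_logistic(y)
    np.testing.assert_allclose(null.mu0, 1926 / 4864)


def test_balanced_fit_is_half():
    y = np.array([0, 1] * 30)
    null = fit_null_logistic(y)
    np.testing.assert_allclose(null.mu0, 0.5)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        fit_null_logistic(np.ones(10))


def test_covariate_fit_matches_irls_oracle(rng):
    """One binary covariate: statsmodels fit equals a hand-rolled IRLS."""
    n = 200
    x = rng.integers(0, 2, n).astype(float)
    from scipy.special import expit

    y = (rng.random(n) < expit(-0.3 + 0.8 * x)).astype(float)
    null = fit_null_logistic(y, covariates=x[:, None])
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    for _ in range(50):
        p = expit(X @ beta)
        W = p * (1 - p)
        delta = np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - p))
        beta += delta
        if np.abs(delta).max() < 1e-12:
            break
    np.testing.assert_allclose(null.mu0, expit(X @ beta), atol=1e-8)


# ------------------------------------------------------------- Q statistic


def test_q_zero_for_zero_residuals():
    mu0 = np.full(6, 0.5)
    y = mu0.copy()
    K = np.eye(6)
    q, lam = score_statistic(y, NullModel(mu0=mu0, X=np.ones((6, 1))), K)
    assert q == 0.0


def test_zero_kernel_gives_zero():
    y = np.array([0.0, 1.0, 1.0, 0.0])
    null = fit_null_logistic(y)
    q, lam = score_statistic(y, null, np.zeros((4, 4)))
    assert q == 0.0
    assert np.all(lam == 0)
    p, _ = pvalue_mixture_chisq(q, lam)
    assert p == 1.0


def test_q_and_eigenvalues_match_dense_oracle(rng):
    """8-sample toy: Q equals a brute-force quadratic-form loop and the
    eigenvalues match an independent dense eigendecomposition."""
    for _ in range(5):
        Z = rng.integers(0, 3, size=(8, 3)).astype(float)
        y = rng.integers(0, 2, size=8).astype(float)
        y[0], y[1] = 0, 1  # both classes
        null = fit_null_logistic(y)
        w = rng.uniform(0.5, 2.0, 3)
        K = build_kernel(Z, w, KernelSpec(weight_scheme="flat"))
        q, lam = score_statistic(y, null, K)
        resid = y - null.mu0
        q_brute = sum(
            resid[i] * K[i, j] * resid[j] for i in range(8) for j in range(8)
        ) / 2.0
        assert q == pytest.approx(q_brute, abs=1e-10)
        d = null.mu0 * (1 - null.mu0)
        X = null.X
        P0 = np.diag(d) - (X * d[:, None]) @ np.linalg.inv(
            X.T @ (X * d[:, None])
        ) @ (X * d[:, None]).T
        wv, V = np.linalg.eigh(P0)
        P0h = (V * np.sqrt(np.clip(wv, 0, None))) @ V.T
        lam_oracle = np.sort(np.clip(np.linalg.eigvalsh(0.5 * P0h @ K @ P0h), 0, None))[::-1]
        np.testing.assert_allclose(lam, lam_oracle, atol=1e-10)
        # the p x p linear fast path shares the non-zero spectrum
        q2, lam2 = linear_score_statistic(y, null, Z, w)
        assert q2 == pytest.approx(q, abs=1e-10)
        nz = lam[lam > 1e-10]
        np.testing.assert_allclose(lam2[: nz.size], nz, atol=1e-10)


def test_nonsymmetric_kernel_rejected():
    y = np.array([0.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        score_statistic(y, fit_null_logistic(y), np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]]))


def test_zero_weight_noise_snp_leaves_q_unchanged(rng):
    Z = rng.binomial(2, 0.3, size=(40, 4)).astype(float)
    noise = rng.binomial(2, 0.3, 40).astype(float)[:, None]
    y = rng.integers(0, 2, 40).astype(float)
    y[:2] = [0, 1]
    null = fit_null_logistic(y)
    w = np.ones(4)
    q1, lam1 = linear_score_statistic(y, null, Z, w)
    q2, lam2 = linear_score_statistic(
        y, null, np.hstack([Z, noise]), np.append(w, 0.0)
    )
    assert q2 == pytest.approx(q1, abs=1e-12)
    p1, _ = pvalue_mixture_chisq(q1, lam1)
    p2, _ = pvalue_mixture_chisq(q2, lam2)
    assert p2 == pytest.approx(p1, abs=1e-8)


# ----------------------------------------------------------- mixture tail


def test_single_eigenvalue_is_chi2_tail():
    p, used = pvalue_mixture_chisq(5.0, np.array([1.0]))
    assert p == pytest.approx(float(chi2.sf(5.0, 1)), abs=1e-10)


def test_two_component_mixture_matches_monte_carlo(rng):
    """Mixture 2*chi2 + chi2 at Q=5 vs 10^6 Monte-Carlo draws."""
    p, _ = pvalue_mixture_chisq(5.0, np.array([2.0, 1.0]))
    draws = 2 * rng.chisquare(1, 10**6) + rng.chisquare(1, 10**6)
    p_mc = (draws > 5.0).mean()
    se = np.sqrt(p_mc * (1 - p_mc) / 10**6)
    assert abs(p - p_mc) <= 3 * se


def test_moment_method_close_to_davies():
    lam = np.array([3.0, 2.0, 1.0, 0.5])
    p_d, _ = pvalue_mixture_chisq(10.0, lam, method="davies")
    p_m, _ = pvalue_mixture_chisq(10.0, lam, method="moment")
    assert p_m == pytest.approx(p_d, abs=5e-3)


def test_negative_eigenvalues_rejected():
    with pytest.raises(ValueError):
        pvalue_mixture_chisq(1.0, np.array([-0.5, 1.0]))


# --------------------------------------------------------------- Bonferroni


@pytest.mark.parametrize(
    "p_raw,n,expected",
    [
        (7.57e-8, 276, 2.08932e-5),
        (3.59e-5, 276, 9.9084e-3),
        (0.5, 276, 1.0),
    ],
)
def test_bonferroni_adjustment(p_raw, n, expected):
    assert bonferroni(p_raw, n) == pytest.approx(expected, rel=1e-3)


def test_test_pathways_sorting_and_flags(small_bundle):
    from padnet.pipeline import pathway_snp_sets
    from padnet.qc import filter_dataset, impute_most_frequent, map_snps_to_genes

    data, _ = filter_dataset(small_bundle.data)
    data = impute_most_frequent(data)
    mapping, _ = map_snps_to_genes(data.snps, small_bundle.genes)
    sets = pathway_snp_sets(small_bundle.pathways, mapping)
    # flat weights: the matched analysis for equal-per-SNP common-variant effects
    results = assoc.test_pathways(data, sets, spec=KernelSpec(weight_scheme="flat"))
    ps = [r.p_raw for r in results if r.error is None]
    assert ps == sorted(ps)
    n = len([r for r in results if r.error is None])
    for r in results:
        if r.error is None:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * n))
            assert r.p_adjusted >= r.p_raw
            assert r.significant == (r.p_raw * n < 0.05)
    # the planted risk pathway reaches Bonferroni significance; pathways
    # sharing its risk genes may also surface (membership overlaps)
    pw01 = next(r for r in results if r.pathway_id == "PW01")
    assert pw01.significant


def test_unknown_snp_set_recorded_not_raised(small_bundle):
    from padnet.assoc import PathwaySnpSet
    from padnet.qc import impute_most_frequent

    data = impute_most_frequent(small_bundle.data)
    good = PathwaySnpSet("ok", [data.snps["snp_id"].iloc[0]])
    bad = PathwaySnpSet("bad", ["nonexistent_snp"])
    results = assoc.test_pathways(data, [good, bad])
    by_id = {r.pathway_id: r for r in results}
    assert by_id["bad"].error is not None
    assert by_id["ok"].error is None
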
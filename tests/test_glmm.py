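"""GLMM engine: degenerate cases, recovery, quadrature oracle, ZIP, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln
from numpy.polynomial.hermite import hermgauss

from arcticfit.glmm import ModelSpec, build_design, fit_glmm, fit_zip_glmm
from arcticfit.selection import likelihood_ratio_test

from conftest import poisson_glmm_data


# ------------------------------------------------------------------ oracles

def gh_marginal_loglik(y, X, beta, groups, sigma, family="poisson", n_nodes=40):
    """Adaptive Gauss–Hermite marginal log-likelihood for one random intercept.

    Centres the quadrature at each group's conditional mode (Newton on the
    scalar), the standard adaptive scheme.  Independent of the Laplace code."""
    nodes, weights = hermgauss(n_nodes)
    eta0 = X @ beta
    total = 0.0
    for g in np.unique(groups):
        idx = groups == g
        yg, eg = y[idx], eta0[idx]

        def cond_ll(u):
            eta = eg + u
            if family == "poisson":
                return float(np.sum(yg * eta - np.exp(eta) - gammaln(yg + 1))) \
                    - 0.5 * u * u / sigma**2
            p = 1.0 / (1.0 + np.exp(-eta))
            return float(np.sum(yg * eta - np.log1p(np.exp(eta)))) - 0.5 * u * u / sigma**2

        # scalar Newton for the mode
        u = 0.0
        for _ in range(50):
            eta = eg + u
            mu = np.exp(eta) if family == "poisson" else 1.0 / (1.0 + np.exp(-eta))
            g1 = float(np.sum(yg - mu)) - u / sigma**2
            w = mu if family == "poisson" else mu * (1 - mu)
            g2 = -float(np.sum(w)) - 1.0 / sigma**2
            step = g1 / g2
            u -= step
            if abs(step) < 1e-12:
                break
        s_hat = 1.0 / np.sqrt(-g2)
        z = u + np.sqrt(2.0) * s_hat * nodes
        vals = np.array([cond_ll(zi) for zi in z])
        log_terms = vals + nodes**2 + np.log(weights) \
            + 0.5 * np.log(2.0) + np.log(s_hat) - 0.5 * np.log(2 * np.pi * sigma**2)
        m = log_terms.max()
        total += m + np.log(np.exp(log_terms - m).sum())
    return total


# ------------------------------------------------------------------ degenerate cases

def test_no_random_effect_matches_statsmodels_glm():
    """With the grouping dropped (single level), coefficients equal the plain
    GLM fit (statsmodels as the independent oracle)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    d = poisson_glmm_data(rng, b=0.4, year_sd=0.0, n=400, n_years=1)
    fit = fit_glmm(ModelSpec("y", "poisson", fixed=["genotype"], random=["year"]), d)
    X = np.column_stack([np.ones(len(d)), (d["genotype"] == "TC").to_numpy(float)])
    glm = sm.GLM(d["y"].to_numpy(), X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(fit.coef.to_numpy(), glm.params, atol=1e-6)
    np.testing.assert_allclose(
        fit.params["se"].to_numpy(), glm.bse, rtol=1e-3)
    assert fit.random_sd == {}  # single-level grouping dropped


def test_binomial_glmm_matches_glm_without_grouping():
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    n = 500
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
    d = pd.DataFrame({"y": (rng.random(n) < p).astype(float), "x": x})
    fit = fit_glmm(ModelSpec("y", "binomial", fixed=["x"], random=[]), d)
    X = np.column_stack([np.ones(n), x])
    glm = sm.GLM(d["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.coef.to_numpy(), glm.params, atol=1e-6)
    assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)


def test_laplace_close_to_quadrature_oracle():
    """Laplace log-likelihood within 0.05 of adaptive quadrature on 50 rows."""
    rng = np.random.default_rng(2)
    d = poisson_glmm_data(rng, b=0.5, year_sd=0.4, n=50, n_years=8, intercept=0.3)
    fit = fit_glmm(ModelSpec("y", "poisson", fixed=["genotype"], random=["year"]), d)
    X = np.column_stack([np.ones(len(d)), (d["genotype"] == "TC").to_numpy(float)])
    groups = pd.factorize(d["year"])[0]
    oracle = gh_marginal_loglik(
        d["y"].to_numpy(), X, fit.coef.to_numpy(), groups,
        fit.random_sd["year"], family="poisson")
    assert fit.loglik == pytest.approx(oracle, abs=0.05)


# ------------------------------------------------------------------ recovery

def test_poisson_glmm_parameter_recovery():
    """b_TC = 0.3, year SD 0.2, n = 1500: mean estimate over replicates ≈ 0.3
    (smaller replicate count than the headline check; acceptance runs 100)."""
    rng = np.random.default_rng(3)
    est, sds = [], []
    for _ in range(30):
        d = poisson_glmm_data(rng, b=0.3, year_sd=0.2, n=1500)
        fit = fit_glmm(ModelSpec("y", "poisson", fixed=["genotype"], random=["year"]), d)
        est.append(fit.coef_row("genotype[TC]")["estimate"])
        sds.append(fit.random_sd["year"])
    assert abs(np.mean(est) - 0.3) < 0.05
    assert abs(np.mean(sds) - 0.2) < 0.08


def test_gaussian_glmm_recovers_variance_components():
    rng = np.random.default_rng(4)
    n, n_g = 2000, 25
    grp = rng.integers(0, n_g, size=n)
    u = rng.normal(0, 0.5, size=n_g)
    y = 1.0 + u[grp] + rng.normal(0, 1.0, size=n)
    d = pd.DataFrame({"y": y, "g": grp.astype(str)})
    fit = fit_glmm(ModelSpec("y", "gaussian", fixed=[], random=["g"]), d)
    assert fit.random_sd["g"] == pytest.approx(0.5, abs=0.15)
    assert fit.extras["resid_sd"] == pytest.approx(1.0, abs=0.06)
    assert fit.coef["(Intercept)"] == pytest.approx(1.0, abs=0.3)


# ------------------------------------------------------------------ zero inflation

def test_zip_reduces_to_poisson_when_no_structural_zeros():
    rng = np.random.default_rng(5)
    d = poisson_glmm_data(rng, b=0.3, year_sd=0.2, n=1200, intercept=0.4)
    zip_fit = fit_zip_glmm(ModelSpec("y", "zip", fixed=["genotype"], random=["year"]), d)
    pois_fit = fit_glmm(ModelSpec("y", "poisson", fixed=["genotype"], random=["year"]), d)
    b_zip = zip_fit.coef_row("genotype[TC]")
    b_pois = pois_fit.coef_row("genotype[TC]")
    assert abs(b_zip["estimate"] - b_pois["estimate"]) < 2 * b_pois["se"]
    assert zip_fit.extras["zi_prob"] < 0.08


def test_zip_recovers_both_components():
    rng = np.random.default_rng(6)
    ests_b, ests_pi = [], []
    for _ in range(20):
        n = 2000
        year = rng.integers(0, 10, size=n)
        u = rng.normal(0, 0.2, size=10)
        geno = np.where(rng.random(n) < 0.3, "TC", "CC")
        mu = np.exp(0.5 + 0.4 * (geno == "TC") + u[year])
        y = rng.poisson(mu)
        y[rng.random(n) < 0.4] = 0  # structural zeros
        d = pd.DataFrame({"y": y.astype(float), "genotype": geno,
                          "year": year.astype(str)})
        fit = fit_zip_glmm(ModelSpec("y", "zip", fixed=["genotype"], random=["year"]), d)
        ests_b.append(fit.coef_row("genotype[TC]")["estimate"])
        ests_pi.append(fit.extras["zi_prob"])
    assert abs(np.mean(ests_b) - 0.4) < 0.1
    assert abs(np.mean(ests_pi) - 0.4) < 0.1


def test_zip_all_zero_response_rejected():
    d = pd.DataFrame({"y": np.zeros(50), "genotype": ["CC"] * 25 + ["TC"] * 25,
                      "year": ["a", "b"] * 25})
    with pytest.raises(ValueError, match="all-zero"):
        fit_zip_glmm(ModelSpec("y", "zip", fixed=["genotype"], random=["year"]), d)


# ------------------------------------------------------------------ LRT

def test_lrt_identical_models_and_chi2_oracle():
    rng = np.random.default_rng(7)
    d = poisson_glmm_data(rng, b=0.0, n=300)
    spec = ModelSpec("y", "poisson", fixed=["genotype"], random=["year"])
    fit = fit_glmm(spec, d)
    chi2, df, p = likelihood_ratio_test(fit, fit)
    assert (chi2, df, p) == (0.0, 0, 1.0)
    # ll₀ = −10, ll₁ = −8, df = 1 → χ² = 4, p ≈ 0.0455
    assert stats.chi2.sf(4.0, 1) == pytest.approx(0.0455, abs=2e-4)


def test_lrt_rejects_non_nested():
    rng = np.random.default_rng(8)
    d = poisson_glmm_data(rng, n=200)
    d["x"] = rng.normal(size=len(d))
    f_a = fit_glmm(ModelSpec("y", "poisson", fixed=["genotype"], random=["year"]), d)
    f_b = fit_glmm(ModelSpec("y", "poisson", fixed=["x"], random=["year"]), d)
    with pytest.raises(ValueError):
        likelihood_ratio_test(f_a, f_b)


def test_lrt_invariant_to_affine_reparameterization():
    rng = np.random.default_rng(9)
    d = poisson_glmm_data(rng, b=0.2, n=600)
    d["x"] = rng.normal(size=len(d))
    d["x_affine"] = 3.0 * d["x"] - 7.0
    def lrt_with(xcol):
        f1 = fit_glmm(ModelSpec("y", "poisson", fixed=["genotype", xcol],
                                random=["year"]), d)
        f0 = fit_glmm(ModelSpec("y", "poisson", fixed=[xcol], random=["year"]), d)
        return likelihood_ratio_test(f0, f1)[0]
    assert lrt_with("x") == pytest.approx(lrt_with("x_affine"), abs=5e-3)


# ------------------------------------------------------------------ design builder

def test_design_treatment_coding_and_interactions():
    d = pd.DataFrame(
        {"genotype": ["CC", "TC", "TT", "CC"], "sex": ["F", "M", "F", "M"],
         "age": [1.0, 2.0, 3.0, 4.0]}
    )
    X, info = build_design(d, ["genotype", "sex", "age", "genotype:sex"])
    assert info.columns[0] == "(Intercept)"
    assert "genotype[TC]" in info.columns and "genotype[TT]" in info.columns
    assert info.levels["genotype"][0] == "CC"  # reference level
    j = info.columns.index("genotype[TC]:sex[M]")
    np.testing.assert_array_equal(X[:, j], [0, 1, 0, 0])


def test_rank_deficient_design_rejected():
    d = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    with pytest.raises(ValueError, match="rank"):
        fit_glmm(ModelSpec("y", "gaussian", fixed=["a", "b"], random=[]), d)


def test_interaction_requires_main_effect():
    with pytest.raises(ValueError, match="main effect"):
        ModelSpec("y", "poisson", fixed=["genotype:sex"], random=[])
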
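"""Mixed-model association scan with genomic control.

The scan follows the two-step residual strategy used for large wild-pedigree
GWAS: (1) fit a polygenic linear mixed model with the GRM as the single
random effect by REML on the eigenrotated data, (2) score-test each SNP
against the environmental (GRAMMAR) residuals with the variance taken under
the fitted null covariance, so the statistic is (gᵀPy)²/(gᵀPg) with
P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹.  Binary traits are analysed on the observed
0/1 scale.  Genomic control divides every χ² by λ_GC (median χ² over the
χ²₁ median 0.4549) before re-computing p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from arcticfit.panel import GenotypePanel
from arcticfit.popgen import GRM

#: median of the χ² distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class PolygenicFit:
    """REML polygenic model: trait ~ covariates + g, g ~ N(0, σ²_g · GRM)."""

    ids: np.ndarray
    sigma_g2: float
    sigma_e2: float
    heritability: float
    beta: np.ndarray
    residuals: np.ndarray  # environmental (GRAMMAR) residuals on the data scale
    # eigen machinery reused by the score tests
    eigvecs: np.ndarray = field(repr=False)
    eigvals: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)  # λ_r·d + 1 per eigencomponent
    X_rot: np.ndarray = field(repr=False)
    resid_rot: np.ndarray = field(repr=False)
    loglik: float = np.nan


@dataclass
class ScanResult:
    """Per-SNP association statistics with genomic-control correction."""

    table: pd.DataFrame  # snp_id, scaffold, pos, chi2, p_raw, p_corrected, significant
    lambda_gc: float
    threshold: float
    alpha: float
    n_tests: int

    @property
    def top_snp(self) -> pd.Series:
        ok = self.table.dropna(subset=["p_corrected"])
        return ok.loc[ok["p_corrected"].idxmin()]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold α / number of tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def genomic_inflation(stats_chi2) -> float:
    """λ_GC = median(χ²) / median(χ²₁)."""
    arr = np.asarray(stats_chi2, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite statistics supplied")
    return float(np.median(arr) / CHI2_1_MEDIAN)


def qq_summary(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) −log₁₀ p against uniform plotting positions (i−0.5)/m."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    m = p.size
    observed = -np.log10(np.sort(p))  # descending −log₁₀ p, aligned with expected
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return expected, observed


def _reml_neg_loglik(log_ratio: float, d: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray):
    """Negative REML log-likelihood profiled over σ²_e, at variance ratio
    λ_r = σ²_g/σ²_e.  Returns (nll, beta, sigma_e2)."""
    lam = np.exp(log_ratio)
    w = lam * d + 1.0
    Xw = X_rot / w[:, None]
    XtWX = X_rot.T @ Xw
    XtWy = Xw.T @ y_rot
    beta = np.linalg.solve(XtWX, XtWy)
    r = y_rot - X_rot @ beta
    n, p = X_rot.shape
    quad = float(r @ (r / w))
    sigma_e2 = quad / (n - p)
    _, logdet_xx = np.linalg.slogdet(XtWX)
    nll = 0.5 * ((n - p) * np.log(sigma_e2) + np.log(w).sum() + logdet_xx + (n - p))
    return nll, beta, sigma_e2


def fit_polygenic(trait, grm: GRM, covariates=None, ids=None, tol: float = 1e-8) -> PolygenicFit:
    """REML fit of the single-GRM polygenic model via eigendecomposition.

    ``trait`` is a per-individual vector aligned with ``grm.ids`` (or with
    ``ids``).  Returns variance components and the environmental residuals
    used by the per-SNP score tests.
    """
    y = np.asarray(trait, dtype=float)
    if np.var(y) == 0:
        raise ValueError("trait is constant")
    n = y.size
    if n != grm.matrix.shape[0]:
        raise ValueError("trait length does not match GRM")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    if np.linalg.matrix_rank(np.column_stack([X, y])) <= X.shape[1]:
        raise ValueError("confounded design: trait lies in the covariate span")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")

    G = grm.matrix
    d, U = np.linalg.eigh(G)
    if d.min() < -1e-8:
        d_j, U = np.linalg.eigh(G + 1e-6 * np.eye(n))
        if d_j.min() < 0:
            raise ValueError("GRM is not positive semi-definite after jitter")
        d = d_j
    d = np.maximum(d, 0.0)
    y_rot = U.T @ y
    X_rot = U.T @ X

    obj = lambda lr: _reml_neg_loglik(lr, d, y_rot, X_rot)[0]
    # coarse grid then local refinement on the log variance-ratio scale
    grid = np.linspace(-10.0, 8.0, 37)
    vals = [obj(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    opt_x = res.x
    # parsimony tie-break: a flat likelihood in the ratio (e.g. GRM ∝ I)
    # resolves to the no-relatedness model
    if obj(grid[0]) <= res.fun + 1e-6:
        opt_x = grid[0]
    nll, beta, sigma_e2 = _reml_neg_loglik(opt_x, d, y_rot, X_rot)
    lam = float(np.exp(opt_x))
    sigma_g2 = lam * sigma_e2
    mean_diag = float(np.mean(np.diag(G)))
    h2 = sigma_g2 * mean_diag / (sigma_g2 * mean_diag + sigma_e2)
    w = lam * d + 1.0
    resid_rot = (y_rot - X_rot @ beta) / w  # = σ²_e V⁻¹(y − Xβ) in rotated basis
    residuals = U @ resid_rot * 1.0
    return PolygenicFit(
        ids=np.asarray(grm.ids if ids is None else ids),
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        heritability=float(np.clip(h2, 0.0, 1.0)),
        beta=beta,
        residuals=residuals,
        eigvecs=U,
        eigvals=d,
        weights=w,
        X_rot=X_rot,
        resid_rot=resid_rot,
        loglik=float(-nll),
    )


def _score_scan(fit: PolygenicFit, panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP score χ² and a polymorphic mask."""
    X = panel.dosage.copy()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    called = (~np.isnan(X)).sum(axis=0)
    poly = (called > 0) & (np.nanvar(X, axis=0) > 0)
    inds = np.where(np.isnan(X))
    X[inds] = 2.0 * p[inds[1]]
    Xc = X - X.mean(axis=0, keepdims=True)

    sw = np.sqrt(fit.weights)
    A = (fit.eigvecs.T @ Xc) / sw[:, None]          # W^{-1/2} Uᵀ g, per SNP
    b = fit.resid_rot * fit.weights / sw            # W^{-1/2} (y* − X*β)
    Xw = fit.X_rot / sw[:, None]
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    AtX = A.T @ Xw
    gPg = (A * A).sum(axis=0) - np.einsum("ij,jk,ik->i", AtX, XtX_inv, AtX)
    num = (A.T @ b) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = num / (gPg * fit.sigma_e2)
    chi2[~poly] = np.nan
    chi2[gPg <= 0] = np.nan
    return chi2, poly


def association_scan(
    fit: PolygenicFit,
    panel: GenotypePanel,
    alpha: float = 0.05,
    lambda_correct: str = "if_above_one",
) -> ScanResult:
    """Score test of every SNP against the polygenic-model residuals.

    Monomorphic SNPs get missing p-values and are excluded from λ_GC and
    from the Bonferroni count.  ``lambda_correct`` is one of
    ``"if_above_one"`` (default: deflation left uncorrected), ``"always"``
    or ``"never"``.
    """
    chi2, poly = _score_scan(fit, panel)
    lam_gc = genomic_inflation(chi2[poly])
    if lambda_correct == "always" or (lambda_correct == "if_above_one" and lam_gc > 1.0):
        chi2_adj = chi2 / lam_gc
    elif lambda_correct in ("if_above_one", "never"):
        chi2_adj = chi2
    else:
        raise ValueError(f"unknown lambda_correct mode {lambda_correct!r}")
    p_raw = stats.chi2.sf(chi2, df=1)
    p_corr = stats.chi2.sf(chi2_adj, df=1)
    n_tests = int(poly.sum())
    threshold = bonferroni_threshold(alpha, n_tests)
    table = pd.DataFrame(
        {
            "snp_id": panel.marker_map["snp_id"].to_numpy(),
            "scaffold": panel.marker_map["scaffold"].to_numpy(),
            "pos": panel.marker_map["pos"].to_numpy(),
            "chi2": chi2,
            "p_raw": p_raw,
            "p_corrected": p_corr,
        }
    )
    table["significant"] = table["p_corrected"] < threshold
    return ScanResult(table=table, lambda_gc=lam_gc, threshold=threshold,
                      alpha=alpha, n_tests=n_tests)


def candidate_region_scan(
    fitness,
    panel: GenotypePanel,
    grm: GRM,
    scaffold: str | None = None,
    alpha: float = 0.05,
    lambda_correct: str = "if_above_one",
) -> ScanResult:
    """Association scan of a continuous fitness trait restricted to one scaffold.

    The Bonferroni threshold uses the regional marker count.
    """
    region = panel
    if scaffold is not None:
        mask = panel.marker_map["scaffold"].to_numpy() == scaffold
        if not mask.any():
            raise ValueError(f"no markers on scaffold {scaffold!r}")
        region = panel.subset_markers(mask)
    if region.n_snps == 0:
        raise ValueError("empty candidate region")
    fit = fit_polygenic(fitness, grm)
    return association_scan(fit, region, alpha=alpha, lambda_correct=lambda_correct)
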
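"""Generalized linear mixed models with Gaussian random intercepts.

Fitting follows the lme4 recipe: for a candidate vector of variance
parameters the fixed effects and random-effect modes are found jointly by
penalized iteratively reweighted least squares (a damped Newton method on the
joint penalized log-likelihood), and the marginal likelihood is evaluated by
the Laplace approximation
``ll = f(β̂, û) − ½ log det(I + D^{1/2} Zᵀ W Z D^{1/2})``,
where ``f`` is the penalized log-likelihood, ``D`` the diagonal random-effect
covariance and ``W`` the negative second derivative of the observation
log-likelihood at the mode.  The outer optimization over (log) random-effect
standard deviations and any extra family parameters uses Nelder–Mead.

Families: Poisson (log link; non-integer responses allowed by evaluating the
density with the gamma-function generalization of the factorial), binomial
(logit), Gaussian (identity, residual SD profiled in the outer step) and
zero-inflated Poisson (log link count component, intercept-only structural
zero probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

class Family:
    name: str = ""
    n_extra: int = 0
    extra_names: tuple = ()

    def loglik(self, y, eta, extra):
        """Per-observation (loglik, d loglik/dη, d² loglik/dη²)."""
        raise NotImplementedError

    def mean(self, eta, extra):
        raise NotImplementedError

    def dmu_deta(self, eta, extra):
        raise NotImplementedError

    def check_response(self, y) -> None:
        pass


class PoissonLog(Family):
    name = "poisson"

    def loglik(self, y, eta, extra):
        mu = np.exp(eta)
        ll = y * eta - mu - gammaln(y + 1.0)
        return ll, y - mu, -mu

    def mean(self, eta, extra):
        return np.exp(eta)

    def dmu_deta(self, eta, extra):
        return np.exp(eta)

    def check_response(self, y) -> None:
        if (y < 0).any():
            raise ValueError("Poisson response must be non-negative")


class BinomialLogit(Family):
    name = "binomial"

    def loglik(self, y, eta, extra):
        p = expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        return ll, y - p, -p * (1.0 - p)

    def mean(self, eta, extra):
        return expit(eta)

    def dmu_deta(self, eta, extra):
        p = expit(eta)
        return p * (1.0 - p)

    def check_response(self, y) -> None:
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial response must be 0/1")


class GaussianIdentity(Family):
    name = "gaussian"
    n_extra = 1
    extra_names = ("log_resid_sd",)

    def loglik(self, y, eta, extra):
        s2 = np.exp(2.0 * extra[0])
        r = y - eta
        ll = -0.5 * (r * r / s2 + np.log(2.0 * np.pi * s2))
        return ll, r / s2, np.full_like(y, -1.0 / s2)

    def mean(self, eta, extra):
        return eta

    def dmu_deta(self, eta, extra):
        return np.ones_like(eta)


class ZIPoissonLog(Family):
    """Zero-inflated Poisson: structural zeros with intercept-only logit π."""

    name = "zip"
    n_extra = 1
    extra_names = ("logit_zi_prob",)

    def loglik(self, y, eta, extra):
        pi = expit(extra[0])
        mu = np.exp(eta)
        is_zero = y == 0
        ll = np.where(
            is_zero,
            np.log(pi + (1.0 - pi) * np.exp(-np.minimum(mu, 700.0))),
            np.log1p(-pi) + y * eta - mu - gammaln(y + 1.0),
        )
        g = (1.0 - pi) * np.exp(-np.minimum(mu, 700.0))
        denom = pi + g
        d1_zero = -g * mu / denom
        d2_zero = (g * mu * ((mu - 1.0) * denom) - (g * mu) ** 2) / denom**2
        d1 = np.where(is_zero, d1_zero, y - mu)
        d2 = np.where(is_zero, d2_zero, -mu)
        return ll, d1, d2

    def mean(self, eta, extra):
        return (1.0 - expit(extra[0])) * np.exp(eta)

    def dmu_deta(self, eta, extra):
        return (1.0 - expit(extra[0])) * np.exp(eta)

    def check_response(self, y) -> None:
        if (y < 0).any():
            raise ValueError("count response must be non-negative")
        if (y == 0).all():
            raise ValueError("all-zero response: zero-inflated model unidentifiable")


FAMILIES = {
    "poisson": PoissonLog,
    "poisson-log": PoissonLog,
    "binomial": BinomialLogit,
    "binomial-logit": BinomialLogit,
    "gaussian": GaussianIdentity,
    "gaussian-identity": GaussianIdentity,
    "zip": ZIPoissonLog,
    "zip-log": ZIPoissonLog,
}


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Expansion of model terms into columns with treatment coding."""

    terms: list
    columns: list
    # per categorical variable: ordered levels (first = reference)
    levels: dict


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def _term_columns(data: pd.DataFrame, var: str, levels: dict) -> tuple[np.ndarray, list]:
    s = data[var]
    if _is_categorical(s):
        if var not in levels:
            levels[var] = sorted(pd.unique(s.astype(str)))
        lv = levels[var]
        unknown = set(s.astype(str)) - set(lv)
        if unknown:
            raise ValueError(f"unknown level(s) {unknown} for {var!r}")
        cols = np.column_stack([(s.astype(str) == l).to_numpy(float) for l in lv[1:]]) \
            if len(lv) > 1 else np.empty((len(s), 0))
        names = [f"{var}[{l}]" for l in lv[1:]]
        return cols, names
    return s.to_numpy(float)[:, None], [var]


def build_design(
    data: pd.DataFrame,
    fixed_terms: Sequence[str],
    levels: dict | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + treatment-coded main effects and ``a:b`` interactions.

    Categorical variables use the first sorted level as reference (CC sorts
    before TC/TT, so the white homozygote is the reference genotype).
    ``levels`` can pre-pin level orderings (used when re-building rows for
    prediction).
    """
    levels = {} if levels is None else dict(levels)
    X_cols = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    for term in fixed_terms:
        parts = term.split(":")
        cols, nm = _term_columns(data, parts[0], levels)
        for p in parts[1:]:
            c2, n2 = _term_columns(data, p, levels)
            cols = np.einsum("ij,ik->ijk", cols, c2).reshape(len(data), -1)
            nm = [f"{a}:{b}" for a in nm for b in n2]
        X_cols.append(cols)
        names.extend(nm)
    X = np.hstack(X_cols)
    return X, DesignInfo(terms=list(fixed_terms), columns=names, levels=levels)


def _random_blocks(data: pd.DataFrame, random_terms: Sequence[str]):
    """One-hot matrix per grouping factor; <2-level groupings are dropped."""
    blocks, used, level_maps = [], [], []
    for g in random_terms:
        codes, lv = pd.factorize(data[g].astype(str), sort=True)
        if len(lv) < 2:
            log.warning("random intercept %r has <2 levels; dropped", g)
            continue
        Z = np.zeros((len(data), len(lv)))
        Z[np.arange(len(data)), codes] = 1.0
        blocks.append(Z)
        used.append(g)
        level_maps.append(list(lv))
    return blocks, used, level_maps


# ---------------------------------------------------------------------------
# model spec and fit containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Response, family, fixed terms and random-intercept groupings."""

    response: str
    family: str
    fixed: Sequence[str] = field(default_factory=list)
    random: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        mains = {t for t in self.fixed if ":" not in t}
        for t in self.fixed:
            for p in t.split(":"):
                if ":" not in t:
                    continue
                if p not in mains:
                    raise ValueError(f"interaction {t!r} references absent main effect {p!r}")


@dataclass
class ModelFit:
    """Fitted GLMM: coefficients, random-effect SDs, Laplace log-likelihood."""

    spec: ModelSpec
    params: pd.DataFrame  # term, estimate, se, ci_low, ci_high
    vcov: np.ndarray
    random_sd: dict
    extras: dict
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    design_info: DesignInfo
    random_groups: list
    u_modes: dict = field(default_factory=dict, repr=False)

    @property
    def coef(self) -> pd.Series:
        return self.params.set_index("term")["estimate"]

    def coef_row(self, name_fragment: str) -> pd.Series:
        hits = self.params[self.params["term"].str.contains(name_fragment, regex=False)]
        if len(hits) != 1:
            raise KeyError(f"{name_fragment!r} matches {len(hits)} terms")
        return hits.iloc[0]


# ---------------------------------------------------------------------------
# core fitting
# ---------------------------------------------------------------------------

def _pirls(family, y, X, Zb, d_var, extra, beta0=None, u0=None, max_iter=100, tol=1e-8):
    """Damped Newton on the joint penalized log-likelihood over (β, u)."""
    n, p = X.shape
    q = sum(Z.shape[1] for Z in Zb)
    Z = np.hstack(Zb) if Zb else np.zeros((n, 0))
    d_inv = np.concatenate(
        [np.full(Zb[k].shape[1], 1.0 / d_var[k]) for k in range(len(Zb))]
    ) if Zb else np.zeros(0)
    C = np.hstack([X, Z])
    theta = np.zeros(p + q)
    if beta0 is not None:
        theta[:p] = beta0
    if u0 is not None and u0.size == q:
        theta[p:] = u0

    def objective(th):
        eta = C @ th
        ll, d1, d2 = family.loglik(y, eta, extra)
        pen = 0.5 * np.sum(d_inv * th[p:] ** 2)
        return ll.sum() - pen, d1, d2

    f, d1, d2 = objective(theta)
    for _ in range(max_iter):
        grad = C.T @ d1
        grad[p:] -= d_inv * theta[p:]
        if np.max(np.abs(grad)) < tol:
            break
        W = np.maximum(-d2, 1e-10)
        H = (C * W[:, None]).T @ C
        H[p:, p:] += np.diag(d_inv) if q else 0.0
        H.flat[:: p + q + 1] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            f_new, d1_new, d2_new = objective(cand)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        else:
            break
        theta, f, d1, d2 = cand, f_new, d1_new, d2_new
    converged = np.max(np.abs(grad)) < 1e-6
    return theta[:p], theta[p:], f, d2, converged


def _laplace_loglik(family, y, X, Zb, d_var, extra, state):
    beta, u, f, d2, conv = _pirls(
        family, y, X, Zb, d_var, extra,
        beta0=state.get("beta"), u0=state.get("u", np.zeros(0)),
    )
    state["beta"], state["u"] = beta, u
    state["converged"] = conv
    if Zb:
        Z = np.hstack(Zb)
        W = np.maximum(-d2, 1e-10)
        sd = np.concatenate([np.full(Zb[k].shape[1], np.sqrt(d_var[k])) for k in range(len(Zb))])
        M = (Z * W[:, None]).T @ Z
        M = M * sd[:, None] * sd[None, :]
        M.flat[:: M.shape[0] + 1] += 1.0
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        return f - 0.5 * logdet
    return f


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, levels: dict | None = None) -> ModelFit:
    """Maximum-likelihood GLMM fit with the Laplace approximation.

    Random-intercept groupings with fewer than two levels are dropped with a
    warning.  Non-convergence is flagged on the returned fit (and the LRT
    refuses flagged fits).
    """
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    family = FAMILIES[spec.family]()
    y = data[spec.response].to_numpy(float)
    family.check_response(y)
    X, dinfo = build_design(data, spec.fixed, levels=levels)
    if not np.isfinite(X).all():
        raise ValueError("fixed-effect design contains non-finite values")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    Zb, groups, level_maps = _random_blocks(data, spec.random)

    k = len(Zb)
    n_extra = family.n_extra
    state: dict = {}

    def neg_ll(theta):
        d_var = np.exp(2.0 * np.clip(theta[:k], -8.0, 4.0))
        extra = theta[k:]
        return -_laplace_loglik(family, y, X, Zb, d_var, extra, state)

    x0 = np.concatenate([np.full(k, np.log(0.3)), np.zeros(n_extra)])
    if family.name == "gaussian":
        x0[k:] = np.log(max(np.std(y), 1e-3))
    if k + n_extra > 0:
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        theta_hat = res.x
        outer_ok = bool(res.success)
        loglik = -float(res.fun)
    else:
        theta_hat = x0
        outer_ok = True
        loglik = -neg_ll(theta_hat)
    # refresh state at the optimum
    loglik = -neg_ll(theta_hat)
    d_var = np.exp(2.0 * np.clip(theta_hat[:k], -8.0, 4.0))
    extra = theta_hat[k:]
    beta, u = state["beta"], state["u"]
    inner_ok = bool(state.get("converged", True))

    # conditional covariance of beta from the joint penalized Hessian
    eta = X @ beta + (np.hstack(Zb) @ u if Zb else 0.0)
    _, _, d2 = family.loglik(y, eta, extra)
    W = np.maximum(-d2, 1e-10)
    C = np.hstack([X] + Zb) if Zb else X
    H = (C * W[:, None]).T @ C
    p = X.shape[1]
    if Zb:
        d_inv = np.concatenate([np.full(Zb[j].shape[1], 1.0 / d_var[j]) for j in range(k)])
        H[p:, p:] += np.diag(d_inv)
    H.flat[:: H.shape[0] + 1] += 1e-10
    cov_full = np.linalg.inv(H)
    vcov = cov_full[:p, :p]
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    z = 1.959963984540054
    params = pd.DataFrame(
        {
            "term": dinfo.columns,
            "estimate": beta,
            "se": se,
            "ci_low": beta - z * se,
            "ci_high": beta + z * se,
        }
    )
    random_sd = {g: float(np.exp(np.clip(theta_hat[j], -8.0, 4.0))) for j, g in enumerate(groups)}
    extras = {nm: float(v) for nm, v in zip(family.extra_names, extra)}
    if family.name == "zip":
        extras["zi_prob"] = float(expit(extra[0]))
    if family.name == "gaussian":
        extras["resid_sd"] = float(np.exp(extra[0]))
    u_modes = {}
    off = 0
    for j, g in enumerate(groups):
        u_modes[g] = pd.Series(u[off : off + Zb[j].shape[1]], index=level_maps[j])
        off += Zb[j].shape[1]
    return ModelFit(
        spec=spec,
        params=params,
        vcov=vcov,
        random_sd=random_sd,
        extras=extras,
        loglik=float(loglik),
        n_params=p + k + n_extra,
        n_obs=len(y),
        converged=inner_ok and outer_ok,
        design_info=dinfo,
        random_groups=groups,
        u_modes=u_modes,
    )


def fit_zip_glmm(spec: ModelSpec, data: pd.DataFrame, **kw) -> ModelFit:
    """Zero-inflated Poisson GLMM (structural-zero component intercept-only)."""
    if FAMILIES[spec.family] is not ZIPoissonLog:
        spec = ModelSpec(spec.response, "zip", spec.fixed, spec.random)
    return fit_glmm(spec, data, **kw)
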
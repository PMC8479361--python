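"""Selection models: fitness and fitness components against colour genotype.

Wraps the GLMM engine with the analysis conventions of the study design:
annual individual fitness Λᵢ is modelled per sex with a Poisson log-link
GLMM and random intercepts for subpopulation and year (the Poisson density
is evaluated with the gamma-function generalization, so the continuous Λᵢ
needs no rounding; a rounding option is exposed for sensitivity checks);
fecundity uses a zero-inflated Poisson; survival, breeding and recruitment
probabilities use binomial logit GLMMs.  Genotype is a two-level factor
(CC reference, TC) after excluding the rare TT homozygotes; effects of the
environment enter as genotype × environment interactions tested by
likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from arcticfit.glmm import ModelFit, ModelSpec, build_design, fit_glmm, fit_zip_glmm

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_glmm",
    "fit_zip_glmm",
    "exclude_rare_tt",
    "likelihood_ratio_test",
    "genotype_environment_tests",
    "heterozygosity_fitness_model",
    "predict_genotype_fitness",
    "prune_nonsignificant_terms",
]


def exclude_rare_tt(data: pd.DataFrame, genotype_col: str = "genotype",
                    min_count: int = 10) -> pd.DataFrame:
    """Drop TT rows when the TT count per sex is below ``min_count``.

    Mirrors the study design where blue homozygotes were too rare to model.
    """
    if genotype_col not in data.columns:
        raise ValueError(f"column {genotype_col!r} missing")
    out = data
    for sex in out["sex"].unique() if "sex" in out.columns else [None]:
        sub = out if sex is None else out[out["sex"] == sex]
        n_tt = int((sub[genotype_col] == "TT").sum())
        if 0 < n_tt < min_count:
            log.info("excluding %d TT rows (sex=%s): below threshold %d", n_tt, sex, min_count)
            drop = (out[genotype_col] == "TT") if sex is None else \
                ((out[genotype_col] == "TT") & (out["sex"] == sex))
            out = out[~drop]
    return out.copy()


def likelihood_ratio_test(fit0: ModelFit, fit1: ModelFit) -> tuple[float, int, float]:
    """LRT of nested fits: χ² = 2(ll₁ − ll₀) clipped at zero.

    ``fit0`` must be nested in ``fit1`` (same response, family, data rows;
    fit0's terms a subset of fit1's).  Both fits must have converged.
    """
    if not (fit0.converged and fit1.converged):
        raise ValueError("refusing LRT on a non-converged fit")
    same_data = fit0.n_obs == fit1.n_obs
    same_model = (fit0.spec.response == fit1.spec.response
                  and fit0.spec.family == fit1.spec.family)
    nested = set(fit0.spec.fixed) <= set(fit1.spec.fixed) and \
        set(fit0.spec.random) <= set(fit1.spec.random)
    if not (same_data and same_model and nested):
        raise ValueError("fits are not nested on the same data")
    df = fit1.n_params - fit0.n_params
    if df <= 0:
        if set(fit0.spec.fixed) == set(fit1.spec.fixed) and \
                set(fit0.spec.random) == set(fit1.spec.random):
            return 0.0, 0, 1.0
        raise ValueError("larger model does not add parameters")
    chi2 = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    p = float(stats.chi2.sf(chi2, df=df)) if df > 0 else 1.0
    return chi2, df, p


def _drop_empty_cells(data: pd.DataFrame, genotype_col: str, env: str) -> pd.DataFrame:
    """Drop environment levels with an empty genotype × level cell (warned)."""
    if data[env].dtype.kind in "fiu":
        return data
    tab = pd.crosstab(data[env], data[genotype_col])
    bad = tab.index[(tab == 0).any(axis=1)]
    if len(bad):
        log.warning("dropping %s level(s) %s with empty genotype cells", env, list(bad))
        data = data[~data[env].isin(bad)]
    return data


def genotype_environment_tests(
    data: pd.DataFrame,
    base_spec: ModelSpec,
    environments: tuple = ("rodent_phase", "first_snowfall", "last_snowfall", "origin"),
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """LRT of genotype × environment interaction, one model per environment.

    Each row reports the χ², interaction degrees of freedom (e.g. 3 for a
    4-level rodent phase against a 2-level genotype contrast) and p-value;
    environments constant in the data are skipped with an explicit status.
    """
    rows = []
    for env in environments:
        if env not in data.columns:
            rows.append((env, np.nan, 0, np.nan, "absent"))
            continue
        if data[env].nunique() < 2:
            rows.append((env, np.nan, 0, np.nan, "skipped: constant"))
            continue
        sub = _drop_empty_cells(data, genotype_col, env)
        if sub[env].nunique() < 2:
            rows.append((env, np.nan, 0, np.nan, "skipped: empty cells"))
            continue
        fixed0 = list(base_spec.fixed)
        if env not in fixed0:
            fixed0 = fixed0 + [env]
        fixed1 = fixed0 + [f"{genotype_col}:{env}"]
        fit0 = fit_glmm(replace(base_spec, fixed=fixed0), sub)
        fit1 = fit_glmm(replace(base_spec, fixed=fixed1), sub)
        try:
            chi2, df, p = likelihood_ratio_test(fit0, fit1)
            rows.append((env, chi2, df, p, "ok"))
        except ValueError as err:
            rows.append((env, np.nan, 0, np.nan, f"failed: {err}"))
    return pd.DataFrame(rows, columns=["environment", "chi2", "df", "p", "status"])


def heterozygosity_fitness_model(
    fitness: pd.DataFrame,
    heterozygosity: pd.Series,
    genotype_col: str = "genotype",
    fitness_response: str = "Lambda_i",
    fitness_family: str = "poisson",
    random: tuple = ("year", "subpop"),
) -> dict:
    """Heterozygosity differences between genotypes, and whether genotype
    effects on fitness are heterozygosity-driven.

    Fits (1) a Gaussian model of genome-wide heterozygosity on genotype and
    origin with their interaction LRT, and (2) the fitness model with and
    without heterozygosity as a covariate, reporting LRTs for each.
    """
    data = fitness.copy()
    data["heterozygosity"] = data["id"].map(heterozygosity)
    data = data.dropna(subset=["heterozygosity"])
    per_ind = data.drop_duplicates("id")
    if per_ind["heterozygosity"].var() == 0:
        raise ValueError("heterozygosity is constant; model degenerate")

    het_spec = ModelSpec("heterozygosity", "gaussian",
                         fixed=[genotype_col, "origin"], random=[])
    het_fit = fit_glmm(het_spec, per_ind)
    het_fit0 = fit_glmm(replace(het_spec, fixed=["origin"]), per_ind)
    chi2_g, df_g, p_g = likelihood_ratio_test(het_fit0, het_fit)
    het_int = fit_glmm(replace(het_spec, fixed=[genotype_col, "origin",
                                                f"{genotype_col}:origin"]), per_ind)
    chi2_i, df_i, p_i = likelihood_ratio_test(het_fit, het_int)

    fit_base = fit_glmm(
        ModelSpec(fitness_response, fitness_family, fixed=[genotype_col], random=list(random)),
        data,
    )
    fit_het = fit_glmm(
        ModelSpec(fitness_response, fitness_family,
                  fixed=[genotype_col, "heterozygosity"], random=list(random)),
        data,
    )
    chi2_h, df_h, p_h = likelihood_ratio_test(fit_base, fit_het)
    return {
        "het_model": het_fit,
        "genotype_lrt": {"chi2": chi2_g, "df": df_g, "p": p_g},
        "genotype_origin_interaction_lrt": {"chi2": chi2_i, "df": df_i, "p": p_i},
        "fitness_het_fit": fit_het,
        "fitness_het_lrt": {"chi2": chi2_h, "df": df_h, "p": p_h},
    }


def predict_genotype_fitness(fit: ModelFit, genotype_levels,
                             genotype_col: str = "genotype") -> pd.DataFrame:
    """Population-level predictions per genotype with delta-method 95% CIs.

    Random effects are set to zero and other covariates to their reference
    (categoricals) or zero (numerics, which are centred in the pipeline).
    """
    if not fit.converged:
        raise ValueError("refusing predictions from a non-converged fit")
    levels = fit.design_info.levels
    if genotype_col not in levels:
        raise ValueError(f"{genotype_col!r} is not a factor of the fitted model")
    known = levels[genotype_col]
    from arcticfit.glmm import FAMILIES

    family = FAMILIES[fit.spec.family]()
    extra = np.array([fit.extras[n] for n in family.extra_names]) if family.extra_names else np.zeros(0)
    rows = []
    for g in genotype_levels:
        if g not in known:
            raise ValueError(f"genotype level {g!r} absent from the fit")
        ref_row = {}
        for var, lv in levels.items():
            ref_row[var] = g if var == genotype_col else lv[0]
        # numeric covariates at zero
        for term in fit.design_info.terms:
            for p in term.split(":"):
                if p not in ref_row:
                    ref_row[p] = 0.0
        row_df = pd.DataFrame([ref_row])
        X, _ = build_design(row_df, fit.design_info.terms, levels=levels)
        x = X[0]
        eta = float(x @ fit.coef.to_numpy())
        se_eta = float(np.sqrt(x @ fit.vcov @ x))
        mu = float(family.mean(np.array([eta]), extra)[0])
        dmu = float(family.dmu_deta(np.array([eta]), extra)[0])
        se_mu = abs(dmu) * se_eta
        rows.append((g, mu, se_mu, mu - 1.959963984540054 * se_mu,
                     mu + 1.959963984540054 * se_mu))
    return pd.DataFrame(rows, columns=["genotype", "prediction", "se", "ci_low", "ci_high"])


def prune_nonsignificant_terms(
    spec: ModelSpec,
    data: pd.DataFrame,
    candidate_terms: list,
    alpha: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Remove candidate (interaction) terms that fail their LRT at ``alpha``.

    Terms are tested one at a time against the model without them, least
    significant dropped first, following the report-main-effects-after-
    pruning convention.  Returns the pruned spec and the LRT log.
    """
    current = list(spec.fixed)
    records = []
    remaining = [t for t in candidate_terms if t in current]
    while remaining:
        results = []
        for term in remaining:
            reduced = [t for t in current if t != term]
            fit0 = fit_glmm(replace(spec, fixed=reduced), data)
            fit1 = fit_glmm(replace(spec, fixed=current), data)
            chi2, df, p = likelihood_ratio_test(fit0, fit1)
            results.append((term, chi2, df, p))
        results.sort(key=lambda r: -r[3])
        term, chi2, df, p = results[0]
        records.append((term, chi2, df, p, p >= alpha))
        if p >= alpha:
            current.remove(term)
            remaining.remove(term)
        else:
            for term, chi2, df, p in results[1:]:
                records.append((term, chi2, df, p, False))
            break
    logdf = pd.DataFrame(records, columns=["term", "chi2", "df", "p", "dropped"])
    return replace(spec, fixed=current), logdf
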
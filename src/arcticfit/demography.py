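"""Pre-breeding-census life-history coding, projection matrices and Λᵢ.

The census year t runs 1 April of t to 31 March of t+1 (foxes suffer most
mortality in winter, so the census sits just before breeding).  Individuals
enter the census at age class 1 the year after birth; age classes are pooled
at 5.  Annual survival Jᵢ is 1 when the individual is alive after 1 April of
t+1; fecundity Bᵢ counts the pups born in t that recruit into the t+1
census.  Per-sex Leslie matrices carry Fₓ = mean(Bᵢ)/2 on the top row (each
recruit is split between its two parents) and Pₓ = mean(Jᵢ) on the
subdiagonal with a survival self-loop for the pooled terminal class.  Annual
individual fitness is Λᵢ = (Bᵢ·v₁/2 + Jᵢ·v₍ₓ₊₁₎)/vₓ with v the reproductive
values (dominant left eigenvector, v₁ = 1, v₆ := v₅), so that E(Λᵢ) = λ,
the multiplicative growth rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from arcticfit.synthpop import rodent_phase

log = logging.getLogger(__name__)

MAX_AGE_CLASS = 5


def census_year_of(date) -> int:
    """Census year containing a calendar date (1 April – 31 March windows)."""
    ts = pd.Timestamp(date)
    return int(ts.year if ts.month >= 4 else ts.year - 1)


@dataclass
class DemographicModel:
    """Per-sex projection matrix with its growth rate and eigen structure."""

    sex: str
    A: np.ndarray
    growth_rate: float
    v: np.ndarray  # reproductive values, v[0] = 1
    u: np.ndarray  # stable age distribution, v·u = 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "sex": self.sex,
                "projection_matrix": self.A.tolist(),
                "growth_rate": self.growth_rate,
                "reproductive_values": self.v.tolist(),
                "stable_age_distribution": self.u.tolist(),
            },
            indent=2,
        )


def build_census(
    pedigree: pd.DataFrame,
    observations: pd.DataFrame,
    cycle_origin: int | None = None,
) -> pd.DataFrame:
    """One row per individual per census year alive, from last-alive dates.

    ``observations`` has columns ``id`` and either ``last_alive_year``
    (census year) or ``last_alive_date`` (calendar date, converted).  Age
    class is min(year − birth year, 5); survival Jᵢ is presence in the next
    census year.  An individual observed before its birth year is a
    data-integrity error.
    """
    obs = observations.copy()
    if "last_alive_year" not in obs.columns:
        obs["last_alive_year"] = obs["last_alive_date"].map(census_year_of)
    ped = pedigree.set_index("id")
    merged = obs.join(ped[["birth_year", "sex", "subpop", "origin"]], on="id")
    if merged["birth_year"].isna().any():
        raise ValueError("observations refer to individuals missing from the pedigree")
    if (merged["last_alive_year"] < merged["birth_year"]).any():
        bad = merged.loc[merged["last_alive_year"] < merged["birth_year"], "id"].tolist()
        raise ValueError(f"individuals observed before birth: {bad}")
    if cycle_origin is None:
        cycle_origin = int(merged["birth_year"].min())

    rows = []
    for rec in merged.itertuples(index=False):
        first = int(rec.birth_year) + 1  # pups enter at age class 1 the next census
        for t in range(first, int(rec.last_alive_year) + 1):
            x = min(t - int(rec.birth_year), MAX_AGE_CLASS)
            j = int(rec.last_alive_year >= t + 1)
            rows.append((rec.id, t, rec.sex, x, j, rec.subpop, rec.origin,
                         rodent_phase(t, cycle_origin)))
    return pd.DataFrame(
        rows,
        columns=["id", "year", "sex", "age_class", "survival", "subpop", "origin",
                 "rodent_phase"],
    )


def count_recruits(pedigree: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Attach Bᵢ (recruits) and the bred flag to each census record.

    A pup born in year t recruits when it holds a census record in t+1.
    ``bred`` is 1 when the individual is recorded as a parent of any pup born
    in t, whether or not the pup recruited.
    """
    present = set(zip(census["id"], census["year"]))
    recruits: dict[tuple, int] = {}
    bred: set[tuple] = set()
    for pup in pedigree.itertuples(index=False):
        by = int(pup.birth_year)
        recruited = (pup.id, by + 1) in present
        for parent in (pup.sire, pup.dam):
            if parent is None or (isinstance(parent, (int, np.integer)) and parent < 0) or pd.isna(parent):
                continue
            bred.add((parent, by))
            if recruited:
                recruits[(parent, by)] = recruits.get((parent, by), 0) + 1
    out = census.copy()
    keys = list(zip(out["id"], out["year"]))
    out["recruits"] = [recruits.get(k, 0) for k in keys]
    out["bred"] = [int(k in bred) for k in keys]
    return out


def build_projection_matrix(census_one_sex: pd.DataFrame, pool_empty: bool = True) -> np.ndarray:
    """Leslie-type pre-breeding matrix from one sex's census records.

    Top row Fₓ = mean(Bᵢ)/2 (the halving allocates each recruit equally to
    its two parents, mirroring the ½ in Λᵢ); subdiagonal Pₓ = mean(Jᵢ) for
    x = 1..4; A₅₅ = mean(J) of class 5 (self-loop for the pooled terminal
    class).  Empty age classes are filled with the pooled overall rate when
    ``pool_empty`` (logged), otherwise raise.
    """
    if len(census_one_sex) == 0:
        raise ValueError("empty census stratum")
    if "recruits" not in census_one_sex.columns:
        raise ValueError("census lacks recruit counts; run count_recruits first")
    F = np.zeros(MAX_AGE_CLASS)
    P = np.zeros(MAX_AGE_CLASS)
    overall_F = census_one_sex["recruits"].mean() / 2.0
    overall_P = census_one_sex["survival"].mean()
    for x in range(1, MAX_AGE_CLASS + 1):
        sub = census_one_sex[census_one_sex["age_class"] == x]
        if len(sub) == 0:
            if not pool_empty:
                raise ValueError(f"no census records in age class {x}")
            log.warning("age class %d empty; using pooled rates", x)
            F[x - 1], P[x - 1] = overall_F, overall_P
        else:
            F[x - 1] = sub["recruits"].mean() / 2.0
            P[x - 1] = sub["survival"].mean()
    A = np.zeros((MAX_AGE_CLASS, MAX_AGE_CLASS))
    A[0, :] = F
    for x in range(1, MAX_AGE_CLASS):
        A[x, x - 1] = P[x - 1]
    A[-1, -1] = P[-1]
    return A


def growth_rate(A: np.ndarray) -> float:
    """Dominant eigenvalue λ (real and positive for a valid Leslie matrix)."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("projection matrix must be non-negative")
    if not A.any():
        raise ValueError("zero projection matrix has no growth rate")
    vals = np.linalg.eigvals(A)
    lam = vals[np.argmax(vals.real)]
    if abs(lam.imag) > 1e-10 * max(abs(lam.real), 1.0):
        raise ValueError("dominant eigenvalue is complex; matrix is not Leslie-like")
    return float(lam.real)


def reproductive_values(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reproductive values v (left eigenvector, v₁ = 1) and stable age
    distribution u (right eigenvector, scaled so v·u = 1)."""
    A = np.asarray(A, dtype=float)
    lam = growth_rate(A)
    vals_r, vecs_r = np.linalg.eig(A)
    iu = int(np.argmax(vals_r.real))
    vals_l, vecs_l = np.linalg.eig(A.T)
    iv = int(np.argmax(vals_l.real))
    if abs(vals_r[iu].imag) > 1e-10 or abs(vals_l[iv].imag) > 1e-10:
        raise ValueError("complex dominant eigenpair")
    u = vecs_r[:, iu].real
    v = vecs_l[:, iv].real
    if v[0] == 0:
        raise ValueError("reproductive value of the first age class is zero")
    v = v / v[0]
    if (v < -1e-10).any() or (u * np.sign(u.sum()) < -1e-10).any():
        raise ValueError("dominant eigenvectors are not non-negative")
    v = np.maximum(v, 0.0)
    u = u * np.sign(u.sum())
    u = u / (v @ u)
    # eigen identities to tight tolerance
    if max(np.abs(v @ A - lam * v).max(), np.abs(A @ u - lam * u).max()) > 1e-8:
        raise ValueError("eigenvector residual too large")
    return v, u


def fit_demographic_model(census_one_sex: pd.DataFrame, sex: str) -> DemographicModel:
    """Mean projection matrix, growth rate and reproductive values for one sex."""
    A = build_projection_matrix(census_one_sex)
    lam = growth_rate(A)
    v, u = reproductive_values(A)
    return DemographicModel(sex=sex, A=A, growth_rate=lam, v=v, u=u)


def individual_fitness(census: pd.DataFrame, models: dict[str, DemographicModel]) -> pd.DataFrame:
    """Annual individual fitness Λᵢ = (Bᵢ·v₁/2 + Jᵢ·v₍ₓ₊₁₎)/vₓ per record.

    ``models`` maps sex label to its DemographicModel; the terminal
    convention v₆ := v₅ matches the pooled-class self-loop.  Wᵢ = Λᵢ·vₓ and
    the two components are returned alongside.
    """
    out = census.copy()
    lam_i = np.empty(len(out))
    w_i = np.empty(len(out))
    comp_b = np.empty(len(out))
    comp_j = np.empty(len(out))
    for sex, model in models.items():
        mask = (out["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        v = model.v
        v_ext = np.append(v, v[-1])  # v₆ := v₅
        x = out.loc[mask, "age_class"].to_numpy(dtype=int)
        B = out.loc[mask, "recruits"].to_numpy(dtype=float)
        J = out.loc[mask, "survival"].to_numpy(dtype=float)
        cb = B * v[0] / 2.0
        cj = J * v_ext[x]  # v_{x+1} with 0-based v
        lam_i[mask] = (cb + cj) / v[x - 1]
        w_i[mask] = cb + cj
        comp_b[mask], comp_j[mask] = cb, cj
    known = out["sex"].isin(models.keys()).to_numpy()
    if not known.all():
        raise ValueError("census contains sexes without a demographic model")
    out["Lambda_i"] = lam_i
    out["W_i"] = w_i
    out["component_recruits"] = comp_b
    out["component_survival"] = comp_j
    return out
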
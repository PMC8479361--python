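"""Census coding, Leslie matrices, reproductive values and Λᵢ."""

import numpy as np
import pandas as pd
import pytest

from arcticfit import demography
from arcticfit.demography import (
    DemographicModel,
    build_census,
    build_projection_matrix,
    census_year_of,
    count_recruits,
    growth_rate,
    individual_fitness,
    reproductive_values,
)


def _model(v, sex="F", lam=1.0):
    v = np.asarray(v, dtype=float)
    u = np.ones_like(v)
    u = u / (v @ u)
    return DemographicModel(sex=sex, A=np.eye(len(v)), growth_rate=lam, v=v, u=u)


# ------------------------------------------------------------------ census

def test_census_calendar_hand_traced():
    """Born 2010, last seen June 2012 → records 2011 (x=1, J=1), 2012 (x=2, J=0)."""
    ped = pd.DataFrame(
        {"id": [1], "sire": [-1], "dam": [-1], "birth_year": [2010],
         "sex": ["F"], "subpop": [1], "origin": ["wild"]}
    )
    obs = pd.DataFrame({"id": [1], "last_alive_date": ["2012-06-15"]})
    census = build_census(ped, obs, cycle_origin=2007)
    assert census_year_of("2012-06-15") == 2012
    assert census_year_of("2012-02-15") == 2011  # before 1 April → previous census
    assert len(census) == 2
    r2011 = census[census["year"] == 2011].iloc[0]
    r2012 = census[census["year"] == 2012].iloc[0]
    assert (r2011["age_class"], r2011["survival"]) == (1, 1)
    assert (r2012["age_class"], r2012["survival"]) == (2, 0)


def test_age_class_pooled_at_five():
    ped = pd.DataFrame(
        {"id": [1], "sire": [-1], "dam": [-1], "birth_year": [2007],
         "sex": ["M"], "subpop": [1], "origin": ["wild"]}
    )
    obs = pd.DataFrame({"id": [1], "last_alive_year": [2014]})
    census = build_census(ped, obs)
    assert census["age_class"].max() == 5
    assert (census.loc[census["year"] >= 2012, "age_class"] == 5).all()


def test_pup_seen_only_in_birth_summer_has_no_record():
    ped = pd.DataFrame(
        {"id": [1], "sire": [-1], "dam": [-1], "birth_year": [2010],
         "sex": ["F"], "subpop": [1], "origin": ["wild"]}
    )
    obs = pd.DataFrame({"id": [1], "last_alive_year": [2010]})
    assert len(build_census(ped, obs)) == 0


def test_observation_before_birth_rejected():
    ped = pd.DataFrame(
        {"id": [1], "sire": [-1], "dam": [-1], "birth_year": [2012],
         "sex": ["F"], "subpop": [1], "origin": ["wild"]}
    )
    obs = pd.DataFrame({"id": [1], "last_alive_year": [2010]})
    with pytest.raises(ValueError, match="before birth"):
        build_census(ped, obs)


def test_census_matches_simulator_ground_truth(small_sim):
    """Census derived from pedigree + last-alive dates reproduces the
    simulator's own life-history coding (dual-route consistency)."""
    lh = small_sim.life_history
    y0, y1 = int(lh["year"].min()), int(lh["year"].max())
    census = build_census(small_sim.pedigree, small_sim.observations, cycle_origin=y0)
    census = count_recruits(small_sim.pedigree, census)
    census = census[(census["year"] >= y0) & (census["year"] <= y1)]
    merged = census.merge(lh, on=["id", "year"], suffixes=("_c", "_t"))
    assert len(merged) == len(lh)
    assert (merged["age_class_c"] == merged["age_class_t"]).all()
    assert (merged["survival_c"] == merged["survival_t"]).all()
    assert (merged["recruits_c"] == merged["recruits_t"]).all()
    assert (merged["bred_c"] == merged["bred_t"]).all()


def test_count_recruits_cases():
    ped = pd.DataFrame(
        {
            "id": [1, 2, 10, 11, 12, 13],
            "sire": [-1, -1, 1, 1, 1, 1],
            "dam": [-1, -1, 2, 2, 2, 2],
            "birth_year": [2008, 2008, 2010, 2010, 2011, 2011],
            "sex": ["M", "F", "F", "M", "F", "M"],
            "subpop": [1] * 6,
            "origin": ["wild"] * 6,
        }
    )
    # pups 10 recruits (alive 2011), 11 does not; 2011 litter (12, 13) no recruits
    obs = pd.DataFrame({"id": [1, 2, 10, 11, 12, 13],
                        "last_alive_year": [2012, 2012, 2011, 2010, 2011, 2011]})
    census = count_recruits(ped, build_census(ped, obs))
    sire_2010 = census.query("id == 1 and year == 2010").iloc[0]
    assert (sire_2010["recruits"], sire_2010["bred"]) == (1, 1)
    sire_2011 = census.query("id == 1 and year == 2011").iloc[0]
    assert (sire_2011["recruits"], sire_2011["bred"]) == (0, 1)  # bred, no recruits
    dam_2009 = census.query("id == 2 and year == 2009").iloc[0]
    assert (dam_2009["recruits"], dam_2009["bred"]) == (0, 0)  # non-parent year


# ------------------------------------------------------------------ projection matrix

def _census_from_rates(B_by_class, J_by_class):
    rows = []
    for x, (bs, js) in enumerate(zip(B_by_class, J_by_class), start=1):
        for b, j in zip(bs, js):
            rows.append((x, b, j))
    df = pd.DataFrame(rows, columns=["age_class", "recruits", "survival"])
    df["sex"] = "F"
    return df


def test_projection_matrix_means_of_constants():
    census = _census_from_rates(
        [[2, 2]] * 5, [[1, 1]] * 5
    )
    A = build_projection_matrix(census)
    assert np.allclose(A[0], 1.0)  # F = mean(B)/2 = 1
    assert np.allclose(np.diag(A, -1), 1.0)
    assert A[4, 4] == 1.0


def test_projection_matrix_no_breeding_at_age_one():
    census = _census_from_rates(
        [[0, 0], [2, 2], [2, 2], [2, 2], [2, 2]], [[1, 0]] * 5
    )
    A = build_projection_matrix(census)
    assert A[0, 0] == 0.0
    assert A[0, 1] == 1.0
    assert np.allclose(np.diag(A, -1), 0.5)


def test_two_class_toy_lambda_one():
    """F = (0, 2), P₁ = 0.5 → λ² = F₂P₁ = 1."""
    A = np.array([[0.0, 2.0], [0.5, 0.0]])
    assert growth_rate(A) == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------ eigen structure

def test_growth_rate_properties():
    assert growth_rate(np.diag([0.9, 0.8, 0.3])) == pytest.approx(0.9)
    A = np.array([[0.2, 1.5], [0.6, 0.1]])
    assert growth_rate(3 * A) == pytest.approx(3 * growth_rate(A))
    with pytest.raises(ValueError):
        growth_rate(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        growth_rate(np.array([[0.1, -0.2], [0.3, 0.1]]))


def test_reproductive_values_closed_form():
    A = np.array([[0.0, 2.0], [0.5, 0.0]])
    v, u = reproductive_values(A)
    np.testing.assert_allclose(v, [1.0, 2.0], atol=1e-10)
    assert v @ u == pytest.approx(1.0, abs=1e-12)
    lam = growth_rate(A)
    assert np.abs(v @ A - lam * v).max() < 1e-10
    assert np.abs(A @ u - lam * u).max() < 1e-10


def test_symmetric_matrix_v_proportional_to_u():
    A = np.array([[0.5, 0.3, 0.0], [0.3, 0.4, 0.2], [0.0, 0.2, 0.6]])
    v, u = reproductive_values(A)
    ratio = v / u
    assert np.allclose(ratio, ratio[0])


def test_terminal_fecundity_raises_terminal_reproductive_value():
    base = np.array([
        [0.0, 0.5, 0.8, 0.8, 0.4],
        [0.5, 0, 0, 0, 0],
        [0, 0.6, 0, 0, 0],
        [0, 0, 0.6, 0, 0],
        [0, 0, 0, 0.5, 0.4],
    ])
    v0, _ = reproductive_values(base)
    bumped = base.copy()
    bumped[0, 4] += 0.8
    v1, _ = reproductive_values(bumped)
    assert v1[4] / v1[0] > v0[4] / v0[0]


# ------------------------------------------------------------------ Λᵢ

def test_lambda_i_arithmetic():
    model = _model([1.0, 2.0])
    rec = pd.DataFrame(
        {"id": [1], "year": [2010], "sex": ["F"], "age_class": [1],
         "survival": [1], "recruits": [1]}
    )
    # terminal convention inside a 2-class model: v₃ := v₂
    out = individual_fitness(rec, {"F": model})
    assert out["Lambda_i"].iloc[0] == pytest.approx((0.5 + 2.0) / 1.0)
    assert out["W_i"].iloc[0] == pytest.approx(2.5)


def test_lambda_i_zero_when_dead_and_barren():
    model = _model([1.0, 1.4, 1.2, 1.0, 0.8])
    rec = pd.DataFrame(
        {"id": [1], "year": [2010], "sex": ["F"], "age_class": [3],
         "survival": [0], "recruits": [0]}
    )
    assert individual_fitness(rec, {"F": model})["Lambda_i"].iloc[0] == 0.0


def test_lambda_i_terminal_class_self_loop():
    model = _model([1.0, 1.4, 1.2, 1.0, 0.8])
    rec = pd.DataFrame(
        {"id": [1], "year": [2010], "sex": ["F"], "age_class": [5],
         "survival": [1], "recruits": [0]}
    )
    # v₆ := v₅ so a surviving, non-breeding terminal individual has Λ = 1
    assert individual_fitness(rec, {"F": model})["Lambda_i"].iloc[0] == pytest.approx(1.0)


def test_lambda_i_invariant_to_rescaling_v():
    rng = np.random.default_rng(0)
    rec = pd.DataFrame(
        {"id": np.arange(20), "year": 2010, "sex": "F",
         "age_class": rng.integers(1, 6, 20),
         "survival": rng.integers(0, 2, 20),
         "recruits": rng.poisson(1.0, 20)}
    )
    v = np.array([1.0, 1.3, 1.1, 0.9, 0.7])
    out1 = individual_fitness(rec, {"F": _model(v)})
    out7 = individual_fitness(rec, {"F": _model(7 * v)})
    np.testing.assert_allclose(out1["Lambda_i"], out7["Lambda_i"], rtol=1e-12)


def test_recruit_halving_conserves_recruits(small_sim):
    """Σ over parents of Bᵢ/2 equals the total recruit count (both parents
    are always known in the simulator)."""
    lh = small_sim.life_history
    ped = small_sim.pedigree
    y1 = int(lh["year"].max())
    # recruits: pups with a census record (alive the year after birth)
    recruited = ped[(ped["sire"] >= 0) & (ped["birth_year"] < y1)]
    alive_next = recruited["id"].isin(lh["id"])
    total_recruits = int(alive_next.sum())
    allocated = lh.loc[lh["year"] < y1, "recruits"].sum() / 2.0
    assert allocated == pytest.approx(total_recruits)


def test_mean_lambda_i_equals_growth_rate_from_same_census(small_sim):
    """When A is estimated from the census itself, the mean of Λᵢ equals λ
    exactly (the reproductive-value weighting identity)."""
    lh = small_sim.life_history
    for sex in ("F", "M"):
        sub = lh[lh["sex"] == sex]
        model = demography.fit_demographic_model(sub, sex)
        fit = individual_fitness(sub, {sex: model})
        # stage-weighted identity: Σₓ nₓ (vA)ₓ / vₓ = λ Σₓ nₓ
        assert fit["Lambda_i"].mean() == pytest.approx(model.growth_rate, rel=1e-10)
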
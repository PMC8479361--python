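"""Forward simulation of a pedigreed, age-structured fox population.

The generator emulates the structure of a Scandinavian Arctic fox study
population: a pre-breeding census (1 April – 31 March), five age classes with
the oldest class pooled, socially monogamous annual pairing within
subpopulations, a biallelic autosomal colour locus where T (blue) is dominant
over C (white), a SNP panel with an LD block around the causal locus, field
phenotyping error, captive/wild origin labels, a four-phase rodent cycle and
snow-season covariates.  All ground-truth parameters live in
:class:`SimConfig` so recovery tests can check them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from arcticfit.panel import COLOUR_GENOTYPES, GenotypePanel

RODENT_PHASES = ("low", "increase", "peak", "decline")


@dataclass
class VitalRates:
    """Per-sex, per-age-class annual survival and mean recruit rates.

    ``survival[sex][x-1]`` is the probability an age-class-x individual is
    alive at the next census; ``recruits[sex][x-1]`` is the mean number of
    recruits (pups alive at the next census) credited to a breeding
    individual of that class.  Defaults give a population with multiplicative
    growth close to one, which is the regime of the monitored population.
    """

    survival: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "F": (0.50, 0.60, 0.60, 0.55, 0.45),
            "M": (0.50, 0.60, 0.60, 0.55, 0.45),
        }
    )
    recruits: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "F": (0.8, 1.6, 1.8, 1.6, 1.2),
            "M": (0.8, 1.6, 1.8, 1.6, 1.2),
        }
    )

    def validate(self) -> None:
        for table in (self.survival, self.recruits):
            for sex in ("F", "M"):
                rates = np.asarray(table[sex], dtype=float)
                if rates.shape != (5,) or (rates < 0).any():
                    raise ValueError("vital rates must be five non-negative values per sex")
        for sex in ("F", "M"):
            if np.any(np.asarray(self.survival[sex]) > 1):
                raise ValueError("survival rates must be probabilities")


@dataclass
class SimConfig:
    """Ground-truth parameters for one simulated study population."""

    n_founders: int = 200
    n_years: int = 12
    n_subpops: int = 4
    start_year: int = 2007
    T_allele_freq: float = 0.11
    # multiplier on survival and fecundity rates per colour genotype (truth b)
    genotype_fitness_effects: Mapping[str, float] = field(
        default_factory=lambda: {"CC": 1.0, "TC": 1.15, "TT": 1.15}
    )
    phenotyping_error_rate: float = 0.015
    vital_rates: VitalRates = field(default_factory=VitalRates)
    rodent_cycle_phases: tuple = RODENT_PHASES
    # fecundity multiplier through the rodent cycle (food-driven litters)
    rodent_fecundity_effect: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.5, "increase": 1.4, "peak": 1.6, "decline": 0.7}
    )
    rodent_survival_effect: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.92, "increase": 1.04, "peak": 1.08, "decline": 0.96}
    )
    # day-of-year means/sds of first (autumn) and last (spring) snowfall
    snow_params: Mapping[str, float] = field(
        default_factory=lambda: {
            "first_mean": 280.0,
            "first_sd": 10.0,
            "last_mean": 120.0,
            "last_sd": 10.0,
        }
    )
    n_snps: int = 1000
    n_scaffolds: int = 20
    causal_scaffold: int = 11
    snp_spacing_bp: int = 10_000
    ld_block_half_width: int = 1_000_000
    ld_decay_rate: float = 1.05e-5
    breeding_prob: float = 0.75
    # probability a den-marked pup survives to recruit at the next census;
    # litter sizes are drawn so the recruit rate matches vital_rates.recruits
    pup_recruit_prob: float = 0.55
    year_sd: float = 0.20
    subpop_sd: float = 0.15
    captive_fraction: float = 0.30
    missing_genotype_rate: float = 0.0
    # uniform per-individual-year probability of a missed census observation
    miss_detection_prob: float = 0.0
    max_pairs_per_subpop: int | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "T_allele_freq",
            "phenotyping_error_rate",
            "breeding_prob",
            "captive_fraction",
            "missing_genotype_rate",
            "miss_detection_prob",
            "pup_recruit_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if len(self.rodent_cycle_phases) != 4:
            raise ValueError("rodent cycle must have period 4")
        if self.n_founders < 2 or self.n_years < 1 or self.n_subpops < 1:
            raise ValueError("need at least 2 founders, 1 year and 1 subpopulation")
        if any(m < 0 for m in self.genotype_fitness_effects.values()):
            raise ValueError("genotype fitness multipliers must be non-negative")
        self.vital_rates.validate()


def rodent_phase(year: int, cycle_origin: int = 2007, phases: Sequence[str] = RODENT_PHASES) -> str:
    """Phase of the deterministic 4-year rodent cycle for a census year."""
    return phases[(year - cycle_origin) % 4]


def assign_colour_phenotype(colour_genotype, error_rate: float, rng: np.random.Generator):
    """Colour phenotype under recessive-white inheritance with field error.

    CC is white, TC and TT are blue; with probability ``error_rate`` the
    opposite phenotype is recorded (mis-phenotyping in the field is assumed
    symmetric).  Accepts a scalar genotype or an array.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must lie in [0, 1], got {error_rate}")
    geno = np.atleast_1d(np.asarray(colour_genotype, dtype=object))
    if not np.isin(geno, COLOUR_GENOTYPES).all():
        raise ValueError("genotypes must be CC, TC or TT")
    mendelian = np.where(geno == "CC", "white", "blue")
    flip = rng.random(geno.shape) < error_rate
    pheno = np.where(flip, np.where(mendelian == "white", "blue", "white"), mendelian)
    if np.isscalar(colour_genotype) or isinstance(colour_genotype, str):
        return pheno.item()
    return pheno


# ---------------------------------------------------------------------------
# marker map and founder haplotypes
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


def build_marker_map(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, int]:
    """Evenly spaced markers over ``n_scaffolds``; the causal locus sits in
    the middle of the causal scaffold.  Returns (map, causal_index)."""
    per = np.full(config.n_scaffolds, config.n_snps // config.n_scaffolds)
    per[: config.n_snps % config.n_scaffolds] += 1
    rows = []
    for s, count in enumerate(per, start=1):
        for j in range(count):
            rows.append((f"scaffold_{s}", j * config.snp_spacing_bp))
    mmap = pd.DataFrame(rows, columns=["scaffold", "pos"])
    causal_scaffold = f"scaffold_{min(config.causal_scaffold, config.n_scaffolds)}"
    on_scaffold = np.flatnonzero(mmap["scaffold"].to_numpy() == causal_scaffold)
    causal_index = int(on_scaffold[len(on_scaffold) // 2])
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=len(mmap))
    mmap["a1"] = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    mmap["a2"] = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    # the colour locus is C (white, reference) / T (blue, alternate)
    mmap.loc[causal_index, ["a1", "a2"]] = ["C", "T"]
    mmap["snp_id"] = [
        f"AX{si + 1:07d}" if si != causal_index else "AX_COLOUR"
        for si in range(len(mmap))
    ]
    return mmap, causal_index


def simulate_linked_snps(
    config: SimConfig,
    founder_causal_haplotypes: np.ndarray,
    rng: np.random.Generator,
    marker_map: pd.DataFrame | None = None,
    causal_index: int | None = None,
) -> np.ndarray:
    """Founder haplotypes for the whole panel given causal-locus haplotypes.

    Markers within ``ld_block_half_width`` of the causal locus on its
    scaffold copy the causal allele state with probability
    ``exp(-ld_decay_rate * d / 2)`` (else draw independently at the causal
    allele frequency), so the expected founder r² at distance d is
    ``exp(-ld_decay_rate * d)``.  Markers outside the block are independent
    with allele frequencies uniform on (0.1, 0.9).
    """
    if marker_map is None:
        marker_map, causal_index = build_marker_map(config, rng)
    hap_c = np.asarray(founder_causal_haplotypes, dtype=np.int8)
    n_hap = hap_c.shape[0]
    m = len(marker_map)
    p_causal = hap_c.mean() if 0 < hap_c.mean() < 1 else config.T_allele_freq
    scaff = marker_map["scaffold"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    dist = np.abs(pos - pos[causal_index])
    in_block = (scaff == scaff[causal_index]) & (dist <= config.ld_block_half_width)

    haps = np.empty((n_hap, m), dtype=np.int8)
    freqs = rng.uniform(0.1, 0.9, size=m)
    haps[:] = (rng.random((n_hap, m)) < freqs[None, :]).astype(np.int8)
    # LD block: copy-with-probability construction gives corr = copy prob
    copy_prob = np.exp(-config.ld_decay_rate * dist[in_block] / 2.0)
    copied = rng.random((n_hap, in_block.sum())) < copy_prob[None, :]
    indep = (rng.random((n_hap, in_block.sum())) < p_causal).astype(np.int8)
    haps[:, in_block] = np.where(copied, hap_c[:, None], indep)
    haps[:, causal_index] = hap_c
    return haps


def _meiosis(config, hap_a, hap_b, block_cols, block_rec, rng):
    """One gamete: free recombination between scaffolds/outside the block,
    exponential-distance linkage inside the block."""
    m = hap_a.shape[0]
    choose_b = rng.random(m) < 0.5
    if block_cols.size:
        start = rng.random() < 0.5
        switches = rng.random(block_cols.size - 1) < block_rec
        track = np.empty(block_cols.size, dtype=bool)
        track[0] = start
        np.logical_xor.accumulate(np.concatenate(([start], switches)), out=track)
        choose_b[block_cols] = track
    return np.where(choose_b, hap_b, hap_a)


class PopulationExtinct(Exception):
    """Raised internally; surfaced through SimulationResult.extinct."""


@dataclass
class SimulationResult:
    pedigree: pd.DataFrame
    panel: GenotypePanel | None
    life_history: pd.DataFrame
    phenotypes: pd.Series | None
    observations: pd.DataFrame
    extinct: bool
    extinct_year: int | None
    config: SimConfig


def simulate_population(config: SimConfig, rng: np.random.Generator | None = None) -> SimulationResult:
    """Evolve the population year by year under the configured vital rates.

    Returns the pedigree, genotype panel, life-history table (one row per
    individual per census year alive at age ≥ 1), colour phenotypes and an
    observation table of last-alive census years.  Identical seeds give
    bit-identical outputs.  If the population dies out the run is returned
    with ``extinct=True`` rather than raising.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    marker_map, causal_index = build_marker_map(config, rng)
    n = config.n_founders
    founder_causal = (rng.random(2 * n) < config.T_allele_freq).astype(np.int8)
    founder_haps = simulate_linked_snps(config, founder_causal, rng, marker_map, causal_index)

    pos = marker_map["pos"].to_numpy()
    scaff = marker_map["scaffold"].to_numpy()
    dist = np.abs(pos - pos[causal_index])
    in_block = (scaff == scaff[causal_index]) & (dist <= config.ld_block_half_width)
    block_cols = np.flatnonzero(in_block)
    block_gaps = np.diff(pos[block_cols])
    block_rec = 0.5 * (1.0 - np.exp(-config.ld_decay_rate * block_gaps))

    # per-individual state, grown as lists of arrays
    hapA = [founder_haps[2 * i] for i in range(n)]
    hapB = [founder_haps[2 * i + 1] for i in range(n)]
    sex = list(rng.permuted(np.array(["F", "M"] * (n // 2 + 1))[:n]))
    subpop = list(rng.integers(1, config.n_subpops + 1, size=n))
    origin = list(np.where(rng.random(n) < config.captive_fraction, "captive", "wild"))
    # founders start at ages 1..3 so every age class fills within a few years
    founder_age = rng.integers(1, 4, size=n)
    birth_year = list(config.start_year - founder_age)
    sire = [-1] * n
    dam = [-1] * n
    den = list(rng.integers(1, 4 * config.n_subpops + 1, size=n))
    alive = list(np.ones(n, dtype=bool))
    last_alive = [config.start_year - 1] * n  # updated each survived census

    year_eff_f = np.exp(rng.normal(0.0, config.year_sd, size=config.n_years))
    year_eff_s = np.exp(rng.normal(0.0, config.year_sd / 2.0, size=config.n_years))
    sub_eff_f = np.exp(rng.normal(0.0, config.subpop_sd, size=config.n_subpops + 1))
    sub_eff_s = np.exp(rng.normal(0.0, config.subpop_sd / 2.0, size=config.n_subpops + 1))
    snow = config.snow_params
    snow_first = rng.normal(snow["first_mean"], snow["first_sd"], size=config.n_years)
    snow_last = rng.normal(snow["last_mean"], snow["last_sd"], size=config.n_years)

    geno_mult = config.genotype_fitness_effects
    surv_rates = {s: np.asarray(config.vital_rates.survival[s], float) for s in ("FM")}
    rec_rates = {s: np.asarray(config.vital_rates.recruits[s], float) for s in ("FM")}

    lh_rows: list[tuple] = []
    extinct = False
    extinct_year = None

    def colour_of(i: int) -> str:
        return COLOUR_GENOTYPES[int(hapA[i][causal_index] + hapB[i][causal_index])]

    for yi in range(config.n_years):
        t = config.start_year + yi
        phase = rodent_phase(t, config.start_year, config.rodent_cycle_phases)
        adults = [i for i in range(len(alive)) if alive[i] and birth_year[i] < t]
        if not adults:
            extinct, extinct_year = True, t
            break

        # --- seasonal monogamous pairing within subpopulation -------------
        mate: dict[int, int] = {}
        for sp in range(1, config.n_subpops + 1):
            females = [i for i in adults if subpop[i] == sp and sex[i] == "F"]
            males = [i for i in adults if subpop[i] == sp and sex[i] == "M"]
            rng.shuffle(females)
            rng.shuffle(males)
            n_pairs = min(len(females), len(males))
            if config.max_pairs_per_subpop is not None:
                n_pairs = min(n_pairs, config.max_pairs_per_subpop)
            for f, m_ in zip(females[:n_pairs], males[:n_pairs]):
                mate[f] = m_
                mate[m_] = f

        # --- breeding: litters drawn per pair; pups recruit independently ---
        recruits_of = dict.fromkeys(adults, 0)
        bred_of = dict.fromkeys(adults, 0)
        newborn: list[tuple[int, int, bool]] = []  # (dam, sire, recruited)
        p_rec = config.pup_recruit_prob
        for f, m_ in mate.items():
            if sex[f] != "F":
                continue
            if rng.random() >= config.breeding_prob:
                continue
            x_f = min(t - birth_year[f], 5)
            rate = (
                rec_rates["F"][x_f - 1]
                * config.rodent_fecundity_effect[phase]
                * year_eff_f[yi]
                * sub_eff_f[subpop[f]]
                * np.sqrt(geno_mult[colour_of(f)] * geno_mult[colour_of(m_)])
            )
            # litter scaled so the recruit rate keeps its configured mean
            n_pups = rng.poisson(rate / p_rec) if p_rec > 0 else 0
            if n_pups == 0:
                continue
            bred_of[f] = bred_of[m_] = 1
            recruited = rng.random(n_pups) < p_rec
            n_rec = int(recruited.sum())
            recruits_of[f] += n_rec
            recruits_of[m_] += n_rec
            newborn.extend((f, m_, bool(r)) for r in recruited)

        # --- survival of current individuals -------------------------------
        survived = dict.fromkeys(adults, 0)
        for i in adults:
            x = min(t - birth_year[i], 5)
            p = (
                surv_rates[sex[i]][x - 1]
                * config.rodent_survival_effect[phase]
                * year_eff_s[yi]
                * sub_eff_s[subpop[i]]
                * geno_mult[colour_of(i)]
            )
            j = int(rng.random() < min(p, 0.97))
            survived[i] = j
            # survivors are known alive after 1 April of t+1
            last_alive[i] = t + 1 if j else t
            if not j:
                alive[i] = False

        for i in adults:
            x = min(t - birth_year[i], 5)
            observed = rng.random() >= config.miss_detection_prob
            lh_rows.append(
                (
                    i, t, sex[i], x, survived[i], recruits_of[i], bred_of[i],
                    subpop[i], origin[i], phase,
                    snow_first[yi], snow_last[yi], observed,
                )
            )

        # --- pup genotypes via Mendelian transmission ------------------------
        for f, m_, recruited_pup in newborn:
            gam_f = _meiosis(config, hapA[f], hapB[f], block_cols, block_rec, rng)
            gam_m = _meiosis(config, hapA[m_], hapB[m_], block_cols, block_rec, rng)
            hapA.append(gam_f)
            hapB.append(gam_m)
            sex.append("F" if rng.random() < 0.5 else "M")
            subpop.append(subpop[f])
            origin.append("wild")
            birth_year.append(t)
            sire.append(m_)
            dam.append(f)
            den.append(den[f])
            alive.append(recruited_pup)
            # a recruit is by definition alive after 1 April of t+1
            last_alive.append(t + 1 if recruited_pup else t)

        if not any(alive):
            extinct, extinct_year = True, t + 1
            break

    n_total = len(hapA)
    ids = np.arange(n_total)
    pedigree = pd.DataFrame(
        {
            "id": ids,
            "sire": sire,
            "dam": dam,
            "birth_year": birth_year,
            "sex": sex,
            "subpop": subpop,
            "origin": origin,
            "den": den,
        }
    )
    observations = pd.DataFrame({"id": ids, "last_alive_year": last_alive})

    dosage = (np.asarray(hapA, dtype=np.int8) + np.asarray(hapB, dtype=np.int8)).astype(float)
    if config.missing_genotype_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_genotype_rate
        miss[:, causal_index] = False
        dosage[miss] = np.nan
    panel = GenotypePanel(dosage=dosage, marker_map=marker_map, ids=ids, causal_index=causal_index)

    phenotypes = pd.Series(
        assign_colour_phenotype(panel.colour_genotype, config.phenotyping_error_rate, rng),
        index=ids,
        name="colour",
    )
    life_history = pd.DataFrame(
        lh_rows,
        columns=[
            "id", "year", "sex", "age_class", "survival", "recruits", "bred",
            "subpop", "origin", "rodent_phase", "first_snowfall", "last_snowfall",
            "observed",
        ],
    )
    return SimulationResult(
        pedigree=pedigree,
        panel=panel,
        life_history=life_history,
        phenotypes=phenotypes,
        observations=observations,
        extinct=extinct,
        extinct_year=extinct_year,
        config=config,
    )
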
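"""End-to-end orchestration: simulate → genomics → GWAS → demography → selection.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so stages can be re-run in isolation.
All intermediate tables are persisted as CSV/TSV and genotypes round-trip
through PED/MAP to exercise the readers.  The run report is a JSON document
validated against the schema shipped as ``report_schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from arcticfit import demography, gwas, io, popgen, selection
from arcticfit.glmm import ModelSpec
from arcticfit.synthpop import SimConfig, VitalRates, simulate_population

log = logging.getLogger(__name__)


def concordance_table(colour_genotypes, phenotypes) -> tuple[pd.DataFrame, float]:
    """Genotype × phenotype counts and the recessive-white concordance fraction.

    Concordance counts CC–white and TC/TT–blue pairs as matches.
    """
    geno = pd.Series(np.asarray(colour_genotypes, dtype=object), name="genotype")
    pheno = pd.Series(np.asarray(phenotypes, dtype=object), name="phenotype")
    if not geno.isin(["CC", "TC", "TT"]).all():
        raise ValueError("unknown genotype labels")
    if not pheno.isin(["white", "blue"]).all():
        raise ValueError("unknown phenotype labels")
    table = pd.crosstab(geno, pheno).reindex(
        index=["CC", "TC", "TT"], columns=["white", "blue"], fill_value=0
    )
    expected = np.where(geno == "CC", "white", "blue")
    concordance = float((pheno.to_numpy() == expected).mean())
    return table, concordance


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    outdir: str = "arcticfit_run"
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    ped_prefix: str | None = None   # analyse existing PED/MAP instead of simulating
    pedigree_csv: str | None = None
    life_history_csv: str | None = None
    alpha: float = 0.05
    grm_method: str = "vanraden"
    lambda_correct: str = "if_above_one"
    ld_prune_params: tuple = (50, 5, 2.0)
    run_components: bool = True
    run_gxe: bool = True
    run_candidate_region: bool = True
    tt_min_count: int = 10

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", {})
        vr = sim_raw.pop("vital_rates", None)
        sim = SimConfig(**sim_raw)
        if vr is not None:
            sim.vital_rates = VitalRates(**vr)
        cfg = cls(simulate=sim, **raw)
        if cfg.ped_prefix is None and sim is None:
            raise ValueError("config needs either input paths or a simulate block")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def validate_report(report: dict) -> None:
    """Check the report against the checked-in JSON schema (subset validator
    covering required keys and primitive types)."""
    schema = json.loads(
        resources.files("arcticfit").joinpath("report_schema.json").read_text()
    )

    def check(node, sch, path="report"):
        t = sch.get("type")
        if t == "object":
            if not isinstance(node, dict):
                raise ValueError(f"{path}: expected object")
            for key in sch.get("required", []):
                if key not in node:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in sch.get("properties", {}).items():
                if key in node:
                    check(node[key], sub, f"{path}.{key}")
        elif t == "array":
            if not isinstance(node, list):
                raise ValueError(f"{path}: expected array")
            if "items" in sch:
                for i, item in enumerate(node):
                    check(item, sch["items"], f"{path}[{i}]")
        elif t == "number":
            if node is not None and not isinstance(node, (int, float)):
                raise ValueError(f"{path}: expected number")
        elif t == "integer":
            if not isinstance(node, int):
                raise ValueError(f"{path}: expected integer")
        elif t == "string":
            if not isinstance(node, str):
                raise ValueError(f"{path}: expected string")
        elif t == "boolean":
            if not isinstance(node, bool):
                raise ValueError(f"{path}: expected boolean")

    check(report, schema)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the validated run report (also written
    to ``<outdir>/report.json``).  A stage failure aborts with the stage name
    while partial outputs stay on disk."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    report: dict = {"seed": config.seed, "alpha": config.alpha, "stages": [], "artifacts": {}}
    t_start = time.perf_counter()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.perf_counter() - t_start)
        report["stages"].append(name)

    # ------------------------------------------------------------------ simulate
    stage("simulate")
    try:
        if config.ped_prefix is not None:
            panel, samples = io.read_ped_map(config.ped_prefix, causal_snp_id="AX_COLOUR")
            pedigree = pd.read_csv(config.pedigree_csv)
            life_history = pd.read_csv(config.life_history_csv)
            phenotypes = samples.set_index("id")["colour"]
            observations = life_history.groupby("id")["year"].max().rename(
                "last_alive_year").reset_index()
            sim_extinct = False
        else:
            sim_cfg = config.simulate
            rng = np.random.default_rng(seeds[0])
            sim = simulate_population(sim_cfg, rng)
            if sim.extinct:
                report["extinct"] = True
                report["extinct_year"] = sim.extinct_year
            panel, pedigree = sim.panel, sim.pedigree
            life_history, phenotypes = sim.life_history, sim.phenotypes
            observations = sim.observations
            sim_extinct = sim.extinct
        pedigree.to_csv(out / "pedigree.csv", index=False)
        life_history.to_csv(out / "life_history.csv", index=False)
        sexes = pedigree.set_index("id")["sex"]
        io.write_ped_map(panel, str(out / "genotypes"), phenotypes=phenotypes, sex=sexes)
        # round-trip through the PED/MAP readers
        panel, samples = io.read_ped_map(str(out / "genotypes"), causal_snp_id="AX_COLOUR")
        phenotypes = samples.set_index("id")["colour"]
    except Exception as err:  # noqa: BLE001
        raise StageFailure("simulate", err) from err
    if sim_extinct:
        report["report_version"] = 1
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
        return report

    # ------------------------------------------------------------------ genomics
    stage("genomics")
    try:
        w, s, v = config.ld_prune_params
        pruned_idx = popgen.ld_prune(panel, int(w), int(s), float(v))
        grm = popgen.compute_grm(panel.subset_markers(pruned_idx), method=config.grm_method)
        io.write_grm(grm, str(out / "grm"))
        het = popgen.genomewide_heterozygosity(panel)
        coords, var_frac = popgen.principal_components(grm, k=3)
        report["genomics"] = {
            "n_snps": panel.n_snps,
            "n_pruned_retained": int(len(pruned_idx)),
            "pc_variance_fractions": var_frac.tolist(),
        }
    except Exception as err:  # noqa: BLE001
        raise StageFailure("genomics", err) from err

    # ------------------------------------------------------------------ gwas
    stage("gwas")
    try:
        trait = (phenotypes == "blue").astype(float).to_numpy()
        polyfit = gwas.fit_polygenic(trait, grm)
        scan = gwas.association_scan(polyfit, panel, alpha=config.alpha,
                                     lambda_correct=config.lambda_correct)
        scan.table.to_csv(out / "gwas_scan.tsv", sep="\t", index=False)
        top = scan.top_snp
        geno_tab, concordance = concordance_table(panel.colour_genotype, phenotypes.to_numpy())
        report["gwas"] = {
            "lambda_gc": scan.lambda_gc,
            "threshold": scan.threshold,
            "n_tests": scan.n_tests,
            "n_significant": int(scan.table["significant"].sum()),
            "top_snp": str(top["snp_id"]),
            "top_snp_p": float(top["p_corrected"]),
            "top_snp_is_causal": bool(
                panel.causal_index is not None
                and top["snp_id"] == panel.marker_map.loc[panel.causal_index, "snp_id"]
            ),
            "heritability": polyfit.heritability,
        }
        report["concordance"] = {
            "counts": {g: {ph: int(geno_tab.loc[g, ph]) for ph in geno_tab.columns}
                       for g in geno_tab.index},
            "fraction": concordance,
        }
    except Exception as err:  # noqa: BLE001
        raise StageFailure("gwas", err) from err

    # ------------------------------------------------------------------ demography
    stage("demography")
    try:
        y0, y1 = int(life_history["year"].min()), int(life_history["year"].max())
        census = demography.build_census(pedigree, observations, cycle_origin=y0)
        census = demography.count_recruits(pedigree, census)
        # study window: recruits of year y1 were countable above (their y1+1
        # presence is recorded), but only census years y0..y1 are analysed
        census = census[(census["year"] >= y0) & (census["year"] <= y1)].reset_index(drop=True)
        snow = life_history.drop_duplicates("year")[
            ["year", "first_snowfall", "last_snowfall"]]
        census = census.merge(snow, on="year", how="left")
        models = {}
        for sex in ("F", "M"):
            models[sex] = demography.fit_demographic_model(
                census[census["sex"] == sex], sex)
            (out / f"demographic_model_{sex}.json").write_text(models[sex].to_json())
        fitness = demography.individual_fitness(census, models)
        fitness.to_csv(out / "fitness.csv", index=False)
        report["demography"] = {
            sex: {
                "growth_rate": m.growth_rate,
                "reproductive_values": m.v.tolist(),
                "stable_age_distribution": m.u.tolist(),
            }
            for sex, m in models.items()
        }
    except Exception as err:  # noqa: BLE001
        raise StageFailure("demography", err) from err

    # ------------------------------------------------------------------ selection
    stage("selection")
    try:
        geno_map = pd.Series(panel.colour_genotype, index=panel.ids)
        fitness["genotype"] = fitness["id"].map(geno_map)
        fitness = fitness.dropna(subset=["genotype"])
        data = selection.exclude_rare_tt(fitness, min_count=config.tt_min_count)
        mean_age = data["age_class"].mean()
        data["age_c"] = data["age_class"] - mean_age
        data["age2_c"] = data["age_c"] ** 2

        sel_report: dict = {}
        for sex in ("F", "M"):
            sub = data[data["sex"] == sex]
            spec1 = ModelSpec("Lambda_i", "poisson", fixed=["genotype"],
                              random=["year", "subpop"])
            spec0 = ModelSpec("Lambda_i", "poisson", fixed=[], random=["year", "subpop"])
            fit1 = selection.fit_glmm(spec1, sub)
            fit0 = selection.fit_glmm(spec0, sub)
            chi2, df, p = selection.likelihood_ratio_test(fit0, fit1)
            b = fit1.coef_row("genotype[TC]")
            preds = selection.predict_genotype_fitness(fit1, ["CC", "TC"])
            preds.to_csv(out / f"predictions_Lambda_{sex}.tsv", sep="\t", index=False)
            sel_report[sex] = {
                "b_TC": float(b["estimate"]), "se": float(b["se"]),
                "ci_low": float(b["ci_low"]), "ci_high": float(b["ci_high"]),
                "lrt_chi2": chi2, "lrt_df": df, "lrt_p": p,
            }
            if config.run_gxe:
                gxe = selection.genotype_environment_tests(
                    sub, ModelSpec("Lambda_i", "poisson", fixed=["genotype"],
                                   random=["year", "subpop"]))
                gxe.to_csv(out / f"gxe_Lambda_{sex}.tsv", sep="\t", index=False)
                sel_report[sex]["gxe"] = {
                    r.environment: {"chi2": None if pd.isna(r.chi2) else float(r.chi2),
                                    "df": int(r.df),
                                    "p": None if pd.isna(r.p) else float(r.p),
                                    "status": r.status}
                    for r in gxe.itertuples(index=False)
                }
        report["selection"] = sel_report

        if config.run_components:
            comp: dict = {}
            base_fixed = ["genotype", "sex", "age_c", "age2_c"]
            for name, response, family in (
                ("fecundity", "recruits", "zip"),
                ("survival", "survival", "binomial"),
                ("breeding", "bred", "binomial"),
            ):
                spec1 = ModelSpec(response, family, fixed=base_fixed,
                                  random=["year", "subpop"])
                spec0 = ModelSpec(response, family,
                                  fixed=["sex", "age_c", "age2_c"],
                                  random=["year", "subpop"])
                f1 = selection.fit_glmm(spec1, data)
                f0 = selection.fit_glmm(spec0, data)
                chi2, df, p = selection.likelihood_ratio_test(f0, f1)
                b = f1.coef_row("genotype[TC]")
                comp[name] = {"b_TC": float(b["estimate"]), "se": float(b["se"]),
                              "lrt_chi2": chi2, "lrt_df": df, "lrt_p": p}
            # recruitment probability: only pups marked at dens (known birth
            # year); final-year litters are censored and excluded
            juv = pedigree[(pedigree["sire"] >= 0) & pedigree["birth_year"].notna()
                           & (pedigree["birth_year"] < y1)].copy()
            # recruited = holds any census record (present at the census after birth)
            juv["recruited"] = juv["id"].isin(set(census["id"])).astype(float)
            juv["genotype"] = juv["id"].map(geno_map)
            juv = juv.dropna(subset=["genotype"])
            juv = selection.exclude_rare_tt(juv, min_count=config.tt_min_count)
            spec1 = ModelSpec("recruited", "binomial", fixed=["genotype", "sex"],
                              random=["birth_year", "den"])
            spec0 = ModelSpec("recruited", "binomial", fixed=["sex"],
                              random=["birth_year", "den"])
            f1 = selection.fit_glmm(spec1, juv)
            f0 = selection.fit_glmm(spec0, juv)
            chi2, df, p = selection.likelihood_ratio_test(f0, f1)
            b = f1.coef_row("genotype[TC]")
            comp["recruitment"] = {"b_TC": float(b["estimate"]), "se": float(b["se"]),
                                   "lrt_chi2": chi2, "lrt_df": df, "lrt_p": p,
                                   "n_juveniles": int(len(juv))}
            report["components"] = comp
    except Exception as err:  # noqa: BLE001
        raise StageFailure("selection", err) from err

    # ------------------------------------------------------------------ candidate region
    if config.run_candidate_region and panel.causal_index is not None:
        stage("candidate_region")
        try:
            causal_scaffold = str(panel.marker_map.loc[panel.causal_index, "scaffold"])
            per_ind = fitness.groupby("id")["Lambda_i"].mean()
            common = [i for i in panel.ids if i in per_ind.index]
            sub_panel = panel.subset_individuals(np.asarray(common))
            pruned = popgen.ld_prune(sub_panel)
            grm_fit = popgen.compute_grm(sub_panel.subset_markers(pruned),
                                         method=config.grm_method)
            region_scan = gwas.candidate_region_scan(
                per_ind.loc[common].to_numpy(), sub_panel, grm_fit,
                scaffold=causal_scaffold, alpha=config.alpha,
                lambda_correct=config.lambda_correct)
            region_scan.table.to_csv(out / "candidate_region_scan.tsv", sep="\t",
                                     index=False)
            rtop = region_scan.top_snp
            report["candidate_region"] = {
                "scaffold": causal_scaffold,
                "n_tests": region_scan.n_tests,
                "threshold": region_scan.threshold,
                "top_snp": str(rtop["snp_id"]),
                "top_snp_p": float(rtop["p_corrected"]),
                "n_significant": int(region_scan.table["significant"].sum()),
            }
        except Exception as err:  # noqa: BLE001
            raise StageFailure("candidate_region", err) from err

    # ------------------------------------------------------------------ report
    stage("report")
    report["report_version"] = 1
    for f in sorted(out.iterdir()):
        if f.name != "report.json" and f.is_file():
            report["artifacts"][f.name] = _sha256(f)
    report = _jsonable(report)
    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
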
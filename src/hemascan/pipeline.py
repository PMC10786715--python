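"""End-to-end pipeline: simulate -> gate -> qc -> scan -> clump -> clinical
-> pgs -> survive -> meta -> ica, with a reproducibility manifest.

Each stage reads the previous stage's files from the run directory,
writes its own TSV outputs and appends SHA-256 checksums to
``manifest.json``; re-running with the same config and seed reproduces
every output byte for byte.  A single global seed fans out to per-stage
child seeds through a keyed blake2 hash, so one stage's draws never
depend on another's.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import clinical as clin
from . import gwas, pgs, qc, simulate
from .config import STAGE_ORDER, PipelineConfig
from .gating import (
    default_gate_definitions,
    default_ratio_definitions,
    featurize_cohort,
    phenotypes_to_long,
    read_events,
    write_events_csv,
)
from .genotypes import read_vcf, write_vcf

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

STAGE_DEPS = {
    "simulate": [],
    "gate": ["simulate"],
    "qc": ["gate"],
    "scan": ["qc", "simulate"],
    "clump": ["scan"],
    "clinical": ["qc", "simulate", "clump"],
    "pgs": ["scan", "clump", "simulate"],
    "survive": ["pgs", "simulate"],
    "meta": ["survive"],
    "ica": ["clinical"],
}

#: gates excluded from genetic association (non-normal traits)
SCAN_EXCLUDED_GATES = ("DEBRIS", "GHOST", "NRBC")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage child seed: blake2b(global_seed:stage) mod 2^31."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2**31)


class PipelineError(RuntimeError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """A pipeline run directory with its manifest."""

    def __init__(self, config: PipelineConfig, outdir: str):
        self.config = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.manifest_path = os.path.join(outdir, "manifest.json")
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        else:
            self.manifest = {"seed": config.seed, "stages": {}, "files": {}}

    def path(self, *parts: str) -> str:
        p = os.path.join(self.outdir, *parts)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        return p

    def record(self, stage: str, paths: list[str], params: dict | None = None) -> None:
        entry = {"seed": stage_seed(self.config.seed, stage), "outputs": []}
        if params:
            entry["parameters"] = params
        for p in paths:
            rel = os.path.relpath(p, self.outdir)
            digest = _sha256(p)
            entry["outputs"].append(rel)
            self.manifest["files"][rel] = digest
        self.manifest["stages"][stage] = entry
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    def require(self, stage: str) -> None:
        for dep in STAGE_DEPS[stage]:
            if dep not in self.manifest["stages"]:
                raise PipelineError(
                    f"stage {stage!r} requires stage {dep!r}, which has not run "
                    f"(enabled stages: {self.config.stages})"
                )


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(run: Run) -> None:
    cfg = run.config.simulation
    cfg.seed = stage_seed(run.config.seed, "simulate")
    gm = simulate.simulate_genotypes(cfg)
    states = simulate.simulate_donor_states(cfg, gm)
    covariates = simulate.simulate_covariates(cfg, states)
    latents = simulate.latent_frame(states)
    outcomes = simulate.simulate_outcomes(latents, cfg)

    paths = []
    vcf = run.path("simulate", "genotypes.vcf")
    write_vcf(gm, vcf)
    paths.append(vcf)
    events_dir = os.path.dirname(run.path("simulate", "events", "_"))
    for state in states:
        for cond in cfg.conditions:
            for table in simulate.simulate_events(state, cond, cfg):
                paths.append(write_events_csv(table, events_dir))
    paths.append(_write_tsv(covariates, run.path("simulate", "covariates.tsv")))
    paths.append(
        _write_tsv(latents.reset_index(names="donor"), run.path("simulate", "latents.tsv"))
    )
    paths.append(_write_tsv(outcomes, run.path("simulate", "outcomes.tsv")))
    run.record("simulate", paths, {"n_donors": cfg.n_donors, "n_variants": cfg.n_variants})


def stage_gate(run: Run) -> None:
    run.require("gate")
    cfg = run.config.simulation
    events_dir = os.path.join(run.outdir, "simulate", "events")
    tables = [
        read_events(os.path.join(events_dir, f))
        for f in sorted(os.listdir(events_dir))
        if f.endswith(".csv")
    ]
    gates = default_gate_definitions(cfg.gate_templates)
    ratios = default_ratio_definitions()
    wide = featurize_cohort(tables, gates, ratios)
    paths = [
        _write_tsv(wide.reset_index(names="donor"), run.path("gate", "phenotypes_wide.tsv")),
        _write_tsv(phenotypes_to_long(wide.reset_index(names="donor").set_index("donor")),
                   run.path("gate", "phenotypes_long.tsv")),
    ]
    run.record("gate", paths, {"n_gates": len(gates)})


def stage_qc(run: Run) -> None:
    run.require("qc")
    wide = pd.read_csv(
        os.path.join(run.outdir, "gate", "phenotypes_wide.tsv"), sep="\t"
    ).set_index("donor")
    params = run.config.qc
    params.seed = stage_seed(run.config.seed, "qc")
    result = qc.run_qc(wide, params, conditions=run.config.simulation.conditions)
    est = qc.estimate_independent_traits(
        {"all": result.matrix.dropna(axis=1, how="all")},
        run.config.qc.variance_threshold,
    )
    paths = [
        _write_tsv(result.matrix.reset_index(names="donor"), run.path("qc", "phenotypes_qc.tsv")),
        _write_tsv(result.report, run.path("qc", "qc_report.tsv")),
    ]
    with open(run.path("qc", "independent_traits.json"), "w") as fh:
        json.dump({"per_block": est.per_block, "overall": est.overall,
                   "threshold": est.threshold}, fh, indent=2, sort_keys=True)
    paths.append(run.path("qc", "independent_traits.json"))
    run.record("qc", paths, {
        "mad_multiplier": params.mad_multiplier,
        "ica_mad_multiplier": params.ica_mad_multiplier,
        "masked_cells": int(result.cell_mask.values.sum()),
        "removed_donors": len(result.removed_donors),
    })


def _scan_traits(run: Run) -> pd.DataFrame:
    traits = pd.read_csv(
        os.path.join(run.outdir, "qc", "phenotypes_qc.tsv"), sep="\t"
    ).set_index("donor")
    drop = [
        c for c in traits.columns
        if any(f"_{g}_" in c for g in SCAN_EXCLUDED_GATES)
    ]
    traits = traits.drop(columns=drop)
    # restrict to informative traits (some variance after QC)
    keep = [c for c in traits.columns if traits[c].std(skipna=True) > 0]
    return traits[keep]


def stage_scan(run: Run) -> None:
    run.require("scan")
    gm = read_vcf(os.path.join(run.outdir, "simulate", "genotypes.vcf"))
    gm_f, report = gwas.variant_qc(gm, run.config.scan)
    pcs = gwas.genotype_pcs(gm_f, run.config.scan.n_pcs)
    covariates = pd.read_csv(
        os.path.join(run.outdir, "simulate", "covariates.tsv"), sep="\t"
    ).set_index("donor")
    cov = pd.concat(
        [covariates[["age", "sex", "draw_time"]], pcs], axis=1
    ).loc[gm_f.donors]
    traits = _scan_traits(run)
    results = gwas.scan_traits(traits, gm_f, cov)
    paths = [
        _write_tsv(results, run.path("scan", "summary_stats.tsv")),
        _write_tsv(report.variant_exclusions, run.path("scan", "variant_exclusions.tsv")),
        _write_tsv(report.donor_exclusions, run.path("scan", "donor_exclusions.tsv")),
        _write_tsv(pcs.reset_index(names="donor"), run.path("scan", "genotype_pcs.tsv")),
    ]
    vcf = run.path("scan", "genotypes_filtered.vcf")
    write_vcf(gm_f, vcf)
    paths.append(vcf)
    run.record("scan", paths, {
        "n_traits": traits.shape[1],
        "n_variants": gm_f.n_variants,
        "maf_floor": run.config.scan.maf_floor,
        "hwe_p_floor": run.config.scan.hwe_p_floor,
    })


def stage_clump(run: Run) -> None:
    run.require("clump")
    results = pd.read_csv(os.path.join(run.outdir, "scan", "summary_stats.tsv"), sep="\t")
    gm = read_vcf(os.path.join(run.outdir, "scan", "genotypes_filtered.vcf"))
    regions = gwas.clump(results, gm, run.config.scan)
    paths = [_write_tsv(gwas.regions_to_frame(regions), run.path("clump", "regions.tsv"))]
    run.record("clump", paths, {
        "significance": run.config.scan.significance,
        "clump_r2": run.config.scan.clump_r2,
        "clump_kb": run.config.scan.clump_kb,
        "n_regions": len(regions),
    })


def _selected_traits(run: Run, results: pd.DataFrame) -> list[str]:
    regions_df = pd.read_csv(os.path.join(run.outdir, "clump", "regions.tsv"), sep="\t")
    selected: list[str] = []
    if len(regions_df):
        from .gwas import ClumpedRegion

        regions = [
            ClumpedRegion(
                lead=r.lead, lead_trait=r.lead_trait, lead_p=r.lead_p,
                members=str(r.members).split(","),
                supporting_traits=set(str(r.supporting_traits).split(",")),
            )
            for r in regions_df.itertuples(index=False)
        ]
        selected = clin.select_top_traits(results, regions, k=3)
    if not selected:
        # fallback at demo scale: strongest overall scan signals
        selected = (
            results.groupby("trait")["p"].min().sort_values().head(5).index.to_list()
        )
    return selected


def stage_clinical(run: Run) -> None:
    run.require("clinical")
    results = pd.read_csv(os.path.join(run.outdir, "scan", "summary_stats.tsv"), sep="\t")
    selected = _selected_traits(run, results)
    traits = pd.read_csv(
        os.path.join(run.outdir, "qc", "phenotypes_qc.tsv"), sep="\t"
    ).set_index("donor")[
        [t for t in selected if True]
    ]
    covariates = pd.read_csv(
        os.path.join(run.outdir, "simulate", "covariates.tsv"), sep="\t"
    ).set_index("donor")
    outcomes = pd.read_csv(os.path.join(run.outdir, "simulate", "outcomes.tsv"), sep="\t")
    case = (
        outcomes.assign(
            case=(outcomes["diagnosis_age"].notna() | outcomes["problem_list_only"]).astype(int)
        )
        .pivot(index="donor", columns="outcome", values="case")
    )
    clin_table = pd.concat([case, covariates[["eGFR", "HbA1C"]]], axis=1)
    long, wide = clin.association_matrix(
        traits,
        clin_table,
        binary_outcomes=list(case.columns),
        continuous_labs=["eGFR", "HbA1C"],
        covariates=covariates[["age", "race", "sex", "draw_time"]],
        min_cases=10,
    )
    paths = [
        _write_tsv(long, run.path("clinical", "associations.tsv")),
        _write_tsv(wide.reset_index(), run.path("clinical", "score_matrix.tsv")),
    ]
    with open(run.path("clinical", "selected_traits.json"), "w") as fh:
        json.dump(selected, fh, indent=2)
    paths.append(run.path("clinical", "selected_traits.json"))
    run.record("clinical", paths, {"n_traits": len(selected)})


def stage_pgs(run: Run) -> None:
    run.require("pgs")
    results = pd.read_csv(os.path.join(run.outdir, "scan", "summary_stats.tsv"), sep="\t")
    gm = read_vcf(os.path.join(run.outdir, "scan", "genotypes_filtered.vcf"))
    selected = _selected_traits(run, results)[:3]
    paths = []
    scores = {}
    for trait in selected:
        sub = results[results["trait"] == trait].dropna(subset=["p"])
        w = pgs.build_pgs(sub, gm, run.config.pgs, trait=trait)
        if w.weights.empty:
            logger.warning("no PGS weights for %s; skipped", trait)
            continue
        safe = trait.replace("/", "-")
        paths.append(_write_tsv(w.weights, run.path("pgs", f"weights_{safe}.tsv")))
        scores[trait] = pgs.score(gm, w)["score_scaled"]
    if not scores:
        raise PipelineError("pgs stage produced no scores for any selected trait")
    score_df = pd.DataFrame(scores)
    paths.append(
        _write_tsv(score_df.reset_index(names="donor"), run.path("pgs", "scores.tsv"))
    )
    run.record("pgs", paths, {"traits": list(score_df.columns), **asdict(run.config.pgs)})


def stage_survive(run: Run) -> None:
    run.require("survive")
    scores = pd.read_csv(os.path.join(run.outdir, "pgs", "scores.tsv"), sep="\t").set_index("donor")
    outcomes = pd.read_csv(os.path.join(run.outdir, "simulate", "outcomes.tsv"), sep="\t")
    covariates = pd.read_csv(
        os.path.join(run.outdir, "simulate", "covariates.tsv"), sep="\t"
    ).set_index("donor")
    pcs = pd.read_csv(
        os.path.join(run.outdir, "scan", "genotype_pcs.tsv"), sep="\t"
    ).set_index("donor")
    rows = []
    enc_frames = []
    for outcome, sub in outcomes.groupby("outcome"):
        encoded, dropped = pgs.encode_survival(sub, run.config.survival.instant_window)
        encoded = encoded.set_index("donor")
        enc_frames.append(encoded.assign(outcome=outcome).reset_index())
        for trait in scores.columns:
            df = encoded.join(covariates[["sex"]]).join(pcs[["PC1", "PC2"]])
            df["score"] = scores[trait].reindex(df.index)
            df = df.dropna(subset=["score"])
            try:
                fit = pgs.cox_delayed_entry(
                    df.reset_index(), ["sex", "PC1", "PC2", "score"],
                    run.config.survival.min_events,
                )
            except (ValueError, RuntimeError) as exc:
                logger.warning("cox fit skipped for %s/%s: %s", trait, outcome, exc)
                continue
            srow = fit[fit["covariate"] == "score"].iloc[0]
            rows.append({
                "trait": trait, "outcome": outcome,
                "log_hr": srow["log_hr"], "se": srow["se"],
                "z": srow["z"], "p": srow["p"],
                "n": len(df), "events": int(df["event"].sum()),
            })
    paths = [
        _write_tsv(pd.concat(enc_frames, ignore_index=True), run.path("survive", "encoded_records.tsv")),
        _write_tsv(pd.DataFrame(rows), run.path("survive", "cox_results.tsv")),
    ]
    run.record("survive", paths, {"instant_window": run.config.survival.instant_window})


def stage_meta(run: Run) -> None:
    run.require("meta")
    scores = pd.read_csv(os.path.join(run.outdir, "pgs", "scores.tsv"), sep="\t").set_index("donor")
    outcomes = pd.read_csv(os.path.join(run.outdir, "simulate", "outcomes.tsv"), sep="\t")
    covariates = pd.read_csv(
        os.path.join(run.outdir, "simulate", "covariates.tsv"), sep="\t"
    ).set_index("donor")
    pcs = pd.read_csv(
        os.path.join(run.outdir, "scan", "genotype_pcs.tsv"), sep="\t"
    ).set_index("donor")
    # two pseudo-cohorts by deterministic donor split, meta-analyzed per model
    donors = sorted(scores.index)
    rng = np.random.default_rng(stage_seed(run.config.seed, "meta"))
    perm = rng.permutation(len(donors))
    half = len(donors) // 2
    cohorts = {
        "cohortA": {donors[i] for i in perm[:half]},
        "cohortB": {donors[i] for i in perm[half:]},
    }
    metas = {}
    study_rows = []
    for outcome, sub in outcomes.groupby("outcome"):
        encoded, _ = pgs.encode_survival(sub, run.config.survival.instant_window)
        encoded = encoded.set_index("donor")
        for trait in scores.columns:
            ests, ses = [], []
            for cname, members in cohorts.items():
                df = encoded[encoded.index.isin(members)].join(
                    covariates[["sex"]]).join(pcs[["PC1", "PC2"]])
                df["score"] = scores[trait].reindex(df.index)
                df = df.dropna(subset=["score"])
                try:
                    fit = pgs.cox_delayed_entry(
                        df.reset_index(), ["sex", "PC1", "PC2", "score"],
                        run.config.survival.min_events,
                    )
                except (ValueError, RuntimeError):
                    continue
                srow = fit[fit["covariate"] == "score"].iloc[0]
                if np.isfinite(srow["log_hr"]) and np.isfinite(srow["se"]):
                    ests.append(float(srow["log_hr"]))
                    ses.append(float(srow["se"]))
                    study_rows.append({
                        "model": f"{trait}|{outcome}", "cohort": cname,
                        "log_hr": srow["log_hr"], "se": srow["se"],
                    })
            if ests:
                metas[f"{trait}|{outcome}"] = pgs.meta_random_effects(ests, ses)
    table = pgs.meta_table(metas)
    paths = [
        _write_tsv(table, run.path("meta", "meta_results.tsv")),
        _write_tsv(pd.DataFrame(study_rows), run.path("meta", "per_cohort.tsv")),
    ]
    run.record("meta", paths, {"n_models": len(metas)})


def stage_ica(run: Run) -> None:
    run.require("ica")
    wide = pd.read_csv(
        os.path.join(run.outdir, "clinical", "score_matrix.tsv"), sep="\t"
    ).set_index("trait")
    proj = clin.ica_project(wide, seed=stage_seed(run.config.seed, "ica"))
    paths = [
        _write_tsv(proj.coordinates.reset_index(names="endpoint"),
                   run.path("ica", "endpoint_coordinates.tsv")),
        _write_tsv(proj.loadings.reset_index(names="trait"),
                   run.path("ica", "trait_loadings.tsv")),
    ]
    run.record("ica", paths, {"seed_used": proj.seed_used})


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gate": stage_gate,
    "qc": stage_qc,
    "scan": stage_scan,
    "clump": stage_clump,
    "clinical": stage_clinical,
    "pgs": stage_pgs,
    "survive": stage_survive,
    "meta": stage_meta,
    "ica": stage_ica,
}


def run_pipeline(config: PipelineConfig, outdir: str) -> Run:
    """Execute the enabled stages in fixed order; abort on first failure."""
    run = Run(config, outdir)
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            STAGE_FUNCS[stage](run)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return run
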
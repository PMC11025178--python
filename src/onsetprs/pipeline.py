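"""End-to-end orchestration of the synthetic age-of-onset PRS analysis.

``run_pipeline`` executes: simulate (optional) -> variant QC -> EO/LO split
-> per-population Cox scans -> clumping -> PRS construction (General-,
EO-, LO- and merged scores) -> incidence-weighted Cox fits with EO-vs-LO
heterogeneity -> time-dependent ROC at the landmark ages -> two-sample MR
screen. Every stage writes its outputs under the run directory and the
manifest records parameters, seeds, row counts and file checksums so two
runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, gwascox, prslab, syndata, tdroc, wcox
from .containers import PRSModel
from .exceptions import ValidationError
from .mrlab import TwoSampleMR, harmonize_tables
from .syndata import MRSimConfig, SimulationConfig

DEFAULT_LANDMARKS = [(65.0, None), (70.0, 55.0), (85.0, 70.0)]


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # either simulate=True, or provide the three input paths
    simulate: bool = True
    genotypes_path: str | None = None
    cohort_path: str | None = None
    incidence_path: str | None = None
    sim: dict = field(default_factory=dict)        # SimulationConfig overrides
    mr_sim: dict = field(default_factory=dict)     # MRSimConfig overrides
    # stage thresholds
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.95
    age_cut: float = 55.0
    p_index: float = 1e-5
    clump_r2: float = 0.8
    clump_window_kb: float = 10_000.0
    merge_r2: float = 0.8
    covariates: list[str] = field(default_factory=lambda: ["age_assess"])
    landmarks: list = field(default_factory=lambda: list(DEFAULT_LANDMARKS))
    mr_p_max: float = 5e-8
    mr_clump_r2: float = 0.001
    run_mr: bool = True
    reported_prs_path: str | None = None  # enables the merged-PRS stage

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genotypes_path", "cohort_path", "incidence_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(
                        f"simulate=False requires {name} to be set")
                if not Path(p).exists():
                    raise ValidationError(f"{name} does not exist: {p}")
        for name in ("maf_min", "call_rate_min"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} outside [0, 1]")
        if self.age_cut <= 0:
            raise ValidationError("age_cut must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": _cfg_dict(config),
                      "stages": {}, "checksums": {}}

    def record(stage, path, **counts):
        manifest["stages"].setdefault(stage, {}).update(counts)
        if path is not None:
            manifest["checksums"][str(Path(path).name)] = _sha256(Path(path))

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.sim})
        geno = syndata.simulate_genotypes(sim_cfg)
        cohort = syndata.simulate_onset(geno, sim_cfg)
        incidence = syndata.incidence_table(sim_cfg)
        io.write_dosage_tsv(geno, out / "genotypes.tsv")
        io.write_cohort(cohort, out / "cohort.tsv")
        io.write_incidence(incidence, out / "incidence.tsv")
        record("simulate", out / "genotypes.tsv",
               n_samples=geno.n_samples, n_variants=geno.n_variants,
               n_events=cohort.n_events)
        record("simulate", out / "cohort.tsv")
        record("simulate", out / "incidence.tsv")
    else:
        geno = io.read_dosage_tsv(config.genotypes_path)
        cohort = io.read_cohort(config.cohort_path,
                                covariates=config.covariates)
        incidence = io.read_incidence(config.incidence_path)
        record("load", None, n_samples=geno.n_samples,
               n_variants=geno.n_variants)

    # --- QC ---------------------------------------------------------------
    geno_qc, qc_report = gwascox.variant_qc(
        geno, config.maf_min, config.hwe_p_min, config.call_rate_min)
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    record("qc", out / "qc_report.tsv",
           n_in=geno.n_variants, n_removed=int(qc_report["removed"].sum()),
           n_kept=geno_qc.n_variants)

    # --- split + scans ----------------------------------------------------
    eo, lo = gwascox.split_population(cohort, config.age_cut)
    record("split", None, n_general=len(cohort), n_eo=len(eo), n_lo=len(lo))
    populations = {"General": cohort, "EO": eo, "LO": lo}
    eo_mask = (cohort.table["exit_age"] <= config.age_cut).to_numpy()
    masks = {"General": np.ones(len(cohort), bool),
             "EO": eo_mask, "LO": ~eo_mask}
    scans = {}
    for name, pop in populations.items():
        scan = gwascox.cox_scan(geno_qc.subset_samples(masks[name]), pop,
                                covariate_names=config.covariates)
        io.write_sumstats(scan, out / f"scan_{name}.tsv")
        record(f"scan_{name}", out / f"scan_{name}.tsv", n_variants=len(scan))
        scans[name] = scan

    # --- clump + PRS ------------------------------------------------------
    weights_sched = wcox.interpolate_incidence(incidence)
    w = wcox.make_weights(cohort, weights_sched)
    general_scores = None
    prs_models = {}
    for name, scan in scans.items():
        clumped = prslab.clump(scan, geno_qc, p_index=config.p_index,
                               r2_max=config.clump_r2,
                               window_kb=config.clump_window_kb)
        hits = scan.set_index("variant_id").loc[clumped.index_variants]
        model = PRSModel(pd.DataFrame({
            "variant_id": clumped.index_variants,
            "chr": hits["chr"].to_numpy(),
            "pos": hits["pos"].to_numpy(),
            "effect_allele": hits["ea"].to_numpy(),
            "other_allele": hits["oa"].to_numpy(),
            "weight": hits["beta"].to_numpy(),
            "provenance": "gwas",
        }), name=f"{name}-PRS")
        prs_models[name] = model
        io.write_prs_model(model, out / f"prs_{name}.tsv")
        record(f"prs_{name}", out / f"prs_{name}.tsv", n_variants=len(model))

    # --- merged PRSs (reported variants replace correlated scan hits) ----
    if config.reported_prs_path is not None:
        reported = io.read_prs_model(config.reported_prs_path,
                                     name="reported")
        for name in list(prs_models):
            scan = scans[name]
            hits = scan.loc[scan["variant_id"].isin(
                prs_models[name].entries["variant_id"])]
            merged = prslab.merge_prs(reported, hits, geno_qc,
                                      r2_replace=config.merge_r2,
                                      name=f"merged-{name}")
            prs_models[f"merged-{name}"] = merged
            io.write_prs_model(merged, out / f"prs_merged_{name}.tsv")
            record(f"prs_merged_{name}", out / f"prs_merged_{name}.tsv",
                   n_variants=len(merged))

    # --- weighted Cox + heterogeneity ------------------------------------
    est_rows = []
    het_rows = []
    for model_name, model in prs_models.items():
        if len(model) == 0:
            continue
        scores = prslab.compute_prs(geno_qc, model)["score"].to_numpy()
        z, _ = prslab.standardize_and_quintile(scores, scores)
        per_pop = {}
        for pop_name, pop in populations.items():
            if pop.n_events == 0:
                continue
            est = wcox.weighted_cox_fit(
                pop, z[masks[pop_name]], config.covariates,
                weights=w[masks[pop_name]],
                exposure_name=f"{model_name}-PRS")
            per_pop[pop_name] = est
            est_rows.append(est.as_row())
        if "EO" in per_pop and "LO" in per_pop:
            het = wcox.cochran_q([(per_pop["EO"].beta, per_pop["EO"].se),
                                  (per_pop["LO"].beta, per_pop["LO"].se)])
            het_rows.append({"prs": model_name, "Q": het.Q, "df": het.df,
                             "I2": het.I2, "p_het": het.p_het})
    pd.DataFrame(est_rows).to_csv(out / "estimates.tsv", sep="\t", index=False)
    pd.DataFrame(het_rows).to_csv(out / "heterogeneity.tsv", sep="\t",
                                  index=False)
    record("wcox", out / "estimates.tsv", n_estimates=len(est_rows))
    record("het", out / "heterogeneity.tsv", n_pairs=len(het_rows))

    # --- time-dependent ROC ----------------------------------------------
    roc_rows = []
    for model_name, model in prs_models.items():
        if len(model) == 0:
            continue
        scores = prslab.compute_prs(geno_qc, model)["score"].to_numpy()
        for predict_time, excl in config.landmarks:
            filtered = tdroc.landmark_filter(cohort, predict_time, excl)
            keep = cohort.table["sample_id"].isin(
                filtered.table["sample_id"]).to_numpy()
            t = filtered.table
            try:
                curve = tdroc.td_roc_km(
                    scores[keep], t["exit_age"].to_numpy(),
                    t["event"].to_numpy(), predict_time,
                    n_excluded=t.attrs.get("n_excluded_by_landmark", 0))
            except Exception:
                continue
            roc_rows.append({"prs": model_name, "predict_time": predict_time,
                             "auc": curve.auc, "n_used": curve.n_used,
                             "n_excluded": curve.n_excluded_by_landmark})
    pd.DataFrame(roc_rows).to_csv(out / "tdroc.tsv", sep="\t", index=False)
    record("tdroc", out / "tdroc.tsv", n_curves=len(roc_rows))

    # --- MR screen --------------------------------------------------------
    if config.run_mr:
        mr_cfg = MRSimConfig(**{"seed": config.seed, **config.mr_sim})
        exp_tab, out_tab = syndata.simulate_mr_sumstats(mr_cfg)
        dataset = harmonize_tables(exp_tab, out_tab)
        mr_res = TwoSampleMR(dataset).fit(seed=config.seed)
        row = mr_res.result.as_row()
        pd.DataFrame([row]).to_csv(out / "mr_results.tsv", sep="\t",
                                   index=False)
        record("mr", out / "mr_results.tsv", n_iv=mr_res.result.n_iv)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str))
    return manifest


def _cfg_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["landmarks"] = [[a, b] for a, b in config.landmarks]
    return d
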
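"""End-to-end pipeline driver: transform -> screen -> associate -> pqtl ->
integrate -> stratify, with a reproducibility manifest.

The manifest records input hashes, the seed, thresholds and output hashes
but no wall-clock information, so rerunning with an identical config and
seed reproduces every output file bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, cohort_stats, enrichment, io, pqtl, roc
from .datatypes import ALL_MEASURES, SURVEY_SCORES, DataError
from .simulate import SimConfig, default_study_config, simulate_cohort, write_simulated

log = logging.getLogger(__name__)

STAGES = ("transform", "screen", "associate", "pqtl", "integrate", "stratify")

_FLOAT_FMT = "%.17g"


@dataclass
class PipelineConfig:
    """Paths, thresholds and (optionally) a simulation block.

    When ``simulate`` is set the five input files are generated into
    ``<outdir>/inputs`` first; otherwise every input path must exist.
    """

    outdir: str = "results"
    seed: int = 0
    # input paths (ignored when simulating)
    subjects: str | None = None
    proteins: str | None = None
    surveys: str | None = None
    genotypes: str | None = None
    annotation: str | None = None
    disease: str | None = None
    tss: str | None = None
    external: str | None = None
    genotype_format: str = "tsv"
    # thresholds
    alpha_screen: float = 0.05
    alpha_pqtl_report: float = 0.05
    alpha_top_hits: float = 0.01
    top_n: int = 50
    auc_min: float = 0.75
    roc_p_max: float = 0.05
    roc_n_min: int = 15
    # analysis choices
    covariate_overrides: dict = field(default_factory=dict)
    marker_a: str = "rs9332739"
    marker_b: str = "rs800292"
    directionality_analytes: tuple = ("C3", "Bb")
    # simulation block: None, "default", or a dict of SimConfig fields
    simulate: object = None

    def __post_init__(self) -> None:
        for name in ("alpha_screen", "alpha_pqtl_report", "alpha_top_hits", "roc_p_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise DataError(f"{name} must lie in (0, 1); got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig | None:
        if self.simulate is None or self.simulate is False:
            return None
        if self.simulate == "default" or self.simulate is True:
            return default_study_config(seed=self.seed)
        cfg = default_study_config(seed=self.seed)
        for key, val in dict(self.simulate).items():
            if not hasattr(cfg, key):
                raise DataError(f"unknown simulation key: {key}")
            setattr(cfg, key, val)
        return cfg

    def validate_inputs(self) -> None:
        if self.sim_config() is not None:
            return
        required = ("subjects", "proteins", "genotypes", "annotation")
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise DataError(f"config missing required input path: {name}")
            if not Path(value).exists():
                raise DataError(f"input file not found: {name} = {value}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; earlier stages are
    always computed in memory so any subset can be requested.  Returns the
    manifest dict (also written to ``<outdir>/manifest.json``)."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = set(stages)
    unknown = requested - set(STAGES)
    if unknown:
        raise DataError(f"unknown stages: {sorted(unknown)}")
    outputs: dict[str, Path] = {}
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = path

    stage_names: list[str] = []
    try:
        # --- inputs -------------------------------------------------------
        t0 = time.perf_counter()
        sim_cfg = config.sim_config()
        if sim_cfg is not None:
            sim = simulate_cohort(sim_cfg, seed=config.seed)
            input_paths = write_simulated(sim, outdir / "inputs")
            cohort = sim.cohort
            raw = sim.raw_proteins
            surveys = sim.surveys
            genotypes = sim.genotypes
            disease = sim.disease_table
            tss = sim.tss_table
        else:
            input_paths = {
                k: getattr(config, k)
                for k in ("subjects", "proteins", "surveys", "genotypes",
                          "annotation", "disease", "tss", "external")
                if getattr(config, k)
            }
            cohort = io.read_subjects(config.subjects)
            raw = io.read_raw_proteins(config.proteins)
            surveys = io.read_surveys(config.surveys) if config.surveys else None
            genotypes = io.read_genotypes(
                config.genotypes, config.genotype_format, config.annotation
            )
            disease = io.read_disease_table(config.disease) if config.disease else None
            tss = io.read_tss_table(config.tss) if config.tss else None
        external = (
            pd.read_csv(config.external, sep="\t") if config.external else None
        )
        log.info("inputs ready in %.2fs", time.perf_counter() - t0)

        # --- transform ----------------------------------------------------
        stage_names.append("transform")
        panel = io.log2_transform(raw)
        if "transform" in requested:
            emit("panel_log2.tsv", lambda p: io.write_panel(panel, p))

        # --- screen -------------------------------------------------------
        stage_names.append("screen")
        demo = cohort_stats.compare_demographics(cohort)
        screen = cohort_stats.screen_covariates(
            panel, cohort, alpha=config.alpha_screen,
            overrides=config.covariate_overrides,
        )
        covariate_map = cohort_stats.selected_covariates(screen)
        corr_r, corr_p = cohort_stats.protein_correlations(panel)
        if "screen" in requested:
            emit("demographics.tsv", lambda p: _write_tsv(demo, p))
            emit("covariate_screen.tsv", lambda p: io.write_results(screen, p, "covariate_screen"))
            emit("protein_correlations.tsv",
                 lambda p: corr_r.to_csv(p, sep="\t", float_format=_FLOAT_FMT))
            emit("protein_correlation_pvalues.tsv",
                 lambda p: corr_p.to_csv(p, sep="\t", float_format=_FLOAT_FMT))

        # --- associate ----------------------------------------------------
        stage_names.append("associate")
        assoc_rows = []
        for analyte in ALL_MEASURES:
            covs = tuple(covariate_map.get(analyte, ()))
            lin = association.case_control_linear(panel, cohort, analyte, covs)
            assoc_rows.append(
                {"analyte": analyte, "model": "linear", "term": "group",
                 "beta": lin.coef("group"), "se": float(lin.terms.loc["group", "se"]),
                 "p_value": lin.pvalue("group"), "n_used": lin.n_used}
            )
            logi = association.case_control_logistic(panel, cohort, analyte, covs)
            if logi.converged:
                assoc_rows.append(
                    {"analyte": analyte, "model": "logistic", "term": "protein",
                     "beta": logi.coef("protein"),
                     "se": float(logi.terms.loc["protein", "se"]),
                     "p_value": logi.pvalue("protein"), "n_used": logi.n_used}
                )
        case_control = pd.DataFrame(assoc_rows)
        survey_rows = []
        if surveys is not None:
            for analyte in ALL_MEASURES:
                covs = tuple(covariate_map.get(analyte, ()))
                for score in SURVEY_SCORES:
                    try:
                        fit = association.survey_association(
                            panel, surveys, cohort, analyte, score, covs
                        )
                    except DataError as exc:
                        log.info("survey fit skipped (%s/%s): %s", analyte, score, exc)
                        continue
                    survey_rows.append(
                        {"analyte": analyte, "score": score,
                         "beta": fit.coef("score"),
                         "se": float(fit.terms.loc["score", "se"]),
                         "p_value": fit.pvalue("score"), "n_used": fit.n_used}
                    )
        survey_assoc = pd.DataFrame(survey_rows)
        if "associate" in requested:
            emit("case_control.tsv", lambda p: _write_tsv(case_control, p))
            emit("survey_assoc.tsv", lambda p: _write_tsv(survey_assoc, p))

        # --- pqtl ---------------------------------------------------------
        stage_names.append("pqtl")
        scan_table, summary = pqtl.scan(genotypes, panel, cohort, covariate_map)
        if tss is not None:
            scan_table = enrichment.annotate_cis_trans(scan_table, genotypes.snps, tss)
        hits = enrichment.top_hits(scan_table, genotypes.snps, config.alpha_top_hits)
        summary["top_hit_snps"] = int(len(hits.pooled_snps))
        summary["top_hit_genes"] = int(len(hits.pooled_genes))
        top_frames = []
        for analyte, frame in sorted(hits.snps_by_analyte.items()):
            top = frame.nsmallest(config.top_n, "p_fvr").copy()
            top.insert(0, "analyte", analyte)
            top_frames.append(top)
        top_table = (
            pd.concat(top_frames, ignore_index=True)
            if top_frames
            else pd.DataFrame(columns=["analyte", "rsid", "gene", "functional_group", "p_fvr"])
        )
        if "pqtl" in requested:
            emit("pqtl_scan.tsv", lambda p: io.write_results(scan_table, p, "pqtl"))
            emit("pqtl_top_hits.tsv", lambda p: _write_tsv(top_table, p))
            emit("pqtl_summary.json",
                 lambda p: Path(p).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n"))

        # --- integrate ----------------------------------------------------
        stage_names.append("integrate")
        enrich = enrichment.enrichment_scores(hits)
        overlap = (
            enrichment.overlap_disease_snps(scan_table, disease, config.alpha_pqtl_report)
            if disease is not None
            else pd.DataFrame()
        )
        dir_rows = []
        if disease is not None:
            for analyte in config.directionality_analytes:
                pts = enrichment.directionality_points(
                    scan_table, disease, analyte, genotypes.snps,
                    p_threshold=config.alpha_pqtl_report,
                )
                if len(pts) < 3:
                    log.info("directionality for %s skipped: %d point(s)", analyte, len(pts))
                    continue
                res = enrichment.directionality(pts)
                res["analyte"] = analyte
                dir_rows.append(res)
        directionality = pd.DataFrame(
            dir_rows, columns=["analyte", "slope", "intercept", "r_squared", "n"]
        )
        ext_overlap = (
            enrichment.external_overlap(hits, external, genotypes.snps, config.top_n)
            if external is not None
            else None
        )
        if "integrate" in requested:
            emit("enrichment.tsv", lambda p: io.write_results(enrich, p, "enrichment"))
            emit("overlap.tsv", lambda p: _write_tsv(overlap, p))
            emit("directionality.tsv", lambda p: _write_tsv(directionality, p))
            if ext_overlap is not None:
                emit("external_overlap.tsv", lambda p: _write_tsv(ext_overlap, p))

        # --- stratify -----------------------------------------------------
        stage_names.append("stratify")
        filters = roc.RocFilters(
            auc_min=config.auc_min, p_max=config.roc_p_max, n_min=config.roc_n_min
        )
        snp_set = (
            sorted(overlap["rsid"].unique())
            if len(overlap)
            else sorted(
                scan_table.nsmallest(min(10, len(scan_table)), "p_fvr")["rsid"].unique()
            )
        )
        roc_screen = roc.screen_strata(
            genotypes, panel, cohort, snp_set, covariate_map, filters
        )
        labels = roc.assign_subgroups(genotypes, cohort, config.marker_a, config.marker_b)
        subgroup_table = pd.DataFrame(
            {"subject_id": labels.index, "subgroup": labels.values}
        )
        bundle = roc.subgroup_reanalysis(
            panel, labels, cohort, genotypes, surveys=surveys,
            covariate_map=covariate_map, filters=filters,
            survey_scores=SURVEY_SCORES if surveys is not None else (),
        )
        model_rows = []
        for r in bundle["lrt"].itertuples():
            model_rows.append(
                {"analyte": r.analyte, "model": "lrt", "term": "protein",
                 "beta": np.nan, "se": np.nan, "p_value": r.p_value, "n_used": r.n_used}
            )
        for analyte, fit in bundle["multinomial"].items():
            for level, terms in fit.level_terms.items():
                if level == fit.reference:
                    continue
                model_rows.append(
                    {"analyte": analyte, "model": f"multinomial[{level}]",
                     "term": "protein", "beta": float(terms.loc["protein", "beta"]),
                     "se": float(terms.loc["protein", "se"]),
                     "p_value": float(terms.loc["protein", "p"]), "n_used": fit.n_used}
                )
        for r in bundle["contrasts"].itertuples():
            model_rows.append(
                {"analyte": r.analyte, "model": "contrast",
                 "term": f"{r.group_a}-{r.group_b}", "beta": r.estimate,
                 "se": r.se, "p_value": r.p_value, "n_used": np.nan}
            )
        subgroup_models = pd.DataFrame(model_rows)
        if "stratify" in requested:
            emit("roc_screen.tsv", lambda p: io.write_results(roc_screen, p, "roc"))
            emit("subgroups.tsv", lambda p: _write_tsv(subgroup_table, p))
            emit("subgroup_models.tsv", lambda p: _write_tsv(subgroup_models, p))
            emit("subgroup_roc.tsv", lambda p: io.write_results(bundle["het_roc"], p, "roc"))
            if bundle["het_surveys"] is not None:
                emit("subgroup_survey_assoc.tsv", lambda p: _write_tsv(bundle["het_surveys"], p))
    except Exception as exc:
        failed_marker.write_text(
            f"stage {stage_names[-1] if stage_names else 'inputs'} failed: {exc}\n"
        )
        raise

    # --- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha_screen": config.alpha_screen,
            "alpha_pqtl_report": config.alpha_pqtl_report,
            "alpha_top_hits": config.alpha_top_hits,
            "auc_min": config.auc_min,
            "roc_p_max": config.roc_p_max,
            "roc_n_min": config.roc_n_min,
        },
        "markers": [config.marker_a, config.marker_b],
        "stages": list(stages),
        "inputs": {
            k: _sha256(Path(v)) for k, v in sorted(input_paths.items())
            if v and Path(v).exists()
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
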
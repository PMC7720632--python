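"""End-to-end orchestration of the discovery pipeline.

``run_pipeline`` binds the stages: preprocessing -> univariate Cox
screen -> Cox-BE and elastic-net arms -> protein-level intersection ->
signature score -> combined clinical+signature index -> log-rank
optimized three-group stratification and index comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from . import io, scoring, selection, survstats
from .config import PipelineConfig, SimulationConfig, derive_seed
from .preprocess import ExpressionMatrix, preprocess_pipeline
from .scoring import MIPI_HIGH_MIN, MIPI_LOW_MAX
from .synthetic import SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

RISK_LABELS = {0: "LR", 1: "IR", 2: "HR"}


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    qc: pd.DataFrame
    clinical: pd.DataFrame
    screen: pd.DataFrame
    candidates: List[str]
    be_runs: list
    be_consensus: frozenset
    coxbe_panel: pd.DataFrame
    enr: selection.ENRResult
    enr_panel: pd.DataFrame
    signature: selection.SignaturePanel
    scores: Optional[pd.DataFrame] = None
    ris: Optional[scoring.RISResult] = None
    index_weights: Optional[scoring.IndexWeights] = None
    multivariate: Optional[pd.DataFrame] = None
    stratification: Optional[pd.DataFrame] = None
    cutpoints: Optional[survstats.CutpointSearchResult] = None
    comparison: Optional[pd.DataFrame] = None
    log: List[str] = field(default_factory=list)


def _endpoint(clinical: pd.DataFrame, endpoint: str):
    if endpoint == "OS":
        return clinical["os_months"].to_numpy(float), clinical["os_event"].to_numpy(int)
    return clinical["pfs_months"].to_numpy(float), clinical["pfs_event"].to_numpy(int)


def run_pipeline(
    spots: pd.DataFrame,
    clinical: pd.DataFrame,
    annotation: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full analysis on a spot-level table and clinical data."""
    cfg = cfg or PipelineConfig()
    log: List[str] = []

    # stage seeds derive from the single pipeline seed
    cfg.be.rng_seed = derive_seed(cfg.rng_seed, "be")
    cfg.enr.rng_seed = derive_seed(cfg.rng_seed, "enr")

    matrix, qc, pre_log = preprocess_pipeline(spots, annotation, cfg)
    log.extend(pre_log)

    clin = clinical.set_index("patient_id").loc[
        [s for s in matrix.values.index if s in set(clinical["patient_id"])]
    ]
    X = matrix.values.loc[clin.index]
    time, event = _endpoint(clin, cfg.endpoint)

    screen = selection.cox_screen(X, time, event, alpha=cfg.screen_alpha)
    candidates = screen.loc[screen["passed"], "analyte_id"].tolist()
    log.append(f"univariate Cox screen: {len(candidates)} analytes at p < {cfg.screen_alpha}")

    be_runs, consensus = selection.backward_eliminate(
        X, time, event, candidates, cfg.be, dichotomize=cfg.dichotomize
    )
    coxbe_panel = selection.dedupe_clones(sorted(consensus), screen, annotation)
    log.append(
        f"Cox-BE consensus over {cfg.be.n_runs} runs: {len(consensus)} analytes, "
        f"{len(coxbe_panel)} proteins"
    )

    enr = selection.enr_select(X, time, event, cfg.enr)
    enr_panel = selection.dedupe_clones(enr.selected_analytes, screen, annotation)
    log.append(
        f"ENR: alpha={enr.chosen_alpha}, RMSE={enr.rmse:.2f}, R2={enr.r2:.2f}, "
        f"{len(enr.selected_analytes)} analytes, {len(enr_panel)} proteins"
    )

    signature = selection.intersect_panels(coxbe_panel, enr_panel, screen, annotation)
    log.append(f"intersected signature: {len(signature)} proteins")

    result = PipelineResult(
        matrix=matrix, qc=qc, clinical=clin.reset_index(), screen=screen,
        candidates=candidates, be_runs=be_runs, be_consensus=consensus,
        coxbe_panel=coxbe_panel, enr=enr, enr_panel=enr_panel,
        signature=signature, log=log,
    )
    if len(signature) == 0:
        logger.warning("empty signature panel; scoring and stratification skipped")
        return result

    # ---- scoring ---------------------------------------------------------
    rep_cols = [signature.representative_clone[p] for p in signature.protein_ids]
    wts = {signature.representative_clone[p]: signature.weights[p]
           for p in signature.protein_ids}
    ris = scoring.compute_ris(
        X[rep_cols], wts, time=time, event=event, form="ternary",
        min_frac=cfg.min_frac,
    )
    mipi_score, mipi_cat = scoring.compute_mipi(clin.reset_index())
    ris_value = (
        ris.s_ternary.astype(float) if cfg.ris_form == "ternary" else ris.s_continuous
    )

    cov = pd.DataFrame(
        {"mipi_score": mipi_score, "ris": ris_value}, index=clin.index
    )
    if cfg.index_weights == "refit":
        weights, multivariate = scoring.fit_multivariate(cov, time, event)
    else:
        weights = scoring.published_weights()
        _, multivariate = scoring.fit_multivariate(cov, time, event)
    mipi_ris = scoring.compute_mipi_ris(mipi_score, ris_value, weights)
    log.append(
        f"index weights ({weights.source}): w_mipi={weights.w_mipi:.3f}, "
        f"w_ris={weights.w_ris:.3f}"
    )

    scores = pd.DataFrame(
        {
            "patient_id": clin.index,
            "mipi_score": mipi_score,
            "mipi_category": mipi_cat,
            "s_continuous": ris.s_continuous,
            "s_ternary": ris.s_ternary,
            "mipi_ris": mipi_ris,
        }
    ).reset_index(drop=True)

    # ---- stratification & evaluation ------------------------------------
    ok = np.isfinite(mipi_ris)
    cut = survstats.optimal_cutpoints(
        mipi_ris[ok], time[ok], event[ok], n_groups=3, min_frac=cfg.min_frac
    )
    groups = np.full(len(clin), -1)
    groups[ok] = cut.groups
    scores["risk_group"] = [RISK_LABELS.get(g, "missing") for g in groups]
    log.append(
        f"combined-index cutpoints: {cut.cutpoints[0]:.3f}/{cut.cutpoints[1]:.3f} "
        f"(chi2={cut.chi2:.2f}, p={cut.p:.4f}, groups={cut.group_sizes})"
    )

    pfs_t, pfs_e = _endpoint(clin, "PFS")
    comparison = survstats.compare_indices(
        {
            "MIPI": mipi_score,
            "RIS": ris.s_continuous,
            "MIPI_ris": mipi_ris,
        },
        time,
        event,
        pfs_time=pfs_t,
        pfs_event=pfs_e,
        fixed_cutpoints={"MIPI": (MIPI_LOW_MAX, MIPI_HIGH_MIN)},
        min_frac=cfg.min_frac,
    )

    result.scores = scores
    result.ris = ris
    result.index_weights = weights
    result.multivariate = multivariate
    result.stratification = scores[["patient_id", "mipi_ris", "risk_group"]]
    result.cutpoints = cut
    result.comparison = comparison
    return result


def run_all(
    sim_cfg: SimulationConfig,
    pipe_cfg: Optional[PipelineConfig] = None,
    out_dir=None,
) -> tuple:
    """Simulate a cohort, run the pipeline, optionally write all artifacts.

    Returns ``(cohort, result)``; with ``out_dir`` set, writes the
    synthetic inputs, every stage output and a deterministic manifest.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    cohort = generate_cohort(sim_cfg)
    result = run_pipeline(cohort.spots, cohort.clinical, cohort.annotation, pipe_cfg)
    if out_dir is not None:
        write_artifacts(cohort, result, sim_cfg, pipe_cfg, out_dir)
    return cohort, result


def write_artifacts(cohort: SyntheticCohort, result: PipelineResult,
                    sim_cfg: SimulationConfig, pipe_cfg: PipelineConfig,
                    out_dir) -> dict:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot = {"simulation": sim_cfg.to_dict(), "pipeline": pipe_cfg.to_dict()}
    comment = io.header_comment(snapshot, sim_cfg.rng_seed)

    paths = {}
    io.write_spot_table(cohort.spots, out / "spots.tsv", comment)
    io.write_clinical(cohort.clinical, out / "clinical.csv", comment)
    io.write_annotation(cohort.annotation, out / "annotation.csv", comment)
    io.write_json(cohort.truth.to_dict(), out / "ground_truth.json")
    paths.update(
        spots=out / "spots.tsv", clinical=out / "clinical.csv",
        annotation=out / "annotation.csv", ground_truth=out / "ground_truth.json",
    )

    io.write_expression(result.matrix, out / "expression.tsv",
                        out / "expression_samples.tsv", comment)
    io._write_table(result.qc, out / "qc.csv", ",", comment)
    io._write_table(result.screen, out / "screen.csv", ",", comment)
    be_df = pd.DataFrame(
        [
            {"run": r.run, "n_selected": r.n_selected, "loocv_auc": r.loocv_auc,
             "selected": ";".join(sorted(r.selected_analytes))}
            for r in result.be_runs
        ]
    )
    io._write_table(be_df, out / "be_runs.csv", ",", comment)
    io._write_table(result.enr.per_alpha, out / "enr_path.csv", ",", comment)
    io.write_json(result.signature.to_dict(), out / "panel.json")
    paths.update(
        expression=out / "expression.tsv", qc=out / "qc.csv",
        screen=out / "screen.csv", be_runs=out / "be_runs.csv",
        enr_path=out / "enr_path.csv", panel=out / "panel.json",
    )

    if result.scores is not None:
        io._write_table(result.scores, out / "scores.csv", ",", comment)
        io.write_json(result.index_weights.to_dict(), out / "index_weights.json")
        io._write_table(result.multivariate, out / "multivariate.csv", ",", comment)
        io._write_table(result.comparison, out / "comparison.csv", ",", comment)
        io._write_table(result.stratification, out / "stratification.csv", ",", comment)
        stats = {
            "cutpoints": list(result.cutpoints.cutpoints),
            "logrank_chi2": result.cutpoints.chi2,
            "logrank_df": result.cutpoints.df,
            "logrank_p": result.cutpoints.p,
            "group_sizes": list(result.cutpoints.group_sizes),
        }
        io.write_json(stats, out / "stats.json")
        clin = result.clinical
        groups = result.scores["risk_group"].to_numpy()
        ok = groups != "missing"
        survstats.plot_km_by_group(
            clin.loc[ok, "os_months"], clin.loc[ok, "os_event"],
            pd.Categorical(groups[ok], categories=["LR", "IR", "HR"]).codes,
            out / "km_mipi_ris_os.png", title="combined index, overall survival",
        )
        paths.update(
            scores=out / "scores.csv", index_weights=out / "index_weights.json",
            multivariate=out / "multivariate.csv", comparison=out / "comparison.csv",
            stratification=out / "stratification.csv", stats=out / "stats.json",
            km_plot=out / "km_mipi_ris_os.png",
        )

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")

    manifest = io.build_manifest(
        snapshot, sim_cfg.rng_seed,
        inputs={}, outputs={k: str(v) for k, v in paths.items()},
    )
    io.write_json(manifest, out / "manifest.json")
    return manifest
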
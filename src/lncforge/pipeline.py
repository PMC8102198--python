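"""End-to-end orchestration: discovery -> positional classification ->
heterogeneity/DE -> per-patient calls -> cohort rule -> dynamics and
tumor specificity -> chromatin de novo activation.

Stage order mirrors the analysis funnel: the dynamics/specificity stage
consumes only cohort-deregulated lncRNAs, and de novo classification
only tumor-specific ones, so the reported counts are non-increasing
along novel >= deregulated >= specific >= de novo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chromatin import (
    active_profile,
    classify_de_novo,
    expression_contrast_de_novo,
    promoter_window,
)
from .deregulation import (
    cohort_deregulation,
    coefficient_of_variation,
    compare_cv,
    moderated_de,
    per_patient_calls,
)
from .discovery import (
    catalog_composition,
    chromosome_distribution,
    expressed_mask,
    filter_novel_lncrnas,
)
from .dynamics import (
    POPULATION_ORDER,
    cluster_dynamics,
    mm_specific_rule,
    population_centroids,
    population_mean_tpm,
)
from .genomic_model import (
    ExpressionMatrix,
    PipelineParams,
    gene_spans,
    read_bed_segmentation,
    read_gtf,
    read_scores,
)
from .positional import classify_positions, host_gene_expression_contrast

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Input paths plus parameters for one pipeline run."""

    candidates_gtf: str
    coding_gtf: str
    scores_tsv: str
    expr_tsv: str
    groups_tsv: str
    annotated_gtf: str | None = None
    bcell_gtf: str | None = None
    seg_manifest: str | None = None
    out_dir: str = "lncforge_out"
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        for name in ("candidates_gtf", "coding_gtf", "scores_tsv",
                     "expr_tsv", "groups_tsv", "annotated_gtf",
                     "bcell_gtf", "seg_manifest"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


@dataclass
class RunReport:
    counts: dict
    stats: dict
    params: dict
    seed: int
    version: str

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "params": self.params,
            "counts": self.counts,
            "stats": self.stats,
        }

    def check_funnel(self) -> None:
        c = self.counts
        chain = ["n_candidates", "n_novel_lncrna", "n_cohort_deregulated",
                 "n_mm_specific", "n_de_novo"]
        for a, b in zip(chain, chain[1:]):
            if c[b] > c[a]:
                raise AssertionError(f"funnel violated: {b}={c[b]} > {a}={c[a]}")


def _contrast_dict(contrast) -> dict:
    return {
        "n_" + contrast.label_a: contrast.n_a,
        "n_" + contrast.label_b: contrast.n_b,
        "median_" + contrast.label_a: contrast.median_a,
        "median_" + contrast.label_b: contrast.median_b,
        "statistic": contrast.statistic,
        "p_value": contrast.p_value,
        "testable": contrast.testable,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage, write stage TSVs plus ``report.json`` under
    ``config.out_dir``, and return the report.

    Deterministic: rerunning with the same inputs and parameters yields
    byte-identical outputs.
    """
    config.validate()
    params = config.params
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    candidates = read_gtf(config.candidates_gtf, "candidate_novel")
    coding = read_gtf(config.coding_gtf, "coding")
    annotated = read_gtf(config.annotated_gtf, "annotated_lncRNA") if config.annotated_gtf else []
    bcell = read_gtf(config.bcell_gtf, "bcell_lncRNA") if config.bcell_gtf else []
    scores = read_scores(config.scores_tsv)
    for t in candidates:
        t.coding_potential_score = scores.get(t.transcript_id)
    expr = ExpressionMatrix.read_tsv(config.expr_tsv, config.groups_tsv)

    counts: dict = {"n_candidates": len(candidates)}
    stats: dict = {}

    # ---- discovery -------------------------------------------------
    logger.info("discovery: %d candidates, thresholds length>%d, score<%g, "
                ">=%g TPM in >=%d MM samples", len(candidates),
                params.min_length_bp, params.max_coding_potential,
                params.min_tpm, params.min_samples)
    if candidates:
        catalog = filter_novel_lncrnas(candidates, expr, params)
    else:
        catalog = pd.DataFrame(
            columns=["gene_id", "chrom", "length_bp", "coding_potential_score",
                     "n_expressed_samples", "pass_length",
                     "pass_coding_potential", "pass_expression",
                     "is_novel_lncrna"],
        ).rename_axis("transcript_id")
    catalog.sort_index().to_csv(out / "catalog.tsv", sep="\t")
    novel_ids = sorted(catalog.index[catalog.get("is_novel_lncrna", pd.Series(dtype=bool))])
    counts["n_novel_lncrna"] = len(novel_ids)

    composition = catalog_composition(catalog, coding, annotated, bcell, expr, params)
    composition.to_csv(out / "composition.tsv", sep="\t")
    stats["composition_pct"] = composition["pct_of_expressed"].round(4).to_dict()

    novel_by_id = {t.transcript_id: t for t in candidates}
    dist = chromosome_distribution({
        "coding": coding,
        "annotated_lncRNA": annotated,
        "bcell_lncRNA": bcell,
        "novel_lncRNA": [novel_by_id[i] for i in novel_ids],
    })
    dist.to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)

    # ---- positional classification ---------------------------------
    coding_spans = gene_spans(coding)
    if novel_ids:
        lnc_spans = {i: novel_by_id[i].span for i in novel_ids}
        positions = classify_positions(lnc_spans, coding_spans)
    else:
        positions = pd.DataFrame(
            columns=["relation", "nearest_coding_gene_id", "distance_bp"]
        ).rename_axis("lncrna_id")
    positions.sort_index().to_csv(out / "positions.tsv", sep="\t")
    counts["position_relations"] = (
        positions["relation"].value_counts().sort_index().to_dict()
    )

    mm_samples = expr.samples_in_group("MM")
    coding_ids = [t.transcript_id for t in coding if t.transcript_id in expr.values.index]
    coding_mean = expr.values.loc[coding_ids, mm_samples].mean(axis=1)
    hosts = set(
        positions.loc[positions["relation"] == "inside", "nearest_coding_gene_id"]
    )
    if len(coding_mean):
        stats["host_gene_contrast"] = _contrast_dict(
            host_gene_expression_contrast(coding_mean, hosts)
        )

    # ---- heterogeneity + moderated DE ------------------------------
    lnc_ids = novel_ids + [
        t.transcript_id for t in annotated + bcell if t.transcript_id in expr.values.index
    ]
    expressed = expressed_mask(expr, params)
    expressed_lnc = [
        i for i in lnc_ids
        if i in set(novel_ids) or bool(expressed.get(i, False))
    ]
    cv_frames = []
    for group in ("MM", "BMPC"):
        cv_frames.append(coefficient_of_variation(expr, group))
    cv = pd.concat(cv_frames, axis=1)
    cv.sort_index().to_csv(out / "cv.tsv", sep="\t")
    lnc_in_expr = [i for i in expressed_lnc if i in cv.index]
    cmp_res = compare_cv(cv.loc[lnc_in_expr, "cv_MM"], cv.loc[coding_ids, "cv_MM"])
    stats["cv_lnc_vs_coding_MM"] = {
        "t": cmp_res.t, "df": cmp_res.df, "p_value": cmp_res.p_value,
        "mean_cv_lncRNA": cmp_res.mean_a, "mean_cv_coding": cmp_res.mean_b,
        "testable": cmp_res.testable,
    }

    try:
        de = moderated_de(expr, "MM", "BMPC", params)
        de.table.sort_index().to_csv(out / "moderated_de.tsv", sep="\t")
        counts["n_de_b_gt_threshold"] = int(de.table["is_de"].sum())
        stats["de_hyperparams"] = {
            "d0": de.d0 if de.d0 != float("inf") else "inf",
            "s0_sq": de.s0_sq, "prior_p": de.prior_p, "v0": de.v0,
        }
    except ValueError as exc:
        logger.warning("moderated DE skipped: %s", exc)
        counts["n_de_b_gt_threshold"] = 0

    # ---- per-patient calls + cohort rule ---------------------------
    if expressed_lnc:
        calls = per_patient_calls(expr, params, gene_ids=expressed_lnc)
        calls.sort_index().to_csv(out / "patient_calls.tsv", sep="\t")
        cohort = cohort_deregulation(calls, params)
    else:
        cohort = pd.DataFrame(columns=["frac_up", "frac_down", "cohort_label"])
    cohort.sort_index().to_csv(out / "cohort_deregulation.tsv", sep="\t")
    up_ids = sorted(cohort.index[cohort.get("cohort_label", pd.Series(dtype=str)) == "up"])
    down_ids = sorted(cohort.index[cohort.get("cohort_label", pd.Series(dtype=str)) == "down"])
    counts["n_cohort_up"] = len(up_ids)
    counts["n_cohort_down"] = len(down_ids)
    counts["n_cohort_deregulated"] = len(up_ids) + len(down_ids)

    # ---- dynamics + tumor specificity ------------------------------
    dereg_ids = up_ids + down_ids
    specific_ids: list[str] = []
    if dereg_ids:
        sub = expr.subset_genes(dereg_ids)
        centroids = population_centroids(sub, POPULATION_ORDER)
        mean_tpm = population_mean_tpm(sub, POPULATION_ORDER)
        dyn = centroids.copy()
        if len(dereg_ids) >= params.k_clusters:
            clustering = cluster_dynamics(centroids, params.k_clusters, params.seed)
            dyn["cluster"] = clustering.assignments
        else:
            dyn["cluster"] = -1
        specific = mm_specific_rule(mean_tpm, params)
        dyn["mm_specific"] = specific
        dyn.sort_index().to_csv(out / "dynamics.tsv", sep="\t")
        specific_ids = sorted(specific.index[specific])
    counts["n_mm_specific"] = len(specific_ids)

    # ---- chromatin de novo activation ------------------------------
    de_novo_ids: list[str] = []
    if specific_ids and config.seg_manifest:
        manifest = pd.read_csv(config.seg_manifest, sep="\t")
        base = Path(config.seg_manifest).parent
        segmentations, cell_groups = {}, {}
        for _, row in manifest.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            segmentations[row["cell_type"]] = read_bed_segmentation(p, row["cell_type"])
            cell_groups[row["cell_type"]] = (
                "MM" if str(row["group"]).upper() == "MM" else "normal"
            )
        loci = {i: promoter_window(novel_by_id[i], params) for i in specific_ids
                if i in novel_by_id}
        profile = active_profile(segmentations, cell_groups, loci, params)
        dn = classify_de_novo(profile, params)
        dn = dn.join(profile.normal.add_prefix("active_"))
        dn.sort_index().to_csv(out / "de_novo.tsv", sep="\t")
        de_novo_ids = sorted(dn.index[dn["de_novo"]])
        mm_mean = expr.values.loc[list(dn.index), mm_samples].mean(axis=1)
        stats["de_novo_expression_contrast"] = _contrast_dict(
            expression_contrast_de_novo(mm_mean, set(de_novo_ids))
        )
    counts["n_de_novo"] = len(de_novo_ids)

    report = RunReport(
        counts=counts, stats=stats, params=params.to_dict(),
        seed=params.seed, version=__version__,
    )
    report.check_funnel()
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True, default=str)
    )
    return report
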
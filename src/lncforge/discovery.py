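"""Novel-lncRNA discovery cascade and catalog composition summaries.

Candidates from de novo transcriptome assembly are filtered by mature
length (> 200 bp), coding potential (PhyloCSF-style score < 0) and
expression (>= 1 TPM in >= 3 tumor samples). All three predicates are
always evaluated and recorded so failures are auditable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic_model import (
    ExpressionMatrix,
    PipelineParams,
    TranscriptModel,
    natural_chrom_key,
    transcript_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "expressed_mask",
    "filter_novel_lncrnas",
    "catalog_composition",
    "chromosome_distribution",
]


def expressed_mask(
    expr: ExpressionMatrix,
    params: PipelineParams,
    group: str = "MM",
) -> pd.Series:
    """Boolean per-gene mask: TPM >= min_tpm in >= min_samples samples of
    ``group`` (the uniform "expressed" rule used across all gene classes)."""
    samples = expr.samples_in_group(group)
    n_pass = (expr.values[samples] >= params.min_tpm).sum(axis=1)
    return n_pass >= params.min_samples


def filter_novel_lncrnas(
    candidates: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    params: PipelineParams,
    group: str = "MM",
) -> pd.DataFrame:
    """Apply the three-filter discovery cascade to candidate transcripts.

    Returns the catalog: one row per candidate with its length, score,
    number of expressing tumor samples, the outcome of each filter, and
    ``is_novel_lncrna`` (all three passed). Candidates absent from the
    expression matrix fail the expression filter (logged, not an error).

    ``group`` selects which sample group the expression filter is
    evaluated on; the tumor cohort by default.
    """
    samples = expr.samples_in_group(group)
    n_expr = (expr.values[samples] >= params.min_tpm).sum(axis=1)

    rows = []
    missing = []
    for t in candidates:
        if t.coding_potential_score is None:
            raise ValueError(
                f"{t.transcript_id}: candidate lacks a coding-potential score"
            )
        length = transcript_length(t)
        if t.transcript_id in expr.values.index:
            n = int(n_expr.loc[t.transcript_id])
        else:
            n = 0
            missing.append(t.transcript_id)
        pass_length = length > params.min_length_bp
        pass_coding = t.coding_potential_score < params.max_coding_potential
        pass_expression = n >= params.min_samples
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "length_bp": length,
                "coding_potential_score": t.coding_potential_score,
                "n_expressed_samples": n,
                "pass_length": pass_length,
                "pass_coding_potential": pass_coding,
                "pass_expression": pass_expression,
                "is_novel_lncrna": pass_length and pass_coding and pass_expression,
            }
        )
    if missing:
        logger.warning(
            "%d candidates absent from the expression matrix fail the "
            "expression filter: %s%s",
            len(missing), ", ".join(missing[:5]), "..." if len(missing) > 5 else "",
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def catalog_composition(
    catalog: pd.DataFrame,
    coding: Sequence[TranscriptModel],
    annotated_lnc: Sequence[TranscriptModel],
    bcell_lnc: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    params: PipelineParams,
    group: str = "MM",
) -> pd.DataFrame:
    """Count expressed genes per source class and their share of the
    expressed transcriptome.

    The same expressed rule (>= min_tpm TPM in >= min_samples tumor
    samples) is applied to every class; for novel candidates "expressed
    and a lncRNA" means passing the full cascade.
    """
    class_ids = {
        "coding": [t.transcript_id for t in coding],
        "annotated_lncRNA": [t.transcript_id for t in annotated_lnc],
        "bcell_lncRNA": [t.transcript_id for t in bcell_lnc],
        "novel_lncRNA": list(catalog.index),
    }
    seen: dict[str, str] = {}
    dups = []
    for cls, ids in class_ids.items():
        for tid in ids:
            if tid in seen:
                dups.append(tid)
            seen[tid] = cls
    if dups:
        raise ValueError(f"transcript ids present in multiple classes: {sorted(set(dups))[:10]}")

    mask = expressed_mask(expr, params, group=group)
    counts = {}
    for cls, ids in class_ids.items():
        if cls == "novel_lncRNA":
            counts[cls] = int(catalog["is_novel_lncrna"].sum())
        else:
            present = [i for i in ids if i in mask.index]
            counts[cls] = int(mask.loc[present].sum())
    total = sum(counts.values())
    out = pd.DataFrame(
        {
            "n_expressed": pd.Series(counts),
            "pct_of_expressed": pd.Series(
                {c: (100.0 * n / total if total else 0.0) for c, n in counts.items()}
            ),
        }
    )
    out.index.name = "gene_class"
    return out


def chromosome_distribution(
    class_to_transcripts: Mapping[str, Iterable[TranscriptModel]],
) -> pd.DataFrame:
    """Per-chromosome counts and within-chromosome percentages per class,
    rows in natural chromosome order (chr1..chr22, chrX, chrY)."""
    records = []
    for cls, txs in class_to_transcripts.items():
        for t in txs:
            records.append({"gene_class": cls, "chrom": t.chrom})
    if not records:
        return pd.DataFrame(columns=["chrom", "gene_class", "count", "pct_within_chrom"])
    df = pd.DataFrame(records)
    counts = df.groupby(["chrom", "gene_class"]).size().rename("count").reset_index()
    totals = counts.groupby("chrom")["count"].transform("sum")
    counts["pct_within_chrom"] = 100.0 * counts["count"] / totals
    counts = counts.sort_values(
        ["chrom", "gene_class"],
        key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    return counts
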
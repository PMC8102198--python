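"""Positional classification of lncRNAs relative to coding genes.

A lncRNA whose genomic span is fully contained in a coding-gene span is
"inside" (strand-agnostic). Otherwise it is assigned to the nearest
coding gene by span distance and called upstream or downstream in that
gene's frame of reference: a lncRNA on the gene's 5' (TSS) side is
upstream. Partial overlaps fall through to the nearest-gene logic with
distance 0; the side is then taken from which way the lncRNA extends
past the gene boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_model import GenomicInterval, span_distance

__all__ = [
    "PositionCall",
    "classify_position",
    "classify_positions",
    "host_gene_expression_contrast",
    "GroupContrast",
]


@dataclass(frozen=True)
class PositionCall:
    lncrna_id: str
    relation: str  # inside | upstream | downstream
    nearest_coding_gene_id: str
    distance_bp: int


def _side_of(lnc: GenomicInterval, gene: GenomicInterval) -> str:
    """Which side of the gene the lncRNA lies on ('left' or 'right' in
    genome coordinates). For partial overlaps, the side the lncRNA
    extends beyond; a span-tie defaults to 'left'."""
    if lnc.end <= gene.start:
        return "left"
    if lnc.start >= gene.end:
        return "right"
    return "left" if lnc.start < gene.start else "right"


def classify_position(
    lncrna_id: str,
    lnc_span: GenomicInterval,
    gene_spans: dict[str, GenomicInterval],
) -> PositionCall:
    """Classify one lncRNA span against coding-gene spans."""
    if not gene_spans:
        raise ValueError("empty coding-gene set")
    same_chrom = {g: s for g, s in gene_spans.items() if s.chrom == lnc_span.chrom}
    if not same_chrom:
        raise ValueError(
            f"{lncrna_id}: no coding gene on chromosome {lnc_span.chrom}"
        )
    for gid in sorted(same_chrom):
        if same_chrom[gid].contains(lnc_span):
            return PositionCall(lncrna_id, "inside", gid, 0)
    # nearest by span distance; ties broken by lexicographically smaller gene id
    best = min(
        same_chrom.items(), key=lambda kv: (span_distance(lnc_span, kv[1]), kv[0])
    )
    gid, gspan = best
    side = _side_of(lnc_span, gspan)
    if gspan.strand == "-":
        relation = "downstream" if side == "left" else "upstream"
    else:
        relation = "upstream" if side == "left" else "downstream"
    return PositionCall(lncrna_id, relation, gid, span_distance(lnc_span, gspan))


def classify_positions(
    lnc_spans: dict[str, GenomicInterval],
    gene_spans: dict[str, GenomicInterval],
) -> pd.DataFrame:
    calls = [
        classify_position(lid, span, gene_spans)
        for lid, span in lnc_spans.items()
    ]
    return pd.DataFrame(
        {
            "lncrna_id": [c.lncrna_id for c in calls],
            "relation": [c.relation for c in calls],
            "nearest_coding_gene_id": [c.nearest_coding_gene_id for c in calls],
            "distance_bp": [c.distance_bp for c in calls],
        }
    ).set_index("lncrna_id")


@dataclass
class GroupContrast:
    """Two-group Wilcoxon rank-sum contrast on log2(TPM + 1)."""

    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float | None
    p_value: float | None
    testable: bool
    label_a: str = "a"
    label_b: str = "b"


def two_group_rank_contrast(
    values_a: np.ndarray,
    values_b: np.ndarray,
    label_a: str = "a",
    label_b: str = "b",
    log_transform: bool = True,
) -> GroupContrast:
    """Wilcoxon rank-sum (Mann-Whitney U, two-sided) between two groups of
    per-gene expression values; flagged untestable if a group is empty."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if log_transform:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    if len(a) == 0 or len(b) == 0:
        return GroupContrast(
            len(a), len(b),
            float(np.median(a)) if len(a) else float("nan"),
            float(np.median(b)) if len(b) else float("nan"),
            None, None, False, label_a, label_b,
        )
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupContrast(
        len(a), len(b), float(np.median(a)), float(np.median(b)),
        float(stat), float(p), True, label_a, label_b,
    )


def host_gene_expression_contrast(
    coding_mean_tpm: pd.Series,
    host_gene_ids: set[str],
) -> GroupContrast:
    """Contrast tumor expression of coding genes that harbor inside
    lncRNAs against coding genes that do not.

    ``coding_mean_tpm``: per-coding-gene mean TPM over tumor samples.
    ``host_gene_ids``: coding genes with >=1 lncRNA classified inside.
    """
    is_host = coding_mean_tpm.index.isin(host_gene_ids)
    return two_group_rank_contrast(
        coding_mean_tpm[is_host].to_numpy(),
        coding_mean_tpm[~is_host].to_numpy(),
        label_a="with_inside_lncRNA",
        label_b="without_inside_lncRNA",
    )
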
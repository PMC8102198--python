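"""Chromatin-state occupancy over lncRNA promoters and de novo activation.

For each locus (a promoter window around the lncRNA TSS) and cell type,
the fraction of bases in each of the 12 chromatin states is computed
from the cell type's genome segmentation; the "active" fraction sums the
promoter/enhancer states. A locus is de novo activated when it is devoid
of active states in every normal B-cell population but active in a
sufficient fraction of tumor samples — the chromatin signature of loci
repressed throughout normal differentiation and switched on in disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_model import (
    STATES,
    STATE_INDEX,
    LOW_SIGNAL_STATE,
    ChromatinSegmentation,
    GenomicInterval,
    PipelineParams,
    TranscriptModel,
)
from .positional import GroupContrast, two_group_rank_contrast

logger = logging.getLogger(__name__)

__all__ = [
    "promoter_window",
    "state_occupancy",
    "active_fraction",
    "ChromatinProfile",
    "active_profile",
    "classify_de_novo",
    "expression_contrast_de_novo",
]


def promoter_window(t: TranscriptModel, params: PipelineParams) -> GenomicInterval:
    """Strand-aware promoter window [TSS - upstream, TSS + downstream)
    in transcription orientation, clipped at the chromosome start."""
    if t.strand == "+":
        tss = t.exons[0].start
        start = tss - params.promoter_upstream_bp
        end = tss + params.promoter_downstream_bp
    elif t.strand == "-":
        tss = t.exons[-1].end
        start = tss - params.promoter_downstream_bp
        end = tss + params.promoter_upstream_bp
    else:
        raise ValueError(f"{t.transcript_id}: promoter window needs a +/- strand")
    return GenomicInterval(t.chrom, max(0, start), end, t.strand)


def state_occupancy(seg: ChromatinSegmentation, interval: GenomicInterval) -> np.ndarray:
    """Fraction of interval bases in each of the 12 states (sums to 1).

    Bases not covered by any segment count as low signal.
    """
    length = len(interval)
    if length <= 0:
        raise ValueError("interval length must be > 0")
    vec = np.zeros(len(STATES), dtype=float)
    entry = seg.chroms.get(interval.chrom)
    if entry is None:
        vec[STATE_INDEX[LOW_SIGNAL_STATE]] = 1.0
        return vec
    starts, ends, codes = entry
    lo = int(np.searchsorted(ends, interval.start, side="right"))
    hi = int(np.searchsorted(starts, interval.end, side="left"))
    if hi > lo:
        ov = np.minimum(ends[lo:hi], interval.end) - np.maximum(starts[lo:hi], interval.start)
        ov = np.clip(ov, 0, None)
        np.add.at(vec, codes[lo:hi], ov)
    covered = vec.sum()
    vec[STATE_INDEX[LOW_SIGNAL_STATE]] += length - covered
    return vec / length


def active_fraction(
    seg: ChromatinSegmentation, interval: GenomicInterval, params: PipelineParams
) -> float:
    occ = state_occupancy(seg, interval)
    idx = [STATE_INDEX[s] for s in params.active_states]
    return float(occ[idx].sum())


@dataclass
class ChromatinProfile:
    """Active-chromatin occupancy of loci across cell types.

    ``normal``: loci x normal-cell-type active fractions.
    ``tumor``: loci x tumor-sample active fractions.
    ``tumor_active_frac``: per locus, the fraction of tumor samples whose
    active fraction reaches the per-sample activity threshold.
    """

    normal: pd.DataFrame
    tumor: pd.DataFrame
    tumor_active_frac: pd.Series


def active_profile(
    segmentations: dict[str, ChromatinSegmentation],
    cell_type_groups: dict[str, str],
    loci: dict[str, GenomicInterval],
    params: PipelineParams,
) -> ChromatinProfile:
    """Compute active-state occupancy of each locus in every cell type.

    ``cell_type_groups`` maps each segmentation's cell type to "normal"
    or "MM". Loci on chromosomes absent from a segmentation score as
    fully low-signal (warned once per cell type).
    """
    normals = [c for c, g in cell_type_groups.items() if g != "MM"]
    tumors = [c for c, g in cell_type_groups.items() if g == "MM"]
    if not normals or not tumors:
        raise ValueError("need >=1 normal and >=1 MM segmentation")
    missing = set(segmentations) ^ set(cell_type_groups)
    if missing:
        raise ValueError(f"segmentations and groups disagree on: {sorted(missing)}")

    locus_ids = list(loci)
    data = {}
    for cell in normals + tumors:
        seg = segmentations[cell]
        absent = {loci[l].chrom for l in locus_ids} - set(seg.chroms)
        if absent:
            logger.warning(
                "%s: chromosomes %s absent from segmentation; loci there "
                "scored as low signal", cell, sorted(absent),
            )
        data[cell] = [active_fraction(seg, loci[l], params) for l in locus_ids]
    df = pd.DataFrame(data, index=locus_ids)
    tumor_df = df[tumors]
    active_calls = (tumor_df >= params.de_novo_tumor_min_active)
    return ChromatinProfile(
        normal=df[normals],
        tumor=tumor_df,
        tumor_active_frac=active_calls.mean(axis=1).rename("tumor_active_frac"),
    )


def classify_de_novo(profile: ChromatinProfile, params: PipelineParams) -> pd.DataFrame:
    """Call de novo epigenetic activation per locus.

    de novo iff the active fraction is <= de_novo_normal_max_active in
    EVERY normal cell type (repressed/low-signal throughout normal
    differentiation) and the tumor-sample active fraction is
    >= de_novo_min_tumor_frac. Both bounds are inclusive.
    """
    max_normal = profile.normal.max(axis=1)
    de_novo = (max_normal <= params.de_novo_normal_max_active) & (
        profile.tumor_active_frac >= params.de_novo_min_tumor_frac
    )
    return pd.DataFrame(
        {
            "max_normal_active": max_normal,
            "tumor_active_frac": profile.tumor_active_frac,
            "de_novo": de_novo,
        }
    )


def expression_contrast_de_novo(
    mm_mean_tpm: pd.Series, de_novo_ids: set[str]
) -> GroupContrast:
    """Wilcoxon rank-sum contrast of tumor expression between de novo
    activated loci and the remaining (non-de novo) loci."""
    is_dn = mm_mean_tpm.index.isin(de_novo_ids)
    return two_group_rank_contrast(
        mm_mean_tpm[is_dn].to_numpy(),
        mm_mean_tpm[~is_dn].to_numpy(),
        label_a="de_novo",
        label_b="non_de_novo",
    )
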
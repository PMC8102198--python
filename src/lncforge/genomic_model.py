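"""Domain types and file I/O shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere inside the package; GTF
(1-based, inclusive) is converted on read and write so that round-trips
are bit-exact on coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "STATE_INDEX",
    "LOW_SIGNAL_STATE",
    "GenomicInterval",
    "TranscriptModel",
    "ExpressionMatrix",
    "ChromatinSegmentation",
    "PipelineParams",
    "GtfParseError",
    "BedParseError",
    "read_gtf",
    "write_gtf",
    "read_bed_segmentation",
    "write_bed_segmentation",
    "read_scores",
    "write_scores",
    "interval_overlap",
    "span_distance",
    "transcript_length",
    "transcript_span",
    "gene_spans",
    "natural_chrom_key",
]

#: 12-state chromatin vocabulary (histone-mark derived segmentation labels).
STATES = (
    "ActProm", "WkProm", "PsProm",
    "StrEnh1", "StrEnh2", "WkEnh",
    "TxnTrans", "TxnElg", "WkTxn",
    "Heterch", "Polyc", "LowSg",
)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
LOW_SIGNAL_STATE = "LowSg"


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; message carries the line number."""


class BedParseError(ValueError):
    """Raised on a malformed or inconsistent segmentation BED."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        return interval_overlap(self, other)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def span_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two spans on the same chromosome; 0 when they touch
    or overlap."""
    if a.chrom != b.chrom:
        raise ValueError("span_distance requires intervals on one chromosome")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


SOURCES = ("coding", "annotated_lncRNA", "bcell_lncRNA", "candidate_novel")


@dataclass
class TranscriptModel:
    """A transcript as an ordered set of exons on one chromosome/strand.

    ``source`` records provenance: annotated coding gene, previously
    annotated lncRNA, lncRNA identified in normal B cells, or an
    unfiltered candidate from de novo assembly of tumor RNA-seq.
    ``coding_potential_score`` is a PhyloCSF-style comparative-genomics
    score (negative = non-coding evidence); it is an input, not computed
    here.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    source: str = "candidate_novel"
    coding_potential_score: float | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chromosome and strand"
            )
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{prev.start},{prev.end}) and [{nxt.start},{nxt.end})"
                )
        object.__setattr__(self, "exons", exons)
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


def transcript_length(t: TranscriptModel) -> int:
    """Mature (exonic) transcript length in bp — the sum of exon lengths,
    not the genomic span."""
    return sum(len(e) for e in t.exons)


def transcript_span(t: TranscriptModel) -> GenomicInterval:
    return t.span


def gene_spans(transcripts: Iterable[TranscriptModel]) -> dict[str, GenomicInterval]:
    """Collapse transcripts to per-gene genomic spans (min start to max end)."""
    spans: dict[str, GenomicInterval] = {}
    for t in transcripts:
        s = t.span
        if t.gene_id in spans:
            prev = spans[t.gene_id]
            if prev.chrom != s.chrom:
                raise ValueError(f"gene {t.gene_id} spans multiple chromosomes")
            spans[t.gene_id] = GenomicInterval(
                prev.chrom,
                min(prev.start, s.start),
                max(prev.end, s.end),
                prev.strand,
            )
        else:
            spans[t.gene_id] = s
    return spans


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path, source_label: str = "candidate_novel") -> list[TranscriptModel]:
    """Read exon features from a GTF file into TranscriptModel objects.

    GTF coordinates (1-based, inclusive) are converted to the internal
    0-based half-open convention. Only ``exon`` features are used;
    ``transcript_id`` and ``gene_id`` attributes are required.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_by_tx: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1:
                raise GtfParseError(
                    f"{path}:{lineno}: GTF coordinates are 1-based; start={start1}"
                )
            if end1 < start1:
                raise GtfParseError(
                    f"{path}:{lineno}: rejected record, end {end1} < start {start1}"
                )
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            tid = attr["transcript_id"]
            if tid not in exons_by_tx:
                exons_by_tx[tid] = []
                order.append(tid)
                gene_by_tx[tid] = attr["gene_id"]
            exons_by_tx[tid].append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=gene_by_tx[tid],
            exons=tuple(exons_by_tx[tid]),
            source=source_label,
        )
        for tid in order
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write exon features in GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{e.chrom}\t{t.source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_scores(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (transcript_id, coding-potential score)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >=2 columns (transcript_id, score)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_scores(scores: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(scores), "coding_potential_score": list(scores.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with a sample -> group mapping.

    Groups are population labels (NB, CB, CC, GC, MEM, TPC, BMPC) or the
    tumor label (MM). All values are TPM; no unit conversion is attempted.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    unit: str = "TPM"

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.groups, self.unit)

    @classmethod
    def read_tsv(cls, expr_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        gdf = pd.read_csv(groups_path, sep="\t")
        groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
        return cls(values=values, groups=groups)

    def write_tsv(self, expr_path: str | Path, groups_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(expr_path, sep="\t")
        pd.DataFrame(
            {"sample_id": list(self.values.columns),
             "group": [self.groups[s] for s in self.values.columns]}
        ).to_csv(groups_path, sep="\t", index=False)


@dataclass
class ChromatinSegmentation:
    """A per-cell-type tiling of the genome with 12-state labels.

    Segments are stored per chromosome as parallel arrays (starts, ends,
    state codes into :data:`STATES`), sorted and non-overlapping.
    """

    cell_type: str
    chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def add_chrom(self, chrom: str, starts, ends, state_codes) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        codes = np.asarray(state_codes, dtype=np.int16)
        if not (len(starts) == len(ends) == len(codes)):
            raise ValueError("starts/ends/states length mismatch")
        if len(starts) and ((ends <= starts).any() or (starts[1:] < ends[:-1]).any()):
            raise BedParseError(f"{self.cell_type}/{chrom}: unsorted or overlapping segments")
        self.chroms[chrom] = (starts, ends, codes)

    def segments(self, chrom: str):
        """Iterate (start, end, state-name) over one chromosome."""
        starts, ends, codes = self.chroms.get(chrom, (np.array([]),) * 3)
        for s, e, c in zip(starts, ends, codes):
            yield int(s), int(e), STATES[int(c)]


def read_bed_segmentation(path: str | Path, cell_type: str) -> ChromatinSegmentation:
    """Read a BED4 chromatin-state segmentation (0-based half-open).

    Column 4 must be one of the 12 state labels. Overlapping consecutive
    segments and unknown labels raise :class:`BedParseError`.
    """
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, label = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end {end} <= start {start}")
            if label not in STATE_INDEX:
                raise BedParseError(
                    f"{path}:{lineno}: unknown chromatin state {label!r} "
                    f"(expected one of {', '.join(STATES)})"
                )
            rows.setdefault(chrom, []).append((start, end, STATE_INDEX[label]))
    seg = ChromatinSegmentation(cell_type=cell_type)
    for chrom, recs in rows.items():
        recs.sort()
        starts = [r[0] for r in recs]
        ends = [r[1] for r in recs]
        for i in range(1, len(recs)):
            if starts[i] < ends[i - 1]:
                raise BedParseError(
                    f"{path}: {chrom}: segments [{starts[i-1]},{ends[i-1]}) and "
                    f"[{starts[i]},{ends[i]}) overlap"
                )
        seg.add_chrom(chrom, starts, ends, [r[2] for r in recs])
    return seg


def write_bed_segmentation(seg: ChromatinSegmentation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seg.chroms, key=natural_chrom_key):
            for start, end, state in seg.segments(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{state}\n")


def natural_chrom_key(chrom: str):
    """Sort key giving chr1..chr22, chrX, chrY ordering."""
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


@dataclass
class PipelineParams:
    """Every tunable threshold of the pipeline in one place.

    Defaults encode the published filter cascade (mature length > 200 bp,
    coding potential < 0, >= 1 TPM in >= 3 tumor samples), the cohort
    deregulation rule (called in >= 50% of patients, opposite direction in
    < 25%), the B > 3 differential-expression cutoff, and declared choices
    for the promoter window, active-state set, tumor-specificity rule and
    de novo activation thresholds.
    """

    min_length_bp: int = 200          # strict >
    max_coding_potential: float = 0.0  # strict <
    min_tpm: float = 1.0               # >= per sample
    min_samples: int = 3               # >= samples passing min_tpm
    b_threshold: float = 3.0           # DE log-posterior-odds cutoff
    dereg_log2fc: float = 1.0          # per-patient |log2 FC| call threshold
    min_call_frac: float = 0.5         # >= fraction of patients called
    max_opposite_frac: float = 0.25    # < fraction in the opposite direction
    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 500
    active_states: frozenset = frozenset(
        {"ActProm", "WkProm", "StrEnh1", "StrEnh2", "WkEnh"}
    )
    de_novo_normal_max_active: float = 0.05   # <= in every normal cell type
    de_novo_tumor_min_active: float = 0.25    # per-MM-sample active call
    de_novo_min_tumor_frac: float = 0.5       # >= fraction of MM samples active
    normal_max_tpm: float = 1.0        # specificity: ceiling in every normal pop
    tumor_fold: float = 4.0            # specificity: MM mean >= fold * max(normal, 1)
    k_clusters: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("min_call_frac", "max_opposite_frac",
                     "de_novo_normal_max_active", "de_novo_tumor_min_active",
                     "de_novo_min_tumor_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        unknown = set(self.active_states) - set(STATES)
        if unknown:
            raise ValueError(f"unknown active states: {sorted(unknown)}")
        object.__setattr__(self, "active_states", frozenset(self.active_states))

    def replace(self, **kw) -> "PipelineParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["active_states"] = sorted(d["active_states"])
        return d
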
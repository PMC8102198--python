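"""Synthetic multi-omics dataset with planted ground truth.

Generates everything the pipeline consumes — coding/lncRNA annotation
(GTF), candidate novel transcripts with coding-potential scores, TPM
matrices across normal B-cell populations and tumor samples, and
per-cell-type chromatin-state segmentations — while planting the label
of every downstream decision: which candidates survive the discovery
cascade (with every failure mode represented), which genes are
cohort-deregulated, which are tumor-specific, and which are de novo
epigenetically activated.

The genome is laid out in per-coding-gene "units": each unit carries one
coding gene and up to three satellite slots for a candidate lncRNA
placed inside the gene, to its left, or to its right, so positional
relations (upstream/downstream/inside) are planted by construction.
Expression is log-normal TPM with per-sample log2 noise; tumor samples
get their noise standard deviation multiplied by a CV-inflation factor,
emulating the higher expression heterogeneity of tumor cells.
Tumor-specific loci are near-silent across all normal populations and
strongly expressed in tumors, with the de novo subset expressed higher
still and carrying a repressive-to-active chromatin-state replacement in
tumor segmentations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_model import (
    STATE_INDEX,
    ChromatinSegmentation,
    GenomicInterval,
    PipelineParams,
    TranscriptModel,
    write_bed_segmentation,
    write_gtf,
    write_scores,
)

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "archetype_profiles"]

_UNIT = 16_000          # bp per coding-gene unit
_LNC_UNIT = 4_000       # bp per annotated/B-cell lncRNA slot
_GENE_OFS, _GENE_LEN = 3_000, 3_000


@dataclass
class SynthConfig:
    """Study-shaped simulation parameters.

    Sample sizes mirror the modeled cohort: 38 tumor (MM) samples, 3
    BMPC donors and 3 samples per normal B-cell population, with a
    handful of tumor chromatin segmentations. Noise is log2-TPM additive
    (log-normal TPM); ``cv_inflation`` multiplies the tumor noise sd.
    Planted fractions are relative to the candidates passing the
    discovery cascade; the specific set is a subset of the up set and the
    de novo set a subset of the specific set.
    """

    n_coding: int = 300
    n_annotated_lnc: int = 150
    n_bcell_lnc: int = 150
    n_candidate_novel: int = 600
    n_mm_samples: int = 38
    n_bmpc: int = 3
    n_per_population: int = 3
    n_mm_chromatin: int = 6
    populations: tuple = ("NB", "CB", "CC", "GC", "MEM", "TPC", "BMPC")
    n_chromosomes: int = 4
    frac_novel_pass: float = 0.6
    frac_dereg_up: float = 0.25     # of passing candidates; includes specific
    frac_dereg_down: float = 0.20
    frac_specific: float = 0.08     # subset of up
    frac_de_novo: float = 0.03      # subset of specific
    baseline_log2_mean: float = 2.0
    baseline_log2_sd: float = 1.2
    noise_sd: float = 0.25          # per-sample log2-TPM sd in normal samples
    cv_inflation: float = 2.0       # tumor noise sd multiplier
    dereg_log2fc: float = 2.0       # planted effect size (4-fold)
    seed: int = 0

    def __post_init__(self):
        if self.frac_dereg_up + self.frac_dereg_down > 1.0:
            raise ValueError("frac_dereg_up + frac_dereg_down must be <= 1")
        if not (self.frac_de_novo <= self.frac_specific <= self.frac_dereg_up):
            raise ValueError(
                "need frac_de_novo <= frac_specific <= frac_dereg_up "
                "(de novo within specific within up)"
            )
        if self.n_mm_samples < 3:
            raise ValueError("n_mm_samples must be >= 3 for the expression filter")

    def noiseless(self) -> "SynthConfig":
        """Copy of this configuration with all expression noise removed."""
        import dataclasses
        return dataclasses.replace(self, noise_sd=0.0)

    # planted counts -------------------------------------------------
    @property
    def n_pass(self) -> int:
        return round(self.frac_novel_pass * self.n_candidate_novel)

    @property
    def n_up(self) -> int:
        return round(self.frac_dereg_up * self.n_pass)

    @property
    def n_down(self) -> int:
        return round(self.frac_dereg_down * self.n_pass)

    @property
    def n_specific(self) -> int:
        return round(self.frac_specific * self.n_pass)

    @property
    def n_de_novo(self) -> int:
        return round(self.frac_de_novo * self.n_pass)

    def expected_cv_ratio(self) -> float:
        """Closed-form target for mean CV(tumor) / mean CV(BMPC) over null
        genes, combining the log-normal CV with the small-sample bias of
        the sd estimator (normal-theory c4 factor)."""
        sigma = math.log(2.0) * self.noise_sd

        def lognormal_cv(s):
            return math.sqrt(math.expm1(s * s))

        def c4(n):
            return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2.0) / math.gamma((n - 1) / 2.0)

        num = c4(self.n_mm_samples) * lognormal_cv(self.cv_inflation * sigma)
        den = c4(self.n_bmpc) * lognormal_cv(sigma)
        return num / den


@dataclass
class GroundTruth:
    """Planted labels consumed by the test surface."""

    novel_pass: set[str]
    dereg_up: set[str]
    dereg_down: set[str]
    mm_specific: set[str]
    de_novo: set[str]
    position_labels: dict[str, str]          # candidate id -> relation
    filter_fail: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.de_novo <= self.mm_specific:
            raise ValueError("de_novo must be a subset of mm_specific")
        if self.dereg_up & self.dereg_down:
            raise ValueError("dereg_up and dereg_down must be disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "novel_pass": sorted(self.novel_pass),
            "dereg_up": sorted(self.dereg_up),
            "dereg_down": sorted(self.dereg_down),
            "mm_specific": sorted(self.mm_specific),
            "de_novo": sorted(self.de_novo),
            "position_labels": dict(sorted(self.position_labels.items())),
            "filter_fail": {k: sorted(v) for k, v in sorted(self.filter_fail.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            novel_pass=set(d["novel_pass"]),
            dereg_up=set(d["dereg_up"]),
            dereg_down=set(d["dereg_down"]),
            mm_specific=set(d["mm_specific"]),
            de_novo=set(d["de_novo"]),
            position_labels=d["position_labels"],
            filter_fail={k: list(v) for k, v in d.get("filter_fail", {}).items()},
        )


def _two_exon(tid, gid, chrom, start, end, strand, mature_len, source):
    """Build a transcript with the requested mature length inside a span."""
    span = end - start
    if mature_len > span:
        raise ValueError(f"{tid}: mature length {mature_len} exceeds span {span}")
    if mature_len >= span - 50 or mature_len < 60:
        exons = (GenomicInterval(chrom, start, start + mature_len, strand),)
    else:
        a = mature_len // 2
        b = mature_len - a
        exons = (
            GenomicInterval(chrom, start, start + a, strand),
            GenomicInterval(chrom, end - b, end, strand),
        )
    return TranscriptModel(tid, gid, exons, source=source)


# candidate plan record
@dataclass
class _Candidate:
    tid: str
    fails: tuple[str, ...]    # subset of {short, coding_potential, expression}
    role: str                 # null | up | down | specific | de_novo
    zone: str                 # left | inside | right


def _plan_candidates(cfg: SynthConfig, rng: np.random.Generator) -> list[_Candidate]:
    n = cfg.n_candidate_novel
    n_pass, n_up, n_down = cfg.n_pass, cfg.n_up, cfg.n_down
    n_specific, n_de_novo = cfg.n_specific, cfg.n_de_novo
    if n_specific > cfg.n_coding:
        raise ValueError("more specific loci than right-zone slots")

    ids = [f"NOVEL_{i:05d}" for i in range(1, n + 1)]
    plans: list[_Candidate] = []

    # roles among passing candidates: de novo first (within specific,
    # within up), then the rest of up, then down, then null
    for i in range(n_pass):
        if i < n_de_novo:
            role = "de_novo"
        elif i < n_specific:
            role = "specific"
        elif i < n_up:
            role = "up"
        elif i < n_up + n_down:
            role = "down"
        else:
            role = "null"
        plans.append(_Candidate(ids[i], (), role, ""))

    # failing candidates: guarantee one exemplar of every failure-mode
    # combination, then cycle the three single modes
    combos = [
        ("short",), ("coding_potential",), ("expression",),
        ("short", "coding_potential"), ("short", "expression"),
        ("coding_potential", "expression"),
        ("short", "coding_potential", "expression"),
    ]
    singles = [("short",), ("coding_potential",), ("expression",)]
    n_fail = n - n_pass
    if n_fail < len(combos):
        raise ValueError("too few failing candidates to cover all failure modes")
    for j in range(n_fail):
        fails = combos[j] if j < len(combos) else singles[(j - len(combos)) % 3]
        plans.append(_Candidate(ids[n_pass + j], fails, "null", ""))

    # zones: specific/de novo candidates need a right-zone slot (their
    # chromatin is planted there); everything else cycles the three zones
    counts = {"left": 0, "inside": 0, "right": 0}
    cycle = ("left", "inside", "right")
    ci = 0
    for p in plans:
        if p.role in ("specific", "de_novo"):
            p.zone = "right"
        else:
            p.zone = cycle[ci % 3]
            ci += 1
        counts[p.zone] = counts.get(p.zone, 0) + 1
    for zone, c in counts.items():
        if c > cfg.n_coding:
            raise ValueError(
                f"{c} candidates in zone {zone!r} exceed the {cfg.n_coding} "
                "available coding-gene units; increase n_coding"
            )
    return plans


def generate_dataset(cfg: SynthConfig, out_dir: str | Path):
    """Write the full synthetic dataset to ``out_dir``.

    Returns ``(paths, ground_truth)`` where ``paths`` maps logical names
    (coding_gtf, candidates_gtf, scores_tsv, expr_tsv, groups_tsv,
    seg_manifest, ground_truth) to the files written. Deterministic for a
    fixed config: each output artifact draws from its own RNG stream
    derived from the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_scores, rng_expr, rng_chrom = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    params = PipelineParams()  # promoter geometry for chromatin planting

    # ---------------- genome layout ----------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    plans = _plan_candidates(cfg, rng_layout)

    coding: list[TranscriptModel] = []
    gene_units: list[tuple[str, int, str]] = []   # (chrom, unit offset, strand)
    units_per_chrom = math.ceil(cfg.n_coding / cfg.n_chromosomes)
    for i in range(cfg.n_coding):
        chrom = chroms[i % cfg.n_chromosomes]
        u = (i // cfg.n_chromosomes) * _UNIT
        strand = "+" if rng_layout.random() < 0.5 else "-"
        gene_units.append((chrom, u, strand))
        gid = f"CODING_{i + 1:05d}"
        coding.append(
            _two_exon(gid, gid, chrom, u + _GENE_OFS, u + _GENE_OFS + _GENE_LEN,
                      strand, 1800, "coding")
        )

    # annotated and B-cell lncRNAs in their own slots after the units
    lnc_base = units_per_chrom * _UNIT + 10_000
    annotated: list[TranscriptModel] = []
    bcell: list[TranscriptModel] = []
    extra = [("G19", cfg.n_annotated_lnc, annotated),
             ("BCL", cfg.n_bcell_lnc, bcell)]
    slot = 0
    for prefix, count, bucket in extra:
        src = "annotated_lncRNA" if prefix == "G19" else "bcell_lncRNA"
        for i in range(count):
            chrom = chroms[slot % cfg.n_chromosomes]
            v = lnc_base + (slot // cfg.n_chromosomes) * _LNC_UNIT
            strand = "+" if rng_layout.random() < 0.5 else "-"
            span = int(rng_layout.integers(600, 1800))
            mature = int(rng_layout.integers(300, max(span - 100, 301)))
            gid = f"{prefix}_{i + 1:05d}"
            bucket.append(
                _two_exon(gid, gid, chrom, v + 1000, v + 1000 + span, strand,
                          min(mature, span), src)
            )
            slot += 1

    # candidate placement inside the zones of their assigned unit
    zone_counters = {"left": 0, "inside": 0, "right": 0}
    candidates: list[TranscriptModel] = []
    position_labels: dict[str, str] = {}
    boundary_pass_done = False
    short_boundary_done = False
    for p in plans:
        unit_idx = zone_counters[p.zone]
        zone_counters[p.zone] += 1
        chrom, u, gstrand = gene_units[unit_idx]
        strand = "+" if rng_layout.random() < 0.5 else "-"

        if "short" in p.fails:
            if not short_boundary_done:      # exact boundary: 200 bp fails (> is strict)
                mature = 200
                short_boundary_done = True
            else:
                mature = int(rng_layout.integers(80, 200))
        elif p.role == "null" and not p.fails and not boundary_pass_done:
            mature = 201                     # 201 bp passes the > 200 filter
            boundary_pass_done = True
        else:
            mature = int(rng_layout.integers(300, 1500))

        span = max(mature + int(rng_layout.integers(0, 400)), mature)
        if p.zone == "inside":
            gstart, gend = u + _GENE_OFS, u + _GENE_OFS + _GENE_LEN
            span = min(span, _GENE_LEN - 200)
            mature = min(mature, span)
            start = gstart + 100
            end = start + span
            label = "inside"
        elif p.zone == "left":
            d = int(rng_layout.integers(200, 600))
            end = u + _GENE_OFS - d
            span = min(span, end - (u + 500))
            mature = min(mature, span)
            start = end - span
            label = "upstream" if gstrand == "+" else "downstream"
        else:  # right
            d = int(rng_layout.integers(2000, 3500))
            start = u + _GENE_OFS + _GENE_LEN + d
            span = min(span, 1500)
            mature = min(mature, span)
            end = start + span
            label = "downstream" if gstrand == "+" else "upstream"
        candidates.append(_two_exon(p.tid, p.tid, chrom, start, end, strand,
                                    mature, "candidate_novel"))
        position_labels[p.tid] = label

    # ---------------- coding-potential scores ----------------
    scores: dict[str, float] = {}
    cp_boundary_done = False
    exemplar_done = False
    for p, t in zip(plans, candidates):
        if "coding_potential" in p.fails:
            if not cp_boundary_done:
                scores[p.tid] = 0.0          # boundary: score 0 fails (< is strict)
                cp_boundary_done = True
            else:
                scores[p.tid] = float(rng_scores.uniform(0.0, 200.0))
        elif p.role == "null" and not p.fails and not exemplar_done:
            scores[p.tid] = -0.1
            exemplar_done = True
        else:
            scores[p.tid] = float(rng_scores.uniform(-500.0, -1.0))
        t.coding_potential_score = scores[p.tid]

    # ---------------- expression ----------------
    mm_samples = [f"MM_{i + 1:02d}" for i in range(cfg.n_mm_samples)]
    pop_samples: dict[str, list[str]] = {}
    for pop in cfg.populations:
        n = cfg.n_bmpc if pop == "BMPC" else cfg.n_per_population
        pop_samples[pop] = [f"{pop}_{i + 1}" for i in range(n)]
    samples = mm_samples + [s for pop in cfg.populations for s in pop_samples[pop]]
    groups = {s: "MM" for s in mm_samples}
    for pop in cfg.populations:
        groups.update({s: pop for s in pop_samples[pop]})

    gene_rows: list[str] = []
    base_log2: list[np.ndarray] = []        # per gene, per sample baseline log2 TPM
    n_samp = len(samples)
    mm_idx = np.arange(len(mm_samples))
    # units hosting an inside candidate get boosted coding expression
    host_units = set()
    zone_seen = {"left": 0, "inside": 0, "right": 0}
    for p in plans:
        if p.zone == "inside":
            host_units.add(zone_seen["inside"])
        zone_seen[p.zone] += 1

    def flat(level):
        return np.full(n_samp, float(level))

    for i, t in enumerate(coding):
        lvl = float(np.clip(rng_expr.normal(cfg.baseline_log2_mean,
                                            cfg.baseline_log2_sd), -2.0, 6.0))
        if i in host_units:
            lvl += 1.5                       # harboring genes run hotter
        gene_rows.append(t.gene_id)
        base_log2.append(flat(lvl))

    for bucket in (annotated, bcell):
        for t in bucket:
            if rng_expr.random() < 0.7:
                lvl = float(rng_expr.uniform(0.5, 3.5))
            else:
                lvl = float(rng_expr.uniform(-3.0, -1.0))
            gene_rows.append(t.gene_id)
            base_log2.append(flat(lvl))

    exact_tpm: dict[str, np.ndarray] = {}    # rows set verbatim (no noise)
    for p in plans:
        row = None
        if "expression" in p.fails:
            if rng_expr.random() < 0.5:
                row = flat(math.log2(0.2))               # low everywhere
            else:
                vals = np.full(n_samp, 0.05)
                picked = rng_expr.choice(mm_idx, size=2, replace=False)
                vals[picked] = 2.0                       # expressed in only 2 tumors
                exact_tpm[p.tid] = vals
                row = flat(0.0)
        elif p.role == "null" and not p.fails and scores.get(p.tid) == -0.1:
            # the three-filter boundary exemplar: exactly 1 TPM in exactly
            # 3 tumor samples, silent elsewhere
            vals = np.zeros(n_samp)
            vals[mm_idx[:3]] = 1.0
            exact_tpm[p.tid] = vals
            row = flat(0.0)
        elif p.role in ("up", "down"):
            lo, hi = (1.5, 4.0) if p.role == "up" else (2.5, 4.5)
            lvl = float(rng_expr.uniform(lo, hi))
            row = flat(lvl)
            f = float(rng_expr.uniform(0.6, 0.95))
            k = math.ceil(f * len(mm_samples))
            affected = rng_expr.choice(mm_idx, size=k, replace=False)
            delta = cfg.dereg_log2fc if p.role == "up" else -cfg.dereg_log2fc
            row[affected] += delta
        elif p.role in ("specific", "de_novo"):
            low = float(rng_expr.uniform(-3.0, -2.0))    # ~0.13-0.25 TPM
            row = flat(low)
            lo, hi = (5.0, 6.5) if p.role == "de_novo" else (3.5, 4.5)
            row[mm_idx] = float(rng_expr.uniform(lo, hi))
        else:
            lvl = float(rng_expr.uniform(0.5, 3.5))
            row = flat(lvl)
        gene_rows.append(p.tid)
        base_log2.append(row)

    base = np.vstack(base_log2)
    noise_scale = np.full(n_samp, cfg.noise_sd)
    noise_scale[mm_idx] = cfg.noise_sd * cfg.cv_inflation
    noise = rng_expr.normal(0.0, 1.0, size=base.shape) * noise_scale
    tpm = np.power(2.0, base + noise)
    expr_df = pd.DataFrame(tpm, index=gene_rows, columns=samples)
    for tid, vals in exact_tpm.items():
        expr_df.loc[tid] = vals
    expr_df = expr_df.round(6)

    # ---------------- ground truth ----------------
    novel_pass = {p.tid for p in plans if not p.fails}
    specific = {p.tid for p in plans if p.role in ("specific", "de_novo")}
    de_novo = {p.tid for p in plans if p.role == "de_novo"}
    up = {p.tid for p in plans if p.role == "up"} | specific
    down = {p.tid for p in plans if p.role == "down"}
    filter_fail: dict[str, list[str]] = {"short": [], "coding_potential": [], "expression": []}
    for p in plans:
        for mode in p.fails:
            filter_fail[mode].append(p.tid)
    truth = GroundTruth(
        novel_pass=novel_pass, dereg_up=up, dereg_down=down,
        mm_specific=specific, de_novo=de_novo,
        position_labels=position_labels, filter_fail=filter_fail,
    )

    # ---------------- chromatin segmentations ----------------
    cell_types = list(cfg.populations) + [
        f"MM_chrom_{i + 1}" for i in range(cfg.n_mm_chromatin)
    ]
    cell_group = {c: ("MM" if c.startswith("MM_chrom") else "normal") for c in cell_types}
    planted: dict[str, dict[str, list[tuple[int, int, int]]]] = {
        c: {ch: [] for ch in chroms} for c in cell_types
    }

    def put(cell, chrom, start, end, state):
        if end > start:
            planted[cell][chrom].append((start, end, STATE_INDEX[state]))

    for t in coding:
        for c in cell_types:
            put(c, t.chrom, t.span.start, t.span.end, "TxnElg")
    for bucket in (annotated, bcell):
        for t in bucket:
            for c in cell_types:
                put(c, t.chrom, t.span.start, t.span.end, "WkTxn")

    specific_candidates = [
        (p, t) for p, t in zip(plans, candidates) if p.role in ("specific", "de_novo")
    ]
    n_mm = cfg.n_mm_chromatin
    min_active = math.ceil(params.de_novo_min_tumor_frac * n_mm)
    first_de_novo = True
    for p, t in specific_candidates:
        win = promoter = _window(t, params)
        body = t.span
        # body pieces not already covered by the promoter window
        pieces = _subtract(body, promoter)
        if p.role == "de_novo":
            repress = "Heterch" if rng_chrom.random() < 0.5 else "Polyc"
            for c in cfg.populations:
                put(c, t.chrom, min(win.start, body.start), max(win.end, body.end), repress)
            if first_de_novo:
                n_active = min_active            # boundary: exactly the threshold
                first_de_novo = False
            else:
                n_active = int(rng_chrom.integers(min_active, n_mm + 1))
            active_cells = rng_chrom.permutation(n_mm)[:n_active]
            for i in range(n_mm):
                c = f"MM_chrom_{i + 1}"
                if i in active_cells:
                    put(c, t.chrom, win.start, win.end, "ActProm")
                    for s, e in pieces:
                        put(c, t.chrom, s, e, "StrEnh1")
                else:
                    put(c, t.chrom, min(win.start, body.start),
                        max(win.end, body.end), repress)
        else:
            # poised/weakly active in normals: never de novo
            split = win.start + int(0.4 * len(win))
            for c in cfg.populations:
                put(c, t.chrom, win.start, split, "PsProm")
                put(c, t.chrom, split, win.end, "WkEnh")
                for s, e in pieces:
                    put(c, t.chrom, s, e, "WkTxn")
            for i in range(n_mm):
                c = f"MM_chrom_{i + 1}"
                put(c, t.chrom, win.start, win.end, "ActProm")
                for s, e in pieces:
                    put(c, t.chrom, s, e, "StrEnh1")

    chrom_sizes = {ch: 0 for ch in chroms}
    everything = coding + annotated + bcell + candidates
    for t in everything:
        chrom_sizes[t.chrom] = max(chrom_sizes[t.chrom], t.span.end + 5000)

    seg_dir = out / "segmentations"
    seg_dir.mkdir(exist_ok=True)
    manifest_rows = []
    low = STATE_INDEX["LowSg"]
    for c in cell_types:
        seg = ChromatinSegmentation(cell_type=c)
        for ch in chroms:
            recs = sorted(planted[c][ch])
            tiled: list[tuple[int, int, int]] = []
            cursor = 0
            for s, e, st in recs:
                if s < cursor:
                    raise RuntimeError(
                        f"planted segments overlap in {c}/{ch} at {s} (< {cursor})"
                    )
                if s > cursor:
                    tiled.append((cursor, s, low))
                tiled.append((s, e, st))
                cursor = e
            if cursor < chrom_sizes[ch]:
                tiled.append((cursor, chrom_sizes[ch], low))
            seg.add_chrom(ch, [r[0] for r in tiled], [r[1] for r in tiled],
                          [r[2] for r in tiled])
        path = seg_dir / f"{c}.bed"
        write_bed_segmentation(seg, path)
        manifest_rows.append({"path": f"segmentations/{c}.bed",
                              "cell_type": c, "group": cell_group[c]})

    # ---------------- write everything ----------------
    paths = {
        "coding_gtf": out / "coding.gtf",
        "annotated_gtf": out / "annotated_lnc.gtf",
        "bcell_gtf": out / "bcell_lnc.gtf",
        "candidates_gtf": out / "candidates.gtf",
        "scores_tsv": out / "scores.tsv",
        "expr_tsv": out / "expression.tsv",
        "groups_tsv": out / "groups.tsv",
        "seg_manifest": out / "segmentation_manifest.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_gtf(coding, paths["coding_gtf"])
    write_gtf(annotated, paths["annotated_gtf"])
    write_gtf(bcell, paths["bcell_gtf"])
    write_gtf(candidates, paths["candidates_gtf"])
    write_scores(scores, paths["scores_tsv"])
    out_expr = expr_df.copy()
    out_expr.index.name = "gene_id"
    out_expr.to_csv(paths["expr_tsv"], sep="\t")
    pd.DataFrame({"sample_id": samples, "group": [groups[s] for s in samples]}
                 ).to_csv(paths["groups_tsv"], sep="\t", index=False)
    pd.DataFrame(manifest_rows).to_csv(paths["seg_manifest"], sep="\t", index=False)
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}, truth


def _window(t: TranscriptModel, params: PipelineParams) -> GenomicInterval:
    from .chromatin import promoter_window
    return promoter_window(t, params)


def _subtract(body: GenomicInterval, win: GenomicInterval) -> list[tuple[int, int]]:
    """Pieces of ``body`` not covered by ``win`` (both on one chromosome)."""
    pieces = []
    if body.start < win.start:
        pieces.append((body.start, min(body.end, win.start)))
    if body.end > win.end:
        pieces.append((max(body.start, win.end), body.end))
    return [(s, e) for s, e in pieces if e > s]


def archetype_profiles(
    n_per_cluster: int = 50,
    noise_sd: float = 0.05,
    seed: int = 0,
    populations=("NB", "CB", "CC", "GC", "MEM", "TPC", "BMPC", "MM"),
):
    """Three shape-separated expression-dynamics archetypes with planted
    cluster labels, for validating the clustering stage.

    The clustering standardizes each gene's profile, so the archetypes
    differ in shape (not level): irregular through differentiation with
    a high tumor value; monotone decline along differentiation; silent
    through differentiation with a sharp tumor increase.
    """
    rng = np.random.default_rng(seed)
    n_pop = len(populations)
    arch = np.zeros((3, n_pop))
    arch[0] = [3.0, 1.0, 3.5, 1.5, 3.0, 1.2, 2.8, 5.0][:n_pop]
    arch[1] = np.linspace(4.0, 0.5, n_pop)
    arch[2] = [0.05] * (n_pop - 1) + [4.5]
    rows, labels = [], []
    for k in range(3):
        block = arch[k] + rng.normal(0.0, noise_sd, size=(n_per_cluster, n_pop))
        rows.append(block)
        labels.extend([k] * n_per_cluster)
    profiles = pd.DataFrame(
        np.vstack(rows),
        index=[f"ARCH_{i:04d}" for i in range(3 * n_per_cluster)],
        columns=list(populations),
    )
    return profiles, np.asarray(labels)
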
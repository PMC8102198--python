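"""The three-filter discovery cascade and catalog summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_expr
from lncforge.discovery import (
    catalog_composition,
    chromosome_distribution,
    filter_novel_lncrnas,
)
from lncforge.genomic_model import GenomicInterval, PipelineParams, TranscriptModel


def _candidate(tid, length, score, chrom="chr1", start=1000):
    return TranscriptModel(
        tid, tid, (GenomicInterval(chrom, start, start + length, "+"),),
        source="candidate_novel", coding_potential_score=score,
    )


def _mm_expr(per_gene: dict, n_mm=38):
    samples = [f"MM_{i}" for i in range(n_mm)] + ["BMPC_1", "BMPC_2"]
    groups = {s: ("MM" if s.startswith("MM") else "BMPC") for s in samples}
    values = {g: list(v) + [1.0, 1.0] for g, v in per_gene.items()}
    return make_expr(values, samples, groups)


class TestFilterCascade:
    @pytest.mark.parametrize(
        "length, score, n_hi, expected",
        [
            (300, -2.0, 3, True),    # all filters comfortably passed
            (300, 0.0, 38, False),   # coding potential must be strictly < 0
            (201, -0.1, 3, True),    # boundary pass on all three filters
            (200, -2.0, 38, False),  # length must be strictly > 200
            (300, -2.0, 2, False),   # needs >= 3 expressing tumor samples
        ],
    )
    def test_predicates_at_boundaries(self, length, score, n_hi, expected, params):
        expr = _mm_expr({"t": [1.0] * n_hi + [0.0] * (38 - n_hi)})
        cat = filter_novel_lncrnas([_candidate("t", length, score)], expr, params)
        assert bool(cat.loc["t", "is_novel_lncrna"]) is expected

    def test_all_three_outcomes_recorded_even_for_failures(self, params):
        expr = _mm_expr({"t": [5.0] * 38})
        cat = filter_novel_lncrnas([_candidate("t", 100, -2.0)], expr, params)
        row = cat.loc["t"]
        assert not row["pass_length"]
        assert row["pass_coding_potential"] and row["pass_expression"]
        assert not row["is_novel_lncrna"]

    def test_candidate_missing_from_matrix_fails_closed(self, params, caplog):
        expr = _mm_expr({"other": [5.0] * 38})
        with caplog.at_level("WARNING"):
            cat = filter_novel_lncrnas([_candidate("t", 300, -2.0)], expr, params)
        assert not cat.loc["t", "pass_expression"]
        assert "absent from the expression matrix" in caplog.text

    def test_missing_score_is_an_error(self, params):
        t = _candidate("t", 300, None)
        with pytest.raises(ValueError, match="coding-potential score"):
            filter_novel_lncrnas([t], _mm_expr({"t": [5.0] * 38}), params)

    def test_raising_thresholds_never_grows_pass_set(self, params):
        rng = np.random.default_rng(0)
        genes = {f"t{i}": rng.uniform(0, 3, size=38).tolist() for i in range(40)}
        expr = _mm_expr(genes)
        cands = [
            _candidate(f"t{i}", int(rng.integers(100, 600)),
                       float(rng.uniform(-5, 5)))
            for i in range(40)
        ]
        base = filter_novel_lncrnas(cands, expr, params)
        base_set = set(base.index[base["is_novel_lncrna"]])
        for stricter in (
            params.replace(min_tpm=2.0),
            params.replace(min_samples=10),
            params.replace(min_length_bp=400),
        ):
            sub = filter_novel_lncrnas(cands, expr, stricter)
            assert set(sub.index[sub["is_novel_lncrna"]]) <= base_set

    def test_planted_pass_set_recovered_on_noiseless_fixture(
        self, noiseless_run
    ):
        run_dir, _, truth = noiseless_run
        cat = pd.read_csv(run_dir / "catalog.tsv", sep="\t", index_col=0)
        assert set(cat.index[cat["is_novel_lncrna"]]) == truth.novel_pass


class TestComposition:
    def _empty_catalog(self):
        return pd.DataFrame(columns=["is_novel_lncrna"]).rename_axis("transcript_id")

    def test_constructed_82_percent_share(self, params):
        coding = [_candidate(f"c{i}", 300, None, start=1000 + 2000 * i) for i in range(18)]
        lnc = [_candidate(f"l{i}", 300, None, start=50_000 + 2000 * i) for i in range(82)]
        for t in coding:
            t.source = "coding"
        for t in lnc:
            t.source = "annotated_lncRNA"
        expr = _mm_expr({t.transcript_id: [5.0] * 38 for t in coding + lnc})
        comp = catalog_composition(self._empty_catalog(), coding, lnc, [], expr, params)
        assert comp.loc["annotated_lncRNA", "pct_of_expressed"] == pytest.approx(82.0)
        assert comp["pct_of_expressed"].sum() == pytest.approx(100.0)

    def test_zero_expressed_genes_no_division_error(self, params):
        expr = _mm_expr({"x": [0.0] * 38})
        comp = catalog_composition(self._empty_catalog(), [], [], [], expr, params)
        assert (comp["n_expressed"] == 0).all()
        assert (comp["pct_of_expressed"] == 0.0).all()

    def test_duplicate_ids_between_classes_rejected(self, params):
        t1 = _candidate("dup", 300, None)
        t1.source = "coding"
        t2 = _candidate("dup", 300, None, start=9000)
        t2.source = "annotated_lncRNA"
        expr = _mm_expr({"dup": [5.0] * 38})
        with pytest.raises(ValueError, match="dup"):
            catalog_composition(self._empty_catalog(), [t1], [t2], [], expr, params)

    def test_planted_novel_count_from_fixture(self, noiseless_run):
        _, report, truth = noiseless_run
        assert report.counts["n_novel_lncrna"] == len(truth.novel_pass)


class TestChromosomeDistribution:
    def test_single_chromosome_holds_all_mass(self):
        txs = [_candidate(f"t{i}", 300, None, start=1000 * (i + 1)) for i in range(5)]
        dist = chromosome_distribution({"novel": txs})
        assert dist["pct_within_chrom"].tolist() == [100.0]

    def test_uniform_two_chromosome_split(self):
        a = [_candidate(f"a{i}", 300, None, chrom="chr1", start=1000 * (i + 1)) for i in range(4)]
        b = [_candidate(f"b{i}", 300, None, chrom="chr2", start=1000 * (i + 1)) for i in range(4)]
        dist = chromosome_distribution({"x": a + b, "y": a + b})
        assert (dist["pct_within_chrom"] == 50.0).all()

    def test_counts_match_direct_groupby_on_random_placement(self):
        rng = np.random.default_rng(1)
        chroms = [f"chr{int(c)}" for c in rng.integers(1, 23, size=200)]
        txs = {
            "one": [_candidate(f"t{i}", 300, None, chrom=chroms[i]) for i in range(100)],
            "two": [_candidate(f"u{i}", 300, None, chrom=chroms[100 + i]) for i in range(100)],
        }
        dist = chromosome_distribution(txs)
        direct = (
            pd.DataFrame(
                [(cls, t.chrom) for cls, ts in txs.items() for t in ts],
                columns=["gene_class", "chrom"],
            )
            .groupby(["chrom", "gene_class"])
            .size()
        )
        for _, row in dist.iterrows():
            assert row["count"] == direct.loc[(row["chrom"], row["gene_class"])]
        # natural ordering: numeric chromosomes ascending
        order = dist["chrom"].drop_duplicates().tolist()
        nums = [int(c[3:]) for c in order]
        assert nums == sorted(nums)
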
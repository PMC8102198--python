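"""CV heterogeneity, moderated DE, and the per-patient/cohort callers."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_expr
from lncforge.deregulation import (
    cohort_deregulation,
    coefficient_of_variation,
    compare_cv,
    moderated_de,
    per_patient_calls,
)
from lncforge.genomic_model import PipelineParams


def _two_group_expr(genes: dict, n_mm=4, n_bmpc=3):
    samples = [f"MM_{i}" for i in range(n_mm)] + [f"BMPC_{i}" for i in range(n_bmpc)]
    groups = {s: s.split("_")[0] for s in samples}
    return make_expr(genes, samples, groups)


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2.0, 2.0, 2.0], 0.0),
            ([1.0, 3.0], math.sqrt(2.0) / 2.0),  # sd 1.41421 / mean 2
        ],
    )
    def test_formula(self, values, expected):
        expr = make_expr({"g": values}, [f"s{i}" for i in range(len(values))],
                         {f"s{i}": "MM" for i in range(len(values))})
        assert coefficient_of_variation(expr, "MM").loc["g"] == pytest.approx(expected)

    def test_zero_mean_gene_is_undefined(self):
        expr = make_expr({"g": [0.0, 0.0, 0.0]}, ["a", "b", "c"],
                         {"a": "MM", "b": "MM", "c": "MM"})
        assert np.isnan(coefficient_of_variation(expr, "MM").loc["g"])

    def test_unknown_group_is_an_error(self):
        expr = make_expr({"g": [1.0, 2.0]}, ["a", "b"], {"a": "MM", "b": "MM"})
        with pytest.raises(KeyError):
            coefficient_of_variation(expr, "XX")


class TestCompareCv:
    def test_identical_vectors_give_t_zero_p_one(self):
        v = pd.Series([0.1, 0.5, 0.9, 1.3])
        res = compare_cv(v, v.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_power_against_a_half_sd_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            a = pd.Series(rng.normal(0.5, 0.2, size=500))
            b = pd.Series(rng.normal(0.6, 0.2, size=500))  # shift = 0.5 sd
            if compare_cv(a, b).p_value < 0.05:
                hits += 1
        assert hits / 200 > 0.9

    def test_insufficient_data_flagged_untestable(self):
        res = compare_cv(pd.Series([0.1]), pd.Series([0.2, 0.3]))
        assert not res.testable


class TestModeratedDe:
    def _expr(self, seed=0, n_genes=200, n_mm=6, n_bmpc=4):
        rng = np.random.default_rng(seed)
        vals = {f"g{i}": rng.lognormal(1.0, 1.0, size=n_mm + n_bmpc).tolist()
                for i in range(n_genes)}
        samples = [f"MM_{i}" for i in range(n_mm)] + [f"B_{i}" for i in range(n_bmpc)]
        groups = {s: ("MM" if s.startswith("MM") else "BMPC") for s in samples}
        return make_expr(vals, samples, groups)

    def test_d0_zero_limit_equals_ordinary_pooled_t(self, params):
        expr = self._expr()
        res = moderated_de(expr, "MM", "BMPC", params, d0=0.0)
        la = np.log2(expr.values[expr.samples_in_group("MM")] + 1)
        lb = np.log2(expr.values[expr.samples_in_group("BMPC")] + 1)
        ref = stats.ttest_ind(la, lb, axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t_moderated"], ref.statistic, rtol=1e-10)

    def test_d0_infinite_limit_is_pooled_variance_z(self, params):
        expr = self._expr()
        res = moderated_de(expr, "MM", "BMPC", params, d0=np.inf, s0_sq=0.7)
        la = np.log2(expr.values[expr.samples_in_group("MM")] + 1)
        lb = np.log2(expr.values[expr.samples_in_group("BMPC")] + 1)
        c2 = 1 / 6 + 1 / 4
        z = (la.mean(axis=1) - lb.mean(axis=1)) / np.sqrt(0.7 * c2)
        np.testing.assert_allclose(res.table["t_moderated"], z, rtol=1e-10)

    def test_b_ranking_matches_abs_t_ranking(self, params):
        res = moderated_de(self._expr(), "MM", "BMPC", params)
        t_order = res.table["t_moderated"].abs().sort_values().index
        b_order = res.table["b"].loc[t_order]
        assert b_order.is_monotonic_increasing

    def test_equal_effect_smaller_variance_gets_larger_b(self, params):
        # two genes with the same mean difference; the tight one wins
        genes = {
            "tight": [4.0, 4.1, 3.9, 4.0, 1.0, 1.1, 0.9, 1.0],
            "loose": [4.0, 5.5, 2.5, 4.0, 1.0, 2.5, 0.1, 0.4],
        }
        # pad with null genes so hyperparameter fitting has material
        rng = np.random.default_rng(1)
        for i in range(60):
            genes[f"n{i}"] = rng.lognormal(1.0, 0.5, size=8).tolist()
        samples = [f"MM_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)]
        groups = {s: ("MM" if s.startswith("MM") else "BMPC") for s in samples}
        expr = make_expr(genes, samples, groups)
        res = moderated_de(expr, "MM", "BMPC", params)
        assert res.table.loc["tight", "b"] > res.table.loc["loose", "b"]

    def test_too_few_samples_rejected(self, params):
        expr = make_expr({"g": [1.0, 2.0]}, ["MM_0", "B_0"],
                         {"MM_0": "MM", "B_0": "BMPC"})
        with pytest.raises(ValueError):
            moderated_de(expr, "MM", "BMPC", params)


class TestPerPatientCalls:
    def test_fold_change_call_directions(self, params):
        expr = _two_group_expr(
            {
                "up": [9.0, 9.0, 9.0, 9.0, 4.0, 4.0, 4.0],    # L = log2(10/5) = 1
                "flat": [4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
                "lowref": [0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0],  # pseudocount guard
                "down": [1.0, 1.0, 1.0, 1.0, 9.0, 9.0, 9.0],   # L = log2(2/10) < -1
            }
        )
        calls = per_patient_calls(expr, params)
        assert (calls.loc["up"] == "up").all()
        assert (calls.loc["flat"] == "nc").all()
        assert (calls.loc["lowref"] == "nc").all()  # L ~ 0.585 < 1
        assert (calls.loc["down"] == "down").all()

    def test_up_call_requires_expression_floor(self, params):
        # 4-fold but below 1 TPM in the tumor sample: no call
        expr = _two_group_expr({"g": [0.8, 0.8, 0.8, 0.8, 0.1, 0.1, 0.1]})
        calls = per_patient_calls(expr, params)
        assert (calls.loc["g"] == "nc").all()

    def test_down_call_requires_expressed_reference(self, params):
        # reference below 1 TPM cannot support a down call
        expr = _two_group_expr({"g": [0.0, 0.0, 0.0, 0.0, 0.5, 0.5, 0.5]})
        calls = per_patient_calls(expr, params)
        assert (calls.loc["g"] == "nc").all()


class TestCohortRule:
    def _calls(self, n_up, n_down, n=38):
        row = ["up"] * n_up + ["down"] * n_down + ["nc"] * (n - n_up - n_down)
        return pd.DataFrame([row], index=["g"], columns=[f"MM_{i}" for i in range(n)])

    @pytest.mark.parametrize(
        "n_up, n_down, expected",
        [
            (19, 9, "up"),      # frac_up = 0.5, frac_down = 0.2368
            (19, 10, "none"),   # frac_down = 0.2632 >= 0.25 blocks the call
            (0, 0, "none"),
            (9, 19, "down"),
            (38, 0, "up"),
        ],
    )
    def test_documented_boundaries(self, n_up, n_down, expected, params):
        res = cohort_deregulation(self._calls(n_up, n_down), params)
        assert res.loc["g", "cohort_label"] == expected

    def test_matches_exhaustive_enumeration_up_to_n40(self, params):
        """Independent re-statement of the rule checked over every
        (n_up, n_down, n) with n <= 40; up and down are never both true."""
        for n in range(1, 41):
            rows, expected = {}, {}
            for n_up in range(n + 1):
                for n_down in range(n + 1 - n_up):
                    key = f"u{n_up}_d{n_down}"
                    rows[key] = (
                        ["up"] * n_up + ["down"] * n_down
                        + ["nc"] * (n - n_up - n_down)
                    )
                    fu, fd = n_up / n, n_down / n
                    want_up = fu >= 0.5 and fd < 0.25
                    want_down = fd >= 0.5 and fu < 0.25
                    assert not (want_up and want_down)
                    expected[key] = "up" if want_up else ("down" if want_down else "none")
            calls = pd.DataFrame.from_dict(
                rows, orient="index", columns=[f"MM_{i}" for i in range(n)]
            )
            got = cohort_deregulation(calls, params)["cohort_label"]
            assert got.to_dict() == expected, f"mismatch at n={n}"

    def test_planted_cohort_sets_recovered(self, noiseless_run):
        run_dir, _, truth = noiseless_run
        coh = pd.read_csv(run_dir / "cohort_deregulation.tsv", sep="\t", index_col=0)
        assert set(coh.index[coh["cohort_label"] == "up"]) == truth.dereg_up
        assert set(coh.index[coh["cohort_label"] == "down"]) == truth.dereg_down
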
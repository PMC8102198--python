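"""Expression heterogeneity and deregulation calling.

Three complementary views of tumor-vs-reference expression:

* per-gene coefficient of variation (CV) inside a sample group, with a
  Welch t-test to compare CV distributions between gene classes;
* empirical-Bayes moderated differential expression on log2(TPM + 1)
  with a B statistic (log posterior odds of differential expression),
  thresholded at B > 3;
* a per-patient caller: each tumor sample is compared individually to
  the mean of the normal bone-marrow plasma-cell (BMPC) reference, and a
  cohort rule keeps genes called in >= 50% of patients with < 25% of
  patients in the opposite direction. The per-patient operator is a
  pseudocounted log2 fold change with an expression floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

from .genomic_model import ExpressionMatrix, PipelineParams

__all__ = [
    "coefficient_of_variation",
    "CvComparison",
    "compare_cv",
    "ModeratedDeResult",
    "moderated_de",
    "per_patient_calls",
    "cohort_deregulation",
]


def coefficient_of_variation(expr: ExpressionMatrix, group: str) -> pd.Series:
    """Per-gene CV (sample sd with n-1 denominator / sample mean) over the
    samples of ``group``. Genes with zero mean are NaN (undefined) and are
    excluded from downstream comparisons."""
    samples = expr.samples_in_group(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} needs >=2 samples for a CV")
    vals = expr.values[samples]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    cv.name = f"cv_{group}"
    return cv


@dataclass
class CvComparison:
    t: float | None
    df: float | None
    p_value: float | None
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    testable: bool


def compare_cv(cv_a: pd.Series, cv_b: pd.Series) -> CvComparison:
    """Welch two-sample t-test (two-sided) between two CV vectors,
    ignoring undefined (NaN) entries."""
    a = cv_a.dropna().to_numpy(dtype=float)
    b = cv_b.dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        return CvComparison(None, None, None,
                            float(np.mean(a)) if len(a) else float("nan"),
                            float(np.mean(b)) if len(b) else float("nan"),
                            len(a), len(b), False)
    res = stats.ttest_ind(a, b, equal_var=False)
    return CvComparison(
        t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b), testable=True,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_scaled_f(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled-F model, returning
    (prior df d0, prior variance s0^2). d0 = inf when the observed spread
    of log s^2 is no larger than expected from chi^2 sampling alone."""
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 3:
        return np.inf, float(np.median(s2)) if len(s2) else 1e-8
    z = np.log(s2)
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _b_statistic(t: np.ndarray, df_total: float, r: float, prior_p: float) -> np.ndarray:
    """Log posterior odds of differential expression for moderated t values
    with df_total degrees of freedom, variance-ratio r = (v + v0)/v and
    prior DE proportion prior_p."""
    t2 = t * t
    logit = np.log(prior_p / (1.0 - prior_p))
    if np.isinf(df_total):
        return logit - 0.5 * np.log(r) + 0.5 * t2 * (1.0 - 1.0 / r)
    kernel = (t2 + df_total) / (t2 / r + df_total)
    return logit - 0.5 * np.log(r) + 0.5 * (1.0 + df_total) * np.log(kernel)


@dataclass
class ModeratedDeResult:
    """Per-gene moderated differential-expression statistics plus the
    fitted shrinkage hyperparameters."""

    table: pd.DataFrame  # log2_fc, t_moderated, b, is_de
    d0: float            # prior degrees of freedom
    s0_sq: float         # prior variance
    prior_p: float       # prior DE proportion
    v0: float            # prior variance of the (log2) effect size
    df_residual: float
    df_total: float


def moderated_de(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    params: PipelineParams,
    *,
    prior_p: float = 0.01,
    d0: float | None = None,
    s0_sq: float | None = None,
    v0: float | None = None,
) -> ModeratedDeResult:
    """Empirical-Bayes moderated two-group comparison on log2(TPM + 1).

    Per gene g: effect = mean(group_a) - mean(group_b); pooled residual
    variance s_g^2 with d_g = n_a + n_b - 2 df. Hyperparameters (d0,
    s0^2) are fitted by moment-matching log s_g^2 to a scaled-F model
    (closed form), giving the shrunken variance
    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g) and moderated
    t = effect / (s~_g sqrt(1/n_a + 1/n_b)) with d0 + d_g df.

    B is the log posterior odds of differential expression under a point
    mass/normal mixture prior on the effect with proportion ``prior_p``.
    The effect-size prior variance ``v0`` defaults to the value placing
    the B = 0 optimum at the (1 - prior_p) quantile of |t|, so roughly
    the top ``prior_p`` fraction of |t| can reach positive B.

    ``d0``/``s0_sq``/``v0`` may be fixed explicitly (e.g. d0=0 recovers
    the ordinary pooled t-test; d0=inf shrinks every variance to s0^2).
    """
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    n_a, n_b = len(sa), len(sb)
    if n_a < 2 or n_b < 2:
        raise ValueError("moderated_de needs >=2 samples per group")
    dg = float(n_a + n_b - 2)
    if dg <= 0:
        raise ValueError("zero residual degrees of freedom")

    la = np.log2(expr.values[sa].to_numpy(dtype=float) + 1.0)
    lb = np.log2(expr.values[sb].to_numpy(dtype=float) + 1.0)
    effect = la.mean(axis=1) - lb.mean(axis=1)
    ss = la.var(axis=1, ddof=1) * (n_a - 1) + lb.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / dg

    if d0 is None:
        d0_fit, s0_fit = _fit_scaled_f(s2, dg)
    else:
        d0_fit, s0_fit = float(d0), s0_sq
    if s0_fit is None:
        _, s0_fit = _fit_scaled_f(s2, dg)

    if np.isinf(d0_fit):
        s2_post = np.full_like(s2, s0_fit)
        df_total = np.inf
    elif d0_fit == 0:
        s2_post = s2
        df_total = dg
    else:
        s2_post = (d0_fit * s0_fit + dg * s2) / (d0_fit + dg)
        df_total = d0_fit + dg

    c2 = 1.0 / n_a + 1.0 / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * c2)
    t = np.where(np.isfinite(t), t, 0.0)

    if v0 is None:
        # place the B=0 optimum at the (1 - prior_p) quantile of |t|:
        # for a given t*, B is maximized at r = t*^2, i.e. v0 = c2 (t*^2 - 1)
        t_star = float(np.quantile(np.abs(t), 1.0 - prior_p)) if len(t) else 2.0
        v0 = c2 * max(t_star * t_star - 1.0, 1e-6)
    r = (c2 + v0) / c2
    b = _b_statistic(t, df_total, r, prior_p)

    table = pd.DataFrame(
        {
            "log2_fc": effect,
            "t_moderated": t,
            "b": b,
            "is_de": b > params.b_threshold,
        },
        index=expr.values.index,
    )
    return ModeratedDeResult(
        table=table, d0=d0_fit, s0_sq=float(s0_fit), prior_p=prior_p,
        v0=float(v0), df_residual=dg,
        df_total=float(df_total) if np.isfinite(df_total) else np.inf,
    )


def per_patient_calls(
    expr: ExpressionMatrix,
    params: PipelineParams,
    tumor_group: str = "MM",
    reference_group: str = "BMPC",
    gene_ids=None,
) -> pd.DataFrame:
    """Call each gene up/down/nc in each tumor sample against the mean of
    the reference group.

    L = log2((TPM + 1) / (mean reference TPM + 1)). up: L >= dereg_log2fc
    and sample TPM >= min_tpm; down: L <= -dereg_log2fc and reference
    mean >= min_tpm; otherwise nc. The pseudocount guards zero
    references; the floors stop calls driven by sub-TPM noise.
    """
    tumor = expr.samples_in_group(tumor_group)
    ref = expr.samples_in_group(reference_group)
    vals = expr.values if gene_ids is None else expr.values.loc[list(gene_ids)]
    ref_mean = vals[ref].mean(axis=1)
    tm = vals[tumor]
    lfc = np.log2(tm.add(1.0)).sub(np.log2(ref_mean + 1.0), axis=0)
    up = (lfc >= params.dereg_log2fc) & (tm >= params.min_tpm)
    down = lfc <= -params.dereg_log2fc
    down = down.loc[ref_mean.index]
    down = down & (ref_mean >= params.min_tpm).to_numpy()[:, None]
    calls = pd.DataFrame("nc", index=vals.index, columns=tumor)
    calls = calls.mask(up, "up").mask(down, "down")
    return calls


def cohort_deregulation(calls: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    """Apply the cohort rule to a per-patient call matrix.

    A gene is up if called up in >= min_call_frac of all tumor samples
    with < max_opposite_frac called down (symmetrically for down);
    otherwise none. Fractions use all tumor samples as denominator, so
    no-change patients count against both fractions.
    """
    n = calls.shape[1]
    if n < 1:
        raise ValueError("need >=1 tumor sample")
    frac_up = (calls == "up").sum(axis=1) / n
    frac_down = (calls == "down").sum(axis=1) / n
    label = pd.Series("none", index=calls.index, name="cohort_label")
    is_up = (frac_up >= params.min_call_frac) & (frac_down < params.max_opposite_frac)
    is_down = (frac_down >= params.min_call_frac) & (frac_up < params.max_opposite_frac)
    label[is_up] = "up"
    label[is_down] = "down"
    return pd.DataFrame(
        {"frac_up": frac_up, "frac_down": frac_down, "cohort_label": label}
    )
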
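"""Expression dynamics across B-cell differentiation and tumor samples.

Genes are summarized as centroid vectors (mean log2(TPM + 1) per
population) over the differentiation order NB -> CB -> CC -> GC -> MEM
-> TPC -> BMPC followed by MM, clustered with k-means into expression
patterns, and screened with a deterministic tumor-specificity rule:
near-absent expression in every normal population together with a clear
increase in tumor samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .genomic_model import ExpressionMatrix, PipelineParams

#: differentiation order used for centroid vectors (tumor last)
POPULATION_ORDER = ("NB", "CB", "CC", "GC", "MEM", "TPC", "BMPC", "MM")

__all__ = [
    "POPULATION_ORDER",
    "population_centroids",
    "population_mean_tpm",
    "DynamicsClustering",
    "cluster_dynamics",
    "silhouette_scan",
    "mm_specific_rule",
]


def _population_means(
    expr: ExpressionMatrix, populations, log_transform: bool
) -> pd.DataFrame:
    cols = {}
    for pop in populations:
        samples = expr.samples_in_group(pop)  # raises on a missing population
        vals = expr.values[samples]
        if log_transform:
            vals = np.log2(vals + 1.0)
        cols[pop] = vals.mean(axis=1)
    return pd.DataFrame(cols, columns=list(populations))


def population_centroids(
    expr: ExpressionMatrix, populations=POPULATION_ORDER
) -> pd.DataFrame:
    """Per gene and population, the mean of log2(TPM + 1) over that
    population's samples (columns in the given differentiation order)."""
    return _population_means(expr, populations, log_transform=True)


def population_mean_tpm(
    expr: ExpressionMatrix, populations=POPULATION_ORDER
) -> pd.DataFrame:
    """Per gene and population, the mean TPM (linear scale) — the input
    to the tumor-specificity rule."""
    return _population_means(expr, populations, log_transform=False)


@dataclass
class DynamicsClustering:
    assignments: pd.Series       # gene -> cluster id (0-based)
    centroids: pd.DataFrame      # cluster x population, z-score space
    sizes: pd.Series
    inertia: float
    k: int
    seed: int


def cluster_dynamics(
    profiles: pd.DataFrame, k: int, seed: int, n_init: int = 50
) -> DynamicsClustering:
    """k-means over per-gene z-scored centroid profiles.

    Rows are standardized (zero mean, unit variance per gene) so shape,
    not level, drives the clustering; constant rows map to the zero
    vector. Deterministic for a fixed seed; the best of ``n_init``
    restarts by inertia is kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profiles) < k:
        raise ValueError(f"need >= k={k} profiles, got {len(profiles)}")
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if np.allclose(z, z[0]):
        warnings.warn("all profiles are identical after standardization; "
                      "a single cluster is returned")
        labels = np.zeros(len(profiles), dtype=int)
        centroids = pd.DataFrame([z[0]], columns=profiles.columns)
        assignments = pd.Series(labels, index=profiles.index, name="cluster")
        return DynamicsClustering(assignments, centroids,
                                  assignments.value_counts().sort_index(),
                                  0.0, 1, seed)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z)
    assignments = pd.Series(labels, index=profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    return DynamicsClustering(
        assignments=assignments,
        centroids=centroids,
        sizes=assignments.value_counts().sort_index(),
        inertia=float(km.inertia_),
        k=k,
        seed=seed,
    )


def silhouette_scan(
    profiles: pd.DataFrame, seed: int, k_min: int = 2, k_max: int = 8
) -> dict[int, float]:
    """Mean silhouette score for k in [k_min, k_max] — reported alongside
    the default k, never silently overriding it."""
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    out = {}
    for k in range(k_min, min(k_max, len(profiles) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(z)
        if len(np.unique(labels)) < 2:
            continue
        out[k] = float(silhouette_score(z, labels))
    return out


def mm_specific_rule(
    mean_tpm: pd.DataFrame,
    params: PipelineParams,
    tumor_col: str = "MM",
) -> pd.Series:
    """Tumor-specificity call per gene.

    Specific iff mean TPM <= normal_max_tpm in EVERY normal population
    and tumor mean TPM >= tumor_fold * max(normal means, 1); the
    pseudocount of 1 TPM keeps the fold requirement meaningful when all
    normal means are near zero. Invariant to sample order and to
    renaming of the normal populations.
    """
    if tumor_col not in mean_tpm.columns:
        raise ValueError(f"profiles lack a {tumor_col!r} column")
    normals = mean_tpm.drop(columns=[tumor_col])
    if normals.shape[1] == 0:
        raise ValueError("no normal populations in profiles")
    normal_max = normals.max(axis=1)
    low_in_normals = normal_max <= params.normal_max_tpm
    floor = normal_max.clip(lower=1.0)
    elevated_in_tumor = mean_tpm[tumor_col] >= params.tumor_fold * floor
    out = low_in_normals & elevated_in_tumor
    out.name = "mm_specific"
    return out
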
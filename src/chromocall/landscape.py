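"""Bulk chromatin-landscape workflow over merged peak regions.

Per histone modification, peak sets from all samples are merged into a
union region set and a regions x samples raw-count matrix is built.
Low-count noise is removed with a lognormal-ECDF filter: a lognormal is
fit to the positive counts by maximum likelihood, and the threshold is
the largest count (below the fitted median) whose empirical CDF
diverges from the fitted CDF by more than 5%. Counts are then
log10(x+1)-transformed, columns z-scored, embedded by PCA (components
explaining > 1% of variance) and t-SNE (perplexity = nearest integer to
sqrt(n rows)), and clustered with a density-peak algorithm whose
centers have local density rho and separation delta both above the 95th
percentile. Cluster profiles, per-region lineage assignment and
genome-coverage fractions summarize the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .intervals import GenomicInterval

__all__ = [
    "EmbeddingResult",
    "merge_peaks",
    "lognormal_filter",
    "transform_zscore",
    "pca_tsne",
    "density_peak_cluster",
    "summarize_clusters",
    "assign_region_lineage",
    "genome_coverage_fraction",
]


@dataclass
class EmbeddingResult:
    pcs: pd.DataFrame
    variance_fractions: np.ndarray
    coords_2d: pd.DataFrame | None = None
    rho: np.ndarray | None = None
    delta: np.ndarray | None = None
    cluster: np.ndarray | None = None


def merge_peaks(peak_sets: Sequence[Sequence[GenomicInterval]]) -> list[GenomicInterval]:
    """Union of all peak sets; overlapping or book-ended intervals coalesce."""
    if len(peak_sets) == 0:
        raise ValueError("need at least one peak set")
    all_ivs = sorted(
        (iv for ps in peak_sets for iv in ps), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: list[GenomicInterval] = []
    for iv in all_ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def lognormal_filter(
    matrix: pd.DataFrame, max_divergence: float = 0.05
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Mask sub-threshold counts where the count ECDF diverges from a lognormal.

    The lognormal is fit by ML (mean/sd of log counts) to the positive
    entries. Candidate thresholds are the unique positive values below
    the fitted median e^mu; the threshold T is the largest candidate at
    which |empirical ECDF - fitted CDF| exceeds ``max_divergence`` (0 if
    none). Entries < T are set to 0 and rows left all-zero are dropped.
    Returns (filtered matrix, T, divergence profile).
    """
    vals = matrix.to_numpy(dtype=float)
    pos = vals[vals > 0]
    if pos.size < 100:
        raise ValueError("need >= 100 positive entries to fit the lognormal")
    logs = np.log(pos)
    mu, sd = float(np.mean(logs)), float(np.std(logs))
    if sd < 1e-12:
        raise ValueError("all positive entries equal; lognormal fit degenerate")

    sorted_pos = np.sort(pos)
    uniq = np.unique(sorted_pos)
    ecdf = np.searchsorted(sorted_pos, uniq, side="right") / sorted_pos.size
    fitted = norm.cdf((np.log(uniq) - mu) / sd)
    divergence = np.abs(ecdf - fitted)
    profile = pd.DataFrame({"count": uniq, "ecdf": ecdf, "fitted_cdf": fitted,
                            "divergence": divergence})

    below_median = uniq < np.exp(mu)
    bad = below_median & (divergence > max_divergence)
    threshold = float(uniq[bad].max()) if bad.any() else 0.0

    filtered = matrix.where(matrix >= threshold, other=0) if threshold > 0 else matrix.copy()
    filtered = filtered[(filtered.to_numpy() > 0).any(axis=1)]
    return filtered, threshold, profile


def transform_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10(x + 1), then z-score each column (sample)."""
    logged = np.log10(matrix.to_numpy(dtype=float) + 1.0)
    sd = logged.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0.0:
            raise ValueError(f"zero-variance sample column {matrix.columns[j]!r}")
    z = (logged - logged.mean(axis=0)) / sd
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def pca_tsne(
    matrix: pd.DataFrame,
    perplexity: float | None = None,
    seed: int = 0,
    min_variance_fraction: float = 0.01,
    run_tsne: bool = True,
) -> EmbeddingResult:
    """PCA keeping components > 1% variance, then t-SNE at sqrt-n perplexity.

    Rows are observations (regions for the 2-D maps, samples for
    sample-level PCA — pass the matrix in the wanted orientation).
    Duplicate rows are kept.
    """
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    pca = PCA(n_components=min(x.shape), random_state=seed)
    scores = pca.fit_transform(x)
    keep = pca.explained_variance_ratio_ > min_variance_fraction
    if not keep.any():
        keep[0] = True
    scores = scores[:, keep]
    pcs = pd.DataFrame(scores, index=matrix.index,
                       columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    result = EmbeddingResult(pcs=pcs, variance_fractions=pca.explained_variance_ratio_[keep])
    if not run_tsne:
        return result
    if perplexity is None:
        perplexity = float(round(np.sqrt(n)))
    if n < 3 * perplexity + 2:
        raise ValueError(
            f"perplexity {perplexity} infeasible for {n} rows; "
            f"need perplexity <= {(n - 2) / 3:.0f}"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(scores)
    result.coords_2d = pd.DataFrame(coords, index=matrix.index, columns=["tsne1", "tsne2"])
    return result


def density_peak_cluster(
    coords: np.ndarray | pd.DataFrame,
    center_percentile: float = 95.0,
    dc_percentile: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density-peak clustering of 2-D coordinates.

    rho_i is a Gaussian-kernel local density with cutoff distance d_c at
    the ``dc_percentile`` of pairwise distances; delta_i is the distance
    to the nearest point of higher density (the global peak gets the
    maximum distance). Centers have both rho and delta above the
    ``center_percentile``; every other point inherits the label of its
    nearest denser neighbor in decreasing-rho order.

    Returns (rho, delta, labels).
    """
    x = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 points")
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    off_diag = dist[~np.eye(n, dtype=bool)]
    if off_diag.max() == 0.0:
        warnings.warn("all points identical; single cluster", stacklevel=2)
        return np.ones(n), np.zeros(n), np.zeros(n, dtype=int)
    d_c = np.percentile(off_diag, dc_percentile)
    if d_c == 0.0:
        d_c = off_diag[off_diag > 0].min()
    rho = np.exp(-((dist / d_c) ** 2)).sum(axis=1) - 1.0  # exclude self

    order = np.argsort(-rho, kind="stable")
    delta = np.empty(n)
    nn_higher = np.full(n, -1, dtype=int)
    delta[order[0]] = dist.max()
    for k in range(1, n):
        i = order[k]
        denser = order[:k]
        d_sub = dist[i, denser]
        j = int(np.argmin(d_sub))
        delta[i] = d_sub[j]
        nn_higher[i] = denser[j]

    rho_cut = np.percentile(rho, center_percentile)
    delta_cut = np.percentile(delta, center_percentile)
    centers = np.where((rho > rho_cut) & (delta > delta_cut))[0]
    if len(centers) == 0:
        centers = np.array([order[0]])

    labels = np.full(n, -1, dtype=int)
    for lab, c in enumerate(centers):
        labels[c] = lab
    for i in order:
        if labels[i] == -1:
            labels[i] = labels[nn_higher[i]]
    return rho, delta, labels


def summarize_clusters(
    zmatrix: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Per-cluster column means of the z-scored matrix (cluster x sample)."""
    df = zmatrix.copy()
    return df.groupby(pd.Series(labels, index=df.index, name="cluster")).mean()


def assign_region_lineage(
    zmatrix: pd.DataFrame, lineage_map: Mapping[str, str]
) -> pd.Series:
    """Per-region lineage: the lineage group with the maximal mean z-score.

    Ties go to the lexicographically first lineage (flagged by warning).
    """
    missing = set(zmatrix.columns) - set(lineage_map)
    if missing:
        raise ValueError(f"lineage_map missing samples: {sorted(missing)}")
    lineages = sorted(set(lineage_map[s] for s in zmatrix.columns))
    group_means = pd.DataFrame(
        {
            lin: zmatrix[[s for s in zmatrix.columns if lineage_map[s] == lin]].mean(axis=1)
            for lin in lineages
        }
    )
    arr = group_means.to_numpy()
    best = arr.argmax(axis=1)
    n_ties = int((arr == arr[np.arange(len(arr)), best][:, None]).sum(axis=1).max())
    if n_ties > 1 and (arr == arr.max(axis=1, keepdims=True)).sum() > len(arr):
        warnings.warn("lineage ties resolved to the lexicographically first lineage",
                      stacklevel=2)
    return pd.Series([lineages[b] for b in best], index=zmatrix.index, name="lineage")


def genome_coverage_fraction(
    intervals: Sequence[GenomicInterval], genome_length: int
) -> float:
    """Total merged bp covered by the intervals over the genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    merged = merge_peaks([intervals]) if intervals else []
    return sum(iv.width for iv in merged) / genome_length
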
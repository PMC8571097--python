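"""Fusion-oncoprotein binding-site calling from paired-antibody profiling.

Oncogenic KMT2A fusions retain the protein's N terminus and lose the C
terminus, so a genomic site bound by the fusion protein shows excess
signal from N-terminal-epitope antibodies over C-terminal ones, and
fusion-bound sites are characteristically wide. Both properties are
exploited here:

* the per-peak N-over-C ratio (NCR)

      NCR_i = log10( (n_i + min N) / (c_i + min C) ) * F((n_i + c_i)/2)

  where n_i, c_i are summed N-/C-terminal fragment counts in peak i,
  min N / min C are the minimum counts over the sample's peak set, and
  F is the right-continuous empirical CDF of the per-peak mean signals
  (n_k + c_k)/2. The ECDF acts as a multiplicative shrinkage factor on
  the log ratio: a low-signal peak's NCR is pulled toward zero ("no
  evidence of asymmetry") in inverse proportion to its mean signal,
  while high-signal peaks keep their full log ratio;

* a two-component Gaussian mixture is fit to the NCR values, and a
  second one to peak widths. A peak is called a fusion site only when
  it exceeds the density-intersection threshold in BOTH mixtures. If
  the NCR mixture fails to partition (no N/C asymmetry in the sample —
  the expected behavior of a fusion-free control), zero calls are made.

Gene-level targets, recurrent targets across a cohort, "missing
targets" (recurrent targets absent from one sample), genomic-category
annotation with Fisher tests, and cross-sample NCR clustering/PCA round
out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .gmm import GMMFit, PartitionDecision, assess_partition, classify_upper, fit_gmm2
from .intervals import GeneModel, GenomicInterval, overlap_join

__all__ = [
    "PairedPeakSignal",
    "FusionCallResult",
    "TargetGeneSet",
    "compute_ncr",
    "call_fusion_sites",
    "annotate_peak_categories",
    "compare_category_fractions",
    "assign_targets",
    "recurrent_targets",
    "missing_targets",
    "ncr_cluster",
    "ncr_pca",
    "group_signal_test",
]


@dataclass(frozen=True)
class PairedPeakSignal:
    """Summed N-terminal and C-terminal antibody counts for one peak."""

    peak: GenomicInterval
    n_count: int
    c_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.n_count < 0 or self.c_count < 0:
            raise ValueError("antibody counts must be non-negative")


@dataclass
class FusionCallResult:
    """Per-peak call table plus the two mixture fits that produced it."""

    table: pd.DataFrame  # columns: chrom,start,end,peak_id,width,n_count,c_count,ncr,ncr_pass,width_pass,is_fusion
    ncr_fit: GMMFit | None
    ncr_decision: PartitionDecision | None
    width_fit: GMMFit | None
    width_decision: PartitionDecision | None
    sample_id: str

    @property
    def fusion_peak_ids(self) -> set[str]:
        return set(self.table.loc[self.table["is_fusion"], "peak_id"])


@dataclass(frozen=True)
class TargetGeneSet:
    sample_id: str
    gene_ids: frozenset[str]


def compute_ncr(signals: Sequence[PairedPeakSignal]) -> np.ndarray:
    """The N-over-C ratio for every peak of one sample.

    A peak with n_i + min(N) = 0 yields -inf, and one with
    c_i + min(C) = 0 (and positive numerator) yields +inf; both are
    flagged and excluded from downstream mixture fitting, never imputed.
    """
    if len(signals) == 0:
        raise ValueError("empty peak set")
    n = np.array([s.n_count for s in signals], dtype=float)
    c = np.array([s.c_count for s in signals], dtype=float)
    if not np.any(n + c > 0):
        raise ValueError("all peaks have zero total signal")
    min_n, min_c = n.min(), c.min()
    means = (n + c) / 2.0
    sorted_means = np.sort(means)
    # right-continuous ECDF: F(x) = proportion of means <= x
    ecdf = np.searchsorted(sorted_means, means, side="right") / len(means)
    num = n + min_n
    den = c + min_c
    with np.errstate(divide="ignore"):
        ncr = np.log10(np.where(num > 0, num, np.nan) / den) * ecdf
    ncr[num == 0] = -np.inf
    return ncr


WidthTransform = Literal["raw", "log10"]


def call_fusion_sites(
    signals: Sequence[PairedPeakSignal],
    width_transform: WidthTransform = "raw",
    n_starts: int = 4,
    seed: int = 0,
) -> FusionCallResult:
    """Dual-mixture fusion-site calling for one sample.

    NCR and peak-width mixtures are fit and assessed independently; a
    peak is a fusion site iff it lies above the intersection threshold
    in both. A failed partition on either axis zeroes the corresponding
    pass flags (and hence all calls) instead of forcing a split.
    """
    if len(signals) < 10:
        raise ValueError("need >= 10 peaks to fit the mixtures")
    sample_id = signals[0].sample_id
    ncr = compute_ncr(signals)
    widths = np.array([s.peak.width for s in signals], dtype=float)
    wvals = np.log10(widths) if width_transform == "log10" else widths

    ncr_fit = ncr_dec = width_fit = width_dec = None
    ncr_pass = np.zeros(len(signals), dtype=bool)
    width_pass = np.zeros(len(signals), dtype=bool)
    try:
        ncr_fit = fit_gmm2(ncr[np.isfinite(ncr)], n_starts=n_starts, seed=seed)
        ncr_dec = assess_partition(ncr[np.isfinite(ncr)], ncr_fit)
        if ncr_dec.partitioned:
            ncr_pass = classify_upper(ncr, ncr_fit, "above_threshold", ncr_dec)
    except Exception as exc:
        raise type(exc)(f"NCR mixture fit failed for sample {sample_id!r}: {exc}") from exc
    try:
        width_fit = fit_gmm2(wvals, n_starts=n_starts, seed=seed + 1)
        width_dec = assess_partition(wvals, width_fit)
        if width_dec.partitioned:
            width_pass = classify_upper(wvals, width_fit, "above_threshold", width_dec)
    except Exception as exc:
        raise type(exc)(f"width mixture fit failed for sample {sample_id!r}: {exc}") from exc

    table = pd.DataFrame(
        {
            "chrom": [s.peak.chrom for s in signals],
            "start": [s.peak.start for s in signals],
            "end": [s.peak.end for s in signals],
            "peak_id": [s.peak.id for s in signals],
            "width": widths.astype(int),
            "n_count": [s.n_count for s in signals],
            "c_count": [s.c_count for s in signals],
            "ncr": ncr,
            "ncr_pass": ncr_pass,
            "width_pass": width_pass,
            "is_fusion": ncr_pass & width_pass,
        }
    )
    return FusionCallResult(table, ncr_fit, ncr_dec, width_fit, width_dec, sample_id)


# ---------------------------------------------------------------------------
# genomic-category annotation
# ---------------------------------------------------------------------------

CATEGORIES = ("TSS", "gene_body", "intergenic")


def annotate_peak_categories(
    peaks: Sequence[GenomicInterval],
    annotation: Sequence[GeneModel],
    tss_halfwidth: int = 1000,
) -> list[str]:
    """Classify each peak as TSS, gene_body or intergenic (that precedence)."""
    if tss_halfwidth <= 0:
        raise ValueError("tss_halfwidth must be positive")
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    tss_windows = [g.tss_window(tss_halfwidth) for g in annotation]
    bodies = [g.interval for g in annotation]
    at_tss = {qi for qi, _ in overlap_join(peaks, tss_windows)}
    in_body = {qi for qi, _ in overlap_join(peaks, bodies)}
    out = []
    for i in range(len(peaks)):
        if i in at_tss:
            out.append("TSS")
        elif i in in_body:
            out.append("gene_body")
        else:
            out.append("intergenic")
    return out


def compare_category_fractions(
    categories_a: Sequence[str], categories_b: Sequence[str]
) -> pd.DataFrame:
    """Per-category 2x2 Fisher comparison of two peak sets.

    Rows: category; columns: counts in each set, fractions, odds ratio
    (set A in-category odds over set B), and the two-sided exact p.
    """
    rows = []
    a = pd.Series(categories_a)
    b = pd.Series(categories_b)
    for cat in CATEGORIES:
        a_in, a_out = int((a == cat).sum()), int((a != cat).sum())
        b_in, b_out = int((b == cat).sum()), int((b != cat).sum())
        odds, p = stats.fisher_exact([[a_in, a_out], [b_in, b_out]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "a_in": a_in,
                "a_out": a_out,
                "b_in": b_in,
                "b_out": b_out,
                "frac_a": a_in / max(1, len(a)),
                "frac_b": b_in / max(1, len(b)),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# gene-level targets
# ---------------------------------------------------------------------------


def assign_targets(
    calls: FusionCallResult,
    annotation: Sequence[GeneModel],
    tss_halfwidth: int = 1000,
) -> TargetGeneSet:
    """A gene is a target iff any fusion peak touches its TSS window or body."""
    fus = calls.table[calls.table["is_fusion"]]
    peaks = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(fus["chrom"], fus["start"], fus["end"])
    ]
    genes: set[str] = set()
    if peaks:
        windows = [g.tss_window(tss_halfwidth) for g in annotation]
        bodies = [g.interval for g in annotation]
        for _, si in overlap_join(peaks, windows):
            genes.add(annotation[si].gene_id)
        for _, si in overlap_join(peaks, bodies):
            genes.add(annotation[si].gene_id)
    return TargetGeneSet(calls.sample_id, frozenset(genes))


def recurrent_targets(target_sets: Sequence[TargetGeneSet], min_samples: int = 5) -> set[str]:
    """Genes that are targets in at least ``min_samples`` of the cohort."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts: dict[str, int] = {}
    for ts in target_sets:
        for g in ts.gene_ids:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, k in counts.items() if k >= min_samples}


def missing_targets(recurrent_set: set[str], sample_targets: TargetGeneSet) -> set[str]:
    """Recurrent cohort targets that this sample failed to call."""
    return set(recurrent_set) - set(sample_targets.gene_ids)


# ---------------------------------------------------------------------------
# cross-sample structure
# ---------------------------------------------------------------------------


def ncr_cluster(
    ncr_matrix: pd.DataFrame, method: str = "complete"
) -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster samples (columns) on Euclidean NCR distance.

    Returns the scipy linkage matrix and the leaf-ordered sample ids.
    """
    if ncr_matrix.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    linkage = hierarchy.linkage(ncr_matrix.to_numpy().T, method=method, metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    return linkage, [ncr_matrix.columns[i] for i in order]


def ncr_pca(sample_by_site: pd.DataFrame, n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with samples as observations; returns scores and variance fractions."""
    n_comp = n_components or min(sample_by_site.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(sample_by_site.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=sample_by_site.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def group_signal_test(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Classical two-sample t test on per-peak signal, two-sided, uncorrected."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
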
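"""Single-cell chromatin heterogeneity analysis.

Cells are QC-filtered on fragment count (>= 300) and fraction of reads
in aggregate peaks (FRiP within mu - 2*sigma of a Gaussian moment fit),
binned into fixed genome windows (5 kb), reduced with binarized LSI
(TF-IDF + truncated SVD, dropping depth-correlated components) and
embedded with UMAP. Gene activity scores (bin counts over gene body +/-
flank, depth-normalized) are smoothed by k-NN diffusion imputation, and
cell-to-cell heterogeneity is quantified as normalized dispersion
(variance/mean z-scored within equal-count mean bins). Covariance of
imputed scores groups bivalent fusion-target genes into anticorrelated
programs, each with a "high-cell fraction" estimated from a per-gene
two-component mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .gmm import DegenerateInputError, assess_partition, fit_gmm2
from .intervals import FragmentRecord, GeneModel, GenomicInterval, fragments_to_frame

__all__ = [
    "CellProfile",
    "CellBinMatrix",
    "qc_cells",
    "bin_cells",
    "lsi_embed",
    "umap_embed",
    "gene_scores",
    "impute_scores",
    "normalized_dispersion",
    "compare_dispersion",
    "program_correlation",
]


@dataclass(frozen=True)
class CellProfile:
    barcode: str
    n_fragments: int
    frip: float | None
    passed_qc: bool


@dataclass
class CellBinMatrix:
    """Cells x fixed-width genome bins; bin coordinates retained."""

    counts: pd.DataFrame  # index: barcodes, columns: bin ids
    bins: list[GenomicInterval]
    bin_width: int


def qc_cells(
    fragments: Sequence[FragmentRecord] | pd.DataFrame,
    aggregate_peaks: Sequence[GenomicInterval],
    min_fragments: int = 300,
    frip_sd_mult: float = 2.0,
) -> list[CellProfile]:
    """Per-cell fragment-count and FRiP QC.

    FRiP = fraction of a cell's fragment mass overlapping the aggregate
    peaks. Cells with fewer than ``min_fragments`` fragments are removed
    first; mu and sigma are then moment-fit to the survivors' FRiP and
    cells below mu - ``frip_sd_mult``*sigma are removed (sigma = 0 keeps
    all).
    """
    frame = fragments if isinstance(fragments, pd.DataFrame) else fragments_to_frame(fragments)
    frame = frame.reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for iv in aggregate_peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    in_peak = np.zeros(len(frame), dtype=bool)
    for chrom, sub in frame.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        idx = sub.index.to_numpy()
        for row, s, e in zip(idx, sub["start"].to_numpy(), sub["end"].to_numpy()):
            if tree.overlaps(int(s), int(e)):
                in_peak[row] = True

    work = frame.assign(in_peak=in_peak)
    totals = work.groupby("barcode")["count"].sum()
    peak_mass = work.loc[work["in_peak"]].groupby("barcode")["count"].sum()
    peak_mass = peak_mass.reindex(totals.index, fill_value=0)
    frip = peak_mass / totals

    read_pass = totals >= min_fragments
    if not read_pass.any():
        raise ValueError(f"no cells with >= {min_fragments} fragments")
    mu = float(frip[read_pass].mean())
    sigma = float(frip[read_pass].std(ddof=0))
    frip_cut = mu - frip_sd_mult * sigma

    profiles = []
    for bc in totals.index:
        n = int(totals[bc])
        f = float(frip[bc])
        passed = n >= min_fragments and (sigma == 0.0 or f >= frip_cut)
        profiles.append(CellProfile(bc, n, f, passed))
    return profiles


def bin_cells(
    fragments: Sequence[FragmentRecord] | pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_width: int = 5000,
) -> CellBinMatrix:
    """Midpoint-assign fragments to fixed genome bins; counts are conserved."""
    frame = fragments if isinstance(fragments, pd.DataFrame) else fragments_to_frame(fragments)

    bins: list[GenomicInterval] = []
    offsets: dict[str, int] = {}
    for chrom in sorted(chrom_sizes):
        offsets[chrom] = len(bins)
        size = chrom_sizes[chrom]
        for s in range(0, size, bin_width):
            bins.append(GenomicInterval(chrom, s, min(s + bin_width, size)))

    barcodes = sorted(frame["barcode"].unique())
    bc_idx = {b: j for j, b in enumerate(barcodes)}
    mat = np.zeros((len(barcodes), len(bins)), dtype=np.int64)
    for chrom, sub in frame.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (ends > size).any() or (starts < 0).any():
            bad = sub[(ends > size) | (starts < 0)].iloc[0]
            raise ValueError(
                f"fragment beyond chromosome bounds: {chrom}:{bad['start']}-{bad['end']}"
            )
        mids = (starts + ends) // 2
        rows = np.array([bc_idx[b] for b in sub["barcode"]])
        cols = offsets[chrom] + mids // bin_width
        np.add.at(mat, (rows, cols), sub["count"].to_numpy())

    bin_ids = [f"{b.chrom}:{b.start}-{b.end}" for b in bins]
    return CellBinMatrix(pd.DataFrame(mat, index=barcodes, columns=bin_ids), bins, bin_width)


def lsi_embed(
    matrix: CellBinMatrix | pd.DataFrame,
    n_components: int = 30,
    seed: int = 0,
    depth_corr_cutoff: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binarized latent semantic indexing of the cell x bin matrix.

    Counts are binarized; term frequency per cell is divided by the
    cell's binary total; bins are weighted by idf = log(1 + n_cells /
    (1 + bin frequency)); the weighted matrix is reduced by truncated
    SVD. Per-component Pearson correlation with log total fragment count
    is reported, and components with |r| > ``depth_corr_cutoff`` are
    flagged (drop them before neighbors/UMAP).

    Returns (components DataFrame with only unflagged columns kept by
    caller choice, report DataFrame of r and flags); the components
    frame contains ALL components, the report says which to drop.
    """
    counts = matrix.counts if isinstance(matrix, CellBinMatrix) else matrix
    raw = counts.to_numpy(dtype=float)
    if raw.size == 0:
        raise ValueError("empty cell-bin matrix")
    binary = (raw > 0).astype(float)
    nonempty = binary.sum(axis=0) > 0
    binary = binary[:, nonempty]
    if binary.shape[1] < n_components:
        raise ValueError(
            f"need >= {n_components} non-empty bins, have {binary.shape[1]}"
        )
    row_tot = binary.sum(axis=1, keepdims=True)
    if (row_tot == 0).any():
        raise ValueError("cells with zero fragments in the matrix")
    tf = binary / row_tot
    idf = np.log(1.0 + binary.shape[0] / (1.0 + binary.sum(axis=0)))
    x = tf * idf[None, :]

    svd = TruncatedSVD(n_components=n_components, random_state=seed)
    comps = svd.fit_transform(x)

    depth = np.log1p(raw.sum(axis=1))
    rs = []
    for k in range(comps.shape[1]):
        col = comps[:, k]
        if col.std() == 0 or depth.std() == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(col, depth)[0, 1]))
    report = pd.DataFrame(
        {
            "component": [f"LSI{k + 1}" for k in range(comps.shape[1])],
            "depth_r": rs,
            "flagged": [abs(r) > depth_corr_cutoff for r in rs],
        }
    ).set_index("component")
    frame = pd.DataFrame(
        comps, index=counts.index, columns=[f"LSI{k + 1}" for k in range(comps.shape[1])]
    )
    return frame, report


def retained_components(components: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Drop the depth-correlated components flagged by lsi_embed."""
    keep = [c for c in components.columns if not report.loc[c, "flagged"]]
    return components[keep]


def umap_embed(
    components: pd.DataFrame, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1
) -> pd.DataFrame:
    """2-D UMAP of the LSI components; deterministic for a fixed seed."""
    import umap  # deferred: numba compilation is slow at import time

    if len(components) <= n_neighbors:
        raise ValueError(f"need > {n_neighbors} cells for the UMAP neighborhood")
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(components.to_numpy())
    return pd.DataFrame(coords, index=components.index, columns=["umap1", "umap2"])


def gene_scores(
    matrix: CellBinMatrix,
    annotation: Sequence[GeneModel],
    flank: int = 2000,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Raw gene activity: bin counts over gene body +/- flank, depth-normalized.

    Per-cell scores are rescaled to sum to ``target_sum`` (cells with no
    signal over any gene keep all-zero scores).
    """
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    trees: dict[str, IntervalTree] = {}
    for j, b in enumerate(matrix.bins):
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, j)

    counts = matrix.counts.to_numpy(dtype=float)
    scores = np.zeros((counts.shape[0], len(annotation)))
    warned = False
    for gi, gene in enumerate(annotation):
        iv = gene.interval
        tree = trees.get(iv.chrom)
        hits = sorted(h.data for h in tree.overlap(max(0, iv.start - flank), iv.end + flank)) if tree else []
        if not hits:
            if not warned:
                warnings.warn("some genes overlap no bins; scored 0", stacklevel=2)
                warned = True
            continue
        scores[:, gi] = counts[:, hits].sum(axis=1)

    totals = scores.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return pd.DataFrame(
        scores * scale, index=matrix.counts.index, columns=[g.gene_id for g in annotation]
    )


def impute_scores(
    raw_scores: pd.DataFrame, components: pd.DataFrame, k: int = 15, t: int = 3
) -> pd.DataFrame:
    """k-NN diffusion smoothing of gene scores in component space.

    The transition matrix is uniform over each cell's k nearest
    neighbors (self included); imputed = P^t @ raw. t = 0 returns the
    raw scores unchanged.
    """
    if not raw_scores.index.equals(components.index):
        raise ValueError("raw scores and components must cover the same cells")
    n = len(raw_scores)
    if k >= n:
        raise ValueError(f"k = {k} must be < number of cells ({n})")
    if t == 0:
        return raw_scores.copy()
    nn = NearestNeighbors(n_neighbors=k).fit(components.to_numpy())
    _, idx = nn.kneighbors(components.to_numpy())
    smoothed = raw_scores.to_numpy(dtype=float)
    for _ in range(t):
        smoothed = smoothed[idx].mean(axis=1)
    return pd.DataFrame(smoothed, index=raw_scores.index, columns=raw_scores.columns)


def normalized_dispersion(
    scores: pd.DataFrame, n_bins: int = 20
) -> pd.DataFrame:
    """Per-gene dispersion (variance/mean) z-scored within equal-count mean bins.

    Genes with zero mean have undefined dispersion and are excluded with
    a warning. Returns a table indexed by gene with columns mean,
    dispersion, mean_bin, normalized_dispersion.
    """
    means = scores.mean(axis=0)
    keep = means > 0
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} genes with zero mean excluded from dispersion",
            stacklevel=2,
        )
    means = means[keep]
    if len(means) < n_bins:
        raise ValueError(f"need >= {n_bins} genes with positive mean")
    var = scores.loc[:, keep].var(axis=0, ddof=0)
    disp = var / means

    ranks = means.rank(method="first")
    bins = np.minimum((ranks - 1) // np.ceil(len(means) / n_bins), n_bins - 1).astype(int)
    table = pd.DataFrame(
        {"mean": means, "dispersion": disp, "mean_bin": bins}
    )
    normed = np.empty(len(table))
    for b, sub in table.groupby("mean_bin"):
        d = sub["dispersion"].to_numpy()
        sd = d.std()
        z = (d - d.mean()) / sd if sd > 0 else np.zeros(len(d))
        normed[table["mean_bin"].to_numpy() == b] = z
    table["normalized_dispersion"] = normed
    return table


def compare_dispersion(
    table: pd.DataFrame, groups: Mapping[str, set[str]], equal_var: bool = True
) -> pd.DataFrame:
    """Pairwise two-sample t tests of normalized dispersion between gene groups."""
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            da = table.loc[table.index.intersection(list(groups[a])), "normalized_dispersion"]
            db = table.loc[table.index.intersection(list(groups[b])), "normalized_dispersion"]
            if len(da) < 2 or len(db) < 2:
                raise ValueError(f"groups {a!r}/{b!r} need >= 2 genes in the table")
            t, p = stats.ttest_ind(da, db, equal_var=equal_var)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(da.mean()),
                    "mean_b": float(db.mean()),
                    "t": float(t),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def program_correlation(
    imputed: pd.DataFrame,
    genes: Sequence[str],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int], pd.Series]:
    """Gene-gene Pearson correlation, 2-group partition, high-cell fractions.

    Correlation of imputed scores across cells among the given genes;
    average-linkage hierarchical clustering on 1 - r cut into two
    groups; per-gene high-cell fraction = fraction of cells whose score
    exceeds the density-intersection threshold of a per-gene
    two-component mixture (NaN when that mixture does not partition).
    Constant genes are excluded with a warning.
    """
    genes = [g for g in genes if g in imputed.columns]
    if len(genes) < 4:
        raise ValueError("need >= 4 genes present in the score matrix")
    if len(imputed) < 20:
        raise ValueError("need >= 20 cells")
    sub = imputed[genes]
    sds = sub.std(axis=0, ddof=0)
    const = sds[sds == 0].index
    if len(const):
        warnings.warn(f"constant genes excluded from correlation: {list(const)}", stacklevel=2)
        sub = sub.drop(columns=const)
    corr = sub.corr()

    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    partition = {g: int(l) for g, l in zip(corr.index, labels)}

    fractions = {}
    for g in corr.index:
        vals = sub[g].to_numpy()
        try:
            fit = fit_gmm2(vals, seed=seed, n_starts=3)
            dec = assess_partition(vals, fit)
        except DegenerateInputError:
            fractions[g] = np.nan
            continue
        if dec.partitioned:
            fractions[g] = float(np.mean(vals > dec.threshold))
        else:
            fractions[g] = np.nan
    return corr, partition, pd.Series(fractions, name="high_cell_fraction")
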
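"""Bivalent-promoter calling from H3K4me3 / H3K27me3 promoter counts.

A bivalent (poised) promoter carries both the active H3K4me3 and the
repressive H3K27me3 marks. Per sample, fragments for each mark are
quantified in a symmetric window around every TSS (2 kb by default),
a two-component Gaussian mixture is fit to log10(count + 1) per mark to
separate enriched from non-enriched promoters, and a gene is bivalent
when it sits in the enriched component for BOTH marks (posterior rule:
component membership, not a hard cutoff). Group-level bivalency
fractions with pairwise Fisher tests compare fusion-target, missing-
target and control gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gmm import DegenerateInputError, assess_partition, classify_upper, fit_gmm2
from .intervals import CountMatrix, FragmentRecord, GeneModel, count_fragments_in_intervals

__all__ = [
    "BivalencyCall",
    "quantify_tss_windows",
    "call_bivalency",
    "group_bivalency_fractions",
]

STATUSES = ("bivalent", "K4_only", "K27_only", "neither")


@dataclass(frozen=True)
class BivalencyCall:
    gene_id: str
    k4_enriched: bool
    k27_enriched: bool

    @property
    def status(self) -> str:
        if self.k4_enriched and self.k27_enriched:
            return "bivalent"
        if self.k4_enriched:
            return "K4_only"
        if self.k27_enriched:
            return "K27_only"
        return "neither"


def quantify_tss_windows(
    fragments: Sequence[FragmentRecord] | pd.DataFrame,
    annotation: Sequence[GeneModel],
    half_width: int = 1000,
) -> CountMatrix:
    """Fragment counts (midpoint rule) in [tss - half_width, tss + half_width).

    Windows are clipped at chromosome start; midpoint assignment avoids
    double-counting where windows of nearby genes overlap.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    windows = [g.tss_window(half_width) for g in annotation]
    return count_fragments_in_intervals(fragments, windows, mode="midpoint")


def call_bivalency(
    k4_counts: Mapping[str, int] | pd.Series,
    k27_counts: Mapping[str, int] | pd.Series,
    seed: int = 0,
    n_starts: int = 4,
) -> list[BivalencyCall]:
    """Per-gene bivalency status for one sample.

    Each mark's counts are log10(count+1)-transformed and fit with the
    shared two-component mixture; enrichment is membership in the
    higher-mean component (posterior > 0.5). If a mark's mixture fails
    to partition, no gene is enriched for that mark and a warning is
    raised — so on structureless data zero bivalent genes are called.
    """
    k4 = pd.Series(k4_counts)
    k27 = pd.Series(k27_counts)
    if not k4.index.equals(k27.index):
        k27 = k27.reindex(k4.index)
        if k27.isna().any():
            raise ValueError("K4 and K27 counts must cover the same genes")
    if len(k4) < 10:
        raise DegenerateInputError("need >= 10 genes")

    enriched = {}
    for mark, counts in (("H3K4me3", k4), ("H3K27me3", k27)):
        vals = np.log10(counts.to_numpy(dtype=float) + 1.0)
        fit = fit_gmm2(vals, seed=seed, n_starts=n_starts)
        dec = assess_partition(vals, fit)
        if dec.partitioned:
            enriched[mark] = classify_upper(vals, fit, "posterior", dec)
        else:
            warnings.warn(
                f"{mark} mixture did not partition the promoter counts; "
                "no genes called enriched for this mark",
                stacklevel=2,
            )
            enriched[mark] = np.zeros(len(vals), dtype=bool)

    return [
        BivalencyCall(g, bool(e4), bool(e27))
        for g, e4, e27 in zip(k4.index, enriched["H3K4me3"], enriched["H3K27me3"])
    ]


def group_bivalency_fractions(
    calls: Sequence[BivalencyCall],
    groups: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bivalent fraction per gene group, plus pairwise two-sided Fisher tests.

    Groups must be disjoint and present among the calls. Returns
    (per-group summary, pairwise test table).
    """
    by_gene = {c.gene_id: c for c in calls}
    names = list(groups)
    for i, a in enumerate(names):
        if len(groups[a]) == 0:
            raise ValueError(f"group {a!r} is empty")
        missing = groups[a] - by_gene.keys()
        if missing:
            raise ValueError(f"group {a!r} has genes absent from the calls: {sorted(missing)[:5]}")
        for b in names[i + 1 :]:
            if groups[a] & groups[b]:
                raise ValueError(f"groups {a!r} and {b!r} overlap")

    tallies = {}
    for name in names:
        n_biv = sum(1 for g in groups[name] if by_gene[g].status == "bivalent")
        tallies[name] = (n_biv, len(groups[name]) - n_biv)
    summary = pd.DataFrame(
        {
            "n_genes": {n: sum(tallies[n]) for n in names},
            "n_bivalent": {n: tallies[n][0] for n in names},
            "fraction_bivalent": {n: tallies[n][0] / sum(tallies[n]) for n in names},
        }
    )
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            table = [list(tallies[a]), list(tallies[b])]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "odds_ratio": odds, "p_value": p})
    return summary, pd.DataFrame(rows)
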
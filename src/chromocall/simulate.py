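"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, with the
planted structure the analyses assume recorded in a SyntheticTruth
object that serves as the recovery oracle:

* a fusion-profiling experiment: narrow TSS peaks plus a planted subset
  of wide gene-body peaks, a planted fraction of which carry N-over-C
  asymmetry (fusion sites). Width scales follow the characteristic
  regimes of fusion-bound versus ordinary wide domains (mean ~13 kb
  versus ~8 kb);
* promoter-mark counts for two histone marks with planted
  enriched/bivalent statuses at a configurable fold change;
* a multi-sample region-count matrix with shared, lineage-blocked and
  sample-specific regions;
* single-cell fragments with two anticorrelated gene programs occupying
  minority/majority cell fractions, plus mean-matched unimodal control
  genes for dispersion comparisons.

All generators are pure functions of (parameters, seed): rerunning with
the same arguments reproduces identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CountMatrix,
    FragmentRecord,
    GeneModel,
    GenomicInterval,
)
from .fusion import PairedPeakSignal

__all__ = [
    "SyntheticTruth",
    "make_annotation",
    "simulate_fusion_experiment",
    "simulate_promoter_marks",
    "simulate_landscape",
    "simulate_single_cells",
    "call_fixture_peaks",
]

LINEAGES = ("ALL", "AML", "MPAL")


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the full parameter record."""

    fusion_peak_ids: set[str] = field(default_factory=set)
    wide_peak_ids: set[str] = field(default_factory=set)
    fusion_gene_ids: set[str] = field(default_factory=set)
    gene_status: dict[str, str] = field(default_factory=dict)
    bivalent_gene_ids: set[str] = field(default_factory=set)
    region_class: dict[str, str] = field(default_factory=dict)
    region_lineage: dict[str, str] = field(default_factory=dict)
    sample_lineage: dict[str, str] = field(default_factory=dict)
    cell_program: dict[str, str] = field(default_factory=dict)
    program_a_genes: set[str] = field(default_factory=set)
    program_b_genes: set[str] = field(default_factory=set)
    matched_control_genes: set[str] = field(default_factory=set)
    low_frip_cells: set[str] = field(default_factory=set)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _ser(v):
            if isinstance(v, set):
                return sorted(v)
            return v

        with open(path, "w") as fh:
            json.dump({k: _ser(v) for k, v in self.__dict__.items()}, fh, indent=1,
                      default=str)


def _nbinom(rng: np.random.Generator, mean, size_param: float, shape=None):
    """Negative binomial draws parameterized by mean and size (dispersion)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size_param, p, size=shape if shape is not None else mean.shape)


def make_annotation(
    n_genes: int,
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    median_length: float = 20_000.0,
    log_sd: float = 0.5,
) -> list[GeneModel]:
    """Non-overlapping genes with lognormal lengths and random strands.

    Genes are apportioned to chromosomes proportionally to length and
    packed with Dirichlet-distributed gaps, so placement is feasible iff
    the drawn lengths fit.
    """
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    total = sum(chrom_lengths.values())
    alloc = {c: int(round(n_genes * chrom_lengths[c] / total)) for c in chroms}
    # fix rounding drift on the largest chromosome
    drift = n_genes - sum(alloc.values())
    alloc[max(chroms, key=lambda c: chrom_lengths[c])] += drift

    genes: list[GeneModel] = []
    gid = 0
    for chrom in chroms:
        k = alloc[chrom]
        if k == 0:
            continue
        lengths = np.round(
            np.exp(rng.normal(np.log(median_length), log_sd, size=k))
        ).astype(int)
        lengths = np.maximum(lengths, 200)
        slack = chrom_lengths[chrom] - int(lengths.sum())
        if slack < 0:
            raise ValueError(
                f"cannot pack {k} genes totalling {lengths.sum()} bp into "
                f"{chrom} ({chrom_lengths[chrom]} bp)"
            )
        gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * slack).astype(int)
        pos = 0
        for i in range(k):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid:05d}"
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start, end, gene_id, None, strand))
            )
            pos = end
            gid += 1
    return genes


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def simulate_fusion_experiment(
    annotation: Sequence[GeneModel],
    n_peaks: int = 1000,
    frac_wide: float = 0.1,
    frac_fusion: float = 0.05,
    nc_fold: float = 4.0,
    depth: float = 25.0,
    dispersion: float = 40.0,
    seed: int = 0,
    sample_id: str = "sample1",
    fusion_genes: Sequence[str] | None = None,
    excluded_fusion_genes: set[str] | None = None,
    fusion_width_mean: float = 13_100.0,
    fusion_width_sd: float = 10_000.0,
    wide_width_mean: float = 8_200.0,
    wide_width_sd: float = 4_000.0,
    narrow_width_mean: float = 1_500.0,
    tss_halfwidth: int = 1000,
) -> tuple[list[GenomicInterval], list[PairedPeakSignal], dict[str, list[FragmentRecord]], SyntheticTruth]:
    """Paired N-/C-terminal profiling with planted wide, N-enriched peaks.

    Narrow peaks (gamma widths around 1.5 kb) sit on TSSs; wide peaks sit
    in gene bodies clear of the TSS window, the fusion subset with the
    larger width scale and N-terminal counts ``nc_fold`` times the
    C-terminal mean. ``depth`` is the expected C-terminal fragment count
    per kb of peak. Fragments are emitted for four datasets (two N, two
    C antibodies) such that any-overlap counting reproduces the planted
    counts exactly.
    """
    if not (0 <= frac_fusion <= frac_wide <= 1):
        raise ValueError("require 0 <= frac_fusion <= frac_wide <= 1")
    if nc_fold <= 0 or depth <= 0 or dispersion <= 0:
        raise ValueError("nc_fold, depth and dispersion must be positive")
    rng = np.random.default_rng(seed)
    n_wide = int(round(frac_wide * n_peaks))
    n_fusion = int(round(frac_fusion * n_peaks))
    n_narrow = n_peaks - n_wide

    usable = [
        g for g in annotation if g.interval.width - (tss_halfwidth + 200) >= 3000
    ]
    if len(annotation) < n_peaks or len(usable) < n_wide:
        raise ValueError("annotation too small for the requested peak counts")

    by_id = {g.gene_id: g for g in annotation}
    if fusion_genes is not None:
        fusion_gene_list = list(fusion_genes)
        if len(fusion_gene_list) != n_fusion:
            raise ValueError("len(fusion_genes) must equal round(frac_fusion * n_peaks)")
        pool = [g for g in usable if g.gene_id not in set(fusion_gene_list)]
        wide_ctrl = list(rng.choice(len(pool), size=n_wide - n_fusion, replace=False))
        wide_gene_models = [by_id[g] for g in fusion_gene_list] + [pool[i] for i in wide_ctrl]
    else:
        excl = excluded_fusion_genes or set()
        fusion_pool = [g for g in usable if g.gene_id not in excl]
        if len(fusion_pool) < n_fusion:
            raise ValueError("not enough eligible genes for fusion placement")
        fidx = rng.choice(len(fusion_pool), size=n_fusion, replace=False)
        fusion_gene_list = [fusion_pool[i].gene_id for i in fidx]
        pool = [g for g in usable if g.gene_id not in set(fusion_gene_list)]
        widx = rng.choice(len(pool), size=n_wide - n_fusion, replace=False)
        wide_gene_models = [by_id[g] for g in fusion_gene_list] + [pool[i] for i in widx]

    wide_used = {g.gene_id for g in wide_gene_models}
    narrow_pool = [g for g in annotation if g.gene_id not in wide_used]
    nidx = rng.choice(len(narrow_pool), size=n_narrow, replace=False)
    narrow_gene_models = [narrow_pool[i] for i in nidx]

    peaks: list[GenomicInterval] = []
    is_fusion_flags: list[bool] = []
    mu_f, sg_f = _lognormal_params(fusion_width_mean, fusion_width_sd)
    mu_w, sg_w = _lognormal_params(wide_width_mean, wide_width_sd)

    for k, gene in enumerate(wide_gene_models):
        fus = k < n_fusion
        width = int(np.exp(rng.normal(mu_f if fus else mu_w, sg_f if fus else sg_w)))
        width = max(3000, width)
        iv = gene.interval
        if iv.strand == "-":
            lo, hi = iv.start, max(iv.start + 1, gene.tss - tss_halfwidth - 100)
        else:
            lo, hi = min(iv.end - 1, gene.tss + tss_halfwidth + 100), iv.end
        region = hi - lo
        width = min(width, max(3000, region))
        start = lo + int(rng.integers(0, max(1, region - width + 1))) if region > width else lo
        peaks.append(GenomicInterval(iv.chrom, start, start + width,
                                     name=f"peak_w{k:04d}"))
        is_fusion_flags.append(fus)

    for k, gene in enumerate(narrow_gene_models):
        width = max(300, int(rng.gamma(16.0, narrow_width_mean / 16.0)))
        center = gene.tss
        start = max(0, center - width // 2)
        peaks.append(GenomicInterval(gene.interval.chrom, start, start + width,
                                     name=f"peak_n{k:04d}"))
        is_fusion_flags.append(False)

    widths = np.array([p.width for p in peaks], dtype=float)
    fus = np.array(is_fusion_flags)
    c_mean = depth * widths / 1000.0
    n_mean = c_mean * np.where(fus, nc_fold, 1.0)
    # two datasets per terminus, each at half the terminus mean
    n1 = _nbinom(rng, n_mean / 2, dispersion)
    n2 = _nbinom(rng, n_mean / 2, dispersion)
    c1 = _nbinom(rng, c_mean / 2, dispersion)
    c2 = _nbinom(rng, c_mean / 2, dispersion)

    signals = [
        PairedPeakSignal(p, int(a + b), int(c + d), sample_id)
        for p, a, b, c, d in zip(peaks, n1, n2, c1, c2)
    ]
    datasets = {"N1": n1, "N2": n2, "C1": c1, "C2": c2}
    fragments = {
        name: [
            FragmentRecord(p.chrom, p.start, p.end, sample_id, int(k))
            for p, k in zip(peaks, counts)
            if k > 0
        ]
        for name, counts in datasets.items()
    }

    truth = SyntheticTruth(
        fusion_peak_ids={p.id for p, f in zip(peaks, fus) if f},
        wide_peak_ids={p.id for p in peaks[:n_wide]},
        fusion_gene_ids=set(fusion_gene_list),
        params=dict(
            n_peaks=n_peaks, frac_wide=frac_wide, frac_fusion=frac_fusion,
            nc_fold=nc_fold, depth=depth, dispersion=dispersion, seed=seed,
            sample_id=sample_id, fusion_width_mean=fusion_width_mean,
            wide_width_mean=wide_width_mean,
        ),
    )
    return peaks, signals, fragments, truth


def simulate_promoter_marks(
    annotation: Sequence[GeneModel],
    frac_k4: float = 0.45,
    frac_k27: float = 0.40,
    frac_bivalent: float = 0.20,
    effect_fold: float = 8.0,
    depth: float = 8.0,
    dispersion: float = 10.0,
    seed: int = 0,
    sample_id: str = "sample1",
    bivalent_probs: Mapping[str, float] | None = None,
) -> tuple[dict[str, list[FragmentRecord]], SyntheticTruth]:
    """Two-mark promoter counts with planted enriched/bivalent statuses.

    Enriched promoters draw negative-binomial counts at ``effect_fold``
    times the background mean ``depth`` in the mark's TSS window.
    ``bivalent_probs`` optionally fixes per-gene bivalency probabilities
    (gene groups with different planted rates); the marginal single-mark
    fractions are kept by rescaling the remaining statuses.
    """
    for name, v in (("frac_k4", frac_k4), ("frac_k27", frac_k27),
                    ("frac_bivalent", frac_bivalent)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if frac_bivalent > min(frac_k4, frac_k27):
        raise ValueError("frac_bivalent must be <= min(frac_k4, frac_k27)")
    rng = np.random.default_rng(seed)

    statuses: dict[str, str] = {}
    for g in annotation:
        p_biv = bivalent_probs.get(g.gene_id, frac_bivalent) if bivalent_probs else frac_bivalent
        rest = 1.0 - p_biv
        base_rest = 1.0 - frac_bivalent
        scale = rest / base_rest if base_rest > 0 else 0.0
        p_k4 = (frac_k4 - frac_bivalent) * scale
        p_k27 = (frac_k27 - frac_bivalent) * scale
        p_none = max(0.0, 1.0 - p_biv - p_k4 - p_k27)
        statuses[g.gene_id] = str(
            rng.choice(
                ["bivalent", "K4_only", "K27_only", "neither"],
                p=np.array([p_biv, p_k4, p_k27, p_none])
                / (p_biv + p_k4 + p_k27 + p_none),
            )
        )

    fragments: dict[str, list[FragmentRecord]] = {"H3K4me3": [], "H3K27me3": []}
    for g in annotation:
        st = statuses[g.gene_id]
        for mark, enriched in (
            ("H3K4me3", st in ("bivalent", "K4_only")),
            ("H3K27me3", st in ("bivalent", "K27_only")),
        ):
            mean = depth * (effect_fold if enriched else 1.0)
            k = int(_nbinom(rng, np.array(mean), dispersion, shape=()))
            if k > 0:
                # one aggregated record whose midpoint is the TSS window center
                s = max(0, g.tss - 50)
                fragments[mark].append(
                    FragmentRecord(g.interval.chrom, s, s + 100, sample_id, k)
                )

    truth = SyntheticTruth(
        gene_status=statuses,
        bivalent_gene_ids={g for g, s in statuses.items() if s == "bivalent"},
        params=dict(frac_k4=frac_k4, frac_k27=frac_k27, frac_bivalent=frac_bivalent,
                    effect_fold=effect_fold, depth=depth, dispersion=dispersion,
                    seed=seed, sample_id=sample_id),
    )
    return fragments, truth


def simulate_landscape(
    samples_per_lineage: int = 4,
    n_regions: int = 2000,
    frac_shared: float = 0.2,
    frac_lineage_specific: float = 0.5,
    effect_fold: float = 8.0,
    base_mean: float = 20.0,
    dispersion: float = 10.0,
    seed: int = 0,
    region_width: int = 2000,
    region_gap: int = 3000,
    lineages: Sequence[str] = LINEAGES,
) -> tuple[list[GenomicInterval], CountMatrix, SyntheticTruth]:
    """Region x sample count matrix with shared / lineage-blocked structure.

    Shared regions are high in every sample; lineage-specific regions
    are high only in one lineage's samples; the remainder are
    sample-specific noise, high in one uniformly chosen sample, with a
    uniformly drawn *nominal* lineage recorded in the truth so that
    lineage-assignment accuracy on them is measured at chance.
    """
    if frac_shared + frac_lineage_specific > 1:
        raise ValueError("frac_shared + frac_lineage_specific must be <= 1")
    rng = np.random.default_rng(seed)
    samples = [f"{lin}_{i + 1}" for lin in lineages for i in range(samples_per_lineage)]
    sample_lineage = {s: s.rsplit("_", 1)[0] for s in samples}

    regions = [
        GenomicInterval("chrS", i * (region_width + region_gap),
                        i * (region_width + region_gap) + region_width,
                        name=f"region{i:05d}")
        for i in range(n_regions)
    ]
    n_shared = int(round(frac_shared * n_regions))
    n_lin = int(round(frac_lineage_specific * n_regions))
    classes = (["shared"] * n_shared + ["lineage"] * n_lin
               + ["noise"] * (n_regions - n_shared - n_lin))

    mean = np.full((n_regions, len(samples)), base_mean)
    region_class: dict[str, str] = {}
    region_lineage: dict[str, str] = {}
    for i, (reg, cls) in enumerate(zip(regions, classes)):
        region_class[reg.id] = cls
        if cls == "shared":
            mean[i, :] *= effect_fold
        elif cls == "lineage":
            lin = lineages[int(rng.integers(len(lineages)))]
            region_lineage[reg.id] = lin
            cols = [j for j, s in enumerate(samples) if sample_lineage[s] == lin]
            mean[i, cols] *= effect_fold
        else:
            region_lineage[reg.id] = lineages[int(rng.integers(len(lineages)))]
            j = int(rng.integers(len(samples)))
            mean[i, j] *= effect_fold

    counts = _nbinom(rng, mean, dispersion)
    matrix = CountMatrix(pd.DataFrame(counts, index=[r.id for r in regions], columns=samples))
    truth = SyntheticTruth(
        region_class=region_class,
        region_lineage=region_lineage,
        sample_lineage=sample_lineage,
        params=dict(samples_per_lineage=samples_per_lineage, n_regions=n_regions,
                    frac_shared=frac_shared, frac_lineage_specific=frac_lineage_specific,
                    effect_fold=effect_fold, base_mean=base_mean,
                    dispersion=dispersion, seed=seed),
    )
    return regions, matrix, truth


def simulate_single_cells(
    annotation: Sequence[GeneModel],
    n_cells: int = 1000,
    program_genes_a: Sequence[str] = (),
    program_genes_b: Sequence[str] = (),
    frac_program_a: float = 0.15,
    per_cell_depth: float = 1000.0,
    depth_dispersion: float = 10.0,
    program_on_weight: float = 20.0,
    background_weight: float = 1.0,
    housekeeping_weight: float = 4.0,
    n_matched_controls: int | None = None,
    frac_low_frip: float = 0.0,
    low_frip_background: float = 0.6,
    normal_background: float = 0.03,
    fragment_width: int = 200,
    seed: int = 0,
) -> tuple[list[FragmentRecord], SyntheticTruth]:
    """Single-cell fragments with two anticorrelated gene programs.

    Each cell runs program A (probability ``frac_program_a``) or B. A
    cell's fragments are multinomially spread over genes: its on-program
    genes at ``program_on_weight``, the other program's genes at
    ``background_weight``, remaining genes at ``housekeeping_weight``.
    Mean-matched unimodal control genes (constant weight equal to the
    program-A marginal) are planted automatically for dispersion
    comparisons. A ``frac_low_frip`` fraction of cells emit most of
    their fragments into intergenic space (QC outliers).
    """
    pa, pb = set(program_genes_a), set(program_genes_b)
    if pa & pb:
        raise ValueError("program gene sets must be disjoint")
    gene_ids = [g.gene_id for g in annotation]
    missing = (pa | pb) - set(gene_ids)
    if missing:
        raise ValueError(f"program genes absent from annotation: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    # draw programs first so the matched controls hit the REALIZED marginal
    # mean of the minority-program genes (a nominal-fraction mismatch would
    # sort bimodal and control genes into different dispersion mean-bins)
    programs = np.where(rng.random(n_cells) < frac_program_a, "A", "B")
    frac_real = float((programs == "A").mean())
    marginal_a = frac_real * program_on_weight + (1 - frac_real) * background_weight
    others = [g for g in gene_ids if g not in pa and g not in pb]
    n_match = len(pa) if n_matched_controls is None else n_matched_controls
    matched = {str(g) for g in rng.choice(others, size=min(n_match, len(others)), replace=False)}

    by_id = {g.gene_id: g for g in annotation}
    weights_a_cell = np.array(
        [
            program_on_weight if g in pa
            else background_weight if g in pb
            else marginal_a if g in matched
            else housekeeping_weight
            for g in gene_ids
        ]
    )
    weights_b_cell = np.array(
        [
            background_weight if g in pa
            else program_on_weight if g in pb
            else marginal_a if g in matched
            else housekeeping_weight
            for g in gene_ids
        ]
    )

    chrom_sizes: dict[str, int] = {}
    for g in annotation:
        chrom_sizes[g.interval.chrom] = max(
            chrom_sizes.get(g.interval.chrom, 0), g.interval.end + 10_000
        )
    # intergenic gaps for background / low-FRiP fragments
    gaps: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        pos = 0
        for g in sorted((g for g in annotation if g.interval.chrom == chrom),
                        key=lambda g: g.interval.start):
            if g.interval.start - pos > fragment_width + 10:
                gaps.append(GenomicInterval(chrom, pos, g.interval.start))
            pos = g.interval.end
        if chrom_sizes[chrom] - pos > fragment_width + 10:
            gaps.append(GenomicInterval(chrom, pos, chrom_sizes[chrom]))
    gap_weights = np.array([g.width for g in gaps], dtype=float)
    gap_weights /= gap_weights.sum()

    fragments: list[FragmentRecord] = []
    cell_program: dict[str, str] = {}
    low_frip_cells: set[str] = set()
    n_low = int(round(frac_low_frip * n_cells))
    for ci in range(n_cells):
        bc = f"cell{ci:05d}"
        prog = str(programs[ci])
        cell_program[bc] = prog
        depth_c = max(50, int(_nbinom(rng, np.array(per_cell_depth), depth_dispersion,
                                      shape=())))
        bg_frac = low_frip_background if ci < n_low else normal_background
        if ci < n_low:
            low_frip_cells.add(bc)
        n_bg = rng.binomial(depth_c, bg_frac)
        n_sig = depth_c - n_bg

        w = weights_a_cell if prog == "A" else weights_b_cell
        alloc = rng.multinomial(n_sig, w / w.sum())
        for g_idx in np.nonzero(alloc)[0]:
            gene = by_id[gene_ids[g_idx]]
            iv = gene.interval
            # spread the gene's fragments across ~2-kb segments of the body
            n_seg = max(1, (iv.width - fragment_width) // 2000)
            seg_alloc = rng.multinomial(int(alloc[g_idx]), np.full(n_seg, 1.0 / n_seg))
            seg_len = (iv.width - fragment_width) // n_seg
            for si in np.nonzero(seg_alloc)[0]:
                s = iv.start + int(si) * seg_len + int(rng.integers(0, max(1, seg_len)))
                fragments.append(
                    FragmentRecord(iv.chrom, s, s + fragment_width, bc,
                                   int(seg_alloc[si]))
                )
        if n_bg > 0 and len(gaps):
            galloc = rng.multinomial(n_bg, gap_weights)
            for gp_idx in np.nonzero(galloc)[0]:
                gap = gaps[gp_idx]
                s = gap.start + int(rng.integers(0, max(1, gap.width - fragment_width)))
                fragments.append(
                    FragmentRecord(gap.chrom, s, s + fragment_width, bc,
                                   int(galloc[gp_idx]))
                )

    truth = SyntheticTruth(
        cell_program=cell_program,
        program_a_genes=pa,
        program_b_genes=pb,
        matched_control_genes=matched,
        low_frip_cells=low_frip_cells,
        chrom_sizes=chrom_sizes,
        params=dict(n_cells=n_cells, frac_program_a=frac_program_a,
                    per_cell_depth=per_cell_depth, program_on_weight=program_on_weight,
                    background_weight=background_weight,
                    housekeeping_weight=housekeeping_weight,
                    frac_low_frip=frac_low_frip, seed=seed),
    )
    return fragments, truth


def call_fixture_peaks(
    fragments: Sequence[FragmentRecord],
    merge_gap: int = 200,
    min_total: int = 5,
) -> list[GenomicInterval]:
    """Minimal threshold-and-merge peak caller for fixture plumbing.

    Pooled coverage (all barcodes, weighted by count) is thresholded at
    ``min_total`` and above-threshold runs closer than ``merge_gap`` are
    merged. Not a substitute for a real peak caller; used only to
    provide aggregate peaks for synthetic inputs.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for fr in fragments:
        by_chrom.setdefault(fr.chrom, []).append((fr.start, fr.count))
        by_chrom[fr.chrom].append((fr.end, -fr.count))
    peaks: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        events = sorted(by_chrom[chrom])
        cov = 0
        run_start = None
        runs: list[tuple[int, int]] = []
        for pos, delta in events:
            new_cov = cov + delta
            if cov < min_total <= new_cov and run_start is None:
                run_start = pos
            elif run_start is not None and new_cov < min_total <= cov:
                runs.append((run_start, pos))
                run_start = None
            cov = new_cov
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for i, (s, e) in enumerate(merged):
            peaks.append(GenomicInterval(chrom, s, e, name=f"agg_{chrom}_{i}"))
    return peaks
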
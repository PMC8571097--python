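"""Stage orchestration: simulate fixtures, run each analysis stage, manifest.

Each stage is a pure function from input files + config to output
files; ``run_pipeline`` executes requested stages in dependency order
and writes a manifest recording parameters, seeds and SHA-256 digests
of every input and output, so an identical config on identical inputs
reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bivalency as biv
from . import fusion as fus
from . import landscape as land
from . import single_cell as sc
from . import simulate as sim
from .intervals import (
    CountMatrix,
    count_fragments_in_intervals,
    read_fragments,
    read_gene_models,
    read_intervals,
    write_fragments,
    write_gene_models,
    write_intervals,
)

log = logging.getLogger("chromocall")

__all__ = ["run_pipeline", "sha256_file", "write_manifest"]


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, config: dict, files: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "config": config,
        "outputs": {str(p.relative_to(outdir)): sha256_file(p) for p in sorted(files)},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return path


def _default_annotation(cfg: dict, seed: int):
    n_chroms = cfg["simulate"]["n_chroms"]
    length = cfg["simulate"]["chrom_length"]
    chrom_lengths = {f"chr{i + 1}": length for i in range(n_chroms)}
    return sim.make_annotation(cfg["simulate"]["n_genes"], chrom_lengths, seed=seed)


def stage_simulate(outdir: Path, cfg: dict, scenario: str, seed: int) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rng_seed = seed
    annotation = _default_annotation(cfg, rng_seed)
    write_gene_models(outdir / "annotation.bed", annotation)
    written.append(outdir / "annotation.bed")

    if scenario in ("fusion", "all"):
        p = cfg["simulate"]["fusion"]
        peaks, signals, frags, truth = sim.simulate_fusion_experiment(
            annotation, seed=rng_seed + 1, **p
        )
        write_intervals(outdir / "peaks.bed", peaks)
        written.append(outdir / "peaks.bed")
        for name, recs in frags.items():
            path = outdir / f"fragments_{name}.tsv"
            write_fragments(path, recs)
            written.append(path)
        truth.to_json(outdir / "truth_fusion.json")
        written.append(outdir / "truth_fusion.json")
    if scenario in ("bivalency", "all"):
        p = cfg["simulate"]["bivalency"]
        frags, truth = sim.simulate_promoter_marks(annotation, seed=rng_seed + 2, **p)
        for mark, recs in frags.items():
            path = outdir / f"fragments_{mark}.tsv"
            write_fragments(path, recs)
            written.append(path)
        truth.to_json(outdir / "truth_bivalency.json")
        written.append(outdir / "truth_bivalency.json")
    if scenario in ("landscape", "all"):
        p = cfg["simulate"]["landscape"]
        regions, matrix, truth = sim.simulate_landscape(seed=rng_seed + 3, **p)
        write_intervals(outdir / "regions.bed", regions)
        matrix.to_tsv(outdir / "region_counts.tsv")
        pd.Series(truth.sample_lineage, name="lineage").rename_axis("sample").to_csv(
            outdir / "lineages.tsv", sep="\t"
        )
        truth.to_json(outdir / "truth_landscape.json")
        written += [outdir / "regions.bed", outdir / "region_counts.tsv",
                    outdir / "lineages.tsv", outdir / "truth_landscape.json"]
    if scenario in ("sc", "all"):
        p = dict(cfg["simulate"]["sc"])
        n_prog = p.pop("n_program_genes")
        eligible = [g.gene_id for g in annotation]
        prog_a = eligible[:n_prog]
        prog_b = eligible[n_prog : 2 * n_prog]
        frags, truth = sim.simulate_single_cells(
            annotation, program_genes_a=prog_a, program_genes_b=prog_b,
            seed=rng_seed + 4, **p
        )
        write_fragments(outdir / "fragments_sc.tsv", frags)
        pd.Series(truth.chrom_sizes, name="size").rename_axis("chrom").to_csv(
            outdir / "chrom_sizes.tsv", sep="\t"
        )
        truth.to_json(outdir / "truth_sc.json")
        written += [outdir / "fragments_sc.tsv", outdir / "chrom_sizes.tsv",
                    outdir / "truth_sc.json"]
    return written


def stage_fusion(outdir: Path, cfg: dict, peaks_path: Path, fragment_paths: dict[str, Path],
                 annotation_path: Path, seed: int, sample_id: str = "sample1") -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    peaks = read_intervals(peaks_path)
    annotation = read_gene_models(annotation_path)
    counts = {}
    for name, path in fragment_paths.items():
        frags = read_fragments(path)
        counts[name] = count_fragments_in_intervals(frags, peaks, mode="any_overlap")
    barcode = counts["N1"].col_ids[0] if counts["N1"].col_ids else sample_id
    n = counts["N1"].values.get(barcode, 0) + counts["N2"].values.get(barcode, 0)
    c = counts["C1"].values.get(barcode, 0) + counts["C2"].values.get(barcode, 0)
    signals = [
        fus.PairedPeakSignal(p, int(n.iloc[i]), int(c.iloc[i]), sample_id)
        for i, p in enumerate(peaks)
    ]
    fcfg = cfg["fusion"]
    result = fus.call_fusion_sites(
        signals, width_transform=fcfg["width_transform"],
        n_starts=fcfg["n_starts"], seed=seed
    )
    result.table.to_csv(outdir / "fusion_calls.tsv", sep="\t", index=False)
    targets = fus.assign_targets(result, annotation, tss_halfwidth=fcfg["tss_halfwidth"])
    pd.Series(sorted(targets.gene_ids), name="gene_id").to_csv(
        outdir / "target_genes.tsv", sep="\t", index=False
    )
    fits = {
        "ncr_partitioned": bool(result.ncr_decision.partitioned) if result.ncr_decision else None,
        "width_partitioned": bool(result.width_decision.partitioned) if result.width_decision else None,
        "n_fusion_calls": int(result.table["is_fusion"].sum()),
    }
    with open(outdir / "fusion_summary.json", "w") as fh:
        json.dump(fits, fh, indent=1)
    return [outdir / "fusion_calls.tsv", outdir / "target_genes.tsv",
            outdir / "fusion_summary.json"]


def stage_bivalency(outdir: Path, cfg: dict, k4_path: Path, k27_path: Path,
                    annotation_path: Path, seed: int) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = read_gene_models(annotation_path)
    bcfg = cfg["bivalency"]
    k4 = biv.quantify_tss_windows(read_fragments(k4_path), annotation,
                                  half_width=bcfg["tss_halfwidth"])
    k27 = biv.quantify_tss_windows(read_fragments(k27_path), annotation,
                                   half_width=bcfg["tss_halfwidth"])
    k4_s = k4.values.sum(axis=1)
    k27_s = k27.values.sum(axis=1)
    calls = biv.call_bivalency(k4_s, k27_s, seed=seed, n_starts=bcfg["n_starts"])
    table = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "k4_enriched": [c.k4_enriched for c in calls],
            "k27_enriched": [c.k27_enriched for c in calls],
            "status": [c.status for c in calls],
        }
    )
    table.to_csv(outdir / "bivalency_calls.tsv", sep="\t", index=False)
    return [outdir / "bivalency_calls.tsv"]


def stage_landscape(outdir: Path, cfg: dict, counts_path: Path, lineages_path: Path,
                    seed: int) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    lcfg = cfg["landscape"]
    matrix = CountMatrix.from_tsv(counts_path)
    lineage_map = pd.read_csv(lineages_path, sep="\t", index_col=0)["lineage"].to_dict()
    filtered, threshold, _ = land.lognormal_filter(matrix.values,
                                                   max_divergence=lcfg["max_divergence"])
    z = land.transform_zscore(filtered)
    emb = land.pca_tsne(z, perplexity=lcfg["perplexity"], seed=seed,
                        min_variance_fraction=lcfg["min_variance_fraction"])
    rho, delta, labels = land.density_peak_cluster(
        emb.coords_2d.to_numpy(), center_percentile=lcfg["center_percentile"],
        dc_percentile=lcfg["dc_percentile"]
    )
    lineage = land.assign_region_lineage(z, lineage_map)
    out = emb.coords_2d.copy()
    out["rho"], out["delta"], out["cluster"], out["lineage"] = rho, delta, labels, lineage
    filtered.to_csv(outdir / "filtered_counts.tsv", sep="\t", index_label="id")
    out.to_csv(outdir / "embedding.tsv", sep="\t", index_label="id")
    land.summarize_clusters(z, labels).to_csv(outdir / "cluster_profiles.tsv", sep="\t")
    with open(outdir / "landscape_summary.json", "w") as fh:
        json.dump({"filter_threshold": threshold,
                   "n_regions": int(len(filtered)),
                   "n_clusters": int(len(np.unique(labels)))}, fh, indent=1)
    return [outdir / "filtered_counts.tsv", outdir / "embedding.tsv",
            outdir / "cluster_profiles.tsv", outdir / "landscape_summary.json"]


def stage_sc(outdir: Path, cfg: dict, fragments_path: Path, annotation_path: Path,
             chrom_sizes_path: Path, seed: int, peaks_path: Path | None = None) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = cfg["sc"]
    frags = read_fragments(fragments_path)
    annotation = read_gene_models(annotation_path)
    chrom_sizes = pd.read_csv(chrom_sizes_path, sep="\t", index_col=0)["size"].to_dict()
    peaks = (read_intervals(peaks_path) if peaks_path
             else sim.call_fixture_peaks(frags))
    profiles = sc.qc_cells(frags, peaks, min_fragments=scfg["min_fragments"],
                           frip_sd_mult=scfg["frip_sd_mult"])
    qc_table = pd.DataFrame(
        {"barcode": [p.barcode for p in profiles],
         "n_fragments": [p.n_fragments for p in profiles],
         "frip": [p.frip for p in profiles],
         "passed": [p.passed_qc for p in profiles]}
    )
    qc_table.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    passed = {p.barcode for p in profiles if p.passed_qc}
    kept = [f for f in frags if f.barcode in passed]
    binned = sc.bin_cells(kept, chrom_sizes, bin_width=scfg["bin_width"])
    comps, report = sc.lsi_embed(binned, n_components=min(scfg["n_components"],
                                                          binned.counts.shape[0] - 1),
                                 seed=seed, depth_corr_cutoff=scfg["depth_corr_cutoff"])
    retained = sc.retained_components(comps, report)
    coords = sc.umap_embed(retained, seed=seed, n_neighbors=scfg["umap_neighbors"])
    raw = sc.gene_scores(binned, annotation, flank=scfg["flank"],
                         target_sum=scfg["target_sum"])
    imputed = sc.impute_scores(raw, retained, k=scfg["knn_k"], t=scfg["diffusion_t"])
    disp = sc.normalized_dispersion(imputed, n_bins=scfg["dispersion_bins"])
    coords.to_csv(outdir / "embedding_sc.tsv", sep="\t", index_label="barcode")
    disp.to_csv(outdir / "dispersion.tsv", sep="\t", index_label="gene_id")
    report.to_csv(outdir / "lsi_report.tsv", sep="\t")
    return [outdir / "qc.tsv", outdir / "embedding_sc.tsv", outdir / "dispersion.tsv",
            outdir / "lsi_report.tsv"]


def run_pipeline(outdir: str | Path, config: dict, stages: list[str],
                 seed: int | None = None) -> dict:
    """Run the requested stages on self-generated fixtures, in order.

    Stages: simulate, fusion-call, bivalency, landscape, sc. Analysis
    stages read the files that the simulate stage wrote into ``outdir``.
    Returns the combined manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"] if seed is None else seed
    known = ["simulate", "fusion-call", "bivalency", "landscape", "sc"]
    bad = [s for s in stages if s not in known]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    ordered = [s for s in known if s in stages]
    all_files: list[Path] = []
    for stage in ordered:
        log.info("running stage %s (seed %d)", stage, seed)
        if stage == "simulate":
            files = stage_simulate(outdir, config, "all", seed)
        elif stage == "fusion-call":
            files = stage_fusion(
                outdir, config, outdir / "peaks.bed",
                {k: outdir / f"fragments_{k}.tsv" for k in ("N1", "N2", "C1", "C2")},
                outdir / "annotation.bed", seed,
            )
        elif stage == "bivalency":
            files = stage_bivalency(outdir, config, outdir / "fragments_H3K4me3.tsv",
                                    outdir / "fragments_H3K27me3.tsv",
                                    outdir / "annotation.bed", seed)
        elif stage == "landscape":
            files = stage_landscape(outdir, config, outdir / "region_counts.tsv",
                                    outdir / "lineages.tsv", seed)
        else:
            files = stage_sc(outdir, config, outdir / "fragments_sc.tsv",
                             outdir / "annotation.bed", outdir / "chrom_sizes.tsv", seed)
        all_files += files
    manifest_path = write_manifest(outdir, "run", config, all_files)
    with open(manifest_path) as fh:
        return json.load(fh)
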
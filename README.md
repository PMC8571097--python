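# chromocall

Downstream analysis of antibody-tethered chromatin profiling (CUT&RUN /
CUT&Tag) for fusion-oncoprotein leukemias: dual-antibody
fusion-binding-site calling, bivalent-promoter calling,
chromatin-landscape embedding and clustering, and single-cell chromatin
heterogeneity — with seeded synthetic-data generators that plant ground
truth for every stage.

## Who it is for

Computational biologists analyzing paired N-/C-terminal antibody
profiles of a fusion protein (the motivating case is KMT2A-rearranged
leukemia, where the oncoprotein keeps the KMT2A N terminus and loses
the C terminus), or histone-mark profiles (H3K4me3 / H3K27me3) in bulk
and single cells. Inputs are plain-text genomics formats: BED peak and
gene files, 5-column fragment files (`chrom  start  end  barcode
count`), and TSV count matrices.

## The statistics at the core

**N-over-C ratio (NCR).** For peak *i* with summed N-terminal count
*n<sub>i</sub>* and C-terminal count *c<sub>i</sub>*:

    NCR_i = log10( (n_i + min N) / (c_i + min C) ) * F( (n_i + c_i)/2 )

where min N / min C are the minimum counts over the sample's peaks and
*F* is the empirical CDF of the per-peak mean signals. The ECDF factor
shrinks low-signal peaks toward zero, so only well-covered,
N-skewed peaks keep a large NCR.

**Dual mixture classification.** A two-component Gaussian EM (shared by
every stage of the package) is fit to the NCR values and, separately,
to peak widths. A peak is called a fusion site only when it exceeds the
density-intersection threshold in *both* mixtures; if the mixture does
not genuinely partition the data (BIC + separation decision), zero
calls are made — the expected outcome on a fusion-free control sample.

**Bivalent promoters.** Per-mark mixtures on log promoter counts in
±1-kb TSS windows; a gene is bivalent when it sits in the enriched
component for both H3K4me3 and H3K27me3.

**Landscape.** Merged-peak count matrices are cleaned with a
lognormal-ECDF filter (drop counts whose empirical CDF diverges > 5%
from a fitted lognormal), log/z-scored, embedded (PCA > 1% variance →
t-SNE at √n perplexity) and clustered with density peaks (rho/delta at
their 95th percentiles).

**Single cells.** Fragment/FRiP QC, 5-kb binning, binarized LSI (TF-IDF
+ SVD), UMAP, gene scores with k-NN diffusion imputation, normalized
dispersion (variance/mean z-scored within mean bins), and covariance
grouping of genes into anticorrelated programs.

See `docs/methods.md` for the full model descriptions, defaults and
limitations.

## Worked example

Simulate a fusion-profiling experiment and call fusion sites:

```python
from chromocall.simulate import make_annotation, simulate_fusion_experiment
from chromocall.fusion import call_fusion_sites

genes = make_annotation(1200, {"chr1": 60_000_000, "chr2": 60_000_000}, seed=101)
peaks, signals, fragments, truth = simulate_fusion_experiment(
    genes, n_peaks=1000, frac_wide=0.10, frac_fusion=0.05, seed=7002
)
result = call_fusion_sites(signals, seed=7102)
called = result.fusion_peak_ids
tp = len(called & truth.fusion_peak_ids)
print(f"NCR mixture partitioned: {result.ncr_decision.partitioned}")
print(f"NCR threshold: {result.ncr_decision.threshold:.3f}")
print(f"planted {len(truth.fusion_peak_ids)}, called {len(called)}, "
      f"sensitivity {tp / len(truth.fusion_peak_ids):.2f}, "
      f"precision {tp / len(called):.2f}")
```

prints

```
NCR mixture partitioned: True
NCR threshold: 0.154
planted 50, called 52, sensitivity 1.00, precision 0.96
```

i.e. the NCR mixture separated a minority component of N-skewed peaks,
the intersection threshold landed at NCR ≈ 0.15 (well below the planted
4× asymmetry at log10(4) ≈ 0.6, well above the background spike at 0),
and the dual NCR+width rule recovered all 50 planted fusion peaks with
two false positives.

The same workflows are available from the shell:

```bash
chromocall simulate --scenario all --outdir fixtures --seed 7
chromocall fusion-call --outdir out --seed 7 \
    --peaks fixtures/peaks.bed \
    --n1 fixtures/fragments_N1.tsv --n2 fixtures/fragments_N2.tsv \
    --c1 fixtures/fragments_C1.tsv --c2 fixtures/fragments_C2.tsv \
    --annotation fixtures/annotation.bed
chromocall run-all --outdir full_run --seed 7   # every stage + manifest
```

Every run writes a manifest of parameters, seeds and SHA-256 output
digests; identical config + seed reproduces identical bytes.

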
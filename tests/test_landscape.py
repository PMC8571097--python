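"""Peak merging, lognormal-ECDF filtering, embedding and density-peak clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromocall.intervals import GenomicInterval
from chromocall.landscape import (
    assign_region_lineage,
    density_peak_cluster,
    genome_coverage_fraction,
    lognormal_filter,
    merge_peaks,
    pca_tsne,
    summarize_clusters,
    transform_zscore,
)
from chromocall.simulate import simulate_landscape


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestMerge:
    def test_overlap_coalesces(self):
        assert merge_peaks([[iv(0, 100), iv(50, 150)]]) == [iv(0, 150)]

    def test_book_ended_coalesce(self):
        assert merge_peaks([[iv(0, 100), iv(100, 200)]]) == [iv(0, 200)]

    def test_disjoint_unchanged(self):
        assert merge_peaks([[iv(0, 100), iv(200, 300)]]) == [iv(0, 100), iv(200, 300)]

    def test_matches_sweep_oracle(self, rng):
        ivs = []
        for _ in range(500):
            s = int(rng.integers(0, 100_000))
            ivs.append(iv(s, s + int(rng.integers(1, 3000)), f"chr{rng.integers(1, 3)}"))
        merged = merge_peaks([ivs])

        # independent sweep: mark covered bases, read off runs
        for chrom in ("chr1", "chr2"):
            cov = np.zeros(110_000, dtype=bool)
            for x in ivs:
                if x.chrom == chrom:
                    cov[x.start:x.end] = True
            # book-ended runs merge: bridge zero-length gaps is automatic
            edges = np.flatnonzero(np.diff(np.concatenate([[0], cov.view(np.int8), [0]])))
            runs = list(zip(edges[::2], edges[1::2]))
            got = [(m.start, m.end) for m in merged if m.chrom == chrom]
            assert got == runs

    def test_idempotent(self, rng):
        ivs = [iv(int(s), int(s) + 500) for s in rng.integers(0, 30_000, size=100)]
        once = merge_peaks([ivs])
        assert merge_peaks([once]) == once


class TestLognormalFilter:
    def test_pure_lognormal_mostly_retained(self, rng):
        m = pd.DataFrame(np.round(rng.lognormal(4.0, 0.5, size=(2500, 4))),
                         index=[f"r{i}" for i in range(2500)], columns=list("abcd"))
        filtered, T, profile = lognormal_filter(m)
        retained = (filtered.to_numpy() > 0).sum() / (m.to_numpy() > 0).sum()
        assert retained >= 0.99
        assert T <= np.percentile(m.to_numpy(), 1.0)

    def test_contaminant_block_masked_bulk_kept(self, rng):
        bulk = np.round(rng.lognormal(4.0, 0.5, size=7000))
        cont = rng.integers(1, 4, size=3000).astype(float)
        vals = np.concatenate([bulk, cont])
        rng.shuffle(vals)
        m = pd.DataFrame(vals.reshape(-1, 4), index=[f"r{i}" for i in range(2500)],
                         columns=list("abcd"))
        _, T, _ = lognormal_filter(m)
        arr = m.to_numpy()
        masked = arr < T
        is_cont = arr <= 3
        assert masked[is_cont].mean() >= 0.95
        assert (~masked)[(~is_cont) & (arr > 0)].mean() >= 0.95

    def test_never_removes_maximum(self, rng):
        m = pd.DataFrame(np.round(rng.lognormal(3.0, 0.8, size=(500, 4))) + 1,
                         index=[f"r{i}" for i in range(500)], columns=list("abcd"))
        filtered, T, _ = lognormal_filter(m)
        assert filtered.to_numpy().max() == m.to_numpy().max()

    def test_constant_entries_degenerate(self):
        m = pd.DataFrame(np.full((100, 4), 7.0))
        with pytest.raises(ValueError):
            lognormal_filter(m)


class TestTransform:
    def test_zero_count_maps_to_zero_before_scaling(self):
        m = pd.DataFrame({"a": [0.0, 9.0, 99.0]})
        logged = np.log10(m + 1)
        assert logged.iloc[0, 0] == 0.0

    def test_columns_standardized(self, rng):
        m = pd.DataFrame(rng.lognormal(2, 1, size=(200, 3)), columns=list("abc"))
        z = transform_zscore(m)
        assert np.allclose(z.to_numpy().mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.to_numpy().std(axis=0), 1.0, atol=1e-9)

    def test_matches_two_line_oracle(self, rng):
        m = pd.DataFrame(rng.integers(0, 50, size=(50, 2)).astype(float),
                         columns=["x", "y"])
        z = transform_zscore(m)
        logged = np.log10(m.to_numpy() + 1.0)
        expected = (logged - logged.mean(0)) / logged.std(0)
        assert np.allclose(z.to_numpy(), expected)

    def test_zero_variance_column_named(self):
        m = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            transform_zscore(m)


class TestEmbedding:
    def test_variance_cutoff_keeps_major_components(self, rng):
        # one dominant direction plus tiny noise: only PCs above 1% kept
        base = np.outer(rng.normal(size=300), [1.0, 1.0, 1.0, 1.0])
        noise = rng.normal(scale=1e-3, size=(300, 4))
        emb = pca_tsne(pd.DataFrame(base + noise), run_tsne=False)
        assert emb.pcs.shape[1] == 1

    def test_perplexity_sqrt_rule_and_infeasible(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 4)))
        with pytest.raises(ValueError, match="perplexity"):
            pca_tsne(m, perplexity=25.0)

    def test_lineage_blocked_neighbors_share_group(self, annotation_small, rng):
        _, matrix, truth = simulate_landscape(n_regions=900, seed=31)
        from chromocall.landscape import lognormal_filter, transform_zscore

        filtered, _, _ = lognormal_filter(matrix.values)
        z = transform_zscore(filtered)
        emb = pca_tsne(z, run_tsne=False)
        lineage_regions = [r for r in z.index if truth.region_class[r] == "lineage"]
        sub = emb.pcs.loc[lineage_regions].to_numpy()
        labels = np.array([truth.region_lineage[r] for r in lineage_regions])
        from sklearn.neighbors import NearestNeighbors

        _, idx = NearestNeighbors(n_neighbors=11).fit(sub).kneighbors(sub)
        same = (labels[idx[:, 1:]] == labels[:, None]).mean()
        assert same >= 0.9


class TestDensityPeak:
    def blobs(self, seed, n=150, n_bg=2500):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [rng.normal(c, 0.35, size=(n, 2)) for c in ([2, 2], [9, 2], [2, 9])]
            + [rng.uniform(-2, 13, size=(n_bg, 2))]
        )
        return pts, np.repeat([0, 1, 2], n)

    def test_two_tight_blobs_exact(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, size=(100, 2)),
                         rng.normal(8, 0.2, size=(100, 2)),
                         rng.uniform(-4, 12, size=(1200, 2))])
        _, _, lab = density_peak_cluster(pts)
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, lab[:200]) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_blobs_recovered(self, seed):
        pts, truth = self.blobs(seed)
        _, _, lab = density_peak_cluster(pts)
        assert adjusted_rand_score(truth, lab[: len(truth)]) >= 0.95

    def test_rotation_invariance(self):
        pts, truth = self.blobs(3)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        _, _, lab1 = density_peak_cluster(pts)
        _, _, lab2 = density_peak_cluster(pts @ rot.T)
        assert adjusted_rand_score(lab1, lab2) == 1.0

    def test_identical_points_single_cluster(self):
        with pytest.warns(UserWarning, match="identical"):
            _, _, lab = density_peak_cluster(np.zeros((20, 2)))
        assert len(np.unique(lab)) == 1


class TestSummaries:
    def test_single_cluster_profile_is_column_mean(self, rng):
        z = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        prof = summarize_clusters(z, np.zeros(40, dtype=int))
        assert np.allclose(prof.to_numpy().ravel(), z.mean(axis=0).to_numpy())

    def test_lineage_assignment_planted(self):
        _, matrix, truth = simulate_landscape(n_regions=900, seed=41)
        filtered, _, _ = lognormal_filter(matrix.values)
        z = transform_zscore(filtered)
        lineage = assign_region_lineage(z, truth.sample_lineage)
        ids = [r for r in z.index if truth.region_class[r] == "lineage"]
        acc = np.mean([lineage[r] == truth.region_lineage[r] for r in ids])
        assert acc >= 0.95

    def test_missing_sample_in_lineage_map(self, rng):
        z = pd.DataFrame(rng.normal(size=(10, 2)), columns=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            assign_region_lineage(z, {"s1": "ALL"})

    def test_coverage_fraction(self):
        peaks = [iv(0, 4_000), iv(10_000, 16_000)]
        assert genome_coverage_fraction(peaks, 100_000) == pytest.approx(0.10)
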
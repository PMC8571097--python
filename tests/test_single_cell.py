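"""Single-cell QC, binning, LSI, scoring, imputation, dispersion, programs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import NearestNeighbors

from chromocall import single_cell as sc
from chromocall.intervals import FragmentRecord, GenomicInterval
from chromocall.simulate import call_fixture_peaks, simulate_single_cells


@pytest.fixture(scope="module")
def sc_experiment(annotation_compact):
    gids = [g.gene_id for g in annotation_compact]
    frags, truth = simulate_single_cells(
        annotation_compact, n_cells=500,
        program_genes_a=gids[:8], program_genes_b=gids[8:16], seed=22,
    )
    return frags, truth


@pytest.fixture(scope="module")
def sc_processed(sc_experiment, annotation_compact):
    frags, truth = sc_experiment
    peaks = call_fixture_peaks(frags)
    profiles = sc.qc_cells(frags, peaks)
    passed = {p.barcode for p in profiles if p.passed_qc}
    kept = [f for f in frags if f.barcode in passed]
    binned = sc.bin_cells(kept, truth.chrom_sizes)
    comps, report = sc.lsi_embed(binned, seed=2)
    retained = sc.retained_components(comps, report)
    raw = sc.gene_scores(binned, annotation_compact)
    imputed = sc.impute_scores(raw, retained)
    return dict(truth=truth, binned=binned, retained=retained, raw=raw,
                imputed=imputed)


class TestQC:
    def _frags(self, counts):
        out = []
        for i, k in enumerate(counts):
            out.append(FragmentRecord("chr1", 100, 300, f"c{i}", k))
        return out

    def test_fragment_floor_boundary(self):
        peaks = [GenomicInterval("chr1", 0, 1000)]
        profiles = sc.qc_cells(self._frags([299, 300, 500]), peaks)
        by = {p.barcode: p for p in profiles}
        assert not by["c0"].passed_qc
        assert by["c1"].passed_qc and by["c2"].passed_qc

    def test_identical_frip_keeps_all(self):
        peaks = [GenomicInterval("chr1", 0, 1000)]
        profiles = sc.qc_cells(self._frags([400, 500, 600]), peaks)
        assert all(p.passed_qc for p in profiles)
        assert all(p.frip == pytest.approx(1.0) for p in profiles)

    def test_planted_low_frip_outliers_removed(self, annotation_compact):
        gids = [g.gene_id for g in annotation_compact]
        frags, truth = simulate_single_cells(
            annotation_compact, n_cells=300,
            program_genes_a=gids[:8], program_genes_b=gids[8:16],
            frac_low_frip=0.05, low_frip_background=0.8, seed=33,
        )
        # aggregate signal regions are known exactly here: the gene bodies
        peaks = [g.interval for g in annotation_compact]
        profiles = sc.qc_cells(frags, peaks)
        removed_by_frip = {
            p.barcode for p in profiles
            if not p.passed_qc and p.n_fragments >= 300
        }
        assert removed_by_frip == truth.low_frip_cells

    def test_no_cells_pass_is_error(self):
        peaks = [GenomicInterval("chr1", 0, 1000)]
        with pytest.raises(ValueError):
            sc.qc_cells(self._frags([5, 10]), peaks)


class TestBinning:
    def test_midpoint_bin_assignment(self):
        frag = [FragmentRecord("chr1", 4_999, 5_101, "c0")]  # midpoint 5050
        m = sc.bin_cells(frag, {"chr1": 20_000})
        assert m.counts.loc["c0", "chr1:5000-10000"] == 1

    def test_total_mass_conserved(self, sc_experiment):
        frags, truth = sc_experiment
        m = sc.bin_cells(frags, truth.chrom_sizes)
        assert m.counts.to_numpy().sum() == sum(f.count for f in frags)

    def test_hand_tallied_toy_counts(self):
        frags = [
            FragmentRecord("chr1", 0, 200, "a", 2),        # bin 0
            FragmentRecord("chr1", 4_900, 5_300, "a"),     # midpoint 5100 -> bin 1
            FragmentRecord("chr1", 9_999, 10_001, "b"),    # midpoint 10000 -> bin 2
        ]
        m = sc.bin_cells(frags, {"chr1": 15_000}, bin_width=5000)
        assert m.counts.loc["a"].tolist() == [2, 1, 0]
        assert m.counts.loc["b"].tolist() == [0, 0, 1]

    def test_out_of_bounds_fragment_named(self):
        with pytest.raises(ValueError, match="chr1:19000-21000"):
            sc.bin_cells([FragmentRecord("chr1", 19_000, 21_000, "a")],
                         {"chr1": 20_000})


class TestLSI:
    def test_binarization_in_weighting(self):
        counts = pd.DataFrame(
            [[0, 3, 7, 1, 2], [5, 0, 1, 2, 0], [1, 1, 0, 0, 4]],
            index=["a", "b", "c"],
        )
        comps, report = sc.lsi_embed(counts, n_components=2, seed=0)
        scaled = counts * 10  # binarization makes scale irrelevant
        comps2, _ = sc.lsi_embed(scaled, n_components=2, seed=0)
        assert np.allclose(np.abs(comps.to_numpy()), np.abs(comps2.to_numpy()))

    def test_disjoint_populations_separate(self, rng):
        # two populations occupying disjoint bin blocks
        n, bins = 100, 60
        a = (rng.random((n, bins // 2)) < 0.6).astype(int)
        b = (rng.random((n, bins // 2)) < 0.6).astype(int)
        top = np.hstack([a, np.zeros_like(a)])
        bot = np.hstack([np.zeros_like(b), b])
        counts = pd.DataFrame(np.vstack([top, bot]))
        counts = counts[counts.sum(axis=1) > 0]
        comps, report = sc.lsi_embed(counts, n_components=10, seed=0)
        keep = sc.retained_components(comps, report)
        lab = counts.index.to_numpy() < n
        _, idx = NearestNeighbors(n_neighbors=16).fit(keep.to_numpy()).kneighbors()
        assert (lab[idx] == lab[:, None]).mean() >= 0.95

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            sc.lsi_embed(pd.DataFrame(np.zeros((0, 0))))

    def test_program_populations_neighbor_purity(self, sc_processed):
        truth, retained = sc_processed["truth"], sc_processed["retained"]
        prog = np.array([truth.cell_program[b] == "A" for b in retained.index])
        _, idx = NearestNeighbors(n_neighbors=16).fit(retained.to_numpy()).kneighbors()
        assert (prog[idx] == prog[:, None]).mean() >= 0.95


class TestUMAP:
    def test_deterministic_and_separates_programs(self, sc_processed):
        from sklearn.metrics import silhouette_score

        retained, truth = sc_processed["retained"], sc_processed["truth"]
        sub = retained.iloc[:300]
        coords = sc.umap_embed(sub, seed=4)
        again = sc.umap_embed(sub, seed=4)
        assert np.array_equal(coords.to_numpy(), again.to_numpy())
        labels = [truth.cell_program[b] for b in sub.index]
        assert silhouette_score(coords.to_numpy(), labels) > 0.5

    def test_too_few_cells_rejected(self, sc_processed):
        with pytest.raises(ValueError):
            sc.umap_embed(sc_processed["retained"].iloc[:10], seed=0)


class TestGeneScores:
    def test_per_cell_sum_is_target(self, sc_processed):
        raw = sc_processed["raw"]
        sums = raw.sum(axis=1).to_numpy()
        assert np.allclose(sums[sums > 0], 1e4)

    def test_hand_tallied_toy_scores(self):
        from chromocall.intervals import GeneModel

        genes = [
            GeneModel("g1", GenomicInterval("chr1", 0, 4_000, "g1", None, "+")),
            GeneModel("g2", GenomicInterval("chr1", 20_000, 24_000, "g2", None, "+")),
        ]
        frags = [
            FragmentRecord("chr1", 100, 300, "a", 3),      # bin 0 -> g1
            FragmentRecord("chr1", 21_000, 21_200, "a"),   # bin 4 -> g2
            FragmentRecord("chr1", 21_000, 21_200, "b", 2),
        ]
        m = sc.bin_cells(frags, {"chr1": 30_000})
        scores = sc.gene_scores(m, genes, flank=0, target_sum=100.0)
        assert scores.loc["a"].tolist() == [75.0, 25.0]
        assert scores.loc["b"].tolist() == [0.0, 100.0]


class TestImputation:
    def test_t_zero_is_identity(self, sc_processed):
        raw, retained = sc_processed["raw"], sc_processed["retained"]
        assert sc.impute_scores(raw, retained, t=0).equals(raw)

    def test_convex_combination_bounds(self, sc_processed):
        raw, imputed = sc_processed["raw"], sc_processed["imputed"]
        assert imputed.to_numpy().min() >= raw.to_numpy().min() - 1e-9
        assert imputed.to_numpy().max() <= raw.to_numpy().max() + 1e-9

    def test_full_graph_large_t_approaches_mean(self, rng):
        raw = pd.DataFrame(rng.random((30, 3)), index=[f"c{i}" for i in range(30)])
        comps = pd.DataFrame(np.zeros((30, 2)), index=raw.index)
        out = sc.impute_scores(raw, comps, k=29, t=50)
        assert np.allclose(out.to_numpy(), out.to_numpy().mean(axis=0), atol=1e-6)

    def test_imputation_sharpens_program_correlation(self, sc_processed):
        truth = sc_processed["truth"]
        genes = sorted(truth.program_a_genes)
        raw_r = sc_processed["raw"][genes].corr().to_numpy()
        imp_r = sc_processed["imputed"][genes].corr().to_numpy()
        iu = np.triu_indices(len(genes), 1)
        assert imp_r[iu].mean() > raw_r[iu].mean()

    def test_k_too_large_rejected(self, sc_processed):
        raw, retained = sc_processed["raw"], sc_processed["retained"]
        with pytest.raises(ValueError):
            sc.impute_scores(raw, retained, k=len(raw))


class TestDispersion:
    def test_constant_gene_not_above_bin_average(self, rng):
        scores = pd.DataFrame(rng.poisson(10.0, size=(200, 40)).astype(float),
                              columns=[f"g{i}" for i in range(40)])
        scores["gflat"] = 7.0
        table = sc.normalized_dispersion(scores, n_bins=5)
        assert table.loc["gflat", "dispersion"] == 0.0
        assert table.loc["gflat", "normalized_dispersion"] <= 0.0

    def test_bin_means_centered(self, sc_processed):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sc.normalized_dispersion(sc_processed["imputed"])
        for _, sub in table.groupby("mean_bin"):
            assert abs(sub["normalized_dispersion"].mean()) < 1e-6

    def test_bimodal_gene_beats_matched_unimodal(self, sc_processed):
        truth = sc_processed["truth"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sc.normalized_dispersion(sc_processed["imputed"])
        bimodal = table.index.intersection(sorted(truth.program_a_genes))
        matched = table.index.intersection(sorted(truth.matched_control_genes))
        assert table.loc[bimodal, "normalized_dispersion"].mean() > \
            table.loc[matched, "normalized_dispersion"].mean()

    def test_group_comparison_direction(self, sc_processed):
        truth = sc_processed["truth"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sc.normalized_dispersion(sc_processed["imputed"])
        groups = {
            "bivalent_missing_target": set(truth.program_a_genes),
            "bivalent_control": set(table.index)
            - truth.program_a_genes - truth.program_b_genes,
        }
        res = sc.compare_dispersion(table, groups)
        row = res.iloc[0]
        assert row["mean_a"] > row["mean_b"] and row["p_value"] < 0.01


class TestPrograms:
    def test_self_correlation_unity(self, sc_processed):
        truth = sc_processed["truth"]
        genes = sorted(truth.program_a_genes | truth.program_b_genes)
        corr, _, _ = sc.program_correlation(sc_processed["imputed"], genes, seed=0)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_planted_programs_partition_exactly(self, sc_processed):
        truth = sc_processed["truth"]
        A = sorted(truth.program_a_genes)
        B = sorted(truth.program_b_genes)
        corr, part, frac = sc.program_correlation(
            sc_processed["imputed"], A + B, seed=0
        )
        labels_a = {part[g] for g in A}
        labels_b = {part[g] for g in B}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b
        iu = np.triu_indices(len(A), 1)
        assert corr.loc[A, A].to_numpy()[iu].mean() > 0.5
        assert corr.loc[A, B].to_numpy().mean() < 0.0

    def test_high_cell_fraction_matches_planted(self, sc_processed):
        truth = sc_processed["truth"]
        A = sorted(truth.program_a_genes)
        _, _, frac = sc.program_correlation(
            sc_processed["imputed"], A + sorted(truth.program_b_genes), seed=0
        )
        planted = np.mean([truth.cell_program[b] == "A"
                           for b in sc_processed["imputed"].index])
        got = frac[A].dropna()
        assert len(got) >= len(A) - 1
        assert np.allclose(got, planted, atol=0.05)
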
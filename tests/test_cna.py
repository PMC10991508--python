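"""Residuals, window smoothing, clustering, HMM calls, classification."""

import numpy as np
import pandas as pd
import pytest

from clonescape import cna
from clonescape.simulate import simulate_genome


def brute_force_smooth(values, chroms, window):
    """Independent double-loop implementation of the window mean plus
    per-unit median re-centring (oracle)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for u in range(values.shape[0]):
        col = 0
        for chrom in pd.unique(chroms):
            idx = [i for i, c in enumerate(chroms) if c == chrom]
            m = len(idx)
            eff = min(window, m)
            hl, hr = (eff - 1) // 2, eff // 2
            for k in range(m):
                lo, hi = max(0, k - hl), min(m, k + hr + 1)
                out[u, col + k] = np.mean(values[u, [idx[j] for j in range(lo, hi)]])
            col += m
        out[u] -= np.median(out[u])
    return out


def make_profile(values, annotation, n_keep=None):
    """Wrap a dense array as a CnaProfile over the first genes."""
    n = values.shape[1] if n_keep is None else n_keep
    cols = annotation.gene_ids[:n]
    resid = pd.DataFrame(values[:, :n],
                         index=[f"u{i}" for i in range(values.shape[0])],
                         columns=cols)
    return cna.smooth_windows(resid, annotation, window=101)


class TestRelativeExpression:
    def test_background_units_have_near_zero_residuals(self, rng):
        counts = np.tile(rng.poisson(10, 50) + 1, (6, 1))
        ids = [f"u{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(50)]
        res = cna.relative_expression(counts, ids, genes, {"u0", "u1", "u2"})
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-12)

    def test_cutoff_drops_low_mean_genes(self):
        counts = np.zeros((10, 3))
        counts[:, 0] = 5          # mean 5, kept
        counts[0, 1] = 0.9        # mean 0.09 < 0.1, dropped
        counts[:, 2] = 0.11       # mean 0.11, kept
        res = cna.relative_expression(counts, [f"u{i}" for i in range(10)],
                                      ["a", "b", "c"], {"u0"}, cutoff=0.1)
        assert list(res.columns) == ["a", "c"]

    def test_twofold_gene_residual_is_one_log2(self):
        # gene 0 doubled in the foreground unit; many genes so the library
        # shift is negligible, large scale so log2(1+x) ~ log2(x)
        bg = np.full(1000, 1000.0)
        fg = bg.copy()
        fg[0] *= 2
        res = cna.relative_expression(np.vstack([bg, fg]), ["b", "f"],
                                      [f"g{i}" for i in range(1000)], {"b"},
                                      scale=1e6, clip_sd=np.inf)
        assert res.loc["f"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError, match="background"):
            cna.relative_expression(np.ones((2, 5)), ["a", "b"],
                                    list("vwxyz"), set())


class TestSmoothWindows:
    def test_constant_row_unchanged(self, small_annotation):
        prof = make_profile(np.full((2, 200), 1.7), small_annotation)
        np.testing.assert_allclose(prof.values.to_numpy(), 0.0, atol=1e-12)
        # constant in -> constant out; the median re-centring removes it

    def test_impulse_becomes_unit_plateau(self):
        ann = simulate_genome(303, 1, seed=2)
        x = np.zeros((1, 303))
        x[0, 151] = 101.0
        resid = pd.DataFrame(x, index=["u0"], columns=ann.gene_ids)
        prof = cna.smooth_windows(resid, ann, window=101)
        vals = prof.values.to_numpy()[0]
        plateau = vals[101:202]
        np.testing.assert_allclose(plateau, 1.0, atol=1e-12)
        oracle = brute_force_smooth(x, ann.chromosome, 101)
        np.testing.assert_allclose(vals, oracle[0], atol=1e-10)

    def test_matches_brute_force_on_random_profiles(self, small_annotation,
                                                    rng):
        x = rng.normal(0, 1, (5, 200))
        prof = make_profile(x, small_annotation)
        oracle = brute_force_smooth(x, small_annotation.chromosome, 101)
        np.testing.assert_allclose(prof.values.to_numpy(), oracle, atol=1e-10)

    def test_even_window_rejected(self, small_annotation, rng):
        resid = pd.DataFrame(rng.normal(size=(2, 200)),
                             columns=small_annotation.gene_ids)
        with pytest.raises(ValueError, match="odd"):
            cna.smooth_windows(resid, small_annotation, window=100)

    def test_missing_chromosome_warns(self, small_annotation, rng):
        # keep only genes of the first chromosome
        sl = small_annotation.chromosome_slices()["chr1"]
        resid = pd.DataFrame(rng.normal(size=(2, sl.stop - sl.start)),
                             columns=small_annotation.gene_ids[sl])
        with pytest.warns(UserWarning, match="no retained genes"):
            cna.smooth_windows(resid, small_annotation)


class TestClusterProfiles:
    def test_duplicate_profiles_single_cluster(self, small_annotation, rng):
        x = np.tile(rng.normal(0, 1, 200), (4, 1))
        prof = make_profile(x, small_annotation)
        labels = cna.cluster_profiles(prof, n_clusters=1)
        assert labels.nunique() == 1

    def test_two_planted_genotypes_fully_recovered(self, small_annotation,
                                                   rng):
        base_a = np.zeros(200)
        base_a[:50] = 0.5
        base_b = np.zeros(200)
        base_b[100:150] = -0.5
        x = np.vstack([base_a + rng.normal(0, 0.01, 200) for _ in range(10)]
                      + [base_b + rng.normal(0, 0.01, 200) for _ in range(10)])
        prof = make_profile(x, small_annotation)
        labels = cna.cluster_profiles(prof, n_clusters=2)
        from sklearn.metrics import adjusted_rand_score
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_order_invariance_of_partition(self, small_annotation, rng):
        base_a = np.zeros(200); base_a[:50] = 0.5
        base_b = np.zeros(200); base_b[100:150] = -0.5
        x = np.vstack([base_a + rng.normal(0, 0.02, 200) for _ in range(8)]
                      + [base_b + rng.normal(0, 0.02, 200) for _ in range(8)])
        prof = make_profile(x, small_annotation)
        labels = cna.cluster_profiles(prof, n_clusters=2)
        perm = rng.permutation(16)
        prof2 = cna.CnaProfile(values=prof.values.iloc[perm],
                               chromosomes=prof.chromosomes,
                               order_index=prof.order_index, window=101)
        labels2 = cna.cluster_profiles(prof2, n_clusters=2)
        # same partition up to label names
        joined = pd.crosstab(labels.loc[labels2.index], labels2)
        assert (joined > 0).sum().sum() == 2

    def test_more_clusters_than_units_rejected(self, small_annotation, rng):
        prof = make_profile(rng.normal(size=(3, 200)), small_annotation)
        with pytest.raises(ValueError):
            cna.cluster_profiles(prof, n_clusters=5)


class TestMergeClusters:
    def de_data(self, rng, n_de_genes, n_cells=20, n_genes=1000):
        """Two groups differing strongly in exactly n_de_genes genes.

        The remaining genes of the second group are rescaled so expected
        library sizes match — otherwise normalisation smears the shift
        over every gene.
        """
        base = rng.poisson(50, (2 * n_cells, n_genes)).astype(float)
        if n_de_genes:
            # balanced up/down shifts keep the library size unchanged,
            # so no compositional fold-change leaks onto null genes
            ups = (n_de_genes + 1) // 2
            downs = n_de_genes - ups
            base[n_cells:, :ups] += 25.0
            if downs:
                base[n_cells:, ups:n_de_genes] -= ups * 25.0 / downs
        labels = pd.Series([0] * n_cells + [1] * n_cells,
                           index=[f"c{i}" for i in range(2 * n_cells)])
        genes = [f"g{i}" for i in range(n_genes)]
        return base, labels, genes

    def test_identical_clusters_merge(self, rng):
        counts, labels, genes = self.de_data(rng, 0)
        merged = cna.merge_clusters(labels, counts, genes)
        assert merged.nunique() == 1

    def test_nine_de_genes_merge_ten_keep(self, rng):
        counts9, labels, genes = self.de_data(rng, 9)
        assert cna.merge_clusters(labels, counts9, genes).nunique() == 1
        counts10, labels, genes = self.de_data(rng, 10)
        assert cna.merge_clusters(labels, counts10, genes).nunique() == 2

    def test_only_indistinct_pair_merges(self, rng):
        """Three clusters where only (A, B) is below the DE threshold."""
        n = 20
        base = rng.poisson(50, (3 * n, 100)).astype(float)
        base[2 * n:, :30] *= 8.0  # C differs in 30 genes from A and B
        labels = pd.Series([0] * n + [1] * n + [2] * n,
                           index=[f"c{i}" for i in range(3 * n)])
        genes = [f"g{i}" for i in range(100)]
        merged = cna.merge_clusters(labels, base, genes)
        assert merged.nunique() == 2
        assert merged.iloc[0] == merged.iloc[n]        # A and B merged
        assert merged.iloc[0] != merged.iloc[2 * n]    # C kept separate
        # verified against exhaustive pairwise DE recomputation
        from clonescape.io import normalize_lognorm
        from clonescape.signatures import wilcoxon_de
        expr = normalize_lognorm(base)
        ab = wilcoxon_de(expr, genes, np.arange(n), np.arange(n, 2 * n),
                         min_log2fc=0.25)
        ac = wilcoxon_de(expr, genes, np.arange(n), np.arange(2 * n, 3 * n),
                         min_log2fc=0.25)
        assert ab["significant"].sum() < 10 <= ac["significant"].sum()


class TestCallSegments:
    def planted_profile(self, ann, segments, n_units=30, noise=0.02,
                        seed=0):
        rng = np.random.default_rng(seed)
        mean = np.zeros(ann.n_genes)
        for start, end, amp in segments:
            mean[start:end] = amp
        x = mean + rng.normal(0, noise, (n_units, ann.n_genes))
        resid = pd.DataFrame(x, index=[f"u{i}" for i in range(n_units)],
                             columns=ann.gene_ids)
        return cna.smooth_windows(resid, ann, window=101)

    def test_flat_profile_yields_no_segments(self):
        ann = simulate_genome(600, 2, seed=3)
        prof = self.planted_profile(ann, [])
        labels = pd.Series(0, index=prof.values.index)
        calls = cna.call_cna_segments(prof, labels)
        assert calls.calls[0] == []

    def test_planted_step_called_within_half_window(self):
        ann = simulate_genome(1000, 2, seed=4)
        prof = self.planted_profile(ann, [(100, 400, 0.5)])
        labels = pd.Series(0, index=prof.values.index)
        calls = cna.call_cna_segments(prof, labels)
        segs = calls.calls[0]
        assert len(segs) == 1
        seg = segs[0]
        assert seg.state == cna.AMPLIFICATION
        assert abs(seg.start_index - 100) <= 51
        assert abs(seg.end_index - 400) <= 51
        # oracle: threshold the mean smoothed profile at half amplitude
        mean = prof.values.to_numpy().mean(axis=0)
        above = np.flatnonzero(mean > 0.25)
        assert abs(seg.start_index - above[0]) <= 5
        assert abs(seg.end_index - (above[-1] + 1)) <= 5

    def test_deletion_and_amplification_on_different_chromosomes(self):
        ann = simulate_genome(1000, 2, seed=5)
        # chr1: genes 0-499, chr2: 500-999
        prof = self.planted_profile(ann, [(100, 350, -0.5), (600, 850, 0.5)])
        labels = pd.Series(0, index=prof.values.index)
        segs = cna.call_cna_segments(prof, labels).calls[0]
        states = sorted((s.chromosome, s.state) for s in segs)
        assert states == [("chr1", cna.DELETION), ("chr2", cna.AMPLIFICATION)]

    def test_small_cluster_warns_and_calls_nothing(self):
        ann = simulate_genome(600, 2, seed=6)
        prof = self.planted_profile(ann, [(50, 350, 0.5)], n_units=3)
        labels = pd.Series(0, index=prof.values.index)
        with pytest.warns(UserWarning, match="fewer than"):
            calls = cna.call_cna_segments(prof, labels)
        assert calls.calls[0] == []


def call(cluster, chrom, start, end, state, amp):
    return cna.CnaCall(cluster=cluster, chromosome=chrom, start_index=start,
                       end_index=end, state=state, mean_residual=amp,
                       posterior=1.0, n_genes=end - start)


def label_series(sizes):
    labels, units = [], []
    for cl, n in sizes.items():
        for i in range(n):
            units.append(f"{cl}_{i}")
            labels.append(cl)
    return pd.Series(labels, index=units)


class TestClassifyClusters:
    A = ("chr1", 0, 300)
    B = ("chr2", 500, 800)
    AMP = cna.AMPLIFICATION

    def weights(self, labels, per_cluster):
        return pd.Series([per_cluster[l] for l in labels], index=labels.index)

    def test_mutually_exclusive_uniques_are_subclones(self):
        cs = cna.CnaCallSet(calls={
            "X": [call("X", *self.A, self.AMP, 0.4),
                  call("X", *self.B, self.AMP, 0.4),
                  call("X", "chr3", 1000, 1300, self.AMP, 0.4)],
            "Y": [call("Y", *self.A, self.AMP, 0.4),
                  call("Y", *self.B, self.AMP, 0.4),
                  call("Y", "chr4", 1500, 1800, self.AMP, 0.4)],
        })
        labels = label_series({"X": 10, "Y": 10})
        out = cna.classify_clusters(cs, self.weights(labels, {"X": .8, "Y": .8}),
                                    labels)
        assert (out["label"] == "subclone").all()

    def test_cluster_with_only_shared_segments_is_border(self):
        cs = cna.CnaCallSet(calls={
            "X": [call("X", *self.A, self.AMP, 0.4)],
            "Y": [call("Y", *self.B, self.AMP, 0.4)],
            "Z": [call("Z", *self.A, self.AMP, 0.25),
                  call("Z", *self.B, self.AMP, 0.25)],
        })
        labels = label_series({"X": 10, "Y": 10, "Z": 10})
        out = cna.classify_clusters(
            cs, self.weights(labels, {"X": .8, "Y": .8, "Z": .4}), labels)
        assert out.loc["Z", "label"] == "border"
        assert out.loc["X", "label"] == "subclone"
        assert out.loc["Y", "label"] == "subclone"

    def test_single_malignant_cluster_is_subclone(self):
        cs = cna.CnaCallSet(calls={
            "X": [call("X", *self.A, self.AMP, 0.4)]})
        labels = label_series({"X": 10})
        out = cna.classify_clusters(cs, self.weights(labels, {"X": .8}), labels)
        assert out.loc["X", "label"] == "subclone"

    def test_purer_twin_wins_tie_break(self):
        """Identical call sets: the higher-tumour-weight cluster is the
        subclone, its stroma-diluted twin the border."""
        cs = cna.CnaCallSet(calls={
            "X": [call("X", *self.A, self.AMP, 0.4)],
            "Z": [call("Z", *self.A, self.AMP, 0.38)],
        })
        labels = label_series({"X": 10, "Z": 10})
        out = cna.classify_clusters(
            cs, self.weights(labels, {"X": .8, "Z": .4}), labels)
        assert out.loc["X", "label"] == "subclone"
        assert out.loc["Z", "label"] == "border"

    def test_attenuated_echo_does_not_explain_original(self):
        cs = cna.CnaCallSet(calls={
            "X": [call("X", *self.A, self.AMP, 0.4)],
            "Z": [call("Z", *self.A, self.AMP, 0.22)],  # half-amplitude echo
        })
        labels = label_series({"X": 10, "Z": 10})
        out = cna.classify_clusters(
            cs, self.weights(labels, {"X": .8, "Z": .4}), labels)
        assert out.loc["X", "label"] == "subclone"
        assert out.loc["Z", "label"] == "border"

    def test_invariant_to_cluster_relabelling(self):
        def build(names):
            cs = cna.CnaCallSet(calls={
                names[0]: [call(names[0], *self.A, self.AMP, 0.4),
                           call(names[0], "chr3", 900, 1200, self.AMP, 0.4)],
                names[1]: [call(names[1], *self.A, self.AMP, 0.4)],
            })
            labels = label_series({names[0]: 8, names[1]: 8})
            w = self.weights(labels, {names[0]: .8, names[1]: .5})
            return cna.classify_clusters(cs, w, labels)

        out1 = build(["P", "Q"])
        out2 = build(["Q", "P"])
        assert out1.loc["P", "label"] == out2.loc["Q", "label"]
        assert out1.loc["Q", "label"] == out2.loc["P", "label"]

    def test_zero_subclones_warns(self):
        cs = cna.CnaCallSet(calls={"X": [], "Y": []})
        labels = label_series({"X": 5, "Y": 5})
        with pytest.warns(UserWarning, match="no subclone"):
            out = cna.classify_clusters(
                cs, self.weights(labels, {"X": .5, "Y": .5}), labels)
        assert (out["label"] == "border").all()
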
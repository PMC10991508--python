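"""Rank-sum DE, module scores, nearest-reference annotation, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonescape.containers import ReferenceProfiles
from clonescape.signatures import (
    SUBTYPE_LABELS,
    adjust_pvalues,
    annotate_by_reference,
    ligand_infiltrate_correlation,
    module_score,
    module_score_table,
    wilcoxon_de,
)
from clonescape.simulate import _nb_counts


def exact_ranksum_p(x, y):
    """Two-sided rank-sum P by full enumeration (oracle, no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = np.sum(np.argsort(np.argsort(pooled))[:n1] + 1)
    stats = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        ranks = np.argsort(np.argsort(pooled)) + 1
        stats.append(sum(ranks[list(comb)]))
    stats = np.array(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
    return p


class TestWilcoxonDE:
    def test_five_vs_five_extreme_separation(self):
        # all group-a values larger: two-sided P = 2 / C(10,5) = 2/252
        expr = np.zeros((10, 1))
        expr[:5, 0] = [6, 7, 8, 9, 10]
        expr[5:, 0] = [1, 2, 3, 4, 5]
        res = wilcoxon_de(expr, ["g"], np.arange(5), np.arange(5, 10))
        assert res["pval"].iloc[0] == pytest.approx(2 / 252)

    def test_constant_gene_p_one(self):
        expr = np.ones((10, 1))
        res = wilcoxon_de(expr, ["g"], np.arange(5), np.arange(5, 10))
        assert res["pval"].iloc[0] == 1.0

    def test_identical_distributions_nothing_significant(self, rng):
        expr = rng.normal(1, 0.3, (40, 50))
        res = wilcoxon_de(expr, [f"g{i}" for i in range(50)],
                          np.arange(20), np.arange(20, 40))
        assert res["significant"].sum() == 0

    def test_group_overlap_rejected(self, rng):
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(rng.normal(size=(10, 3)), list("abc"),
                        np.arange(5), np.arange(4, 9))

    def test_log2fc_sign_follows_mean_difference(self, rng):
        expr = np.abs(rng.normal(1, 0.2, (20, 5)))
        expr[:10, 0] += 2.0
        res = wilcoxon_de(expr, list("abcde"), np.arange(10),
                          np.arange(10, 20))
        assert res["log2fc"].iloc[0] > 0

    def test_matches_enumeration_small_groups(self, rng):
        for n1, n2 in [(4, 4), (5, 3), (6, 6)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            expr = np.concatenate([x, y])[:, None]
            res = wilcoxon_de(np.tile(expr, (1, 1)), ["g"],
                              np.arange(n1), np.arange(n1, n1 + n2))
            assert res["pval"].iloc[0] == pytest.approx(
                exact_ranksum_p(x, y), abs=1e-12)

    def test_bonferroni_option(self, rng):
        expr = rng.normal(size=(12, 8))
        res = wilcoxon_de(expr, [f"g{i}" for i in range(8)], np.arange(6),
                          np.arange(6, 12), adjust="bonferroni")
        np.testing.assert_allclose(res["padj"],
                                   np.minimum(res["pval"] * 8, 1.0))


class TestBH:
    def test_step_up_matches_hand_computation(self):
        """Textbook BH step-up on a 10-value example, hand-recomputed."""
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042,
                      0.06, 0.074, 0.205, 0.212, 0.216])
        # independent implementation: sort, p*(n/rank), cumulative min
        order = np.argsort(p)
        n = len(p)
        raw = p[order] * n / (np.arange(n) + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expect = np.empty(n)
        expect[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adjust_pvalues(p, "bh"), expect, atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(30)
        assert (adjust_pvalues(p, "bh") >= p - 1e-12).all()


class TestModuleScore:
    def make_null(self, rng, n_units=150, n_genes=800):
        expr = rng.normal(2.0, 0.5, (n_units, n_genes))
        genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
        return expr, genes

    def test_null_score_within_noise(self, rng):
        expr, genes = self.make_null(rng)
        gs = list(rng.choice(genes, 25, replace=False))
        means = []
        for seed in range(20):
            s = module_score(expr, genes, gs, seed=seed)
            means.append(s.mean())
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * max(se, 1e-3)

    def test_unit_constant_offset_cancels(self, rng):
        expr, genes = self.make_null(rng)
        gs = list(rng.choice(genes, 25, replace=False))
        s0 = module_score(expr, genes, gs, seed=5)
        shifted = expr + rng.normal(0, 1, (expr.shape[0], 1))
        s1 = module_score(shifted, genes, gs, seed=5)
        np.testing.assert_allclose(s0, s1, atol=1e-10)

    def test_subtype_table_columns(self, rng):
        expr, genes = self.make_null(rng, n_units=30)
        sets = {name: list(rng.choice(genes, 10, replace=False))
                for name in SUBTYPE_LABELS}
        table = module_score_table(expr, genes, sets, seed=1)
        assert list(table.columns) == list(SUBTYPE_LABELS)

    def test_absent_gene_set_is_error(self, rng):
        expr, genes = self.make_null(rng, n_units=10)
        with pytest.raises(ValueError, match="absent"):
            module_score(expr, genes, ["nope1", "nope2"], seed=0)


class TestAnnotateByReference:
    def make_reference(self, rng, n_types=4, n_genes=120):
        prof = rng.lognormal(0, 1, (n_types, n_genes))
        for t in range(n_types):
            markers = rng.choice(n_genes, 10, replace=False)
            prof[t, markers] *= 8
        prof /= prof.sum(axis=1, keepdims=True)
        return ReferenceProfiles(pd.DataFrame(
            prof, index=[f"t{i}" for i in range(n_types)],
            columns=[f"g{i}" for i in range(n_genes)]))

    def test_reference_rows_label_themselves(self, rng):
        ref = self.make_reference(rng)
        out = annotate_by_reference(ref.profiles.to_numpy(), ref.gene_ids, ref)
        assert list(out["label"]) == ref.cell_types

    def test_noisy_draws_recovered(self, rng):
        ref = self.make_reference(rng)
        R = ref.profiles.to_numpy()
        truth = rng.integers(0, 4, 1000)
        counts = _nb_counts(2000 * R[truth], 2.0, rng)
        out = annotate_by_reference(counts.astype(float), ref.gene_ids, ref)
        acc = np.mean([out["label"].iloc[i] == f"t{truth[i]}"
                       for i in range(1000)])
        assert acc >= 0.95

    def test_tie_between_identical_rows_reported(self, rng):
        prof = np.abs(rng.lognormal(0, 1, (1, 100)))
        dup = np.vstack([prof, prof])
        dup /= dup.sum(axis=1, keepdims=True)
        ref = ReferenceProfiles(pd.DataFrame(
            dup, index=["a", "b"], columns=[f"g{i}" for i in range(100)]))
        out = annotate_by_reference(dup, ref.gene_ids, ref)
        assert out["tied"].all()
        assert (out["label"] == "a").all()  # first type in reference order

    def test_constant_profile_unassigned(self, rng):
        ref = self.make_reference(rng)
        out = annotate_by_reference(np.ones((1, 120)), ref.gene_ids, ref)
        assert out["label"].iloc[0] == "unassigned"

    def test_too_few_shared_genes(self, rng):
        ref = self.make_reference(rng, n_genes=30)
        with pytest.raises(ValueError, match="shared"):
            annotate_by_reference(np.ones((1, 30)), ref.gene_ids, ref)


class TestLigandInfiltrateCorrelation:
    def test_monotone_transform_gives_rho_one(self, rng):
        n = 40
        w = pd.DataFrame({"T": np.sort(rng.random(n)),
                          "F": rng.random(n)},
                         index=[f"u{i}" for i in range(n)])
        expr = np.exp(w["T"].to_numpy())[:, None]  # monotone in weight
        out = ligand_infiltrate_correlation(expr, ["L"], w.index.to_numpy(),
                                            w, ["L"])
        rho = out[(out["ligand"] == "L") & (out["cell_type"] == "T")]["rho"]
        assert rho.iloc[0] == pytest.approx(1.0)

    def test_independent_vectors_calibrated(self, rng):
        hits, total = 0, 0
        for _ in range(300):
            x = rng.normal(size=(30, 1))
            w = pd.DataFrame({"T": rng.random(30)},
                             index=[f"u{i}" for i in range(30)])
            out = ligand_infiltrate_correlation(x, ["L"],
                                                w.index.to_numpy(), w, ["L"])
            hits += (out["pval"] <= 0.05).sum()
            total += len(out)
        assert 0.02 <= hits / total <= 0.08

    def test_constant_vector_flagged(self, rng):
        w = pd.DataFrame({"T": np.full(20, 0.5)},
                         index=[f"u{i}" for i in range(20)])
        out = ligand_infiltrate_correlation(rng.normal(size=(20, 1)), ["L"],
                                            w.index.to_numpy(), w, ["L"])
        assert out["undefined"].iloc[0]

    def test_planted_coupling_top_ranked(self, rng):
        n = 60
        driver = rng.random(n)
        w = pd.DataFrame({"T": driver + rng.normal(0, 0.05, n),
                          "F": rng.random(n), "M": rng.random(n)},
                         index=[f"u{i}" for i in range(n)])
        expr = np.column_stack([driver + rng.normal(0, 0.05, n),
                                rng.random(n), rng.random(n)])
        out = ligand_infiltrate_correlation(expr, ["L0", "L1", "L2"],
                                            w.index.to_numpy(), w,
                                            ["L0", "L1", "L2"])
        top = out.sort_values("rho", ascending=False).iloc[0]
        assert (top["ligand"], top["cell_type"]) == ("L0", "T")

    def test_too_few_units_rejected(self, rng):
        w = pd.DataFrame({"T": rng.random(5)},
                         index=[f"u{i}" for i in range(5)])
        with pytest.raises(ValueError, match="shared units"):
            ligand_infiltrate_correlation(rng.normal(size=(5, 1)), ["L"],
                                          w.index.to_numpy(), w, ["L"])
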
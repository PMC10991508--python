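"""Differential expression, module scores, reference annotation and
ligand-infiltrate correlations.

Differential expression is the two-sided Wilcoxon rank-sum test on
log-normalised values with BH or Bonferroni adjustment; the fold change
is the difference of log2(mean normalised expression + 1e-9) between
groups. Module scores follow the binned-control construction: the score
of a gene set is its mean expression minus the mean of control genes
drawn from matching average-expression bins, so a uniform shift of the
gene set is recovered and cell-level offsets cancel. Nearest-reference
annotation labels each unit with the reference type of maximal Spearman
correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "adjust_pvalues",
    "wilcoxon_de",
    "module_score",
    "module_score_table",
    "annotate_by_reference",
    "ligand_infiltrate_correlation",
]

SUBTYPE_LABELS = ("C1.MES", "C2.IMM", "C4.DIF", "C5.PRO")


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """BH step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    raise ValueError(f"unknown adjustment {method!r}")


def wilcoxon_de(expr, gene_ids, group_a, group_b, adjust: str = "bh",
                fdr: float = 0.05, min_log2fc: float = 1.0) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two unit groups.

    ``expr`` is units x genes log-normalised (natural log1p); ``group_a``
    and ``group_b`` are disjoint row index arrays. The per-gene log2 fold
    change is ``log2(mean_a + eps) - log2(mean_b + eps)`` on the
    de-logged normalised means (eps = 1e-9). ``significant`` flags
    adjusted P < ``fdr`` AND |log2FC| > ``min_log2fc`` (both strict).
    """
    expr = np.asarray(expr, dtype=float)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need >= 3 units")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    xa, xb = expr[group_a], expr[group_b]
    res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided",
                             method="auto")
    pvals = np.atleast_1d(res.pvalue)
    stat = np.atleast_1d(res.statistic)
    eps = 1e-9
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    log2fc = np.log2(mean_a + eps) - np.log2(mean_b + eps)
    padj = adjust_pvalues(pvals, adjust)
    out = pd.DataFrame({
        "gene": np.asarray(gene_ids, dtype=object),
        "log2fc": log2fc,
        "statistic": stat,
        "pval": pvals,
        "padj": padj,
        "frac_a": (xa > 0).mean(axis=0),
        "frac_b": (xb > 0).mean(axis=0),
    })
    out["significant"] = (out["padj"] < fdr) & (out["log2fc"].abs() > min_log2fc)
    return out


def module_score(expr, gene_ids, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Binned-control module score per unit.

    Genes are ranked by dataset-wide average expression and split into
    ``n_bins`` equal-size bins; each gene-set gene contributes up to
    ``n_ctrl`` control genes sampled (without replacement, gene set
    excluded) from its bin. Score = mean expression over the gene set
    minus the mean over the pooled control draw.
    """
    expr = np.asarray(expr, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in gene_set if g in pos]
    if not present:
        missing = sorted(gene_set)
        raise ValueError(f"gene set fully absent from data: {missing}")
    rng = np.random.default_rng(seed)
    gs_idx = np.array([pos[g] for g in present])
    avg = expr.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )
    gs_mask = np.zeros(len(avg), dtype=bool)
    gs_mask[gs_idx] = True
    ctrl_idx = []
    for gi in gs_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]) & ~gs_mask)
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    if not ctrl_idx:
        raise ValueError("no control genes available outside the gene set")
    ctrl_idx = np.concatenate(ctrl_idx)
    return expr[:, gs_idx].mean(axis=1) - expr[:, ctrl_idx].mean(axis=1)


def module_score_table(expr, gene_ids, gene_sets: dict, n_bins: int = 24,
                       n_ctrl: int = 100, seed: int = 0) -> pd.DataFrame:
    """Scores for several gene sets, one column per set (e.g. the four
    molecular-subtype signatures C1.MES, C2.IMM, C4.DIF, C5.PRO)."""
    cols = {
        name: module_score(expr, gene_ids, genes, n_bins=n_bins,
                           n_ctrl=n_ctrl, seed=seed)
        for name, genes in gene_sets.items()
    }
    return pd.DataFrame(cols)


def annotate_by_reference(expr, gene_ids, reference, min_shared: int = 50
                          ) -> pd.DataFrame:
    """Nearest-reference annotation by Spearman correlation.

    Each unit gets the reference cell type maximising the Spearman
    correlation between its profile and the reference profile over the
    shared genes. Constant unit profiles are 'unassigned'; exact ties are
    broken toward the first type in reference order and flagged.

    Returns a DataFrame with columns ``label, best_corr, tied``.
    """
    expr = np.asarray(expr, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    ref = reference.profiles
    shared = [g for g in gene_ids if g in set(ref.columns)]
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes (need >= {min_shared})")
    pos = {g: i for i, g in enumerate(gene_ids)}
    cols = np.array([pos[g] for g in shared])
    X = expr[:, cols]
    R = ref[shared].to_numpy()

    def rank_rows(M):
        return np.apply_along_axis(stats.rankdata, 1, M)

    Xr = rank_rows(X)
    Rr = rank_rows(R)
    Xc = Xr - Xr.mean(axis=1, keepdims=True)
    Rc = Rr - Rr.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    rn = np.linalg.norm(Rc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Rc.T) / np.outer(xn, rn)
    types = list(ref.index)
    labels, best, tied = [], [], []
    for i in range(corr.shape[0]):
        row = corr[i]
        if not np.isfinite(row).any():
            labels.append("unassigned")
            best.append(np.nan)
            tied.append(False)
            continue
        top = np.nanmax(row)
        winners = np.flatnonzero(np.isclose(row, top, rtol=0, atol=1e-12))
        labels.append(types[winners[0]])
        best.append(float(top))
        tied.append(len(winners) > 1)
    return pd.DataFrame({"label": labels, "best_corr": best, "tied": tied})


def ligand_infiltrate_correlation(expr, gene_ids, unit_ids,
                                  weights: pd.DataFrame, ligand_genes
                                  ) -> pd.DataFrame:
    """Spearman correlation of ligand expression with cell-type weights.

    Computed across the units shared between the expression matrix and
    the weight table (at least 10 required); BH adjustment over all
    (ligand, cell type) pairs. Constant vectors yield NaN rho, flagged
    ``undefined``.
    """
    expr = np.asarray(expr, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    unit_ids = np.asarray(unit_ids, dtype=object)
    shared_units = [u for u in unit_ids if u in set(weights.index)]
    if len(shared_units) < 10:
        raise ValueError(f"only {len(shared_units)} shared units (need >= 10)")
    upos = {u: i for i, u in enumerate(unit_ids)}
    rows_idx = np.array([upos[u] for u in shared_units])
    W = weights.loc[shared_units]
    gpos = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    for ligand in ligand_genes:
        if ligand not in gpos:
            continue
        x = expr[rows_idx, gpos[ligand]]
        for ct in W.columns:
            y = W[ct].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append({"ligand": ligand, "cell_type": ct,
                             "rho": np.nan, "pval": np.nan, "undefined": True})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"ligand": ligand, "cell_type": ct,
                         "rho": rho, "pval": p, "undefined": False})
    out = pd.DataFrame(rows)
    if len(out):
        ok = ~out["undefined"]
        out["padj"] = np.nan
        if ok.any():
            out.loc[ok, "padj"] = adjust_pvalues(out.loc[ok, "pval"].to_numpy(), "bh")
    return out
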
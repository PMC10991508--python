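"""Radius neighbour graphs and spatial permutation tests.

Two cells are neighbours when their centroid Euclidean distance is
strictly below the radius (the default radii of 110, 340 and 648 pixels
probe touching cells, the local niche and the wider surrounds).

Two Monte-Carlo tests are provided, both with the add-one empirical
P-value convention (P is never zero) and Benjamini-Hochberg correction
per radius:

* :func:`enrichment_depletion_test` — are cells of type t over- or
  under-represented among the neighbours of the focal (tumour) cells?
  Focal positions stay fixed; the positions of each other cell type are
  re-drawn uniformly from the occupied non-focal positions, which keeps
  the null inside the tissue geometry.
* :func:`clone_comparison_test` — does type t neighbour clone A more
  than clone B? The labels of the pooled heterotypic neighbouring cells
  are permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NeighbourGraph",
    "build_graph",
    "neighbour_proportions",
    "enrichment_depletion_test",
    "clone_comparison_test",
]

DEFAULT_RADII = (110.0, 340.0, 648.0)


@dataclass
class NeighbourGraph:
    """Symmetric radius graph on cell centroids (no self edges)."""

    radius: float
    n_cells: int
    pairs: np.ndarray  # (m, 2) int array, i < j, distance strictly < radius

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(deg, self.pairs[:, 0], 1)
        np.add.at(deg, self.pairs[:, 1], 1)
        return deg

    def adjacency_sets(self):
        adj = [set() for _ in range(self.n_cells)]
        for i, j in self.pairs:
            adj[i].add(int(j))
            adj[j].add(int(i))
        return adj


def build_graph(centroids, radius: float, fov_id=None,
                within_fov_only: bool = False) -> NeighbourGraph:
    """All cell pairs at Euclidean distance strictly below ``radius``.

    With ``within_fov_only`` edges are restricted to cells in the same
    field of view.
    """
    centroids = np.asarray(centroids, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not np.isfinite(centroids).all():
        raise ValueError("non-finite coordinates")
    n = len(centroids)
    if n == 0:
        return NeighbourGraph(radius, 0, np.empty((0, 2), dtype=int))
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]  # query_pairs includes distance == radius
    if within_fov_only:
        if fov_id is None:
            raise ValueError("within_fov_only requires fov_id")
        fov_id = np.asarray(fov_id)
        pairs = pairs[fov_id[pairs[:, 0]] == fov_id[pairs[:, 1]]]
    return NeighbourGraph(radius, n, pairs.astype(int))


def _neighbour_counts(graph: NeighbourGraph, codes: np.ndarray, n_types: int):
    """counts[f, t] = number of neighbours of type t over cells of type f."""
    counts = np.zeros((n_types, n_types), dtype=np.int64)
    if len(graph.pairs):
        a = codes[graph.pairs[:, 0]]
        b = codes[graph.pairs[:, 1]]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    return counts


def neighbour_proportions(graph: NeighbourGraph, labels,
                          drop_homotypic_for=None) -> pd.DataFrame:
    """Row-normalised neighbour-type composition per focal type.

    Entry (f, t) is the fraction of all neighbours of cells of type f
    that are of type t; each row sums to 1. With ``drop_homotypic_for``
    set, edges between two cells of that type are removed before
    normalisation (exposing heterotypic associations). Focal types left
    with zero neighbours get a NaN row.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels must cover all cells")
    types = list(pd.unique(labels))
    code = {t: i for i, t in enumerate(types)}
    codes = np.array([code[l] for l in labels])
    counts = _neighbour_counts(graph, codes, len(types))
    if drop_homotypic_for is not None:
        if drop_homotypic_for not in code:
            raise ValueError(f"unknown type {drop_homotypic_for!r}")
        counts[code[drop_homotypic_for], code[drop_homotypic_for]] = 0
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(props, index=types, columns=types)


def _bh(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _empirical_p(null_ge: int, null_le: int, n_perm: int):
    """Add-one one-sided empirical P values."""
    return (1 + null_ge) / (n_perm + 1), (1 + null_le) / (n_perm + 1)


def enrichment_depletion_test(centroids, labels, focal_types,
                              radii=DEFAULT_RADII, n_perm: int = 1000,
                              alpha: float = 0.05, seed: int = 0,
                              fov_id=None, within_fov_only: bool = False
                              ) -> pd.DataFrame:
    """Neighbourhood enrichment/depletion around fixed focal cells.

    For each non-focal type t and each radius, the statistic is the
    proportion of t among all neighbours of focal cells. The null fixes
    the focal positions and re-draws the n_t positions of type t
    uniformly (without replacement) from all occupied non-focal
    positions, independently per type. Both one-sided add-one P values
    are reported with BH correction across types per radius.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=object)
    centroids = np.asarray(centroids, dtype=float)
    focal_types = set(focal_types)
    if not focal_types & set(labels):
        raise ValueError("no focal cells present")
    rng = np.random.default_rng(seed)
    focal_mask = np.isin(labels, list(focal_types))
    nonfocal_idx = np.flatnonzero(~focal_mask)
    other_types = [t for t in pd.unique(labels[~focal_mask])]

    rows = []
    for radius in radii:
        graph = build_graph(centroids, radius, fov_id=fov_id,
                            within_fov_only=within_fov_only)
        # w[k] = number of focal cells adjacent to non-focal cell k
        w_all = np.zeros(len(labels), dtype=np.int64)
        focal_pair = focal_mask[graph.pairs]
        total = 0
        if len(graph.pairs):
            a, b = graph.pairs[:, 0], graph.pairs[:, 1]
            np.add.at(w_all, b[focal_pair[:, 0]], 1)
            np.add.at(w_all, a[focal_pair[:, 1]], 1)
            # total neighbours of focal cells = sum of focal degrees:
            # one per focal endpoint of each edge
            total = int(focal_pair.sum())
        if total == 0:
            warnings.warn(f"focal cells have no neighbours at radius {radius}")
            continue
        w = w_all[nonfocal_idx]
        nf_labels = labels[nonfocal_idx]
        for t in other_types:
            n_t = int((nf_labels == t).sum())
            obs = int(w[nf_labels == t].sum())
            null = np.empty(n_perm, dtype=np.int64)
            for b_ in range(n_perm):
                pick = rng.choice(len(w), size=n_t, replace=False)
                null[b_] = w[pick].sum()
            p_enr, p_dep = _empirical_p(int((null >= obs).sum()),
                                        int((null <= obs).sum()), n_perm)
            rows.append({
                "radius": radius, "neighbour": t, "n_cells": n_t,
                "proportion": obs / total,
                "null_mean": null.mean() / total,
                "p_enriched": p_enr, "p_depleted": p_dep,
            })
    out = pd.DataFrame(rows)
    if len(out):
        for col in ("p_enriched", "p_depleted"):
            q = np.empty(len(out))
            for radius in out["radius"].unique():
                m = out["radius"] == radius
                q[m.to_numpy()] = _bh(out.loc[m, col].to_numpy())
            out["q" + col[1:]] = q
        out["direction"] = np.where(out["p_enriched"] <= out["p_depleted"],
                                    "enriched", "depleted")
        out["significant"] = np.minimum(out["q_enriched"], out["q_depleted"]) <= alpha
    return out


def clone_comparison_test(centroids, labels, clone_a, clone_b,
                          radii=DEFAULT_RADII, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          fov_id=None, within_fov_only: bool = False
                          ) -> pd.DataFrame:
    """Compare the heterotypic neighbourhoods of two tumour clones.

    Statistic per non-tumour type t and radius: proportion of t among
    the heterotypic (non-tumour) neighbours of ``clone_a`` minus the
    same for ``clone_b``. The null permutes the labels of the pooled
    neighbouring non-tumour cells; tumour positions stay fixed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=object)
    centroids = np.asarray(centroids, dtype=float)
    for c in (clone_a, clone_b):
        if c not in labels:
            raise ValueError(f"clone label {c!r} not present")
    rng = np.random.default_rng(seed)
    tumour = np.isin(labels, [clone_a, clone_b])
    types = [t for t in pd.unique(labels[~tumour])]
    code = {t: i for i, t in enumerate(types)}

    rows = []
    for radius in radii:
        graph = build_graph(centroids, radius, fov_id=fov_id,
                            within_fov_only=within_fov_only)
        wa = np.zeros(len(labels), dtype=np.int64)
        wb = np.zeros(len(labels), dtype=np.int64)
        if len(graph.pairs):
            a_, b_ = graph.pairs[:, 0], graph.pairs[:, 1]
            for w, clone in ((wa, clone_a), (wb, clone_b)):
                cl = labels == clone
                het = ~tumour
                sel = cl[a_] & het[b_]
                np.add.at(w, b_[sel], 1)
                sel = cl[b_] & het[a_]
                np.add.at(w, a_[sel], 1)
        involved = np.flatnonzero((wa + wb) > 0)
        Wa, Wb = int(wa.sum()), int(wb.sum())
        if Wa == 0 or Wb == 0:
            warnings.warn(
                f"a clone has no heterotypic neighbours at radius {radius}; skipped"
            )
            continue
        wa_s, wb_s = wa[involved].astype(float), wb[involved].astype(float)
        codes_s = np.array([code[l] for l in labels[involved]])
        one_hot = np.zeros((len(involved), len(types)))
        one_hot[np.arange(len(involved)), codes_s] = 1.0
        obs = wa_s @ one_hot / Wa - wb_s @ one_hot / Wb
        null = np.empty((n_perm, len(types)))
        for it in range(n_perm):
            perm = rng.permutation(len(involved))
            oh = one_hot[perm]
            null[it] = wa_s @ oh / Wa - wb_s @ oh / Wb
        eps = 1e-12
        for ti, t in enumerate(types):
            p_a, p_b = _empirical_p(
                int((null[:, ti] >= obs[ti] - eps).sum()),
                int((null[:, ti] <= obs[ti] + eps).sum()), n_perm)
            rows.append({
                "radius": radius, "neighbour": t,
                "difference": obs[ti],
                "p_higher_a": p_a, "p_higher_b": p_b,
            })
    out = pd.DataFrame(rows)
    if len(out):
        for col in ("p_higher_a", "p_higher_b"):
            q = np.empty(len(out))
            for radius in out["radius"].unique():
                m = out["radius"] == radius
                q[m.to_numpy()] = _bh(out.loc[m, col].to_numpy())
            out["q" + col[1:]] = q
        out["direction"] = np.where(out["p_higher_a"] <= out["p_higher_b"],
                                    clone_a, clone_b)
        out["significant"] = np.minimum(out["q_higher_a"], out["q_higher_b"]) <= alpha
    return out
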
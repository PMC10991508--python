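"""Reference-based spot decomposition and background selection.

Per-spot cell-type weights are estimated by non-negative least squares
on library-size-normalised profiles, projected onto the probability
simplex by renormalisation. This is a deliberately simple surrogate for
full probabilistic deconvolution: the pipeline only consumes the
tumour-weight ordering and the 0.15 background cut, both of which the
least-squares weights preserve.

Spots whose tumour weight falls strictly below 0.15 form the "normal"
background whose mean expression anchors CNA inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .containers import ReferenceProfiles

__all__ = ["build_reference", "decompose_units", "select_background"]


def build_reference(sc_counts, gene_ids, labels) -> ReferenceProfiles:
    """Mean library-size-normalised profile per cell type.

    Row ``t`` is the mean over cells of type ``t`` of ``count / cell_total``.
    Every label must have at least one cell.
    """
    counts = sp.csr_matrix(sc_counts).astype(float)
    labels = np.asarray(labels, dtype=object)
    if counts.shape[0] != len(labels):
        raise ValueError("labels length does not match cell count")
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("cells with zero total counts; filter first")
    norm = counts.multiply((1.0 / totals)[:, None]).tocsr()
    rows = {}
    for t in pd.unique(labels):
        mask = labels == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        rows[t] = np.asarray(norm[mask].mean(axis=0)).ravel()
    profiles = pd.DataFrame(rows, index=np.asarray(gene_ids, dtype=object)).T
    return ReferenceProfiles(profiles)


def _shared_genes(unit_genes, reference: ReferenceProfiles,
                  min_shared: int = 50, rare_type_frac: float = 0.01):
    """Genes present in both matrices, excluding genes expressed in fewer
    than ``rare_type_frac`` of reference types."""
    ref = reference.profiles
    n_types = ref.shape[0]
    expressed = (ref.to_numpy() > 0).sum(axis=0) / n_types
    ref_genes = set(ref.columns[expressed >= rare_type_frac])
    shared = [g for g in unit_genes if g in ref_genes]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with reference (need >= {min_shared})"
        )
    return shared


def decompose_units(counts, gene_ids, reference: ReferenceProfiles,
                    unit_ids=None, min_shared: int = 50) -> pd.DataFrame:
    """Estimate per-unit cell-type weights on the probability simplex.

    Each unit profile (normalised to sum 1 over the shared genes) is fit
    by non-negative least squares against the reference rows and the
    weights renormalised to sum 1. All-zero units get a NaN row and are
    excluded downstream.

    Returns a units x types DataFrame (the weight table).
    """
    counts = sp.csr_matrix(counts).astype(float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    if unit_ids is None:
        unit_ids = np.array([f"unit_{i}" for i in range(counts.shape[0])],
                            dtype=object)
    shared = _shared_genes(gene_ids, reference, min_shared=min_shared)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    cols = np.array([gidx[g] for g in shared])
    sub = counts[:, cols].toarray()
    ref = reference.profiles[shared].to_numpy()  # types x shared
    ref = ref / ref.sum(axis=1, keepdims=True)
    A = ref.T  # genes x types

    weights = np.full((counts.shape[0], ref.shape[0]), np.nan)
    totals = sub.sum(axis=1)
    for i in range(sub.shape[0]):
        if totals[i] == 0:
            continue  # undefined, flagged as NaN
        b = sub[i] / totals[i]
        w, _ = scipy.optimize.nnls(A, b)
        s = w.sum()
        weights[i] = w / s if s > 0 else np.nan
    return pd.DataFrame(weights, index=unit_ids, columns=reference.cell_types)


def select_background(weights: pd.DataFrame, tumour_type: str,
                      threshold: float = 0.15):
    """Units whose tumour weight is strictly below ``threshold``.

    These low-tumour units serve as the normal reference for CNA
    inference; an empty selection is a hard error because the inference
    cannot proceed without a background.
    """
    if tumour_type not in weights.columns:
        raise ValueError(f"{tumour_type!r} not among weight columns")
    w = weights[tumour_type]
    selected = set(weights.index[(w < threshold) & w.notna()])
    if not selected:
        raise ValueError(
            "no background units below the tumour-weight threshold "
            f"{threshold}; raise the threshold or check the reference"
        )
    return selected
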
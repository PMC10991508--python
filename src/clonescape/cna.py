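"""Expression-based CNA inference and subclone/border classification.

The procedure follows the classic smoothed relative-expression approach:

1. genes below a mean-count cutoff (default 0.1) are dropped and each
   unit's log2-normalised expression is expressed as a residual against
   the mean of the low-tumour background units, clipped at +/-3
   background standard deviations (denoising);
2. residuals are averaged over a 101-gene sliding window along each
   chromosome (windows never cross chromosome boundaries) and re-centred
   per unit by its median;
3. units are clustered hierarchically (Ward, Euclidean) on the smoothed
   profiles; clusters separated by fewer than 10 differentially
   expressed genes are merged;
4. per cluster, a 3-state Gaussian HMM (deletion / neutral /
   amplification) segments the cluster-mean profile per chromosome;
   segments whose mean state posterior falls below 0.5 are demoted to
   neutral, leaving only high-confidence calls;
5. a cluster is a *subclone* iff it carries at least one high-confidence
   segment seen in no other cluster (50% of its genes covered by a
   matching-state call of comparable amplitude); a cluster whose calls
   are all shared with others is a *border* region — a tumour/stroma
   mixture, not a distinct genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from hmmlearn.hmm import GaussianHMM
from scipy.spatial.distance import squareform
from sklearn.metrics import pairwise_distances, silhouette_score

from .annotation import GeneAnnotation

__all__ = [
    "CnaProfile",
    "CnaCall",
    "CnaCallSet",
    "relative_expression",
    "smooth_windows",
    "cluster_profiles",
    "merge_clusters",
    "refine_assignments",
    "merge_collinear_clusters",
    "merge_equivalent_callsets",
    "call_cna_segments",
    "classify_clusters",
]

DELETION, NEUTRAL, AMPLIFICATION = "deletion", "neutral", "amplification"
_STATE_NAMES = {0: DELETION, 1: NEUTRAL, 2: AMPLIFICATION}


# ---------------------------------------------------------------------------
# residuals & smoothing
# ---------------------------------------------------------------------------

def relative_expression(counts, unit_ids, gene_ids, background_ids,
                        cutoff: float = 0.1, scale: float = 1e4,
                        clip_sd: float = 3.0) -> pd.DataFrame:
    """Log2 residual expression relative to the background mean.

    Genes with mean raw count across all units below ``cutoff`` are
    removed. Each unit's log2(1 + scale*c/total) profile has the
    background-unit mean subtracted per gene; residuals are clipped at
    ``clip_sd`` standard deviations of the background residuals (one
    global scale), a light denoising step.
    """
    counts = sp.csr_matrix(counts).astype(float)
    unit_ids = np.asarray(unit_ids, dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    background_ids = set(background_ids)
    if not background_ids:
        raise ValueError("background set is empty")
    bg_mask = np.array([u in background_ids for u in unit_ids])
    if not bg_mask.any():
        raise ValueError("background ids not found among unit ids")

    mean_raw = np.asarray(counts.mean(axis=0)).ravel()
    keep = mean_raw >= cutoff
    counts = counts[:, keep]
    gene_ids = gene_ids[keep]

    totals = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.where(totals > 0, scale / np.maximum(totals, 1), 0.0)
    expr = np.log2(1.0 + counts.multiply(inv[:, None]).toarray())
    bg_mean = expr[bg_mask].mean(axis=0)
    resid = expr - bg_mean
    sigma = resid[bg_mask].std()
    if sigma > 0 and np.isfinite(sigma):
        lim = clip_sd * sigma
        np.clip(resid, -lim, lim, out=resid)
    return pd.DataFrame(resid, index=unit_ids, columns=gene_ids)


@dataclass
class CnaProfile:
    """Smoothed relative-expression profile (units x ordered genes)."""

    values: pd.DataFrame
    chromosomes: np.ndarray  # per column
    order_index: np.ndarray  # genome-wide gene rank per column
    window: int

    def chromosome_blocks(self):
        """Yield (chromosome, column slice) of contiguous blocks."""
        chroms = self.chromosomes
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            yield chroms[i], slice(i, j)
            i = j


def _moving_average(X: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average over min(window, n_cols) genes; truncated at
    block edges."""
    m = X.shape[1]
    eff = min(window, m)
    hl, hr = (eff - 1) // 2, eff // 2
    P = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    i = np.arange(m)
    lo = np.maximum(0, i - hl)
    hi = np.minimum(m, i + hr + 1)
    return (P[:, hi] - P[:, lo]) / (hi - lo)


def smooth_windows(residuals: pd.DataFrame, annotation: GeneAnnotation,
                   window: int = 101) -> CnaProfile:
    """Sliding-window smoothing along the genome.

    Each value is the centred mean over min(window, genes on that
    chromosome) genes; windows never cross chromosome boundaries, and at
    block edges the window is truncated. Units are re-centred by
    subtracting their median smoothed value, which guards against
    library-depth artefacts.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    pos = {g: i for i, g in enumerate(annotation.gene_ids)}
    missing = [g for g in residuals.columns if g not in pos]
    if missing:
        raise ValueError(f"{len(missing)} genes absent from annotation")
    order_index = np.array([pos[g] for g in residuals.columns])
    order = np.argsort(order_index)
    resid = residuals.iloc[:, order]
    order_index = order_index[order]
    chroms = annotation.chromosome[order_index]

    present = set(chroms)
    for c in annotation.chrom_order:
        if c not in present:
            warnings.warn(f"chromosome {c} has no retained genes; skipped")

    X = resid.to_numpy()
    out = np.empty_like(X)
    i = 0
    while i < len(chroms):
        j = i
        while j < len(chroms) and chroms[j] == chroms[i]:
            j += 1
        out[:, i:j] = _moving_average(X[:, i:j], window)
        i = j
    out -= np.median(out, axis=1, keepdims=True)
    values = pd.DataFrame(out, index=resid.index, columns=resid.columns)
    return CnaProfile(values=values, chromosomes=np.asarray(chroms),
                      order_index=order_index, window=window)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _pca_scores(X: np.ndarray, n_pcs) -> np.ndarray:
    """Project profiles onto their leading principal components.

    Genotype structure lives in a handful of directions while the
    per-spot window noise is spread over every gene, so truncating to
    ``n_pcs`` components denoises the Euclidean geometry the clustering
    sees. ``n_pcs=None`` keeps the full profiles.
    """
    if n_pcs is None or min(X.shape) <= n_pcs:
        return X
    Xc = X - X.mean(axis=0)
    # deterministic truncated SVD via the small Gram matrix side
    from scipy.sparse.linalg import svds

    U, S, _ = svds(Xc, k=n_pcs, random_state=0)
    order = np.argsort(S)[::-1]
    return U[:, order] * S[order]


def cluster_profiles(profile: CnaProfile, n_clusters="auto",
                     k_range=(2, 8), n_pcs: int = 10,
                     extra_features=None) -> pd.Series:
    """Ward hierarchical clustering of smoothed profiles.

    Profiles are first projected onto their ``n_pcs`` leading principal
    components (Euclidean distances on the denoised representation);
    ``extra_features`` columns (already on a comparable scale, e.g. a
    scaled tumour weight) are appended to that representation. With
    ``n_clusters="auto"`` the dendrogram cut maximising the mean
    silhouette over ``k_range`` replaces a manual choice; ties go to the
    smaller k. An explicit integer k is honoured as-is.
    """
    X = profile.values.to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units to cluster")
    if isinstance(n_clusters, (int, np.integer)):
        if n_clusters > n:
            raise ValueError(f"requested {n_clusters} clusters for {n} units")
        if n_clusters == 1:
            return pd.Series(np.zeros(n, dtype=int), index=profile.values.index)
    X = _pca_scores(X, n_pcs)
    if extra_features is not None:
        X = np.column_stack([X, np.asarray(extra_features, dtype=float)])
    D = pairwise_distances(X, metric="euclidean")
    Z = sch.linkage(squareform(D, checks=False), method="ward")
    if n_clusters == "auto":
        if float(D.max()) == 0.0:  # all profiles identical
            return pd.Series(np.zeros(n, dtype=int), index=profile.values.index)
        best_k, best_sil, best_labels = None, -np.inf, None
        for k in range(k_range[0], min(k_range[1], n - 1) + 1):
            labels = sch.fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(D, labels, metric="precomputed")
            if sil > best_sil + 1e-12:
                best_k, best_sil, best_labels = k, sil, labels
        if best_labels is None:
            best_labels = np.ones(n, dtype=int)
        labels = best_labels
    else:
        labels = sch.fcluster(Z, t=int(n_clusters), criterion="maxclust")
    # stable relabelling by order of first appearance
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: r for r, i in enumerate(np.sort(first))}
    return pd.Series([remap[l] for l in labels], index=profile.values.index)


def merge_clusters(labels: pd.Series, counts, gene_ids, min_de_genes: int = 10,
                   fdr: float = 0.05, min_log2fc: float = 0.25,
                   adjust: str = "bh", profile: "CnaProfile" = None,
                   profile_delta: float = 0.1,
                   min_distinct_genes: int = 200,
                   unit_weights: pd.Series = None,
                   max_weight_gap: float = 0.15) -> pd.Series:
    """Merge cluster pairs separated by fewer than ``min_de_genes``
    differentially expressed genes (Wilcoxon, BH FDR < ``fdr``,
    |log2FC| > ``min_log2fc``).

    With a ``profile`` given, a pair is additionally required to be
    indistinct in CNA-profile space before it may merge: fewer than
    ``min_distinct_genes`` genes whose cluster-mean smoothed residuals
    differ by more than ``profile_delta`` (log2). This is the
    counterpart of keeping only visually distinctive CNA profiles as
    separate clusters — a genuine CNA difference spans a segment-scale
    stretch of smoothed genes (hundreds, given segment lengths plus the
    window ramp), whereas splits along correlated window noise produce
    only scattered short excursions, so segment-scale defaults keep
    clusters separate exactly when a consistent CNA difference exists,
    even when shallow counts leave the per-gene rank test underpowered.

    With ``unit_weights`` given (per-unit tumour weights), clusters
    whose mean weights differ by ``max_weight_gap`` or more never merge:
    they sample compositionally different tissue (a clone and its
    stroma-diluted border) even when a weak genotype compresses the
    profile contrast.

    The eligible pair with the fewest DE genes is merged first and the
    statistics for pairs involving the merged cluster recomputed; a pair
    with exactly ``min_de_genes`` DE genes is kept separate.
    """
    from .signatures import wilcoxon_de  # deferred: avoids import cycle

    from .io import normalize_lognorm

    expr = normalize_lognorm(counts)
    labels = labels.copy()
    prof_values = None
    if profile is not None:
        prof_values = profile.values.reindex(labels.index)
        if prof_values.isna().any(axis=None):
            raise ValueError("profile does not cover all labelled units")
        prof_values = prof_values.to_numpy()
    w = None
    if unit_weights is not None:
        w = unit_weights.reindex(labels.index).to_numpy()

    def pair_stats(ca, cb):
        la = labels.to_numpy()
        ia, ib = np.flatnonzero(la == ca), np.flatnonzero(la == cb)
        if w is not None:
            gap = abs(np.nanmean(w[ia]) - np.nanmean(w[ib]))
            if gap >= max_weight_gap:
                return min_de_genes, min_distinct_genes  # never mergeable
        n_distinct = 0
        if prof_values is not None:
            diff = prof_values[ia].mean(axis=0) - prof_values[ib].mean(axis=0)
            n_distinct = int((np.abs(diff) > profile_delta).sum())
            if n_distinct >= min_distinct_genes:
                # profile-distinct pairs never merge; skip the DE test
                return min_de_genes, n_distinct
        res = wilcoxon_de(expr, gene_ids, ia, ib, adjust=adjust, fdr=fdr,
                          min_log2fc=min_log2fc)
        return int(res["significant"].sum()), n_distinct

    def mergeable(stats):
        n_de, n_distinct = stats
        return n_de < min_de_genes and (
            prof_values is None or n_distinct < min_distinct_genes)

    clusters = sorted(pd.unique(labels))
    cache = {}
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1:]:
            cache[(ca, cb)] = pair_stats(ca, cb)
    while len(clusters) >= 2:
        eligible = {pair: v for pair, v in cache.items() if mergeable(v)}
        if not eligible:
            break
        (ca, cb), _ = min(eligible.items(), key=lambda kv: kv[1])
        labels[labels == cb] = ca
        clusters.remove(cb)
        cache = {pair: v for pair, v in cache.items()
                 if ca not in pair and cb not in pair}
        for other in clusters:
            if other != ca:
                cache[tuple(sorted((ca, other), key=str))] = pair_stats(ca, other)
    # renumber 0..k-1 preserving order of first appearance
    remap = {}
    out = []
    for l in labels:
        if l not in remap:
            remap[l] = len(remap)
        out.append(remap[l])
    return pd.Series(out, index=labels.index)


def refine_assignments(profile: CnaProfile, labels: pd.Series,
                       n_pcs: int = 10, n_iter: int = 3,
                       extra_features=None) -> pd.Series:
    """Nearest-centroid reassignment of units to cluster mean profiles.

    A few k-means-style iterations in the denoised (PCA) profile space
    (plus any ``extra_features`` columns) clean up boundary units that
    hierarchical clustering attached to the wrong branch; cluster count
    never changes (emptied clusters keep their last members' assignment
    removed).
    """
    X = _pca_scores(profile.values.to_numpy(), n_pcs)
    if extra_features is not None:
        X = np.column_stack([X, np.asarray(extra_features, dtype=float)])
    labels = labels.reindex(profile.values.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all profile units")
    la = labels.to_numpy().copy()
    for _ in range(n_iter):
        clusters = [c for c in pd.unique(la)]
        means = np.vstack([X[la == c].mean(axis=0) for c in clusters])
        d = pairwise_distances(X, means)
        new = np.array(clusters, dtype=object)[d.argmin(axis=1)]
        if (new == la).all():
            break
        la = new
    return pd.Series(la, index=labels.index)


# ---------------------------------------------------------------------------
# HMM segment calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnaCall:
    """A high-confidence non-neutral segment on the kept-gene grid.

    ``start_index``/``end_index`` are genome-wide gene ranks (half-open)
    taken from the annotation, so calls are directly comparable with
    planted segments and across clusters.
    """

    cluster: object
    chromosome: str
    start_index: int
    end_index: int
    state: str
    mean_residual: float
    posterior: float
    n_genes: int

    def overlap_genes(self, other: "CnaCall") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end_index, other.end_index)
                   - max(self.start_index, other.start_index))


@dataclass
class CnaCallSet:
    """Per-cluster high-confidence CNA segments."""

    calls: dict = field(default_factory=dict)  # cluster -> list[CnaCall]

    def clusters(self):
        return list(self.calls)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": c.cluster, "chromosome": c.chromosome,
             "start_index": c.start_index, "end_index": c.end_index,
             "state": c.state, "mean_residual": c.mean_residual,
             "posterior": c.posterior, "n_genes": c.n_genes}
            for calls in self.calls.values() for c in calls
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "chromosome", "start_index", "end_index",
                           "state", "mean_residual", "posterior", "n_genes"]
        )


def _hmm_model(mu: float, sigma: float, self_transition: float) -> GaussianHMM:
    off = (1.0 - self_transition) / 2.0
    model = GaussianHMM(n_components=3, covariance_type="diag",
                        init_params="", params="")
    model.startprob_ = np.array([0.05, 0.9, 0.05])
    model.transmat_ = np.array([
        [self_transition, off, off],
        [off, self_transition, off],
        [off, off, self_transition],
    ])
    model.means_ = np.array([[-mu], [0.0], [mu]])
    model.covars_ = np.full((3, 1), sigma ** 2)
    return model


def call_cna_segments(profile: CnaProfile, labels: pd.Series,
                      background_sd: float = None, min_units: int = 5,
                      self_transition: float = 0.99,
                      min_posterior: float = 0.5,
                      min_amplitude: float = 0.1,
                      min_segment_genes: int = None) -> CnaCallSet:
    """Call high-confidence non-neutral segments per cluster.

    A 3-state Gaussian HMM with means (-mu, 0, +mu) and a shared emission
    SD is decoded on the cluster-mean smoothed profile, chromosome by
    chromosome. The emission SD is the standard error of the cluster
    mean (median per-gene SD over the cluster's units / sqrt(n)); ``mu``
    is the median |value| of the genes beyond the larger of 3 SD and
    half of ``min_amplitude``. Viterbi runs of a non-neutral state
    become segments; a segment is demoted to neutral when its mean state
    posterior falls below ``min_posterior``, its mean residual magnitude
    below ``min_amplitude`` (log2 units), or its length below
    ``min_segment_genes`` (default half the smoothing window — features
    narrower than that are below the resolution of window averaging) —
    the high-confidence filter. Clusters with fewer than ``min_units``
    units are reported with no calls.
    """
    if min_segment_genes is None:
        min_segment_genes = profile.window // 2
    labels = labels.reindex(profile.values.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all profile units")
    callset = CnaCallSet()
    X = profile.values.to_numpy()
    for cl in sorted(pd.unique(labels)):
        mask = (labels == cl).to_numpy()
        callset.calls[cl] = []
        n = int(mask.sum())
        if n < min_units:
            warnings.warn(f"cluster {cl!r} has fewer than {min_units} units; "
                          "no segments called")
            continue
        sub = X[mask]
        x = sub.mean(axis=0)
        # noise level of the cluster-mean profile
        sigma = float(np.median(sub.std(axis=0, ddof=1))) / np.sqrt(n)
        if not np.isfinite(sigma) or sigma < 1e-8:
            # degenerate variance: fall back to the background residual SD
            sigma = background_sd if background_sd else 1e-2
        thresh = max(3.0 * sigma, 0.5 * min_amplitude)
        tail = np.abs(x) > thresh
        if tail.any():
            mu = float(np.median(np.abs(x[tail])))
        else:
            mu = max(6.0 * sigma, min_amplitude)
        mu = max(mu, 6.0 * sigma, min_amplitude)
        model = _hmm_model(mu, sigma, self_transition)
        for chrom, sl in profile.chromosome_blocks():
            xb = x[sl]
            obs = xb[:, None]
            states = model.predict(obs)
            post = model.predict_proba(obs)
            oi = profile.order_index[sl]
            i = 0
            while i < len(states):
                j = i
                while j < len(states) and states[j] == states[i]:
                    j += 1
                s = states[i]
                if s != 1:
                    posterior = float(post[i:j, s].mean())
                    mean_res = float(xb[i:j].mean())
                    if (posterior >= min_posterior
                            and abs(mean_res) >= min_amplitude
                            and j - i >= min_segment_genes):
                        callset.calls[cl].append(CnaCall(
                            cluster=cl, chromosome=chrom,
                            start_index=int(oi[i]), end_index=int(oi[j - 1]) + 1,
                            state=_STATE_NAMES[s],
                            mean_residual=mean_res,
                            posterior=posterior, n_genes=j - i,
                        ))
                i = j
    return callset


def merge_collinear_clusters(profile: CnaProfile, labels: pd.Series,
                             min_corr: float = 0.97,
                             slope_band=(0.8, 1.25),
                             active_threshold: float = 0.15,
                             min_active_genes: int = 30,
                             max_iter: int = 5) -> pd.Series:
    """Merge clusters whose mean profiles are collinear at equal scale.

    Over the genes where either cluster's mean smoothed residual exceeds
    ``active_threshold``, two clusters carrying the same genotype have
    near-perfectly correlated mean profiles (>= ``min_corr``) with
    mutual regression slopes close to 1. A stroma-diluted border is just
    as correlated with its parent but at a clearly attenuated slope
    (~purity ratio), and sibling subclones decorrelate on their unique
    segments, so neither is merged. Pairs with fewer than
    ``min_active_genes`` active genes are left to the other merge rules.
    """
    labels = labels.copy()
    X = profile.values.reindex(labels.index)
    if X.isna().any(axis=None):
        raise ValueError("profile does not cover all labelled units")
    X = X.to_numpy()
    for _ in range(max_iter):
        la = labels.to_numpy()
        clusters = sorted(pd.unique(la), key=str)
        means = {c: X[la == c].mean(axis=0) for c in clusters}
        merged_any = False
        for i, ca in enumerate(clusters):
            for cb in clusters[i + 1:]:
                xa, xb = means[ca], means[cb]
                active = (np.abs(xa) > active_threshold) \
                    | (np.abs(xb) > active_threshold)
                if active.sum() < min_active_genes:
                    continue
                a, b = xa[active], xb[active]
                denom_a, denom_b = float(a @ a), float(b @ b)
                if denom_a < 1e-12 or denom_b < 1e-12:
                    continue
                dot = float(a @ b)
                corr = float(np.corrcoef(a, b)[0, 1])
                slope_ab, slope_ba = dot / denom_b, dot / denom_a
                if (corr >= min_corr
                        and slope_band[0] <= slope_ab <= slope_band[1]
                        and slope_band[0] <= slope_ba <= slope_band[1]):
                    labels[labels == cb] = ca
                    merged_any = True
                    break
            if merged_any:
                break
        if not merged_any:
            return labels
    return labels


def merge_equivalent_callsets(profile: CnaProfile, labels: pd.Series,
                              min_overlap: float = 0.5,
                              max_attenuation: float = 0.8,
                              max_iter: int = 5, **call_kwargs):
    """Merge clusters whose high-confidence call sets are equivalent.

    Two clusters carry the same genotype exactly when each cluster's
    segments are fully explained by the other's (mutual containment at
    comparable amplitude); a stroma-diluted border fails the amplitude
    condition against its parent and a sibling subclone fails on its
    unique segments, so only same-genotype splits collapse. Segments are
    re-called after each round until no equivalent pair remains.

    Returns ``(labels, callset)`` with the callset matching the final
    labels.
    """
    labels = labels.copy()
    for _ in range(max_iter):
        callset = call_cna_segments(profile, labels, **call_kwargs)
        clusters = list(callset.calls)
        parent = {c: c for c in clusters}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        def explains(a_calls, b_calls):
            return all(
                any(_matches(s, o, min_overlap, max_attenuation)
                    for o in b_calls)
                for s in a_calls
            )

        merged_any = False
        for i, ca in enumerate(clusters):
            for cb in clusters[i + 1:]:
                a_calls, b_calls = callset.calls[ca], callset.calls[cb]
                if explains(a_calls, b_calls) and explains(b_calls, a_calls):
                    ra, rb = find(ca), find(cb)
                    if ra != rb:
                        parent[rb] = ra
                        merged_any = True
        if not merged_any:
            return labels, callset
        labels = labels.map(lambda c: find(c))
    return labels, call_cna_segments(profile, labels, **call_kwargs)


# ---------------------------------------------------------------------------
# subclone vs border classification
# ---------------------------------------------------------------------------

SUBCLONE, BORDER, BACKGROUND = "subclone", "border", "background"


def _matches(a: CnaCall, b: CnaCall, min_overlap: float,
             max_attenuation: float = 0.8) -> bool:
    """Does call ``b`` account for call ``a``?

    Same state, at least ``min_overlap`` of ``a``'s genes covered by
    ``b``, and ``b`` at comparable-or-greater amplitude. Both conditions
    are one-way on purpose: in an attenuated copy of a segment (a
    stroma-diluted border) only the strongest stretch crosses the call
    threshold, so the echo is shorter and weaker than the original — it
    is explained by the original, while the full-amplitude original is
    never explained by its echo.
    """
    if a.state != b.state:
        return False
    ov = a.overlap_genes(b)
    if ov == 0:
        return False
    la = a.end_index - a.start_index
    if ov / la < min_overlap:
        return False
    return abs(b.mean_residual) >= max_attenuation * abs(a.mean_residual)


def classify_clusters(callset: CnaCallSet, tumour_weights: pd.Series,
                      labels: pd.Series, background_clusters=(),
                      min_overlap: float = 0.5,
                      max_attenuation: float = 0.8) -> pd.DataFrame:
    """Label each cluster subclone / border / background.

    A cluster is a *subclone* iff at least one of its high-confidence
    segments is observed in no other cluster (at least ``min_overlap``
    of its genes covered by a matching-state call of comparable
    amplitude). A cluster whose
    segments are all observed elsewhere is a *border* region — its CNA
    pattern is explained by a tumour/stroma mixture of an existing clone.
    The tie is broken toward subclone when the cluster's mean tumour
    weight exceeds that of every candidate parent (a cluster whose calls
    cover all of this cluster's segments): diluting a clone with stroma
    can only lower the tumour weight, so the purer cluster of such a
    pair is the genotype and the other its border. Invariant to cluster
    relabelling.

    Returns a DataFrame indexed by cluster with columns
    ``label, n_segments, n_unique_segments, mean_tumour_weight``.
    """
    background_clusters = set(background_clusters)
    clusters = list(callset.calls)
    mean_tw = {}
    for cl in clusters:
        units = labels.index[labels == cl]
        w = tumour_weights.reindex(units).dropna()
        mean_tw[cl] = float(w.mean()) if len(w) else np.nan

    rows = {}
    any_subclone = False
    for cl in clusters:
        if cl in background_clusters:
            rows[cl] = (BACKGROUND, len(callset.calls[cl]), 0, mean_tw[cl])
            continue
        segs = callset.calls[cl]
        others = [o for o in clusters if o != cl and o not in background_clusters]
        covered_by = {o: 0 for o in others}
        n_unique = 0
        for seg in segs:
            seen = False
            for other in others:
                if any(_matches(seg, o, min_overlap, max_attenuation)
                       for o in callset.calls[other]):
                    seen = True
                    covered_by[other] += 1
            if not seen:
                n_unique += 1
        # candidate parents: clusters whose calls cover ALL of cl's segments
        parents = [o for o, k in covered_by.items() if segs and k == len(segs)]
        if n_unique >= 1:
            label = SUBCLONE
        elif parents and mean_tw[cl] > max(mean_tw[p] for p in parents):
            label = SUBCLONE  # mixing with stroma can only lower tumour weight
        else:
            label = BORDER
        any_subclone |= label == SUBCLONE
        rows[cl] = (label, len(segs), n_unique, mean_tw[cl])
    if not any_subclone and any(c not in background_clusters for c in clusters):
        warnings.warn("no subclone found among non-background clusters")
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["label", "n_segments", "n_unique_segments", "mean_tumour_weight"],
    )
    out.index.name = "cluster"
    return out
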
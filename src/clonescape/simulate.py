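"""Synthetic spatial datasets with planted ground truth.

The generators emulate the two modalities the pipeline consumes:

* a Visium-like spot grid where contiguous tumour territories carry
  clone-specific copy-number segments (expressed as fold-changes on
  contiguous gene blocks), a border band mixes one clone 50/50 with
  stroma, and the remaining spots are stroma/immune background;
* a CosMx-like field of cells where tumour clones occupy circular
  territories and non-malignant cell types infiltrate them with
  clone-specific density multipliers, optionally with ligand/receptor
  programs up-shifted in one clone (autocrine loops when both the ligand
  and its cognate receptor are shifted in the same clone).

Counts are negative binomial with gene-level means from a log-normal
baseline: for mean ``mu`` and dispersion ``theta`` the variance is
``mu + mu**2 / theta``. Every generator is deterministic for a fixed
seed and returns a :class:`SimulationTruth` alongside the dataset so
downstream tests can compare against the planted configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import GeneAnnotation
from .containers import CellDataset, ReferenceProfiles, SpotDataset

__all__ = [
    "GenomicSegment",
    "CloneGenotype",
    "SimulationTruth",
    "simulate_genome",
    "simulate_clones",
    "simulate_visium",
    "simulate_cosmx",
    "simulate_lr_programs",
]

#: non-malignant cell types used by both generators
STROMAL_TYPES = ("stroma", "immune")
COSMX_STROMAL_TYPES = ("T_cell", "macrophage", "fibroblast", "endothelial")


@dataclass(frozen=True)
class GenomicSegment:
    """A contiguous gene block with a copy-number fold-change.

    ``start_index``/``end_index`` are genome-wide gene ranks (half-open
    interval) on the :class:`GeneAnnotation` the segment was placed on.
    """

    chromosome: str
    start_index: int
    end_index: int
    log2_effect: float
    shared: bool = False

    def __post_init__(self):
        if self.log2_effect == 0:
            raise ValueError("log2_effect must be nonzero")
        if self.end_index <= self.start_index:
            raise ValueError("empty segment")

    @property
    def n_genes(self) -> int:
        return self.end_index - self.start_index

    def overlaps(self, other: "GenomicSegment") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_index < other.end_index
            and other.start_index < self.end_index
        )


@dataclass(frozen=True)
class CloneGenotype:
    clone_id: str
    segments: tuple

    def __post_init__(self):
        segs = tuple(self.segments)
        for i, a in enumerate(segs):
            for b in segs[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"overlapping segments within {self.clone_id}")
        object.__setattr__(self, "segments", segs)

    @property
    def unique_segments(self) -> tuple:
        return tuple(s for s in self.segments if not s.shared)

    @property
    def shared_segments(self) -> tuple:
        return tuple(s for s in self.segments if s.shared)


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated dataset."""

    seed: int
    genotypes: list = field(default_factory=list)
    #: spots/cells x component weights (clones + stromal types); rows sum to 1
    composition: Optional[pd.DataFrame] = None
    #: per-unit truth label ('clone_0', 'border_0', 'background', cell types...)
    labels: Optional[pd.Series] = None
    #: (clone_id, cell_type) -> density multiplier near that clone
    niche_enrichment: dict = field(default_factory=dict)
    #: (clone_id, gene_id) -> log2 up-shift of that gene in that clone
    lr_programs: dict = field(default_factory=dict)
    #: cell-type mean profiles (types x genes), library-size normalised,
    #: tumour profile WITHOUT any CNA applied
    type_profiles: Optional[pd.DataFrame] = None
    #: geometry of the cell-level simulation (clone territories)
    clone_centers: Optional[np.ndarray] = None
    clone_radius: Optional[float] = None

    def tumour_weight(self) -> pd.Series:
        """Total tumour fraction per unit (sum over clone columns)."""
        clone_cols = [c for c in self.composition.columns if c.startswith("clone_")]
        return self.composition[clone_cols].sum(axis=1)

    def reference_profiles(self) -> ReferenceProfiles:
        """Deconvolution reference: one 'tumour' row plus stromal types."""
        rows = {"tumour": self.type_profiles.loc["tumour"]}
        for t in self.type_profiles.index:
            if t != "tumour":
                rows[t] = self.type_profiles.loc[t]
        return ReferenceProfiles(pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# genome & genotypes
# ---------------------------------------------------------------------------

def simulate_genome(n_genes: int, n_chromosomes: int, seed: int) -> GeneAnnotation:
    """Random gene annotation with genes split near-evenly across chromosomes.

    Starts are strictly increasing within each chromosome (random gaps of
    1-100 kb); chromosome sizes differ by at most one gene.
    """
    if n_genes < 1 or n_chromosomes < 1:
        raise ValueError("n_genes and n_chromosomes must be positive")
    if n_genes < n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_genes, n_chromosomes)
    sizes = [base + (1 if i < extra else 0) for i in range(n_chromosomes)]
    gene_ids, chroms, starts = [], [], []
    g = 0
    for ci, size in enumerate(sizes):
        gaps = rng.integers(1_000, 100_000, size=size)
        pos = np.cumsum(gaps)
        for p in pos:
            gene_ids.append(f"g{g:05d}")
            chroms.append(f"chr{ci + 1}")
            starts.append(int(p))
            g += 1
    return GeneAnnotation(
        gene_ids=np.array(gene_ids, dtype=object),
        chromosome=np.array(chroms, dtype=object),
        start=np.array(starts),
        chrom_order=tuple(f"chr{i + 1}" for i in range(n_chromosomes)),
    )


def _place_segments(annotation, n_segments, seg_len, min_gap, rng):
    """Place non-overlapping equal-length segments, none crossing a
    chromosome boundary, with >= min_gap genes between segments."""
    slices = annotation.chromosome_slices()
    chrom_names = list(slices)
    capacity = {c: slices[c].stop - slices[c].start for c in chrom_names}
    # randomised first-fit assignment of segments to chromosomes
    assignment = {c: 0 for c in chrom_names}
    order = rng.permutation(n_segments)  # noqa: F841  (segments identical; kept for seed stability)
    for _ in range(n_segments):
        feasible = [
            c for c in chrom_names
            if capacity[c] - assignment[c] * (seg_len + min_gap) >= seg_len
        ]
        if not feasible:
            raise ValueError(
                f"genome too small to place {n_segments} segments of "
                f"{seg_len} genes (gap {min_gap})"
            )
        weights = np.array(
            [capacity[c] - assignment[c] * (seg_len + min_gap) for c in feasible],
            dtype=float,
        )
        chosen = feasible[rng.choice(len(feasible), p=weights / weights.sum())]
        assignment[chosen] += 1
    placements = []
    for c in chrom_names:
        m = assignment[c]
        if m == 0:
            continue
        sl = slices[c]
        slack = capacity[c] - m * seg_len - (m - 1) * min_gap
        # distribute slack over the m+1 inter-segment gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=m)) if slack > 0 else np.zeros(m, dtype=int)
        pos = sl.start
        prev_cut = 0
        for k in range(m):
            pos += int(cuts[k] - prev_cut)
            prev_cut = int(cuts[k])
            placements.append((c, pos, pos + seg_len))
            pos += seg_len + min_gap
    idx = rng.permutation(len(placements))
    return [placements[i] for i in idx]


def simulate_clones(
    annotation: GeneAnnotation,
    n_clones: int,
    n_shared_segments: int,
    n_unique_segments: int,
    segment_len_genes: int = 300,
    effect_log2: float = 0.5,
    seed: int = 0,
    min_gap_genes: int = 10,
) -> list:
    """Plant clone genotypes: shared segments carried by every clone plus
    private segments pairwise disjoint across clones.

    Signs alternate between amplification and deletion with magnitude
    ``effect_log2``. Shared and private segments never overlap.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_shared_segments + n_clones * n_unique_segments
    placements = _place_segments(
        annotation, total, segment_len_genes, min_gap_genes, rng
    )
    signs = np.where(np.arange(total) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    shared = [
        GenomicSegment(c, s, e, float(signs[i]) * effect_log2, shared=True)
        for i, (c, s, e) in enumerate(placements[:n_shared_segments])
    ]
    genotypes = []
    k = n_shared_segments
    for ci in range(n_clones):
        private = []
        for _ in range(n_unique_segments):
            c, s, e = placements[k]
            private.append(
                GenomicSegment(c, s, e, float(signs[k]) * effect_log2, shared=False)
            )
            k += 1
        genotypes.append(
            CloneGenotype(clone_id=f"clone_{ci}", segments=tuple(shared + private))
        )
    return genotypes


# ---------------------------------------------------------------------------
# expression model
# ---------------------------------------------------------------------------

def _make_type_profiles(annotation, cell_types, rng, marker_frac=0.05,
                        marker_log2=2.0, baseline_sigma=1.0) -> pd.DataFrame:
    """Cell-type mean profiles: shared log-normal baseline, each type
    up-shifting its own random marker gene subset. Rows sum to 1."""
    n = annotation.n_genes
    baseline = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n)
    n_markers = max(1, int(round(marker_frac * n)))
    profiles = {}
    for t in cell_types:
        prof = baseline.copy()
        markers = rng.choice(n, size=n_markers, replace=False)
        prof[markers] *= 2.0 ** marker_log2
        profiles[t] = prof / prof.sum()
    return pd.DataFrame(profiles, index=annotation.gene_ids).T


def _clone_profile(base_tumour, genotype, annotation, lr_programs=None):
    """Apply CNA fold-changes (and any ligand/receptor program shifts) to
    the tumour base profile; renormalise to sum 1 (library-size effect)."""
    prof = base_tumour.to_numpy().copy()
    for seg in genotype.segments:
        prof[seg.start_index:seg.end_index] *= 2.0 ** seg.log2_effect
    if lr_programs:
        gene_pos = {g: i for i, g in enumerate(annotation.gene_ids)}
        for (clone_id, gene), shift in lr_programs.items():
            if clone_id == genotype.clone_id:
                prof[gene_pos[gene]] *= 2.0 ** shift
    return prof / prof.sum()


def _nb_counts(mean, theta, rng):
    """Negative binomial draws with var = mu + mu^2/theta."""
    if theta <= 0:
        raise ValueError("nb_dispersion must be > 0")
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


# ---------------------------------------------------------------------------
# spot-level (Visium-like)
# ---------------------------------------------------------------------------

def _grow_territories(grid_shape, n_clones, target_size, rng, buffer=2):
    """Grow contiguous clone blobs from well-separated seeds on the grid.

    Blobs expand one random frontier cell at a time and keep a Chebyshev
    buffer of ``buffer`` cells from other blobs so territories never touch.
    Returns an owner array (-1 = unassigned).
    """
    rows, cols = grid_shape
    owner = np.full((rows, cols), -1, dtype=int)
    # spread seeds on a coarse lattice, jittered
    seeds = []
    n_side = int(np.ceil(np.sqrt(n_clones)))
    for ci in range(n_clones):
        r0 = (ci // n_side + 0.5) / n_side
        c0 = (ci % n_side + 0.5) / n_side
        r = int(np.clip(r0 * rows + rng.integers(-rows // 8, rows // 8 + 1), 0, rows - 1))
        c = int(np.clip(c0 * cols + rng.integers(-cols // 8, cols // 8 + 1), 0, cols - 1))
        seeds.append((r, c))
        owner[r, c] = ci
    sizes = [1] * n_clones
    frontiers = [{s} for s in seeds]

    def admissible(r, c, ci):
        if owner[r, c] != -1:
            return False
        rlo, rhi = max(0, r - buffer), min(rows, r + buffer + 1)
        clo, chi = max(0, c - buffer), min(cols, c + buffer + 1)
        block = owner[rlo:rhi, clo:chi]
        return np.all((block == -1) | (block == ci))

    active = list(range(n_clones))
    while active:
        for ci in list(active):
            if sizes[ci] >= target_size or not frontiers[ci]:
                active.remove(ci)
                continue
            # candidate empty neighbours of the frontier
            cands = []
            for (r, c) in frontiers[ci]:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and admissible(rr, cc, ci):
                            cands.append((rr, cc))
            if not cands:
                active.remove(ci)
                continue
            rr, cc = cands[rng.integers(len(cands))]
            owner[rr, cc] = ci
            frontiers[ci].add((rr, cc))
            sizes[ci] += 1
    return owner


def simulate_visium(
    annotation: GeneAnnotation,
    genotypes=None,
    grid_shape=(45, 45),
    depth_mean: float = 6000.0,
    nb_dispersion: float = 2.0,
    seed: int = 0,
    tumour_purity: float = 0.85,
    tumour_fraction: float = 0.45,
    spot_spacing: float = 100.0,
):
    """Simulate a spot grid with contiguous clone territories.

    Spots inside a clone territory mix that clone with stroma at
    ``tumour_purity``; the band of spots immediately surrounding the
    first clone's territory is a 50/50 clone/stroma border; everything
    else is stroma/immune background. Spot spacing is 100 units, echoing
    the Visium array geometry.

    Returns ``(SpotDataset, SimulationTruth)``.
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape must be positive")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    if genotypes is None:
        genotypes = simulate_clones(
            annotation, n_clones=3, n_shared_segments=2, n_unique_segments=1,
            segment_len_genes=min(300, annotation.n_genes // 10),
            effect_log2=0.5, seed=int(rng.integers(2 ** 31)),
        )
    n_clones = len(genotypes)
    n_spots = rows * cols
    target = max(1, int(tumour_fraction * n_spots / n_clones))
    owner = _grow_territories(grid_shape, n_clones, target, rng)

    # border band: unassigned spots Chebyshev-adjacent to clone 0's blob
    border = np.zeros((rows, cols), dtype=bool)
    blob0 = owner == 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            shifted = np.zeros_like(blob0)
            rlo, rhi = max(dr, 0), rows + min(dr, 0)
            clo, chi = max(dc, 0), cols + min(dc, 0)
            shifted[rlo:rhi, clo:chi] = blob0[rlo - dr:rhi - dr, clo - dc:chi - dc]
            border |= shifted
    border &= owner == -1

    cell_types = ["tumour", *STROMAL_TYPES]
    type_profiles = _make_type_profiles(annotation, cell_types, rng)
    clone_profiles = np.vstack([
        _clone_profile(type_profiles.loc["tumour"], g, annotation) for g in genotypes
    ])
    stroma = type_profiles.loc["stroma"].to_numpy()
    immune = type_profiles.loc["immune"].to_numpy()

    comp_cols = [g.clone_id for g in genotypes] + list(STROMAL_TYPES)
    comp = np.zeros((n_spots, len(comp_cols)))
    labels = np.empty(n_spots, dtype=object)
    rr, cc = np.divmod(np.arange(n_spots), cols)
    for s in range(n_spots):
        o = owner[rr[s], cc[s]]
        if o >= 0:
            comp[s, o] = tumour_purity
            comp[s, n_clones] = 1.0 - tumour_purity  # stroma
            labels[s] = f"clone_{o}"
        elif border[rr[s], cc[s]]:
            comp[s, 0] = 0.5
            comp[s, n_clones] = 0.5
            labels[s] = "border_0"
        else:
            comp[s, n_clones] = 0.8
            comp[s, n_clones + 1] = 0.2
            labels[s] = "background"

    mixtures = np.vstack([clone_profiles, stroma, immune])  # components x genes
    spot_mean = comp @ mixtures  # rows sum to 1
    depth = depth_mean * rng.lognormal(mean=0.0, sigma=0.15, size=n_spots)
    counts = _nb_counts(spot_mean * depth[:, None], nb_dispersion, rng)

    spot_ids = np.array([f"spot_{i:05d}" for i in range(n_spots)], dtype=object)
    coords = np.column_stack([rr, cc]).astype(float) * spot_spacing
    ds = SpotDataset(
        counts=sp.csr_matrix(counts),
        spot_ids=spot_ids,
        coordinates=coords,
        gene_ids=annotation.gene_ids,
    )
    truth = SimulationTruth(
        seed=seed,
        genotypes=list(genotypes),
        composition=pd.DataFrame(comp, index=spot_ids, columns=comp_cols),
        labels=pd.Series(labels, index=spot_ids, name="truth_label"),
        type_profiles=type_profiles,
    )
    return ds, truth


def simulate_lr_programs(annotation: GeneAnnotation, clone_id: str = "clone_0",
                         n_planted: int = 5, n_decoys: int = 15,
                         shift_log2: float = 2.0, seed: int = 0):
    """Plant autocrine ligand-receptor programs on the synthetic genome.

    Picks ``n_planted + n_decoys`` disjoint gene pairs from the
    annotation and builds a pair table over them; for the planted pairs
    both the ligand and its cognate receptor are up-shifted by
    ``shift_log2`` in ``clone_id`` (an autocrine loop), the decoy pairs
    are left untouched.

    Returns ``(pair table DataFrame, lr_programs dict)`` ready for
    :func:`simulate_cosmx`.
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_planted + n_decoys
    genes = rng.choice(annotation.gene_ids, size=2 * n_pairs, replace=False)
    table = pd.DataFrame({
        "ligand": genes[:n_pairs],
        "receptor": genes[n_pairs:],
        "location": np.where(np.arange(n_pairs) % 2 == 0,
                             "secreted", "plasma_membrane"),
    })
    programs = {}
    for i in range(n_planted):
        programs[(clone_id, table.loc[i, "ligand"])] = shift_log2
        programs[(clone_id, table.loc[i, "receptor"])] = shift_log2
    return table, programs


# ---------------------------------------------------------------------------
# cell-level (CosMx-like)
# ---------------------------------------------------------------------------

def _fov_grid(n_fovs):
    """Near-square tile grid with exactly n_fovs tiles."""
    best = (1, n_fovs)
    for r in range(1, int(np.sqrt(n_fovs)) + 1):
        if n_fovs % r == 0:
            best = (r, n_fovs // r)
    return best


def simulate_cosmx(
    annotation: GeneAnnotation,
    genotypes=None,
    n_cells: int = 20000,
    n_fovs: int = 20,
    panel_size: int = 960,
    depth_mean: float = 300.0,
    nb_dispersion: float = 2.0,
    niche_enrichment: Optional[dict] = None,
    lr_programs: Optional[dict] = None,
    tumour_fraction: float = 0.4,
    target_neighbours: float = 3.0,
    neighbour_radius: float = 110.0,
    seed: int = 0,
):
    """Simulate single cells with clone territories and biased infiltration.

    Tumour clones occupy equal-area circular territories where the cell
    density is ~3x the bulk; non-malignant cells pick a territory (or the
    bulk) with probability proportional to ``area x multiplier``, so the
    expected density of type ``t`` inside clone ``a``'s territory relative
    to clone ``b``'s equals ``m[t,a] / m[t,b]``. The overall density is set
    so a cell has ``target_neighbours`` neighbours (median ~3 in tissue)
    within ``neighbour_radius`` pixels. Counts are negative binomial on a
    ``panel_size``-gene panel (ligand/receptor program genes always kept).

    Returns ``(CellDataset, SimulationTruth)``.
    """
    if panel_size > annotation.n_genes:
        raise ValueError("panel_size exceeds number of annotated genes")
    rng = np.random.default_rng(seed)
    if genotypes is None:
        genotypes = simulate_clones(
            annotation, n_clones=2, n_shared_segments=2, n_unique_segments=1,
            segment_len_genes=min(300, annotation.n_genes // 10),
            effect_log2=0.5, seed=int(rng.integers(2 ** 31)),
        )
    n_clones = len(genotypes)
    if niche_enrichment is None:
        # default study condition: T cells prefer one clone's territory,
        # fibroblasts the other's, each at twice the bulk density
        niche_enrichment = {("clone_0", "T_cell"): 2.0,
                            ("clone_1", "fibroblast"): 2.0}
    niche_enrichment = dict(niche_enrichment)
    lr_programs = dict(lr_programs or {})
    if any(m <= 0 for m in niche_enrichment.values()):
        raise ValueError("niche multipliers must be > 0")

    cell_types = [g.clone_id for g in genotypes] + list(COSMX_STROMAL_TYPES)
    if n_cells < len(cell_types):
        raise ValueError("n_cells smaller than the number of cell types")

    # geometry: area from the target neighbour count at the reference radius
    area = n_cells * np.pi * neighbour_radius ** 2 / target_neighbours
    fr, fc = _fov_grid(n_fovs)
    side_x = np.sqrt(area * fc / fr)
    side_y = area / side_x

    n_tumour = int(round(tumour_fraction * n_cells))
    per_clone = [n_tumour // n_clones] * n_clones
    per_clone[0] += n_tumour - sum(per_clone)
    # disc area so in-territory tumour density ~ 3x the overall density
    density = n_cells / area
    disc_area = max(per_clone) / (3.0 * density)
    radius = np.sqrt(disc_area / np.pi)
    radius = min(radius, 0.45 * side_y, 0.45 * side_x / n_clones)
    centers = np.array([
        [(k + 0.5) * side_x / n_clones, side_y / 2.0] for k in range(n_clones)
    ])

    def uniform_disc(center, n):
        r = radius * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        return center + np.column_stack([r * np.cos(th), r * np.sin(th)])

    def uniform_bulk(n):
        pts = np.empty((0, 2))
        while len(pts) < n:
            cand = np.column_stack([
                rng.random(2 * n) * side_x, rng.random(2 * n) * side_y
            ])
            d = np.min(
                np.linalg.norm(cand[:, None, :] - centers[None, :, :], axis=2), axis=1
            )
            pts = np.vstack([pts, cand[d > radius]])
        return pts[:n]

    positions, labels = [], []
    for k, g in enumerate(genotypes):
        positions.append(uniform_disc(centers[k], per_clone[k]))
        labels.extend([g.clone_id] * per_clone[k])

    n_rest = n_cells - n_tumour
    stromal = list(COSMX_STROMAL_TYPES)
    type_draw = rng.choice(len(stromal), size=n_rest)
    bulk_area = area - n_clones * np.pi * radius ** 2
    for ti, t in enumerate(stromal):
        n_t = int((type_draw == ti).sum())
        if n_t == 0:
            continue
        zone_w = np.array(
            [niche_enrichment.get((g.clone_id, t), 1.0) * np.pi * radius ** 2
             for g in genotypes] + [bulk_area]
        )
        zones = rng.choice(n_clones + 1, size=n_t, p=zone_w / zone_w.sum())
        for z in range(n_clones):
            nz = int((zones == z).sum())
            if nz:
                positions.append(uniform_disc(centers[z], nz))
                labels.extend([t] * nz)
        nb = int((zones == n_clones).sum())
        if nb:
            positions.append(uniform_bulk(nb))
            labels.extend([t] * nb)

    centroids = np.vstack(positions)
    labels = np.array(labels, dtype=object)
    perm = rng.permutation(n_cells)
    centroids, labels = centroids[perm], labels[perm]

    fov = (
        np.minimum((centroids[:, 1] / side_y * fr).astype(int), fr - 1) * fc
        + np.minimum((centroids[:, 0] / side_x * fc).astype(int), fc - 1)
    )

    # expression: panel = LR-program genes + random fill to panel_size
    forced = sorted({g for (_, g) in lr_programs})
    gene_pos = {g: i for i, g in enumerate(annotation.gene_ids)}
    forced_idx = np.array([gene_pos[g] for g in forced], dtype=int)
    remaining = np.setdiff1d(np.arange(annotation.n_genes), forced_idx)
    fill = rng.choice(remaining, size=panel_size - len(forced_idx), replace=False)
    panel_idx = np.sort(np.concatenate([forced_idx, fill]))
    panel_genes = annotation.gene_ids[panel_idx]

    type_profiles = _make_type_profiles(
        annotation, ["tumour", *COSMX_STROMAL_TYPES], rng
    )
    profile_by_label = {}
    for g in genotypes:
        prof = _clone_profile(
            type_profiles.loc["tumour"], g, annotation, lr_programs
        )
        profile_by_label[g.clone_id] = prof[panel_idx]
    for t in COSMX_STROMAL_TYPES:
        profile_by_label[t] = type_profiles.loc[t].to_numpy()[panel_idx]
    # renormalise on the panel so depth_mean is the expected library size
    for k in profile_by_label:
        profile_by_label[k] = profile_by_label[k] / profile_by_label[k].sum()

    counts = np.zeros((n_cells, len(panel_idx)), dtype=np.int64)
    depth = depth_mean * rng.lognormal(0.0, 0.2, size=n_cells)
    for t, prof in profile_by_label.items():
        mask = labels == t
        if mask.any():
            counts[mask] = _nb_counts(
                depth[mask, None] * prof[None, :], nb_dispersion, rng
            )

    cell_ids = np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)
    ds = CellDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        centroids=centroids,
        fov_id=fov,
        gene_ids=panel_genes,
        type_label=labels,
    )
    truth = SimulationTruth(
        seed=seed,
        genotypes=list(genotypes),
        labels=pd.Series(labels, index=cell_ids, name="truth_label"),
        niche_enrichment=niche_enrichment,
        lr_programs=lr_programs,
        type_profiles=type_profiles,
        clone_centers=centers,
        clone_radius=float(radius),
    )
    return ds, truth
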
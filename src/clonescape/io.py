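"""Readers, writers and QC filters.

Formats: MatrixMarket triplets plus features/barcodes TSV for counts;
TSV for coordinates (``id<TAB>x<TAB>y[<TAB>fov]``); BED-like TSV
(``chrom<TAB>start<TAB>gene_id``) for the gene annotation; JSON for the
simulation truth.

QC thresholds follow the boundary semantics "less than" = strict and
"at least" = inclusive throughout:

* spots with fewer than 400 detected genes are excluded;
* dissociated single cells are kept with >= 500 genes, >= 1000 UMIs and
  a mitochondrial fraction strictly under 0.15;
* imaged cells with fewer than 100 transcripts are excluded.

Normalisation is log1p library-size scaling (``log(1 + scale*c/total)``);
it deliberately replaces variance-stabilising transforms — the rank
tests, correlations and window means downstream are robust to this.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .annotation import GeneAnnotation
from .containers import CellDataset, SpotDataset

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_coordinates",
    "write_coordinates",
    "read_gene_annotation",
    "write_gene_annotation",
    "write_spot_dataset",
    "read_spot_dataset",
    "write_cell_dataset",
    "read_cell_dataset",
    "qc_filter_spots",
    "qc_filter_cells_sc",
    "qc_filter_cells_cosmx",
    "normalize_lognorm",
]


class FormatError(ValueError):
    """Raised when input files are mutually inconsistent."""


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + features/barcodes)
# ---------------------------------------------------------------------------

def write_count_matrix(counts, gene_ids, barcodes, path_matrix, path_features,
                       path_barcodes):
    """Write a units x genes integer matrix as MTX (genes x units, the
    conventional orientation) with features/barcodes TSV."""
    mat = sp.coo_matrix(counts).T.astype(np.int64)
    scipy.io.mmwrite(str(path_matrix), mat, field="integer")
    pd.Series(gene_ids).to_csv(path_features, sep="\t", header=False, index=False)
    pd.Series(barcodes).to_csv(path_barcodes, sep="\t", header=False, index=False)


def read_count_matrix(path_matrix, path_features, path_barcodes):
    """Read counts back as ``(csr units x genes, gene_ids, barcodes)``.

    Round-trips bit-exactly with :func:`write_count_matrix` for integer
    matrices. Dimension mismatches raise :class:`FormatError` naming the
    offending file.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(path_matrix)).T)
    genes = pd.read_csv(path_features, sep="\t", header=None)[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(path_barcodes, sep="\t", header=None)[0].to_numpy(dtype=object)
    if mat.shape[1] != len(genes):
        raise FormatError(
            f"{path_features}: {len(genes)} features but matrix has "
            f"{mat.shape[1]} gene rows"
        )
    if mat.shape[0] != len(barcodes):
        raise FormatError(
            f"{path_barcodes}: {len(barcodes)} barcodes but matrix has "
            f"{mat.shape[0]} unit columns"
        )
    return mat, genes, barcodes


# ---------------------------------------------------------------------------
# coordinates / annotation / bundles
# ---------------------------------------------------------------------------

def write_coordinates(ids, xy, path, fov=None):
    df = pd.DataFrame({"id": ids, "x": xy[:, 0], "y": xy[:, 1]})
    if fov is not None:
        df["fov"] = fov
    df.to_csv(path, sep="\t", index=False)


def read_coordinates(path):
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def write_gene_annotation(annotation: GeneAnnotation, path):
    annotation.to_frame()[["chromosome", "start", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "gene_id"])
    return GeneAnnotation(
        gene_ids=df["gene_id"].to_numpy(dtype=object),
        chromosome=df["chromosome"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
    )


def write_spot_dataset(ds: SpotDataset, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(ds.counts, ds.gene_ids, ds.spot_ids,
                       outdir / "matrix.mtx", outdir / "features.tsv",
                       outdir / "barcodes.tsv")
    write_coordinates(ds.spot_ids, ds.coordinates, outdir / "coordinates.tsv")


def read_spot_dataset(indir) -> SpotDataset:
    indir = Path(indir)
    counts, genes, barcodes = read_count_matrix(
        indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv"
    )
    coords = read_coordinates(indir / "coordinates.tsv")
    coords = coords.set_index("id").loc[barcodes]
    return SpotDataset(counts=counts, spot_ids=barcodes,
                       coordinates=coords[["x", "y"]].to_numpy(),
                       gene_ids=genes)


def write_cell_dataset(ds: CellDataset, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(ds.counts, ds.gene_ids, ds.cell_ids,
                       outdir / "matrix.mtx", outdir / "features.tsv",
                       outdir / "barcodes.tsv")
    write_coordinates(ds.cell_ids, ds.centroids, outdir / "coordinates.tsv",
                      fov=ds.fov_id)
    if ds.type_label is not None:
        pd.DataFrame({"id": ds.cell_ids, "label": ds.type_label}).to_csv(
            outdir / "labels.tsv", sep="\t", index=False
        )


def read_cell_dataset(indir) -> CellDataset:
    indir = Path(indir)
    counts, genes, barcodes = read_count_matrix(
        indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv"
    )
    coords = read_coordinates(indir / "coordinates.tsv")
    if "fov" not in coords.columns:
        raise FormatError(f"{indir / 'coordinates.tsv'}: missing column 'fov'")
    coords = coords.set_index("id").loc[barcodes]
    labels = None
    lab_path = indir / "labels.tsv"
    if lab_path.exists():
        lab = pd.read_csv(lab_path, sep="\t").set_index("id").loc[barcodes]
        labels = lab["label"].to_numpy(dtype=object)
    return CellDataset(counts=counts, cell_ids=barcodes,
                       centroids=coords[["x", "y"]].to_numpy(),
                       fov_id=coords["fov"].to_numpy(),
                       gene_ids=genes, type_label=labels)


def write_truth(truth, path):
    """Persist a SimulationTruth as JSON (composition/labels inline)."""
    payload = {
        "seed": truth.seed,
        "genotypes": [
            {
                "clone_id": g.clone_id,
                "segments": [
                    {"chromosome": s.chromosome, "start_index": int(s.start_index),
                     "end_index": int(s.end_index),
                     "log2_effect": float(s.log2_effect), "shared": bool(s.shared)}
                    for s in g.segments
                ],
            }
            for g in truth.genotypes
        ],
        "niche_enrichment": [
            {"clone": c, "cell_type": t, "multiplier": m}
            for (c, t), m in truth.niche_enrichment.items()
        ],
        "lr_programs": [
            {"clone": c, "gene": g, "log2_shift": s}
            for (c, g), s in truth.lr_programs.items()
        ],
    }
    if truth.labels is not None:
        payload["labels"] = {str(k): str(v) for k, v in truth.labels.items()}
    if truth.composition is not None:
        payload["composition"] = {
            "index": [str(i) for i in truth.composition.index],
            "columns": [str(c) for c in truth.composition.columns],
            "values": truth.composition.to_numpy().tolist(),
        }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def detected_genes_per_unit(counts) -> np.ndarray:
    """Number of genes with count > 0 per unit (row)."""
    return np.asarray((sp.csr_matrix(counts) > 0).sum(axis=1)).ravel()


def qc_filter_spots(ds: SpotDataset, min_genes: int = 400) -> SpotDataset:
    """Drop spots with fewer than ``min_genes`` detected genes (count > 0).

    A spot with exactly ``min_genes`` detected genes is kept; order is
    preserved. Idempotent.
    """
    keep = detected_genes_per_unit(ds.counts) >= min_genes
    return ds.subset_spots(np.flatnonzero(keep))


def qc_filter_cells_sc(counts, gene_ids, mito_gene_ids, min_genes: int = 500,
                       min_umis: int = 1000, max_mito_frac: float = 0.15):
    """Dissociated single-cell QC: keep a cell iff it has >= ``min_genes``
    detected genes AND >= ``min_umis`` total counts AND a mitochondrial
    count fraction strictly below ``max_mito_frac``.

    Returns ``(filtered counts, keep mask)``. Mitochondrial genes are an
    explicit id list; an unknown id is an error (no name-prefix magic).
    """
    counts = sp.csr_matrix(counts)
    gene_ids = np.asarray(gene_ids, dtype=object)
    known = set(gene_ids)
    unknown = [g for g in mito_gene_ids if g not in known]
    if unknown:
        raise ValueError(f"unknown mitochondrial gene ids: {unknown}")
    mito_mask = np.isin(gene_ids, list(mito_gene_ids))
    genes = detected_genes_per_unit(counts)
    umis = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(umis > 0, mito / np.maximum(umis, 1), 0.0)
    keep = (genes >= min_genes) & (umis >= min_umis) & (frac < max_mito_frac)
    return counts[keep], keep


def qc_filter_cells_cosmx(ds: CellDataset, min_transcripts: int = 100) -> CellDataset:
    """Drop imaged cells with fewer than ``min_transcripts`` total transcripts."""
    total = np.asarray(ds.counts.sum(axis=1)).ravel()
    return ds.subset_cells(np.flatnonzero(total >= min_transcripts))


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_lognorm(counts, scale: float = 1e4) -> np.ndarray:
    """log1p library-size normalisation: ``log(1 + scale * c / row_total)``.

    Natural log. Rows with total 0 map to all-zero rows. Returns dense.
    """
    counts = sp.csr_matrix(counts).astype(float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale / totals[nz]
    dense = counts.multiply(inv[:, None]).toarray()
    return np.log1p(dense)
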
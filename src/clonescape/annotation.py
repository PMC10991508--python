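"""Genomic gene annotation used to order genes for CNA inference.

Expression-based copy-number inference smooths relative expression along
the genome, so every gene needs a chromosome, a basepair start and a
genome-wide rank. The container below keeps genes sorted by
(chromosome, start) and exposes per-chromosome blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneAnnotation"]


@dataclass(frozen=True)
class GeneAnnotation:
    """Ordered gene annotation.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per gene.
    chromosome
        Chromosome name per gene. Chromosome order is the order of first
        appearance and is preserved by all downstream operations.
    start
        Start coordinate (bp) per gene; non-decreasing within a chromosome.

    Genes are stored sorted by (chromosome, start); the row position of a
    gene is its genome-wide ``order_index``.
    """

    gene_ids: np.ndarray
    chromosome: np.ndarray
    start: np.ndarray
    chrom_order: tuple = field(default=None)

    def __post_init__(self):
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        chromosome = np.asarray(self.chromosome, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        if not (len(gene_ids) == len(chromosome) == len(start)):
            raise ValueError("gene_ids, chromosome and start must have equal length")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        chrom_order = self.chrom_order
        if chrom_order is None:
            chrom_order = tuple(pd.unique(chromosome))
        rank = {c: i for i, c in enumerate(chrom_order)}
        try:
            key = np.array([rank[c] for c in chromosome])
        except KeyError as exc:  # chromosome missing from chrom_order
            raise ValueError(f"chromosome {exc} not in chrom_order") from exc
        order = np.lexsort((start, key))
        object.__setattr__(self, "gene_ids", gene_ids[order])
        object.__setattr__(self, "chromosome", chromosome[order])
        object.__setattr__(self, "start", start[order])
        object.__setattr__(self, "chrom_order", tuple(chrom_order))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def order_index(self) -> np.ndarray:
        """Genome-wide rank of every gene (0..n_genes-1)."""
        return np.arange(self.n_genes)

    def chromosome_slices(self) -> dict:
        """Mapping chromosome -> slice of contiguous rows."""
        out = {}
        chroms = self.chromosome
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            out[chroms[i]] = slice(i, j)
            i = j
        return out

    def index_of(self, gene_ids) -> np.ndarray:
        """Row positions of the given gene ids."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "start": self.start,
                "gene_id": self.gene_ids,
                "order_index": self.order_index,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        return cls(
            gene_ids=df["gene_id"].to_numpy(),
            chromosome=df["chromosome"].to_numpy(),
            start=df["start"].to_numpy(),
        )
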
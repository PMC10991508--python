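"""Ligand-receptor database handling and subclone communication calls.

The database is a ``ligand, receptor, location`` table
(location in {secreted, plasma_membrane}). The default edit set adds
nine literature-updated pairs (ANXA2-TLR4, CD24-SELE, CD24-L1CAM,
HMGB1-CD24, CXCL10-ACKR2, CXCL17-CXCR4, CXCL17-ACKR3, CD24-SIGLEC10,
S100A8-TLR2) and removes every interaction involving HSP90AA1.

Subclone-specific ligands/receptors must be (i) highly expressed in the
subclone — mean expression at least 50% of the maximum mean across all
populations, (ii) differentially expressed toward the subclone
(FDR < 0.05, log2FC > 1, both strict as stated), and (iii) detected in
at least 10% of the subclone's cells. Edges are weighted by the product
of mean ligand expression in the sender and mean receptor expression in
the receiver; an edge from a subclone to itself is an autocrine loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LRDatabase",
    "DEFAULT_ADDITIONS",
    "DEFAULT_REMOVALS",
    "load_lr_db",
    "demo_lr_table",
    "detection_filter",
    "subclone_candidates",
    "build_edges",
]

SECRETED, MEMBRANE = "secreted", "plasma_membrane"

#: literature-updated pairs appended to the base table
DEFAULT_ADDITIONS = (
    ("ANXA2", "TLR4", SECRETED),
    ("CD24", "SELE", MEMBRANE),
    ("CD24", "L1CAM", MEMBRANE),
    ("HMGB1", "CD24", SECRETED),
    ("CXCL10", "ACKR2", SECRETED),
    ("CXCL17", "CXCR4", SECRETED),
    ("CXCL17", "ACKR3", SECRETED),
    ("CD24", "SIGLEC10", MEMBRANE),
    ("S100A8", "TLR2", SECRETED),
)

#: genes whose interactions are removed wholesale
DEFAULT_REMOVALS = ("HSP90AA1",)


@dataclass
class LRDatabase:
    pairs: pd.DataFrame  # columns ligand, receptor, location

    def __post_init__(self):
        df = self.pairs
        for col in ("ligand", "receptor", "location"):
            if col not in df.columns:
                raise ValueError(f"LR table missing column {col!r}")
        if (df["ligand"].astype(str).str.len() == 0).any() or \
           (df["receptor"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene names in LR table")
        self.pairs = df.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)

    @property
    def ligands(self):
        return set(self.pairs["ligand"])

    @property
    def receptors(self):
        return set(self.pairs["receptor"])

    def receptors_of(self, ligand):
        return list(self.pairs.loc[self.pairs["ligand"] == ligand, "receptor"])

    def ligands_of(self, receptor):
        return list(self.pairs.loc[self.pairs["receptor"] == receptor, "ligand"])

    def __contains__(self, pair):
        ligand, receptor = pair
        return bool(((self.pairs["ligand"] == ligand)
                     & (self.pairs["receptor"] == receptor)).any())


def demo_lr_table() -> pd.DataFrame:
    """Small bundled demo pair table (stand-in for a full curated database)."""
    with resources.files("clonescape.data").joinpath("demo_lr_pairs.csv").open() as fh:
        return pd.read_csv(fh)


def load_lr_db(base_table=None, additions=DEFAULT_ADDITIONS,
               removals=DEFAULT_REMOVALS) -> LRDatabase:
    """Base table plus additions, minus every pair touching a removal gene.

    ``base_table`` may be a DataFrame or a CSV path with columns
    ``ligand,receptor,location``; by default the bundled demo table.
    An addition involving a removal gene is contradictory and raises.
    """
    if base_table is None:
        base = demo_lr_table()
    elif isinstance(base_table, pd.DataFrame):
        base = base_table.copy()
    else:
        base = pd.read_csv(base_table)
    removals = set(removals or ())
    add_rows = pd.DataFrame(list(additions or ()),
                            columns=["ligand", "receptor", "location"])
    bad = add_rows[add_rows["ligand"].isin(removals)
                   | add_rows["receptor"].isin(removals)]
    if len(bad):
        raise ValueError(
            f"additions collide with removal genes: {bad.to_dict('records')}"
        )
    merged = pd.concat([base, add_rows], ignore_index=True)
    keep = ~(merged["ligand"].isin(removals) | merged["receptor"].isin(removals))
    return LRDatabase(merged[keep].reset_index(drop=True))


def detection_filter(counts, gene_ids, labels, min_frac: float = 0.10) -> dict:
    """Genes detected (count > 0) in at least ``min_frac`` of each
    population's cells; genes below the fraction are excluded.

    Returns ``{population: set of detected genes}``.
    """
    counts = sp.csr_matrix(counts)
    gene_ids = np.asarray(gene_ids, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if len(labels) != counts.shape[0]:
        raise ValueError("labels must cover all units")
    detected = {}
    nz = (counts > 0).astype(np.int64)
    for pop in pd.unique(labels):
        mask = labels == pop
        frac = np.asarray(nz[mask].mean(axis=0)).ravel()
        detected[pop] = set(gene_ids[frac >= min_frac])
    return detected


def population_means(expr, gene_ids, labels) -> pd.DataFrame:
    """Mean log-normalised expression per population (populations x genes)."""
    expr = np.asarray(expr)
    labels = np.asarray(labels, dtype=object)
    rows = {pop: expr[labels == pop].mean(axis=0) for pop in pd.unique(labels)}
    return pd.DataFrame(rows, index=np.asarray(gene_ids, dtype=object)).T


def subclone_candidates(expr, gene_ids, labels, de_result: pd.DataFrame,
                        clone_a, clone_b, detection: dict = None,
                        fdr: float = 0.05, min_log2fc: float = 1.0,
                        max_frac: float = 0.5, min_detect_frac: float = 0.10
                        ) -> dict:
    """Up-regulated candidate genes per subclone.

    ``de_result`` is the Wilcoxon DE table for ``clone_a`` vs ``clone_b``
    (positive log2FC toward ``clone_a``). A gene qualifies for a clone
    iff its mean expression there is at least ``max_frac`` of the max
    mean across all populations, its adjusted P is below ``fdr`` with
    log2FC strictly above ``min_log2fc`` toward that clone, and it is
    detected in at least ``min_detect_frac`` of the clone's cells.
    """
    means = population_means(expr, gene_ids, labels)
    if detection is None:
        raise ValueError("detection sets required (see detection_filter)")
    max_mean = means.max(axis=0)
    out = {clone_a: set(), clone_b: set()}
    de = de_result.set_index("gene") if "gene" in de_result.columns else de_result
    for gene in means.columns:
        if gene not in de.index:
            continue  # no DE result for this gene; skipped
        row = de.loc[gene]
        for clone, sign in ((clone_a, 1.0), (clone_b, -1.0)):
            lfc = sign * row["log2fc"]
            if not (row["padj"] < fdr and lfc > min_log2fc):
                continue
            if max_mean[gene] > 0 and means.loc[clone, gene] < max_frac * max_mean[gene]:
                continue
            if gene not in detection.get(clone, ()):
                continue
            out[clone].add(gene)
    return out


def build_edges(candidates: dict, db: LRDatabase, expr, gene_ids, labels,
                detection: dict) -> pd.DataFrame:
    """Weighted sender->receiver ligand-receptor edges.

    For every subclone s and database pair (L, R): if L is an
    up-regulated candidate of s, an edge s -> p is emitted for every
    population p in which R is detected; symmetrically, if R is a
    candidate of s, an edge p -> s is emitted for every population p in
    which L is detected. Weight = mean expression of L in the sender
    times mean expression of R in the receiver; zero-weight edges are
    suppressed. ``autocrine`` flags sender == receiver.
    """
    means = population_means(expr, gene_ids, labels)
    populations = list(means.index)
    rows = []

    def emit(sender, ligand, receptor, receiver):
        if ligand not in means.columns or receptor not in means.columns:
            return
        weight = float(means.loc[sender, ligand] * means.loc[receiver, receptor])
        if weight <= 0:
            return
        loc = db.pairs.loc[(db.pairs["ligand"] == ligand)
                           & (db.pairs["receptor"] == receptor), "location"]
        rows.append({
            "sender": sender, "ligand": ligand, "receptor": receptor,
            "receiver": receiver, "weight": weight,
            "ligand_location": loc.iloc[0] if len(loc) else "",
            "autocrine": sender == receiver,
        })

    for clone, genes in candidates.items():
        for gene in sorted(genes):
            for receptor in db.receptors_of(gene):  # gene as ligand
                for p in populations:
                    if receptor in detection.get(p, ()):
                        emit(clone, gene, receptor, p)
            for ligand in db.ligands_of(gene):  # gene as receptor
                for p in populations:
                    if ligand in detection.get(p, ()):
                        emit(p, ligand, gene, clone)
    out = pd.DataFrame(
        rows, columns=["sender", "ligand", "receptor", "receiver", "weight",
                       "ligand_location", "autocrine"]
    )
    if len(out):
        out = out.drop_duplicates(
            subset=["sender", "ligand", "receptor", "receiver"]
        ).reset_index(drop=True)
    return out
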
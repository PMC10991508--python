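"""End-to-end orchestration with a single config and a run manifest.

``infer_subclones`` chains the spot-level stages (deconvolution,
background selection, residual smoothing, clustering, merging, HMM
calls, subclone/border classification) and is the workhorse used by the
CLI, the acceptance script and the tests. ``run_pipeline`` executes the
full synthetic end-to-end run — simulate, QC, decompose, infer-CNA,
classify, neighbours, communicate, scores — persisting every stage
output with a content-hash manifest so a run is reproducible and each
stage can be re-run from its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna, communication, decompose, io, neighbours, signatures
from .annotation import GeneAnnotation
from .simulate import simulate_cosmx, simulate_genome, simulate_visium

__all__ = ["SubcloneResult", "infer_subclones", "RunConfig", "run_pipeline"]

log = logging.getLogger("clonescape")

#: stage thresholds with their standard defaults
DEFAULT_THRESHOLDS = {
    "background_tumour_weight": 0.15,
    "cna_window_genes": 101,
    "cna_gene_cutoff": 0.1,
    "merge_min_de_genes": 10,
    "neighbour_radii": [110.0, 340.0, 648.0],
    "n_permutations": 1000,
    "significance_alpha": 0.05,
    "de_min_log2fc": 1.0,
    "lr_min_detection_frac": 0.10,
    "lr_max_expression_frac": 0.50,
    "qc_spot_min_genes": 400,
    "qc_sc_min_genes": 500,
    "qc_sc_min_umis": 1000,
    "qc_sc_max_mito_frac": 0.15,
    "qc_cosmx_min_transcripts": 100,
}


@dataclass
class SubcloneResult:
    weights: pd.DataFrame
    background_ids: set
    profile: cna.CnaProfile
    cluster_labels: pd.Series  # over non-background units
    callset: cna.CnaCallSet
    classification: pd.DataFrame

    @property
    def subclone_clusters(self):
        return list(self.classification.index[
            self.classification["label"] == cna.SUBCLONE])

    @property
    def border_clusters(self):
        return list(self.classification.index[
            self.classification["label"] == cna.BORDER])


def infer_subclones(ds, annotation: GeneAnnotation, reference,
                    tumour_type: str = "tumour",
                    background_threshold: float = 0.15,
                    cutoff: float = 0.1, window: int = 101,
                    cluster_k: int = 14, min_de_genes: int = 10,
                    refine_iters: int = 3, min_units: int = 5,
                    tumour_weight_feature: float = 10.0
                    ) -> SubcloneResult:
    """Full spot-level subclone inference on one sample.

    Spots with tumour weight below ``background_threshold`` anchor the
    residuals; the remaining spots are over-clustered into ``cluster_k``
    groups on the smoothed (PCA-denoised) profiles augmented with the
    scaled tumour weight (``tumour_weight_feature`` x weight) — tumour
    content is what separates a stroma-diluted border band from its
    parent clone, exactly as it separates them biologically. Clusters
    separated by fewer than ``min_de_genes`` DE genes and indistinct in
    CNA-profile space are merged — the merge chain, not the initial cut,
    decides the effective cluster count — and boundary spots are cleaned
    by a few nearest-centroid reassignment iterations before segments
    are called and classified.
    """
    weights = decompose.decompose_units(ds.counts, ds.gene_ids, reference,
                                        unit_ids=ds.spot_ids)
    background = decompose.select_background(weights, tumour_type,
                                             background_threshold)
    resid = cna.relative_expression(ds.counts, ds.spot_ids, ds.gene_ids,
                                    background, cutoff=cutoff)
    profile = cna.smooth_windows(resid, annotation, window=window)
    fg_mask = ~profile.values.index.isin(list(background))
    fg_profile = cna.CnaProfile(
        values=profile.values.loc[fg_mask],
        chromosomes=profile.chromosomes,
        order_index=profile.order_index,
        window=profile.window,
    )
    k0 = min(cluster_k, fg_mask.sum())
    tw_feature = (tumour_weight_feature
                  * weights.loc[fg_profile.values.index, tumour_type]
                  .fillna(0.0).to_numpy()[:, None])
    labels = cna.cluster_profiles(fg_profile, n_clusters=k0,
                                  extra_features=tw_feature)
    fg_idx = np.flatnonzero(np.isin(ds.spot_ids, labels.index))
    fg_counts = ds.counts[fg_idx]
    # merge/refine twice: the first refinement cleans boundary spots, after
    # which same-genotype splits that evaded the first merge are no longer
    # extreme noise selections and collapse in the second round
    for _ in range(2):
        labels = cna.merge_clusters(labels, fg_counts, ds.gene_ids,
                                    min_de_genes=min_de_genes,
                                    profile=fg_profile,
                                    unit_weights=weights[tumour_type])
        if refine_iters:
            labels = cna.refine_assignments(fg_profile, labels,
                                            n_iter=refine_iters,
                                            extra_features=tw_feature)
    # same-genotype splits that survive (extra noise calls, attenuated
    # echoes) collapse on profile collinearity and call-set equivalence
    labels = cna.merge_collinear_clusters(fg_profile, labels)
    labels, callset = cna.merge_equivalent_callsets(fg_profile, labels,
                                                    min_units=min_units)
    classification = cna.classify_clusters(callset, weights[tumour_type], labels)
    return SubcloneResult(weights=weights, background_ids=background,
                          profile=profile, cluster_labels=labels,
                          callset=callset, classification=classification)


# ---------------------------------------------------------------------------
# config + end-to-end run
# ---------------------------------------------------------------------------

STAGES = ("simulate", "qc", "decompose", "infer_cna", "classify",
          "neighbours", "communicate", "scores")


@dataclass
class RunConfig:
    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 5
    visium: dict = field(default_factory=dict)
    cosmx: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    annotation_path: str = None
    stages: tuple = STAGES

    def __post_init__(self):
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        if "infer_cna" in self.stages and "simulate" not in self.stages \
                and not self.annotation_path:
            raise ValueError(
                "config field 'annotation_path' is required when the "
                "infer_cna stage is enabled without the simulate stage"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``manifest.json``): stage
    parameters, seeds, thresholds and the SHA-256 of every output file.
    Any stage failure aborts with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest = {"seed": config.seed, "thresholds": thr, "stages": []}
    state = {}

    def record(stage, params, outputs):
        manifest["stages"].append({
            "stage": stage,
            "params": params,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        })
        log.info("stage %s complete (%d outputs)", stage, len(outputs))

    def run_stage(stage, fn):
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    rng = np.random.default_rng(config.seed)

    def stage_simulate():
        annotation = simulate_genome(config.n_genes, config.n_chromosomes,
                                     seed=int(rng.integers(2 ** 31)))
        vis, vis_truth = simulate_visium(annotation,
                                         seed=int(rng.integers(2 ** 31)),
                                         **config.visium)
        cos, cos_truth = simulate_cosmx(annotation,
                                        seed=int(rng.integers(2 ** 31)),
                                        **config.cosmx)
        state.update(annotation=annotation, vis=vis, vis_truth=vis_truth,
                     cos=cos, cos_truth=cos_truth)
        io.write_gene_annotation(annotation, outdir / "genes.bed.tsv")
        io.write_spot_dataset(vis, outdir / "visium")
        io.write_cell_dataset(cos, outdir / "cosmx")
        io.write_truth(vis_truth, outdir / "visium_truth.json")
        io.write_truth(cos_truth, outdir / "cosmx_truth.json")
        record("simulate",
               {"n_genes": config.n_genes, "n_chromosomes": config.n_chromosomes},
               [outdir / "genes.bed.tsv", outdir / "visium_truth.json",
                outdir / "cosmx_truth.json",
                *sorted((outdir / "visium").iterdir()),
                *sorted((outdir / "cosmx").iterdir())])

    def stage_qc():
        state["vis"] = io.qc_filter_spots(state["vis"],
                                          thr["qc_spot_min_genes"])
        state["cos"] = io.qc_filter_cells_cosmx(state["cos"],
                                                thr["qc_cosmx_min_transcripts"])
        summary = outdir / "qc_summary.json"
        summary.write_text(json.dumps({
            "spots_retained": int(state["vis"].n_spots),
            "cells_retained": int(state["cos"].n_cells),
        }, sort_keys=True))
        record("qc", {"spot_min_genes": thr["qc_spot_min_genes"],
                      "cosmx_min_transcripts": thr["qc_cosmx_min_transcripts"]},
               [summary])

    def stage_decompose():
        reference = state["vis_truth"].reference_profiles()
        weights = decompose.decompose_units(
            state["vis"].counts, state["vis"].gene_ids, reference,
            unit_ids=state["vis"].spot_ids)
        state["reference"], state["weights"] = reference, weights
        path = outdir / "weights.tsv"
        weights.to_csv(path, sep="\t")
        record("decompose", {"method": "simplex-projected NNLS"}, [path])

    def stage_infer_cna():
        result = infer_subclones(
            state["vis"], state["annotation"], state["reference"],
            background_threshold=thr["background_tumour_weight"],
            cutoff=thr["cna_gene_cutoff"], window=thr["cna_window_genes"],
            min_de_genes=thr["merge_min_de_genes"])
        state["subclones"] = result
        calls = outdir / "cna_calls.tsv"
        result.callset.to_frame().to_csv(calls, sep="\t", index=False)
        labels = outdir / "cna_clusters.tsv"
        result.cluster_labels.rename("cluster").to_csv(labels, sep="\t")
        record("infer_cna", {"window": thr["cna_window_genes"],
                             "cutoff": thr["cna_gene_cutoff"]},
               [calls, labels])

    def stage_classify():
        path = outdir / "clone_classes.tsv"
        state["subclones"].classification.to_csv(path, sep="\t")
        record("classify", {"rule": "unique high-confidence segments"}, [path])

    def stage_neighbours():
        cos = state["cos"]
        focal = [g.clone_id for g in state["cos_truth"].genotypes]
        stats = neighbours.enrichment_depletion_test(
            cos.centroids, cos.type_label, focal,
            radii=thr["neighbour_radii"], n_perm=thr["n_permutations"],
            alpha=thr["significance_alpha"],
            seed=int(rng.integers(2 ** 31)))
        path = outdir / "neighbour_stats.tsv"
        stats.to_csv(path, sep="\t", index=False)
        state["neighbour_stats"] = stats
        record("neighbours", {"radii": thr["neighbour_radii"],
                              "n_perm": thr["n_permutations"]}, [path])

    def stage_communicate():
        cos = state["cos"]
        truth = state["cos_truth"]
        clones = [g.clone_id for g in truth.genotypes][:2]
        expr = io.normalize_lognorm(cos.counts)
        lab = cos.type_label
        ia = np.flatnonzero(lab == clones[0])
        ib = np.flatnonzero(lab == clones[1])
        de = signatures.wilcoxon_de(expr, cos.gene_ids, ia, ib,
                                    min_log2fc=thr["de_min_log2fc"])
        detection = communication.detection_filter(
            cos.counts, cos.gene_ids, lab,
            min_frac=thr["lr_min_detection_frac"])
        db = communication.load_lr_db()
        cands = communication.subclone_candidates(
            expr, cos.gene_ids, lab, de, clones[0], clones[1],
            detection=detection, fdr=thr["significance_alpha"],
            min_log2fc=thr["de_min_log2fc"],
            max_frac=thr["lr_max_expression_frac"],
            min_detect_frac=thr["lr_min_detection_frac"])
        edges = communication.build_edges(cands, db, expr, cos.gene_ids,
                                          lab, detection)
        path = outdir / "lr_edges.tsv"
        edges.to_csv(path, sep="\t", index=False)
        state["lr_edges"] = edges
        record("communicate", {"min_frac": thr["lr_min_detection_frac"],
                               "min_log2fc": thr["de_min_log2fc"]}, [path])

    def stage_scores():
        vis = state["vis"]
        expr = io.normalize_lognorm(vis.counts)
        truth = state["vis_truth"]
        # demo gene sets: each clone's amplified genes as a signature
        gene_sets = {}
        for g in truth.genotypes:
            genes = []
            for seg in g.unique_segments:
                if seg.log2_effect > 0:
                    genes.extend(state["annotation"].gene_ids[
                        seg.start_index:seg.end_index])
            if genes:
                gene_sets[g.clone_id] = genes
        scores = signatures.module_score_table(
            expr, vis.gene_ids, gene_sets,
            seed=int(rng.integers(2 ** 31)))
        scores.index = vis.spot_ids
        path = outdir / "module_scores.tsv"
        scores.to_csv(path, sep="\t")
        record("scores", {"n_sets": len(gene_sets)}, [path])

    fns = {"simulate": stage_simulate, "qc": stage_qc,
           "decompose": stage_decompose, "infer_cna": stage_infer_cna,
           "classify": stage_classify, "neighbours": stage_neighbours,
           "communicate": stage_communicate, "scores": stage_scores}
    for stage in STAGES:
        if stage in config.stages:
            run_stage(stage, fns[stage])

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
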
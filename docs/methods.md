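# Methods

## Overview

`clonescape` reconstructs tumour subclonal structure from spatial
transcriptomics and asks how subclones interact with their
microenvironment. It operates at two resolutions:

* **spot level** (Visium-like): barcoded 55 µm spots, each a mixture of
  ~1–10 cells. Copy-number alterations (CNAs) are inferred from smoothed
  relative expression, spots are clustered by CNA profile, and clusters
  are classified as *subclones* (carrying at least one private
  high-confidence CNA), *border* regions (tumour/stroma mixtures whose
  CNAs are all attenuated copies of another cluster's), or *background*
  (low-tumour spots that anchor the inference);
* **cell level** (CosMx-like): segmented cells with centroid
  coordinates. Radius neighbour graphs and two Monte-Carlo permutation
  tests quantify which cell types are enriched or depleted around the
  tumour clones, and a ligand–receptor analysis calls subclone-specific
  signalling edges, including autocrine loops.

A synthetic-data module generates both modalities with planted ground
truth; every recovery claim in the test-suite is a comparison against
that truth.

## Synthetic data

**Expression model.** Gene baseline abundances are log-normal
(σ = 1). Each cell type up-shifts its own random 5% marker subset by
2². Clone profiles multiply the tumour base profile by `2^e` on each
planted segment (default |e| = 0.5) and are renormalised, so extra
copies raise a segment's share of the library rather than the library
itself. Counts are negative binomial with mean `μ` and dispersion `θ`
(variance `μ + μ²/θ`, default θ = 2): the standard overdispersed choice
for RNA counts. Spot depth is 6,000 counts (log-normal CV 15%), near
the median library size of real spot data; cell depth is 300 counts on
a 960-gene panel.

**Genotypes.** Clones share `n_shared` segments and carry private
segments that are pairwise disjoint across clones (placed without
overlap, never crossing a chromosome boundary, ≥10-gene gaps).
Amplifications and deletions alternate.

**Spot geometry.** Clone territories are contiguous blobs grown from
separated seeds on the spot grid (spacing 100 units); territory spots
are 85% clone / 15% stroma. The band of spots surrounding the first
clone's territory is a 50/50 clone/stroma *border*; remaining spots are
80/20 stroma/immune background. Compositions are exact (no per-spot
jitter), so the truth record is unambiguous.

**Cell geometry.** The overall density is set so a cell has ~3
neighbours within 110 px, matching the reported median. Tumour clones
occupy equal-area discs at 3× bulk density. Each non-malignant cell
picks a region with probability ∝ area × multiplier, so a niche
multiplier `m` for type *t* near clone *a* makes the expected density of
*t* inside *a*'s territory exactly `m`× the bulk; the default plants
T cells at 2× near one clone and fibroblasts at 2× near the other.
Cells fall into a near-square grid of fields of view (default 20).

**What is not emulated.** Segmentation errors and doublets, spatial
expression gradients within a cell type, platform/batch effects,
gene-length and GC biases, cell-cycle structure, and continuous purity
gradients (compositions are two-level: territory vs border). Passing
tests therefore demonstrate correctness of the statistical machinery
under a faithful but idealised tissue, not robustness to segmentation
or batch artefacts.

## CNA inference and subclone classification

1. **Residuals.** Genes with mean raw count < 0.1 are dropped. Each
   unit's `log2(1 + 10⁴·c/total)` profile minus the background-spot
   mean gives the residual; residuals are clipped at ±3 background SDs
   (one global scale). Background = spots with estimated tumour weight
   strictly below 0.15, from a simplex-projected non-negative
   least-squares decomposition against library-normalised reference
   profiles (weights renormalised to sum 1; all-zero units flagged).
2. **Smoothing.** Centred moving average over min(101, genes on the
   chromosome) genes, truncated at chromosome edges; windows never
   cross chromosomes. Units are re-centred by their median.
3. **Clustering.** Profiles are projected on their 10 leading principal
   components (genotype structure is low-rank; window noise is not) and
   the scaled tumour weight (×10) is appended — tumour content is what
   separates a stroma-diluted border from its parent clone. Ward
   linkage over-clusters to k = 14; the *merge chain* then decides the
   effective cluster count:
   * clusters merge when they have fewer than 10 Wilcoxon DE genes
     (BH FDR < 0.05, |log2FC| > 0.25) **and** are indistinct in profile
     space (< 200 genes differing by > 0.1 log2 — a genuine CNA
     difference spans a segment-scale stretch; noise splits only
     produce scattered short excursions) **and** have similar tumour
     weight (gap < 0.15). Merging and nearest-centroid refinement run
     twice;
   * clusters whose mean profiles are collinear at equal scale
     (correlation ≥ 0.97 and mutual regression slopes in [0.8, 1.25]
     over genes where either profile exceeds 0.15) are the same
     genotype and merge; a border is equally correlated with its parent
     but at slope ≈ purity ratio, and sibling clones decorrelate on
     their private segments;
   * clusters whose high-confidence call sets mutually explain each
     other merge (see segment identity below).
4. **Segment calls.** Per cluster and chromosome, a 3-state Gaussian
   HMM (deletion / neutral / amplification; means −μ, 0, +μ; shared SD;
   self-transition 0.99) is decoded on the cluster-mean profile. The
   emission SD is the standard error of the cluster mean (median
   per-gene SD / √n); μ is the median |value| of the beyond-3σ tail.
   A Viterbi segment is *high-confidence* when its mean state posterior
   is ≥ 0.5, its amplitude is ≥ 0.1 log2 and its length is ≥ half the
   smoothing window (narrower features are below the method's
   resolution).
5. **Segment identity & classification.** A call in cluster A is
   *explained by* cluster B when a same-state call of B covers ≥ 50% of
   its genes at comparable-or-greater amplitude (≥ 0.8×): stromal
   mixing attenuates residuals, so an attenuated echo never explains
   the original. A cluster with ≥ 1 unexplained call is a *subclone*; a
   cluster whose calls are all explained is a *border*, unless its mean
   tumour weight exceeds every candidate parent's (diluting with stroma
   can only lower tumour content, so the purer twin of such a pair is
   the genotype).

Degenerate inputs: clusters below 5 units get no calls (warning); an
empty background set is a hard error; a zero-variance cluster falls
back to the background residual SD.

## Permutation tests

Two cells are neighbours when their centroid distance is strictly below
the radius (defaults 110/340/648 px, graph built with a k-d tree and
exact-distance filtering). Both tests use the add-one empirical P
convention, `(1 + #{null ≥ obs}) / (n_perm + 1)`, report both one-sided
tails, and apply BH per radius across neighbour types.

* **Enrichment/depletion:** focal (tumour) positions stay fixed; the
  positions of each other type are re-drawn without replacement from
  the occupied non-focal positions (the null stays inside the tissue
  geometry). The statistic is the proportion of the type among all
  neighbours of focal cells; because positions are only relabelled, it
  reduces to a weighted subset sum and permutations are exact integer
  comparisons.
* **Clone comparison:** the statistic is the difference in heterotypic
  neighbour composition between two clones; the null permutes the
  labels of the pooled neighbouring non-tumour cells.

With few neighbours the statistic is discrete and ties make the
empirical P conservative (super-uniform); the type-I rate reaches the
nominal level in denser regimes (~8 neighbours per cell).

## Communication analysis

The ligand–receptor table (`ligand, receptor, location`) is edited on
load: nine literature-updated pairs are added and every interaction
involving HSP90AA1 removed. A gene qualifies as a subclone-specific
ligand/receptor when (i) its mean log-normalised expression in the
subclone is ≥ 50% of the maximum mean across all populations, (ii) it
is DE toward the subclone (Wilcoxon, FDR < 0.05, log2FC > 1, both
strict), and (iii) it is detected (count > 0) in ≥ 10% of the
subclone's cells. Edges are weighted by mean ligand expression in the
sender × mean receptor expression in the receiver; zero-weight edges
are suppressed; sender = receiver flags an autocrine loop. All
thresholds are monotone: raising them never adds edges.

## Scores, annotation, correlations

* **Module scores:** genes are ranked by dataset-wide average and split
  into 24 equal-frequency bins; each signature gene contributes up to
  100 control genes sampled from its bin (signature genes excluded).
  Score = mean signature expression − mean control expression, so
  unit-level offsets cancel exactly. A dataset-wide shift of the
  signature genes is recovered up to the top-bin selection bias
  (≈ 2.5 σ/√n_units; ~6% of a 1-log shift at 500 units).
* **Nearest-reference annotation:** Spearman correlation against
  reference profiles over shared genes (≥ 50 required); ties are broken
  toward the first reference type and flagged; constant profiles are
  `unassigned`.
* **Ligand–infiltrate correlations:** Spearman ρ with BH adjustment per
  (ligand, cell-type-weight) pair across shared units (≥ 10 required);
  constant vectors are flagged undefined.
* **DE:** two-sided Wilcoxon rank-sum on log-normalised values
  (exact for small tie-free groups), fold change =
  `log2(mean_a + 1e-9) − log2(mean_b + 1e-9)` on de-logged normalised
  means, BH or Bonferroni adjustment.

## Problem sizes

The test-suite and the acceptance script run the spot-level study at
2,000 genes × 5 chromosomes × ~2,000 spots over 10 seeds; permutation
calibration uses 500 null datasets of 400 cells at 200 permutations
(scaled down from 1,000); power uses 20 runs of 4,000 cells at 1,000
permutations; communication recovery uses 10 runs of 3,000 cells with
5 planted autocrine loops among 15 decoy pairs. These sizes were chosen
so each study completes in minutes on a single core while keeping
Monte-Carlo error well below the decision margins.

## Known limitations

* The decomposition is a least-squares stand-in: it preserves the
  tumour-weight ordering and the 0.15 background cut but is not a
  generative count model, and per-gene overdispersion leaves a noise
  floor on weights that depth does not reduce.
* CNA calls are relative expression states, not integer copy numbers;
  segments shorter than half the smoothing window are invisible by
  construction.
* The border/subclone tie-break assumes borders dilute an existing
  clone; a genuine subclone with uniformly weaker dosage effects and
  lower purity than all siblings would be labelled border.
* The merge chain's profile-distinctness scale (0.1 log2, 200 genes)
  presumes segment-scale CNAs; datasets whose true CNAs are much
  shorter than the smoothing window need a smaller window first.
* Empirical P values are conservative when cells have very few
  neighbours (discrete statistics).
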
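# clonescape

Spatially resolved tumour-subclone analysis for high-grade serous
ovarian carcinoma (HGSOC) and similar CNA-driven cancers: infer
copy-number-based subclones from spot-level spatial transcriptomics,
test how cell types distribute around subclones at single-cell
resolution, and call subclone-specific ligand–receptor signalling,
including autocrine loops.

It is written for computational biologists who have Visium-style spot
data (counts + array coordinates) and/or CosMx-style single-cell
spatial data (counts + centroids + fields of view) and want a tested,
scriptable pipeline rather than a collection of notebook fragments. A
first-class synthetic-data module generates both modalities with
planted ground truth, which is what the test-suite measures recovery
against.

## The model in brief

**CNA inference.** For spot *s* and gene *g* (ordered by chromosome and
position), the relative expression residual is

    r_sg = log2(1 + 10^4 c_sg / C_s) − mean over background spots of the same,

where the *background* is the set of spots with estimated tumour weight
< 0.15 (simplex-constrained NNLS against reference cell-type profiles).
Residuals are averaged over a 101-gene sliding window within each
chromosome and median-centred per spot. Spots are clustered on the
smoothed profiles (Ward on the leading principal components plus the
tumour weight); clusters with fewer than 10 DE genes that are also
indistinct in CNA-profile space are merged. Per cluster, a 3-state
Gaussian HMM (deletion / neutral / amplification) segments the mean
profile; segments with posterior ≥ 0.5, amplitude ≥ 0.1 log2 and
length ≥ half a window are *high-confidence*. A cluster is a
**subclone** iff it has a high-confidence segment found in no other
cluster; a cluster whose segments are all attenuated copies of other
clusters' is a **border** (tumour/stroma mixture, not a genotype).

**Neighbourhood statistics.** Cells are neighbours when their centroid
distance is strictly below a radius (110/340/648 px by default). Two
Monte-Carlo tests with add-one empirical P values and BH correction:
enrichment/depletion of each cell type around the (fixed) tumour cells
under position resampling, and a two-clone comparison of heterotypic
neighbour composition under label permutation.

**Communication.** Ligands/receptors qualify for a subclone when their
mean expression is ≥ 50% of the max across populations, they are DE
toward the subclone (FDR < 0.05, log2FC > 1) and detected in ≥ 10% of
its cells. Edge weight = mean ligand expression in the sender × mean
receptor expression in the receiver; sender = receiver is an autocrine
loop.

See `docs/methods.md` for the full parameterisation and its rationale.

## Worked example

```python
import clonescape as cs
from clonescape.pipeline import infer_subclones

ann = cs.simulate_genome(n_genes=2000, n_chromosomes=5, seed=7)
ds, truth = cs.simulate_visium(ann, seed=7)     # ~2,000 spots, 3 clones
res = infer_subclones(ds, ann, truth.reference_profiles())
print(res.classification)
```

prints

```
            label  n_segments  n_unique_segments  mean_tumour_weight
cluster
0          border           3                  0            0.548885
2        subclone           3                  1            0.835507
3          border           0                  0            0.187101
5        subclone           3                  1            0.834530
6        subclone           3                  1            0.831650
```

Three clusters carry a private high-confidence CNA each — the three
planted subclones. Cluster 0 sits at intermediate tumour weight and
every one of its segments is an attenuated copy of a subclone's — the
planted 50/50 clone/stroma border band. Cluster 3 has no calls at all
(low-tumour spots that cleared the 0.15 background cut). The calls
themselves are in `res.callset.to_frame()`:

```
   cluster chromosome  start_index  end_index          state  mean_residual  posterior  n_genes
0        0       chr1          122        341       deletion      -0.125285   0.997859      218
1        0       chr4         1371       1600       deletion      -0.142220   0.999968      229
2        0       chr5         1600       1856  amplification       0.192965   0.999978      256
3        2       chr1          139        349       deletion      -0.183120   0.999534      209
...
```

— note cluster 0's residuals are ~0.6× cluster 2's on the same
segments, the attenuation signature of a stromal mixture.

The same stages are available from the shell:

```sh
clonescape simulate --mode visium --seed 7 --out sim/
clonescape decompose --ref ref.csv --counts sim/ --out decomp/
clonescape infer-cna --counts sim/ --annotation sim/genes.bed.tsv \
    --background-ids decomp/background_ids.txt --out cna/
clonescape neighbours --counts cells/ --focal clone_0 --focal clone_1 \
    --radii 110,340,648 --n-perm 1000 --seed 1 --out stats.tsv
clonescape run --config config.yaml --out run/    # full pipeline + manifest
```

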
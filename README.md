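# tlsarch

Statistical toolkit for studies of **tertiary lymphoid structure (TLS)
maturity** in tumors. TLS are ectopic lymphoid aggregates whose maturation
state — absent (nTLS), immature (imTLS), or mature with a germinal center
(mTLS) — shapes local anti-tumor immunity. Single-cell studies of TLS
combine several data modalities, each with its own bespoke statistic; this
package implements that statistical layer as tested, composable library
code, exercised end-to-end on synthetic cohorts with planted effects:

* **QC filtering** of cell × gene count matrices (strict-inequality
  thresholds: cells with <200 or >4000 detected genes, >20% mitochondrial
  content, >25,000 UMIs, or doublet score >0.2 excluded; genes in <3 cells
  dropped).
* **Compositional enrichment**: for each cell cluster *c* and status pair
  (A, B), a binomial GLM with logit link on one-vs-rest membership,
  membership ~ status; the contrast is the difference of estimated marginal
  means on the logit scale, reported as
  log₂OR = (logit π̂_A − logit π̂_B)/ln 2 with Wald SE and
  Bonferroni-adjusted p over the rendered grid.
* **Embedding density contrasts**: per-status product-Gaussian KDE on a
  shared grid over a 2-D embedding (UMAP coordinates are an input), with
  node-wise contrasts f̂_A − f̂_B between unit-mass densities.
* **Repertoire analysis**: receptor-class calling (ambiguous = TCR+BCR
  chains; multichain = >2 chains of one paired arm), TCR clonotypes by
  exact paired CDR3-nucleotide identity, BCR clonotypes by single-linkage
  clustering of heavy-chain junctions within (V, J, junction-length)
  partitions at a data-driven threshold, clonal expansion (≥2 cells),
  diversity (Shannon entropy −Σ pᵢ ln pᵢ and D50), and cross-cluster
  clonotype sharing.
* **Gene-set activity**: rank-based AUC scoring per cell (area under the
  recovery curve over the top 5% of ranks, normalized to [0, 1]), with the
  bundled 12-chemokine, 29-gene TLS-imprint, and T-cell-state signatures.
* **Spatial co-occurrence** of deconvolved cell-type abundances C over N
  capture spots: score(A,B) = (Σⱼ C_Aj·C_Bj / N) × 1000.
* **Imaging proximity**: per-core nearest-neighbor distances between
  phenotype-labeled cell positions, medians grouped by TLS status.

A synthetic-data module generates every input with known planted
parameters (exact one-vs-rest odds ratios, clonotype sharing
probabilities, co-localization loadings, Neyman–Scott clustering), so each
statistic has a parameter-recovery test without controlled-access data.

## Worked example

`analysis/` contains numbered drivers that build a synthetic cohort
(3 statuses × 4 samples × 2,000 cells, 300 spatial spots, 6 imaging cores)
and run every stage. After `python analysis/01_simulate_cohort.py`:

```
$ python analysis/03_composition_enrichment.py
mTLS-vs-nTLS log2 odds ratios (planted: Tstem +1.5, Tex -1.0):
cluster   log2_or         p_adj
Myeloid -0.502699  2.391101e-18
    Tex -1.009323  3.964537e-64
  Tstem  1.459365 2.126992e-191
    Bgc -0.509785  3.567122e-19
```

The planted +1.5 enrichment of the stem-like T cluster and −1.0 depletion
of the exhausted cluster in mTLS are recovered (the untouched clusters show
the compensating mass shift). Likewise:

```
$ python analysis/05_repertoire.py
receptor classes: {'TCR': 17833, 'BCR': 5476, 'ambiguous': 451, 'multichain': 240}
TCR clonotypes: 8178, BCR clonotypes: 2936 (clonal distance threshold 0.284)
...
Tstem-Tex shared clonotypes: 1131 -> sharing probability estimate 0.293 (planted 0.3)
```

The CLI exposes the same stages
(`tlsarch simulate|qc|enrich|density|repertoire|score|cooccur|proximity|run`);
`tlsarch run --config cfg.yaml` executes a configured pipeline and writes a
manifest with deterministic output checksums.

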
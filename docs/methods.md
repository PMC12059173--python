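# Methods

This note documents the models and procedures implemented in `tlsarch`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Quality control

Cell exclusion uses strict inequalities — a cell is removed only when its
detected-gene count is *below* 200 or *above* 4,000, its mitochondrial
percentage *exceeds* 20, its UMI total *exceeds* 25,000, or its doublet
score *exceeds* 0.2 — so boundary cells are kept. Doublet scores are an
upstream input; when absent the rule is skipped with a warning rather than
failing. Genes detected in fewer than 3 cells are dropped first, and
per-cell metrics are recomputed on the gene-filtered matrix before
thresholding (a flag restores the un-recomputed variant). The removal
report attributes each lost cell to its first failing rule in a fixed
order (genes-low, genes-high, mito, UMI, doublet) purely for accounting;
the keep mask is the conjunction of all rules. Mitochondrial genes default
to the human `MT-` prefix and are overridable.

## Compositional enrichment

Cluster membership is treated as a binary choice per cell and modeled as
binomial with a logit link, status as the sole factor, separately per
cluster (one-vs-rest) and compartment. For a single categorical factor the
estimated marginal means on the logit scale are the empirical logits, so
each contrast equals the log odds ratio of the corresponding 2×2
contingency table; the GLM route is retained (and tested against the
closed form to ≤1e-6) because it supplies the Wald covariance used for
standard errors and p-values. Cells are pooled across samples within
status; a per-sample aggregation mode keeps sample-level rows in the fit,
which leaves the maximum-likelihood estimate unchanged (the likelihood
factorizes over rows with a shared status parameter) but is useful for
diagnostics. When a cluster is empty (or exhaustive) in one status, 0.5 is
added to all four cells of the implied 2×2 table (Haldane–Anscombe) and
the model refitted on the pseudo-counts; such results carry a
`zero_corrected` flag. The Bonferroni family is the rendered grid —
clusters × pairwise status contrasts — i.e. per-panel adjustment; the
family policy is configurable. Dot-plot columns emit log₂OR as color and
−log₁₀ adjusted p (capped, default 10) as size.

## Embedding density contrasts

Densities use a product-Gaussian kernel evaluated exactly on a regular
grid (default 100×100 over the pooled bounding box padded by 3
bandwidths). Bandwidths follow the normal-reference rule per axis,
h = σ̂ · n^(−1/6) (the rate for a 2-D product kernel), computed on the
*pooled* embedding and shared across statuses: contrasting densities
smoothed at different scales would confound distribution shape with
smoothing. Each status is normalized to unit mass before differencing, so
contrasts compare shape rather than cell abundance; an unnormalized mode
weights each map by its cell-count share. Degenerate (zero-variance) axes
fall back to a fixed minimal bandwidth of 1e-6. Per-cluster versus
per-compartment granularity is a grouping flag; neither is asserted as
canonical. Exact node-wise antisymmetry and the three-status cyclic
identity c(A,B)+c(B,C)+c(C,A)=0 follow from the shared grid and are
enforced by tests.

## Repertoire analysis

Chain records use the AIRR Rearrangement vocabulary; a mapping layer
accepts 10x-style contig CSVs. Cells with at least one TR and one IG locus
are *ambiguous*; cells with more than two chains of one paired arm
(TRA | TRB for T cells, IGH | IGK+IGL for B cells) are *multichain* —
i.e. one secondary alpha or light chain is tolerated, a third is not.
Both classes are excluded from clonotype calling.

TCR clonotypes require exact CDR3-nucleotide identity on both arms: the
key is (sorted TRA junctions, sorted TRB junctions), so single-arm cells
form keys distinct from paired keys and all arms of a dual-alpha cell
enter the key. BCR clonotypes are called within (IGH V gene, J gene,
junction length) partitions by single-linkage hierarchical clustering on
the normalized Hamming distance of heavy-chain junctions, cut at a
threshold; single linkage is the chain-friendly choice for clonal variants
accumulated along a mutation lineage. Light chains do not enter the
distance. Ambiguous multi-gene V/J calls resolve to the first listed gene.
The threshold is estimated from the distance-to-nearest distribution
(each heavy chain's distance to its closest non-identical neighbor within
its partition): with clonal relatives present this distribution is
bimodal, and the threshold is the minimum-density valley between the two
largest modes of a Gaussian KDE on the unique distances (uniqueness makes
the estimate invariant to duplicating sequences). With fewer than 20 heavy
chains or no detectable bimodality it falls back to 0.15 with a warning.

A clonotype is *expanded* (clonal) when present in ≥2 cells, counted over
all assigned cells regardless of cluster. Diversity per group reports
Shannon entropy in natural log and D50 as the percent of clonotypes
(largest first) whose cumulative cell fraction first reaches ≥0.5 — ties
resolve to the first index reaching half. The sharing matrix counts
clonotypes with at least one cell in each of two clusters (diagonal =
clonotypes present in the cluster), optionally decomposed by status; the
shared-feature fraction divides spanning clonotypes by clonotypes present
in either group, per sample or pooled (per-sample default, matching
per-sample box-plot style reporting).

## Gene-set activity

The per-cell score ranks genes by descending expression (ties broken
deterministically by gene index; a seeded random tie-break is available),
walks the top ⌈0.05·n_genes⌉ ranks, accumulates the recovery curve of
set-gene hits, and normalizes its area by the maximum attainable for the
set size — so 1 means the set occupies the very top ranks and 0 means no
set gene enters the window. Because only within-cell ranks matter, the
score is invariant to any monotone per-cell transform; raw counts and
log-normalized values give identical results. The top fraction (0.05) is
the conventional default for this family of scores. The bundled
signatures (12-chemokine, 29-gene TLS imprint, naive, cytotoxicity,
proliferation, progenitor-exhausted/Tfh, terminally exhausted) are
shipped verbatim as printed in their sources; `PTLP` in the TLS imprint is
kept as printed even though it likely denotes PLTP. The separate scaled
module score (for plotting along an externally supplied cell ordering,
e.g. pseudotime) log-normalizes to 10⁴ counts, z-scores per gene, averages
over the set (dropping zero-variance genes with a warning), and min–max
scales to [0, 1], returning 0.5 when all cells tie.

## Spatial co-occurrence

With C the spots × types abundance matrix, score(A,B) =
(Σⱼ C_Aj·C_Bj / N) × 1000, computed for all pairs as CᵀC/N × 1000.
Abundances are used as provided — no per-spot renormalization — and
all-zero spots still count in N; a compositional (row-normalized) mode is
offered for sensitivity analysis. Input tables are assumed pre-filtered to
tissue-covered spots. The score is bilinear in each type's column,
invariant to spot order and to duplicating the spot set.

## Imaging proximity

Distances are raw Euclidean in micrometers with no edge correction (a
documented limitation near core boundaries). For a (from, to) phenotype
pair, each from-cell's nearest to-cell distance is computed with a k-d
tree (verified exactly against the O(n²) loop); self-exclusion for
from = to is by cell id, so coincident distinct cells count at distance 0.
Summaries are per-core medians with a pooled-distances option (per-core
default, since cores are the experimental unit); status-level reporting
takes the median of per-core medians. Phenotype gating is upstream — the
module consumes final labels.

## Synthetic cohorts

The generator produces every pipeline input from explicit specs, all pure
functions of their seed; one global seed expands into per-generator child
seeds by fixed offsets.

* **Composition**: cluster draws are multinomial per status. A planted
  log₂OR for (cluster, status) multiplies that cluster's one-vs-rest odds
  *exactly* (the remaining mass is redistributed proportionally), so the
  GLM's estimand equals the planted value and recovery tests are unbiased
  by construction. Defaults: 3 statuses × 4 samples × 500–2,000 cells,
  4 clusters at equal base proportions.
* **Expression**: Gamma–Poisson (negative binomial, variance μ + μ²/θ,
  default θ = 2 — typical single-cell overdispersion) around lognormal
  per-gene means; signature genes multiplied by (1+effect) in flagged
  cells. The θ → ∞ limit recovers Poisson, which the tests verify.
* **Repertoire**: clone sizes are zeta-distributed (default exponent 2.5,
  heavy-tailed expansion) truncated at the cluster size; junctions are
  random codon-multiple nucleotide strings (30–45 nt); identity of the
  TRA+TRB pair encodes TCR clonotype; BCR heavy chains are per-cell
  mutated copies (rate 0.02) of a per-clone ancestor within a shared
  V/J/length partition. Sharing between a cluster pair merges each of the
  first cluster's clonotypes with one of the second's with the planted
  probability, making the downstream estimator shared/diagonal consistent
  for it. Ambiguous/multichain cells receive an extra other-class chain or
  two extra same-arm chains.
* **Spots**: per-type Gamma(shape = concentration) abundances; a
  co-localized pair additionally shares a per-spot Gamma(1) latent scaled
  by the loading ρ, keeping marginals nonnegative and the co-occurrence
  score monotone in ρ.
* **Points**: clustered phenotypes follow a Neyman–Scott process (Poisson
  parents, default 5·10⁻⁵/μm² on a 1 mm² core; Poisson(20) offspring
  scattered Normal(0, 25 μm)), with all clustered phenotypes sharing one
  parent set so they co-cluster; everything else is complete spatial
  randomness at the matched intensity, giving a fair clustered-vs-random
  proximity contrast.

What the generator does **not** emulate: transcriptome-wide correlation
structure, batch effects, UMI collisions, somatic-hypermutation
phylogenies, segmentation noise in imaging, or spatial autocorrelation of
spot abundances beyond the pairwise latent factor. Passing recovery tests
therefore demonstrate correctness of the statistics under their stated
models, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Floats serialize at 12 significant digits; manifests hash canonicalized
outputs, so identical config + inputs reproduce identical checksums.
Empty matrices, empty groups, unknown labels, overlapping cluster groups
and unnormalizable planted effects raise informative errors; zero-cell
GLM cells, zero-variance KDE axes, unimodal distance distributions, and
min–max ties each have an explicit documented fallback rather than a NaN
path. Problem sizes in the test suite and drivers (e.g. 200 replicates at
10,000 cells/status for GLM recovery; a 24,000-cell demo cohort) were
chosen so every planted effect is resolved well beyond its Monte-Carlo
error while the whole suite stays convenient to run locally.

## Known limitations

* The enrichment model pools cells within status (no random effects);
  between-sample overdispersion will make p-values anti-conservative on
  real cohorts. The per-sample mode surfaces the data to diagnose this.
* The BCR threshold estimator assumes a detectable bimodality; sparse
  repertoires fall back to a fixed 0.15, which may over- or under-merge.
* Density contrasts are descriptive; no significance is attached.
* Proximity statistics ignore boundary effects and core-to-core intensity
  differences beyond the per-core median summary.
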
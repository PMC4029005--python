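# Methods

## Problem and model

Composition-based binning assigns assembled metagenome contigs to source
organisms using only their nucleotide composition.  The underlying
assumption is that oligonucleotide usage (GC content plus k-mer
frequencies for small k) is approximately stationary along a genome and
distinct between genomes, so fragments of one genome form a cloud in
feature space separated from other genomes' clouds.  This holds best for
contigs of at least ~1 kb (shorter fragments have too much sampling noise
in their k-mer frequencies) and for communities whose members differ in
GC and higher-order composition; closely related strains are not
separable this way.

`compbin` bins by **two independent routes and a consensus rule**:

1. *PCA + K-means*: the full composition matrix (GC, then all k-mers for
   k = 2..5; 1361 columns) is z-scored per column, embedded by covariance
   PCA, and clustered with Euclidean K-means (Lloyd), taking the best of
   100 random initializations by within-cluster sum of squares.
2. *ESOM*: z-scored tetranucleotide frequencies (256 columns) train a
   large self-organizing map; the U-matrix — each neuron's mean weight
   distance to its eight grid neighbors — renders genomes as low-distance
   valleys separated by ridges, and connected valley components define
   clusters.

Each route's clusters are named by majority vote over a partial
taxon-annotation table (standing in for homology-based annotation); a
contig keeps its taxon only when both routes give the same name,
conflicts are `DISCARDED`, and a contig labeled by exactly one route
adopts that label flagged `single_route`.  Requiring cross-method
agreement trades a small loss of assigned contigs for much higher
per-bin purity, which is the right trade when bins seed downstream
functional analysis.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `min_len` | 1000 bp | binning length cutoff; below ~1 kb k-mer noise blurs the clusters.  A 500 bp cutoff is kept for assembly statistics only. |
| `ks` | (2,3,4,5) | k-mer orders in the composition matrix (with GC). |
| `strand_mode` | `single` | count k-mers on the given strand; `combined` folds reverse complements onto canonical k-mers and is exposed for robustness checks. |
| `k` | 10 | K-means cluster count; deliberately above the expected 8 taxa — surplus clusters merge when they share a majority label. |
| `runs` | 100 | K-means restarts; the returned SSE is non-increasing in `runs`. |
| `pca_variance` | 0.90 | K-means runs in the PCA subspace covering 90% of variance (denoising; the full-space option is a one-line change). |
| `grid_rows x grid_cols` | 50 x 82 | ESOM grid, ~2 neurons per contig at the default 2000 contigs, near-golden-ratio aspect; toroidal topology avoids edge artifacts. |
| `epochs` | 20 | online SOM passes; learning rate decays 0.5 → 0.05 linearly over all steps, neighborhood radius `max(rows,cols)/2` → 1 linearly over epochs. |
| `ridge_quantile` | 0.6 | neurons below the 60th U-matrix percentile are valley cells; chosen so the valley components recover the planted clusters in the synthetic recovery experiment, and configurable. |
| `min_frac` | 0.5 (strict) | a cluster is named only if one taxon exceeds half of its labeled members; a 50/50 tie stays `UNLABELED` rather than flipping a coin. |

All stochastic steps (initializations, shuffles, subsampling) derive from
one integer seed, so identical seeds give byte-identical outputs.

## Numerical choices

- "Normalized" features are per-column z-scores ((x − mean)/sd, population
  sd); this puts GC and k-mer frequencies on comparable scales for
  Euclidean distances, and is idempotent.  Zero-variance columns become 0
  and are flagged rather than dropped, keeping column order stable.
- k-mer windows containing any non-ACGT base are skipped; a contig is
  only rejected if no valid window remains.
- The SOM BMU search and weight updates run in a compiled kernel
  (float64); the neighborhood is truncated at 3σ.  Quantization error is
  recorded per epoch at assignment time (the standard online measure),
  and the final error and BMUs are recomputed with frozen weights.
- Valley components use 8-connectivity with toroidal wrap-around
  (matching the 8-neighbor U-matrix); ridge contigs join the nearest
  valley component by toroidal grid distance, ties to the lower
  component index.  Components that own no contig produce no cluster.
- Empty K-means clusters are re-seeded from the points farthest from
  their centroids (the standard Lloyd repair, via scikit-learn).
- N50 is the first length, in descending order, whose cumulative sum
  reaches half the filtered total.
- Percent views round half-up (as printed tables do), after quantizing
  at 1e-9 to keep float representation dust from flipping a 0.x5 case.
- Rarefaction is sampling **without** replacement
  (`multivariate_hypergeometric`); the exact expectation
  `E[S] = Σ_t (1 − C(N−n_t, d)/C(N, d))` is exposed and pins the
  Monte-Carlo estimator in tests.
- Published percent columns are inverted to totals by interval
  arithmetic: each printed (hits, percent) row constrains the total to
  the interval where the row re-rounds correctly, and the midpoint of the
  intersection is used.  A single-anchor point estimate (`implied_total`)
  is also provided, but a lone 1-decimal anchor is too coarse to
  reproduce every row of an 8-row table, so whole-column reconstruction
  is the default tool.

## The synthetic-data generator

Each genome is an order-k Markov chain (default k = 2) whose transition
matrix starts from the target base composition, is perturbed
multiplicatively by a genome-specific random pattern (`skew`,
`signature`), and is then iteratively rescaled so the stationary base
distribution matches the target GC (empirical GC lands within ±0.02 at
100 kb, typically ±0.005).  Optional ~1 kb repeat elements are pasted
verbatim at non-overlapping positions, preserving genome length —
mimicking the insertion elements that fragment real assemblies.
Communities draw contig counts per genome from a multinomial with
weights abundance × genome length, contig lengths from a log-normal with
median 2 kb (heavy tail, truncated at the minimum length — matching the
scale of the motivating assembly, whose mean contig was 2.0 kb), and
contig positions uniformly.  A `label_fraction` subset of contigs
receives its true taxon (optionally corrupted at `label_error`).
Amplicon and functional-category tables are straight multinomial draws
from given proportions.

The default eight-genome panel spaces GC targets 0.05 apart
(0.30..0.65) with distinct skew signatures and uneven abundances
(0.03..0.30), 2000 contigs of ≥ 1 kb, 20% labels, genomes of 300 kb.
The genome length is a deliberate scale-down from real bacterial
chromosomes: composition signatures are local, so separability depends
on contig length and GC spacing rather than genome size, and 300 kb
keeps a ten-seed recovery experiment at minutes rather than hours.

What the generator does **not** emulate: read-level noise and chimeras,
assembly artifacts other than repeats, shared/horizontally-transferred
regions between genomes, strain mixtures, codon- or gene-level structure,
and uneven within-genome composition.  Passing the recovery tests
therefore shows the pipeline separates communities whose members differ
compositionally as the model assumes — it does not bound performance on
real assemblies with strain-level overlap or contaminating sequence.

## Design choices where the design was open

- Whether K-means should run on raw features or in PCA space is
  genuinely open; the PCA subspace at 90% variance is the default (it
  denoises and keeps both routes' inputs distinct), and raw-space
  clustering remains available by passing the matrix directly.
- K-mer counting strand is exposed (`single` default, `combined`
  canonical folding) rather than guessed.
- The ESOM grid is toroidal; a spherical layout was considered and not
  implemented (no regular 4-neighbor lattice exists on a sphere, and the
  torus is the established emergent-SOM standard).
- Consensus of a labeled and an unlabeled route adopts the labeled
  route's taxon but flags it, so downstream users can exclude
  single-route contigs if they prefer strictness over yield.
- ARI for parameter recovery is computed over contigs that received a
  real taxon (discarded/unlabeled contigs excluded), with the discard
  count reported separately — the discard rule is itself part of the
  method under test.

## Known limitations

- Composition binning cannot separate genomes with near-identical GC and
  k-mer usage; the consensus rule then discards the overlap rather than
  resolving it.
- The ESOM valley extraction depends on `ridge_quantile`; very uneven
  cluster sizes can merge small genomes into a neighbor's valley at the
  default.
- Coverage is carried as metadata only; hybrid composition+coverage
  binning is out of scope.
- `label_clusters` trusts the majority of a possibly erroneous label
  table; systematic (non-random) annotation errors propagate to bins.
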
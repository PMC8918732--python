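# Methods

## Model

`geosig` treats a metagenomic sample as a bag of strand-ambiguous reads
and asks which labelled city's samples it most resembles in k-mer
composition. Three stages:

1. **Canonical random projection.** Each canonical k-mer (equivalence
   class of a k-mer and its reverse complement under A<C<G<T
   lexicographic order; (4ᵏ+4^(k/2))/2 classes for even k, 4ᵏ/2 for odd
   k) is assigned an i.i.d. standard-normal direction in ℝᴺ, normalized
   to unit length. A read's raw signature is the sum over its valid
   windows; windows containing any symbol outside {A,C,G,T} are
   discarded. The Gaussian direction is the standard isotropic choice;
   the vectors are *not* explicitly orthogonalized — for the default
   N they are nearly orthogonal already, and exact orthogonalization
   would buy nothing the nearest-neighbour search relies on.
2. **Per-sample normalization.** Raw signatures are stacked, the
   column-wise mean of the sample's matrix is subtracted from every
   row, and rows are rescaled to unit norm. Normalizing *after*
   centering both removes read-length effects and discards the
   sample-wide mean direction, which carries no within-sample
   information. Centering is strictly per sample — a query sample is
   centered with its own mean, never the library's — so train and
   query go through the identical transformation. Rows with norm
   < 1e-12 after centering (e.g. a sample of byte-identical reads) are
   dropped and counted in `n_discarded`.
3. **TSVQ + voting.** Recursive k-means builds the cluster tree; level
   extraction yields the sketch; 1/rank-weighted K-nearest-neighbour
   voting over labelled cluster-signatures produces a ranked location
   list and a city call (see below for conventions).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 4 | k-mer length; 136 canonical 4-mers balance resolution and table size |
| `N` | `count_canonical(k)` (136 for k=4) | signature dimension; matches the canonical count so the projection neither inflates nor collapses the feature space |
| `read_cap` | 1,000,000 | reads converted per sample (first usable reads in file order; seeded reservoir subsampling available) |
| `order` | 10 | TSVQ branching factor |
| `depth` | 4 | maximum tree level |
| `level` | 3 | sketch resolution used for the library (up to 100 cluster-signatures per sample at order 10) |
| `K_neighbours` | 3 | neighbours per query cluster; vote gains saturate around 3 |
| `max_iter`, `tol` | 100, 1e-4 | Lloyd iteration cap and relative objective-change convergence threshold |

## Numerical and algorithmic conventions

- **k-means** is a bespoke Lloyd implementation with k-means++ seeding
  from a single per-call seed. Assignment ties go to the lowest cluster
  index; an empty cluster is re-seeded with the point farthest from its
  assigned mean; requesting more clusters than points returns one
  cluster per point; clusters that remain empty (possible only with
  duplicate points) are dropped. The within-cluster sum of squares is
  recorded per iteration and is non-increasing.
- **Tree seeds.** Each sample's clustering seed is
  `crc32(global_seed | sample_id)`, and every k-means call inside a
  tree draws its seed from one per-tree RNG in deterministic DFS
  order, so a run is fully reproducible from the single configured
  seed and samples are seeded independently of collection order.
- **Level extraction.** A branch that exhausts its data above the
  requested level contributes its terminal leaf instead, so the
  returned clusters always partition the sample's reads (counts sum to
  M) and every sample is represented at every level.
- **Distance and ties.** All comparisons use Euclidean distance
  (monotone in cosine distance on unit vectors, and identical to the
  clustering metric). Exact neighbour-distance ties are broken by
  (location_id, sample_id); location score ties by smaller total
  neighbour distance, then location_id. Query clusters vote equally
  regardless of member count; `weight_by_count` is available but off
  by default.
- **Accuracy vs. S@N.** Accuracy is strict: the single top-ranked
  location's city must match. `best_correct_rank` uses competition
  ranking (tied scores share the minimal rank), the generous
  convention for ranked retrieval, so S@1 can exceed accuracy when
  the top score is tied across cities — with integer K=1 match counts
  on small collections this is common, and folding the generous
  convention into accuracy itself would systematically favour K=1.
- **Degenerate inputs.** Reads shorter than k or fully degenerate are
  empty-flagged and skipped (not counted against the read cap); a
  sample with no usable read raises `EmptySampleError`; classifying
  against an empty library raises `EmptyLibraryError`; mismatched
  (k, N) between query and library raises
  `IncompatibleSignatureError`.

## Synthetic data: what it emulates and what it does not

The generator emulates exactly the premise the classifier exploits:
within-city samples share k-mer composition that between-city samples
do not. Each city owns `n_motifs = 5` private marker motifs of
`motif_length = 24` bases (standing in for conserved fragments of
city-enriched organisms), inserted into reads at a Poisson rate of
`marker_rate = 2` per read at full separation, plus a mild
city-specific skew of the background base composition (Dirichlet with
concentration 10 around uniform). A single `separation` knob scales
*both* the insertion rate and the compositional deviation, so
`separation = 0` makes every city's reads identically distributed and
chance-level behaviour testable. Motif length matters: markers much
shorter than ~20 bases leave too little per-read signal for deeper
tree levels to resolve, which is not the regime of real metagenomes
where reads descend from genuinely distinct genomes. Read lengths are
uniform on 50–292 bases, the typical span of overlap-merged paired-end
fragments; degenerate bases are injected per base at a configurable
rate.

Not emulated: real taxa, abundance distributions, sequencing error
models, GC bias, or shared-but-differentially-abundant organisms
between cities. Passing tests therefore demonstrate that the pipeline
recovers planted compositional structure of realistic strength, not
any particular accuracy on real urban microbiome collections.

## Evaluation conditions

The test and acceptance runs use problem sizes chosen to probe each
property with comfortable margin:

- *Recovery / chance*: 4 cities × 6 samples × 2,000 reads at
  separation 1 and 0, TSVQ order 5 depth 3, level 3, 3-NN. At full
  separation LOOXV accuracy should be ≥ 0.9; at zero separation it
  should land in the central 99% binomial region around 1/4.
- *Level and K trends*: 4 cities × 10 samples × 500 reads at
  separation 0.2 — many same-city locations and deliberately noisy
  per-sample sketches, the regime where deeper sketches and
  multi-neighbour voting help, mirroring their benefit on large real
  collections. Accuracy is non-decreasing from level 1 → 3 and from
  K = 1 → 3 at the fixed seed.
- *Structure at scale*: 10 samples of 10,000 signatures for tree
  integrity; 1065 tiny samples for the level-2 library-size
  arithmetic (10 cluster-signatures per sample → 10,650 entries).

## Known limitations

- The method is closed-set: a query from a city absent from the
  library will be assigned to some known city; no novelty detection is
  attempted.
- Signature tables, and hence libraries, are tied to (k, N, seed);
  libraries built with different tables are incompatible by design.
- The bespoke k-means is plain Lloyd over a dense matrix; it is
  intended for the post-sketch problem sizes here (≤ ~10⁶ points ×
  ~10² dimensions per sample), not as a general clustering library.
- LOOXV rebuilds the library per held-out sample by filtering entries,
  which is exact but quadratic in collection size; for very large
  collections a shared index with masking would be the next step.
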
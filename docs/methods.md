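# Methods

## Model

`ragseg` performs hierarchical agglomerative segmentation. Given a
superpixel map S, a boundary probability map P and (for training) a gold
standard G, it builds a region adjacency graph — one node per nonzero
superpixel label, one edge per pair of regions touching under a chosen
pixel connectivity — and repeatedly merges the edge with the lowest
priority until the minimum priority reaches a threshold.

A *policy* is any symmetric function of (graph, node u, node v) returning
a real priority. Shipped policies:

- **mean / median boundary**: mean (or histogram-estimated median) of
  boundary pixel probabilities on the edge;
- **learned**: the probability, under a fitted classifier, that the edge
  is a true boundary (class +1), composed from the feature manager's edge
  vector. With a well-calibrated classifier, threshold 0.5 merges exactly
  while a true merge is more likely than not.

### Guided training agglomeration

Training samples are generated by agglomerating the training graph while
consulting G. Each node is assigned to the gold body with which it shares
the most pixels; an edge's true label is −1 ("should merge") when the two
assignments agree and +1 otherwise. Per epoch, the best-priority edge is
popped, its features and label recorded; −1 merges are executed, +1 edges
become inactive for the epoch ("record the mistake, don't make it"), and
the epoch ends when no active edge remains. After each epoch a fresh
classifier is fitted on all samples so far and its boundary probability
prioritizes the next epoch, so later epochs sample feature vectors from
higher hierarchy levels under a realistic policy. Epoch 1 uses the mean
boundary policy. *Flat learning* (level-0 affinity learning) samples each
initial edge exactly once without agglomerating.

Nodes whose plurality overlap fraction is below `purity_min` (default
0.75) are *ambiguous*: their edges are skipped without recording and
without merging. Merging an ambiguous pair could corrupt subsequent
node-to-body assignments, so the conservative choice is to leave them.

Label convention: **+1 = true boundary / do not merge**, so policy
output aligns with "probability the boundary is real" and low priority
means merge first.

## Feature managers and caches

A feature manager defines per-node and per-edge caches, a combination
rule applied when regions or boundaries merge, and the map from caches to
fixed-length feature vectors. Combination is commutative and associative,
so features are independent of merge order.

- **Moments** (default n=4): cache = (count, Σx, …, Σxⁿ) per channel;
  features = count, mean, standard deviation and standardized central
  moments. Raw-moment cancellation can leave O(machine-eps) variance
  residuals on near-constant regions; variance below 1e−12 of its natural
  scale is snapped to exactly 0 so standardized moments stay finite.
- **Histogram** (default 25 bins on [0, 1], percentiles 10/50/90): cache =
  unnormalized bin counts, summed bin-wise on merge; features = normalized
  histogram plus percentiles linearly interpolated from the cumulative
  counts (accurate to one bin width). Out-of-range values are clipped
  into the edge bins.
- **Convex hull** (2D/3D): the cache is the hull vertex set of the
  region's *unit pixel cells* (each pixel contributes its 2^d cell
  corners). Hulling cell corners rather than pixel centers makes a filled
  a×b rectangle measure exactly ab (convexity 1) and makes even a single
  pixel full-dimensional, so degenerate (collinear/coplanar) inputs never
  reach the hull library; a tiny volume floor (1e−9) remains as a
  fallback regularizer. Merging takes the hull of the union of the two
  vertex sets — mathematically equal to the hull of the union of the
  regions, and never re-reads pixels. Node features: hull volume and
  convexity (region size / hull volume); edge features additionally
  describe the hypothetical merged node.
- **Composite**: tuple-of-child-caches; feature vectors concatenate in
  list order. The default manager is moments(4) + histogram(25,
  percentiles 10/50/90).

The classifier's per-edge input concatenates the edge boundary features
with the elementwise min and max of the two node feature vectors, making
learned policies invariant to edge orientation. Feature lengths that
depend on the channel count of P are finalized when a manager is bound to
a graph.

### Preallocated cache tables

Agglomeration is hierarchical, so at most 2·n_initial node ids and
2·n_initial edge ids can ever exist (each merge retires ≥ 2 ids per new
one; renamed edges keep their id). Caches therefore live in preallocated
tables of that size addressed by incremental ids. The tables are
object-dtype rather than float because hull caches are vertex sets, not
fixed-length float vectors; the bound and the indexing scheme are
unchanged and enforced at run time.

## Agglomeration mechanics

- **Queue**: lazy invalidation. Heap entries carry (priority, insertion
  sequence, u, v); a popped entry is discarded if the edge died or was
  re-prioritized since. Equal priorities resolve first-in-first-out, so
  replays are deterministic.
- **Boundary sets**: the boundary of edge (u, v) is "thick" — pixels of u
  with a neighbor in v plus pixels of v with a neighbor in u. With
  `zero_is_boundary`, zero-labeled ridge pixels between two regions form
  the boundary instead, and regions separated only by a ridge are still
  adjacent.
- **Merge tree**: every executed merge is recorded as (parent, u, v,
  priority) in order. `cut_tree(tree, t)` applies the recorded prefix up
  to the first record with priority ≥ t. This is exactly the sequence a
  threshold-stopped agglomeration executes, so cuts replay stopped runs
  identically even when recorded priorities are non-monotone (learned
  priorities recomputed after a merge can drop back below an earlier
  threshold crossing). `continue_past_threshold=True` merges to
  exhaustion, records everything, and returns the cut at the requested
  threshold — one run then yields the whole threshold sweep.

## Watershed

Marker-based priority flooding: pixels enter a heap keyed by (landscape
value, insertion sequence); markers are enqueued in raster order. Ties in
value therefore resolve first-in-first-out, which divides plateaus
geodesically from the basins that reach them first and is fully
deterministic. Without markers, regional minima under the same
connectivity (plateau-connected components with no lower neighbor,
labeled in raster order) are the markers. The output is line-free: every
pixel gets a basin label.

One consequence, verified in the tests: on a clean boundary-indicator
map, flooding recovers bodies exactly wherever every ridge pixel touches
its own body's interior (e.g., straight boundaries), but pixels at body
junctions whose entire face neighborhood is ridge are intrinsically
ambiguous and can land on either side. The synthetic generator therefore
does not rely on watershed exactness (below).

## Evaluation

All metrics derive from a sparse contingency table built in one pass
(O(n_pixels)). Logarithms are base 2 throughout ("bits"); entropies use
the 0·log 0 = 0 convention. By convention the first argument is the
automatic segmentation A and the second the gold standard B: "under" =
H(B|A) (false merges), "over" = H(A|B) (false splits). Pixels labeled 0
in either image are ignored by default (configurable), matching
ridge-line label maps.

Rand, adjusted Rand and Fowlkes–Mallows come from closed-form pair
counts (Σ C(n_ij, 2) and marginal analogues), never pair enumeration; the
adjusted index uses the permutation-model expectation. The edit distance
is plurality-based: each segment of A is assigned to its plurality body
in B; a body claimed by k segments contributes k−1 false splits, and a
segment overlapping ≥ 2 bodies by more than `tolerance_pixels` (default
1) counts one false merge. This is a documented definition choice, not a
reproduction of any published variant.

`vi_curve` cuts the merge tree at each threshold and reports the
(under, over) pair, the minimum-VI point and the point at threshold 0.5.
Coarsening geometry guarantees over is non-increasing and under
non-decreasing along any merge sequence; merges of pure same-body regions
move the point straight down, merges across bodies strictly rightward.

## Synthetic fixtures

The generator emulates the three pipeline inputs with controllable
difficulty:

- **Gold**: Voronoi cells of `n_bodies` seed points sampled without
  replacement — convex, connected, nonempty bodies.
- **Probability map**: the face-neighbor boundary indicator, Gaussian
  blurred (`boundary_blur`, default 1 px, rescaled to peak 1), plus
  zero-mean Gaussian noise (`noise_sigma`), clipped to [0, 1].
- **Superpixels**: a watershed of the probability map seeded with
  `oversegmentation_factor` random interior points per body, then
  *intersected with the gold standard* — every watershed region is split
  along true boundaries — so superpixels provably never cross a true
  boundary and the under-VI against gold is exactly 0 by construction.
  Connected components are re-extracted, and fragments below
  `min_fragment` (default 4) pixels — slivers at basin junctions — are
  absorbed into a neighboring superpixel of the same body, which never
  violates the guarantee. With factor 1 and no noise the superpixels
  equal the gold standard up to relabeling.

Defaults (shape 64×64, 8 bodies, factor 4, blur 1, noise 0.1) give ~40
superpixels per volume with ~0.2–0.7 bits of initial oversegmentation —
a desk-scale stand-in, not an emulation of real electron-microscopy
texture. What a green end-to-end test establishes: the training loop,
feature plumbing, classifier composition and threshold semantics are
correct, and learning helps under noise on this family of volumes. What
it does not establish: absolute accuracy on real data, robustness to
superpixels that do cross true boundaries, or anisotropic artifacts.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| connectivity order | 1 | face neighbors; cheapest neighborhood, used for RAG and watershed |
| feature manager | moments(4) + histogram(25, pct 10/50/90) | generic intensity statistics |
| classifier | random forest, 100 trees, seeded | heterogeneous features; calibrated-enough probabilities |
| n_epochs | 5 | training agglomerations; fresh classifier per epoch on cumulative samples |
| purity_min | 0.75 | tolerate mild superpixel leakage, reject genuinely mixed nodes |
| threshold | 0.5 | even odds under the learned boundary probability |

Any estimator with `fit` / `predict_proba` can replace the forest.
Policies persist as a directory bundle (JSON manager configuration +
pickled classifier, versioned); deserialized policies reproduce
priorities bit-identically.

## Known limitations

- Node pixel-index lists are stored explicitly; memory scales with pixel
  count (adequate for desk-scale volumes, not out-of-core stacks).
- Oriented boundary statistics (direction-aware mean boundary) are not
  implemented.
- Training requires a complete gold standard for the training volume;
  partial/masked ground truth is unsupported.
- Median-boundary priorities are histogram estimates (one bin width of
  accuracy), not exact order statistics.
- The hull manager supports 2D and 3D only.
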
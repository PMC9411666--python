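# Methods

## Model and assumptions

`mpmim` scores a candidate embedding of spatial-transcriptomics spots by how
much globally coherent spatial structure it carries, on the premise that for
tissue-architecture tasks a good embedding varies smoothly over the slide
(spots in the same anatomical domain receive similar latent values) while a
poor one looks spatially random. The pipeline has two stages:

1. an unsupervised, parameter-free-in-the-learning-sense *transform* —
   stacked neighborhood aggregation over a KNN graph built in embedding
   space — that amplifies the embedding's latent structure before scoring;
2. a *score* — global Moran's I per embedding dimension under a binary
   spatial weight matrix, reduced across dimensions by maximum filtering.

Nothing is trained: the transform is a fixed linear, row-stochastic map, so
results are exactly reproducible and embedding-order invariant.

Assumptions worth stating: spatial coordinates are 2-D (slide data); the
embedding rows and the coordinate rows describe the same spots (enforced by
id alignment); spatial structure expressed by *any single* dimension is
enough to certify quality (that is what max filtering encodes); and
candidate embeddings being compared describe the same sample, so a common
spatial weight matrix is valid for all of them.

## Graph construction

The KNN graph uses exact O(n²) search (the method targets slide-scale
inputs, ≤ a few thousand spots), Euclidean distance in embedding space,
ties broken by ascending node index, and union symmetrization — an edge
survives if either endpoint selected it — which preserves connectivity for
message passing. Pruning then drops, per node, neighbors farther than
mean + 1 sd (population sd) of that node's neighbor distances; the nearest
neighbor is always retained, so no node is ever isolated; symmetry is
re-established by union; the rule is applied exactly once. The mean+sd
criterion is this package's concrete choice of "outlier" — it is scale-free
and cheap, and it is exposed via `MpMimConfig.prune` so alternatives can be
slotted in.

## Message passing

With the "distance" type, weights are a softmax over *raw* neighbor
distances, so farther neighbors receive larger weight. This is deliberate:
the transform injects long-distance dependency to complement the
short-range bias of the upstream models' graph convolutions. Raw distances
feed `exp()` without max-subtraction; any node whose largest neighbor
distance exceeds `overflow_guard = 700` (the double-precision `exp`
overflow bound) falls back to uniform weights at that node, and the "basic"
type applies uniform weights globally. The aggregation sum runs over the
neighborhood excluding the node itself (`include_self=False` by default;
the toggle exists because graph-convolution conventions differ). The graph
and weights are computed once from the original embedding and frozen across
all `l_num` layers; `l_num = 0` is the identity.

Consequences used by the tests: every aggregation matrix is row-stochastic,
so each transformed dimension stays inside the input dimension's
[min, max]; the layer map is linear; with uniform weights the `l`-layer
transform equals the dense matrix power `(D⁻¹A)^l` applied to the input.

Defaults `k_num = 90`, `l_num = 15` are the method's recommended operating
point — deep aggregation with a wide neighborhood is what makes the ranking
stabilize; `k_num = 9` with uniform weights is the documented setting for
lower-dimensional GCN-style inputs.

## Spatial autocorrelation

Moran's I and Geary's C use *binary* weights normalized only through
S0 = Σ w_ij (no row standardization), matching the statistic's plain
definition. Geary's C is reported as 1 − C so its sign convention matches
Moran's I (+1 strong positive autocorrelation, 0 none, −1 negative). Two
weight schemes exist:

* `radius`: w_ij = 1 iff 0 < d_ij ≤ d_radius. The default radius, `"auto"`,
  is the maximum over spots of the nearest-neighbor distance — the smallest
  radius that leaves no spot isolated. On a unit lattice this reduces to
  first-ring adjacency.
* `knn`: spatial k-nearest neighbors, union-symmetrized; default
  `knn_w = 6`, the first-ring neighbor count of the hexagonal Visium array.

A constant dimension has no defined autocorrelation; it is reported as NaN,
excluded from the max/avg/min reduction with a warning (scoring it 0 would
distort the avg and min filters), and an all-constant embedding is an
error. Numerically, both statistics are evaluated through sparse
matrix-vector products and are tested to 1e-10 against double-loop
definitions.

## Ranking and evaluation

Embeddings are ranked by descending filtered score, ties broken by
ascending name for reproducibility. The ground-truth ranking for evaluation
runs K-means (k = number of distinct annotation labels, 10 restarts, fixed
seed) on each embedding and ranks by ARI against the annotations; the
clustering backend is deliberately pluggable in principle since any
clustering method could stand here. Spearman's rho uses tie-averaged ranks
(a deviation from the no-ties textbook formula, needed for real score ties)
with the two-sided large-sample t approximation for the p-value, and is
additionally reported clamped at zero. The per-dimension baseline ranks
embeddings by the *untransformed* statistic of each dimension separately
and reports the best dimension — the strongest member of that family.

## Synthetic fixtures

The generator emulates the *structure* of the study inputs, not their
biology: a Visium-like hexagonally offset lattice (unit spacing,
`20×20 = 400` spots by default), contiguous annotated domains (4 vertical
bands), and per-dimension latent fields. Each field assigns one N(0,1)
value per domain, smooths it with a Gaussian distance kernel (length-scale
`smoothness = 3` lattice units, chosen so domains stay distinguishable but
boundaries are soft), standardizes to unit sd, and adds i.i.d. Gaussian
noise. A suite of `m = 8` embeddings shares one signal field — candidate
embeddings of the same sample share the underlying tissue signal — and
varies only the noise sd, linearly from 3.0 (noise-dominated) down to 0.0
(clean), giving a known construction-order truth. All draws are
`numpy.random.default_rng(seed)`-deterministic.

What the fixtures do **not** emulate: gene-expression counts and library
size, embedding correlations induced by shared model training, anisotropy
or holes in real slides, and annotation noise. Passing the benchmark
therefore shows the pipeline recovers a known smoothness ordering under
realistic geometry — not that it reproduces any specific biological
dataset.

Benchmark problem sizes (400 spots, 8 embeddings, 10 replicate seeds) are
the package's default desk-scale benchmark; the pipeline itself has no such
limits.

## Known limitations

* The softmax-of-distance weighting is not scale-invariant: rescaling an
  embedding changes the weights (though not the graph). This mirrors the
  transform's definition; compare embeddings on a common scale.
* Max filtering certifies quality from one dimension; an embedding with one
  smooth but uninformative dimension can be over-ranked.
* The pruning rule is a documented substitute for an adaptive-pruning
  criterion that has no closed published form.
* `p`-values for Spearman's rho use the large-sample approximation, which is
  crude for suites of fewer than ~10 embeddings.
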
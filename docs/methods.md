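# Methods

`calyxwire` analyses the wiring structure of a bipartite connectome layer:
a set of presynaptic inputs (visual projection neurons, VPNs, and local
visual interneurons, LVINs) contacting a population of postsynaptic
outputs (Kenyon cells, KCs, of the mushroom body's ventral accessory
calyx). The central object is the synapse-count matrix `W` (rows =
inputs, columns = outputs) with a per-pair synapse threshold (default 5
synapses: weaker contacts are treated as absent, matching the convention
of connectome exports). The threshold applies per (pre, post) pair before
any type-level aggregation, so aggregation can never resurrect
sub-threshold contacts.

## Marginal-preserving shuffle nulls

The question every test here asks is: does the observed wiring carry
structure beyond what two marginal properties already explain — the
heterogeneous connection frequencies of the inputs, and the number of
inputs each output samples?

Two shuffle laws are implemented.

* **`method="exact"` (default).** Both margins of the binarized matrix —
  each input's connection count and each output's in-degree — are held
  exactly fixed, and the null is the uniform distribution over binary
  matrices with those margins, sampled by curveball trades (repeatedly
  pick two outputs and randomly re-deal the inputs exclusive to one of
  them; 5 × n_outputs trades per shuffle, a conventional mixing budget at
  these densities; the trade loop is JIT-compiled, with a pure-python
  fallback). This null is exactly calibrated against the package's random
  wiring generator: conditional on its margins, a matrix generated by
  independent per-output input sampling is uniform over the
  margin-constrained ensemble, so observed and shuffled matrices are
  exchangeable under the null hypothesis.
* **`method="weighted"`.** Each output keeps its in-degree and re-draws
  that many distinct inputs sequentially without replacement with
  probability proportional to each input's observed marginal count
  (implemented via the Gumbel top-k equivalence). This is the sampling
  description often used in the mushroom-body literature. It is *not*
  used as the default test null because the observed marginals are
  themselves one noisy realization: re-using them as sampling weights
  produces a null ensemble systematically more heterogeneous than a
  matched generator (in simulation, the first principal component of
  random wiring fell below its own 95% null band in roughly 60% of runs).
  It is retained for comparison and for its own distributional tests.

Both laws conserve per-output in-degree and total edge count exactly and
leave zero-in-degree outputs empty. Shuffles operate on binarized
connectivity (the preserved quantities are defined on binary
connectivity); weighted matrices are binarized with a logged notice.

## PCA spectrum test

Structure is measured on the input covariance: variables are input
channels, observations are outputs, per-input means subtracted. The
fractions of variance carried by each eigenvalue of this covariance are
compared with the pointwise 2.5–97.5 empirical percentile band over 1000
shuffles (configurable); components outside the band are flagged. By
default the spectrum is computed on binarized connectivity; a weighted
option computes the observed spectrum on synapse counts and re-places
each output's observed count multiset onto the shuffled edges. Both
choices are logged. Random wiring should produce ~5% of components
outside the band; channel-restricted (labeled-line) wiring with k
communities produces at least k − 1 dominant structured components.

## Participation ratio

The effective dimensionality of the input currents is
PR(C) = (tr C)² / tr(C²) = (Σᵢ μᵢ)² / Σᵢ μᵢ², where μᵢ are the
eigenvalues of the input covariance C. PR equals the channel count M for
an isotropic spectrum, 1 for rank one, and decreases under concentration
of variance onto few channels at fixed M. PR is computed on
synapse-weighted connectivity by default — input currents depend on
synaptic weight — with a binarized option; standard (mean-subtracted)
covariance is used. The ratio is invariant to overall matrix scaling, so
the covariance normalization convention cancels.

## Conditional input analysis

For every ordered pair of inputs (A, B), count(A, B) is the number of
outputs receiving both (each connection counted once regardless of
synapse count; the diagonal holds per-input partner counts, and the
matrix-product form B·Bᵀ of the binarized matrix is verified against a
brute-force pairwise loop in the tests). Each pair's count is z-scored
against the mean and sd of its shuffle-null distribution; pairs whose
null is degenerate (sd = 0) are reported as z = 0 with a flag rather
than ±∞. K-means (20 restarts, fixed seed) groups inputs by their
z-profiles for each cluster count k in 2..10; k values exceeding the
input count are dropped with a warning.

## Clustering outputs by input composition

Outputs are clustered on their binarized input vectors by spectral
clustering with a cosine-similarity affinity; outputs receiving no
inputs are excluded with a notice. The number of clusters is selected by
the silhouette score computed with Euclidean distance **on the binary
input profiles**, not on the spectral embedding: in the k-dimensional
embedding, k-means always finds well-separated groups, so the embedding
silhouette stays high (~0.5) even for structureless wiring and cannot
flag the absence of structure. On the data-space silhouette a
structureless matrix stays near 0 (a maximum below 0.25 raises a
"no clear structure" flag), while planted block wiring peaks at the true
k. Because sparse profiles make the silhouette noisy, the selected k on
planted data is correct in most but not all draws; the tests assert
recovery statistically over seeds. Hierarchical co-clustering (average
linkage on Jaccard distances) provides row/column leaf orders for
heatmap export.

## Bilateral stereotypy

The stereotypy statistic is the number of left-hemisphere outputs whose
exact binary input-type set also occurs among right-hemisphere outputs.
Both matrices are binarized and aggregated to the cross-hemisphere type
map first; only type labels present on both sides enter the comparison,
outputs with no inputs from the shared types are ineligible and never
counted, and a left output matching several right outputs counts once.
The null re-samples both sides independently (`mode="independent"`) or
shuffles one side and copies it to the other (`mode="mirrored"`, the
bilaterally stereotyped model, whose null match counts stochastically
dominate the independent ones). The p-value uses the finite-ensemble
correction (r + 1) / (n + 1), where r is the number of null counts at
or above the observed count, so it is never exactly zero. Null intervals
are empirical percentiles, not normal approximations: match counts are
small and skewed.

## Synapse-type classification

Each pre→post connection is classified from the spatial dispersion of
its synapse locations: the population variance of Euclidean distances
from the synapse centroid, in nm² (invariant to rigid motion, scaling as
s²). Bouton-claw contacts concentrate synapses in a ball; en-passant
contacts spread them along the axon (for points uniform on a segment of
length L the statistic converges to L²/48). Connections with fewer than
3 synapses are left unclassified — any two-point cloud has dispersion
identically zero, so the statistic is uninformative there. The decision
threshold is calibrated on labeled ground truth: a stratified seeded
train/test split, cutoff at the midpoint between the best-separating
training order statistics (smallest such midpoint on ties), accuracy
reported on the held-out set only. Classification is monotone in
dispersion by construction. The variance is the population (not sample)
form; at the calibration n this choice is immaterial and it keeps the
single-point case defined.

## Receptive fields

An eyemap assigns each ommatidial column a unit view-direction vector
and a columnar marker in tissue coordinates (nm), per neuropil layer
(medulla arbors use the M5 marker layer). A neuron's covered columns are
those whose marker lies within a distance threshold of any skeleton
point (point-to-marker Euclidean distance, no skeleton resampling — node
density of the export is a knob the caller controls). The receptive
field is the spherical convex hull of the covered directions, computed
in the gnomonic projection about the covered set's normalized mean
direction; hull membership of all eyemap columns gives the RF size in
ommatidial columns. The gnomonic hull is well-defined for fields up to a
hemisphere; covered sets spanning more than 150° of visual angle are
rejected, and degenerate (collinear) sets fall back to the covered set
itself. Accessory-medulla neurons have no columnar markers of their own,
so their RFs depend on the marker layer chosen and should be treated as
convention-dependent.

The distance threshold is calibrated per layer against hand-annotated
column sets by maximizing mean Jaccard overlap over a logged grid
(smallest maximizer on ties). RF size is monotone non-decreasing in the
threshold.

View directions are displayed in the equal-area Mollweide projection:
x = (2√2/π) R λ cos θ, y = √2 R sin θ, with 2θ + sin 2θ = π sin φ solved
by Newton iteration to 1e-12 (poles handled analytically); the equator
is φ = 0 and the frontal midline λ = 0.

A Kenyon cell's effective RF combines incident fields linearly, weighted
by synapse count: the direct component sums VPN hull-indicator fields
weighted by VPN→KC synapses; the indirect component sums per-LVIN fields
(each the VPN→LVIN-weighted sum of its VPN indicator fields, normalized
per LVIN so direct and indirect components are on comparable scales)
weighted by LVIN→KC synapses. KCs with no visual input yield empty
fields with a notice.

## Synthetic data generator

The generator emulates the measured circuit's study conditions and is
the default input for every test: 74 inputs onto 147 outputs, per-output
in-degrees drawn from {1..7} with median 3, synapse counts riding above
the 5-synapse threshold on a shifted geometric (p = 0.5; structural
statistics binarize anyway), and a 759-column eyemap. Three wiring
hypotheses are implemented: `random` (inputs sampled ∝ a probability
vector), `labeled_line` (each output samples only its community's
inputs, with a per-draw contamination rate), and `biased_mixture`
(probabilities reweighted by a bias vector). Bilateral pairs are either
`independent` (identical marginal laws, independent draws) or `mirrored`
(one draw copied to both hemispheres). Synapse clouds are isotropic
Gaussians (bouton-claw, sd = σ) or uniform segments with optional jitter
(en-passant, length L). The synthetic eye is a hexagonal patch of unit
view directions (2° spacing) with markers placed radially at 250 µm, and
planted receptive fields are discs of columns whose markers receive
skeleton points within half the true distance threshold.

What the generator does **not** emulate: spatially correlated in-degrees,
type-level weight structure beyond the bias vector, reconstruction
artifacts (split/merged neurons, missed synapses), morphologically
realistic skeletons (labeled point sets suffice for proximity geometry),
and the real eye's anisotropic column spacing. Passing tests therefore
demonstrate correctness and calibration of the statistics under the
stated sampling laws, not robustness to reconstruction error in real
exports.

## Problem sizes and runtime choices

The test and acceptance runs use 1000 shuffles per ensemble (the
convention for these analyses), 50 repetitions for calibration and power
rates, 5 matrices (~27,000 pooled pairs) for the conditional-z exceedance
rate, 30 labeled pairs per class for the synapse-type benchmark, and 6
planted neurons on the 759-column eyemap for RF recovery. These sizes
give Monte-Carlo standard errors comfortably below the margins being
asserted while keeping a full run in a few minutes on one core.

## Numerical choices and degenerate inputs

* Identifier ordering is lexicographic everywhere; score ties in greedy
  matching break by target id (within a query) and query id (between
  competitors); ranking ties break by id. Greedy matching is implemented
  as deferred acceptance with score-ranked targets, whose fixed point is
  the descending-score greedy assignment and is independent of input row
  order.
* Duplicate (pre, post) edge rows are an error (malformed export), never
  silently summed.
* Covariance eigenvalues are clipped at zero (symmetric eigensolver
  round-off); spectrum fractions always sum to 1.
* A single-input matrix yields the degenerate spectrum {1.0} with a
  warning; an all-zero matrix is an error for PR and the spectrum test.
* Coordinates are nanometres as exported; no voxel conversion anywhere.
* All stochastic stages take explicit seeds; the pipeline derives each
  stage's seed from the global seed and the stage name (SHA-256, < 2³¹).

## Known limitations

* The exact-margin null conditions on both observed margins; it cannot
  detect structure expressed purely in the margins themselves (by
  design — that is the hypothesis being controlled for).
* Curveball mixing at 5 sweeps is a convention, not a proof; the
  uniformity of the chain is verified exactly only on small enumerable
  fixtures.
* The optional adapter for live connectome services is not included;
  analyses start from exported edge lists, annotation tables, SWC
  skeletons and eyemap tables.
* RF estimation ignores synapse polarity and dendrite/axon labels; it
  treats all skeleton points as dendritic, which is the correct reading
  for the optic-lobe arbors it is meant for but not in general.
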
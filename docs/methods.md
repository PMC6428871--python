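# Methods

## Similarity layers

A repertoire is a set of unique CDR3 amino-acid clones with read counts.
Input rows with identical CDR3 strings are collapsed by summing counts (the
100% amino-acid identity clone definition); the default filters keep clones
of length ≥ 4 that occurred more than once (`min_len=4`, `min_count=2`).
Ambiguity codes (X, `*`, `_`) are rejected rather than kept, because the
edit-distance metric is defined over the 20-letter alphabet only.  Clone
frequencies, when not supplied, are counts normalized after filtering.

The layered network stores the sparse i < j triangle of pairwise
Levenshtein distances up to `max_ld` (1..12) as three parallel arrays
(src, dst, ld); every exact layer LD_n and cumulative layer LD_≤n is a mask
view of it.  Distances come from edlib's banded alignment with cutoff
`max_ld`: pairs beyond the band are never stored, and any pair whose length
difference exceeds `max_ld` is pruned before alignment (|len(a) − len(b)| is
a lower bound on LD).  The triangle is partitioned into independent row
chunks merged by union, so the edge set is identical for every
`chunk_size`/`workers` setting; parallelism is a within-process joblib pool,
i.e. a partitioning contract rather than a cluster framework.  A
degree-only streaming path (`stream_layer_degree_counts`) accumulates
per-chunk degree counts without materializing edges and is asserted equal
to the graph path.

Node indices follow repertoire order and are persisted with the network, so
exports (GraphML with cdr3_aa/count/degree attributes, edge-list CSV) are
reproducible.

## Global and clone-level metrics

Global metrics of one layer: order N, size L, average degree ⟨k⟩ = 2L/N,
density 2L/(N(N−1)), connected components (scipy sparse BFS), diameter,
clustering coefficient, degree centralization and degree assortativity.
Conventions for the degenerate and ambiguous cases:

* **Diameter** is the largest geodesic, counted in edges, of the largest
  connected component (the layers are almost always disconnected; reporting
  the largest component's diameter makes the quantity well-defined).  Users
  comparing against vertex-count conventions should add 1.
* **Clustering coefficient** is the transitivity ratio 3·triangles/triples;
  the mean of the local coefficients C_j = 2e_j/(k_j(k_j−1)) is reported
  separately (`avg_local_clustering`) since the two differ on heterogeneous
  graphs.  Local C_j of nodes with degree < 2 is 0.
* **Centralization** is Freeman's degree centralization,
  Σ(k_max − k_i)/((N−1)(N−2)), normalized so a star scores 1.
* **Assortativity r** is the Pearson correlation of the degrees at the two
  ends of an edge (both orientations).  It is reported as undefined
  (`None`), not zero, when the edge-end degree variance vanishes (regular
  graphs).  The equivalent formulation through the remaining-degree joint
  distribution e_jk with marginal q_k and variance σ_q² is implemented
  separately and the two are asserted equal in the tests.

Clone-level metrics: degree, local clustering, eigenvector centrality,
authority, PageRank, closeness, betweenness, coreness.

* **Eigenvector / authority** are computed by power iteration to a max-norm
  change below 1e−13 (cap 10⁶ iterations), rescaled to maximum entry 1 and
  resolved to non-negative vectors.  The iteration applies (A + I): the
  shift leaves eigenvectors unchanged and removes the ±λ oscillation that
  plain iteration suffers on bipartite components.  Authority iterates
  (A+I)ᵀ(A+I); on undirected graphs it coincides with eigenvector
  centrality, which the tests assert numerically.  Edgeless graphs yield
  all-zero vectors.
* **PageRank** uses teleport α = 0.85 by default (exposed as a flag) and
  sums to 1; isolated nodes receive the uniform teleport mass.
* **Closeness** is computed within components and normalized by
  (component size − 1), so it lies in [0, 1]; isolated nodes score 0.
* **Betweenness** is unnormalized geodesic-count betweenness.
* **k-core decomposition** reports per-clone coreness, the maximal
  (innermost) core k_max, the percentage of clones composing it, and the
  core-size distribution along k.
* **Neighborhood size** at order d is the number of distinct clones within
  geodesic distance ≤ d of a focal clone, excluding the focal clone itself
  (an inclusion variant sits behind a flag), normalized by N and averaged
  over clones; it is non-decreasing in d and plateaus at
  (component size − 1)/N.
* **Largest clique** search is exact (networkx branch-and-bound) and
  refused above a configurable node-count guard (default 5000) because of
  its exponential worst case.

Cross-sample variability uses CV = (sd/mean)·100 with the sample standard
deviation; CV of a zero-mean metric is undefined.

## Degree-distribution classification

Operating on a degree vector with zeros removed (their count is reported):

1. **Power-law fit.**  Discrete power law p(k) ∝ k^(−α), k ≥ x_min, with
   x_min chosen by minimizing the KS distance between the empirical tail
   CDF and the fitted model over all observed degree values.  A candidate
   threshold is admissible when its tail keeps ≥ 4 observations spanning
   ≥ 2 distinct values; when no candidate qualifies the fit is infeasible —
   the explicit "NA" outcome that perturbation experiments record.  The
   exponent is constrained to [1.5, 3.5], the discrete search range of the
   reference plfit implementation; steeper decays are not meaningful power
   laws and otherwise absorb the narrow tails of light-tailed data.  Two
   estimator channels are kept:
   the *reported parameters* (x_min, α) come from the scan with the exact
   zeta-normalized MLE at every candidate, which recovers simulated
   exponents accurately; the *goodness-of-fit channel* uses the standard
   approximate discrete MLE α ≈ 1 + n[Σ ln(x_i/(x_min − ½))]⁻¹ for its KS
   statistic, because the bootstrap below refits every synthetic replicate
   and must use one and the same estimator on both sides of the comparison
   for the test to be calibrated (verified by the type-I property test).
2. **Bootstrap goodness of fit.**  Semi-parametric bootstrap, 100
   replicates by default: each replicate draws every observation either
   from the fitted power law above x_min (with the empirical tail
   probability) or uniformly from the empirical body below x_min, re-runs
   the x_min scan, and records its KS statistic.  The p-value is the
   fraction of replicates with KS at least the observed value; p ≥ 0.1
   accepts the power law.  Sampling is exact inverse-CDF from a zeta-
   normalized table (~10⁶ support points; the negligible residual mass
   falls back to the continuous-approximation transform).
3. **Exponential vs Poisson.**  When the power law is rejected, a discrete
   exponential (geometric, closed-form MLE) and a truncated Poisson
   (1-d numerical MLE) are fitted on the same support — the tail on which
   the power law was tested — and compared by a Vuong-style normalized
   log-likelihood-ratio statistic z.  The two-sided p-value
   erfc(|z|/√2) < 0.05 declares the models discriminable; the one-sided
   p-value Φ(z) is ≈ 1 when the exponential fits better and ≈ 0 for the
   Poisson.  Non-discriminable cases are classified `undetermined`.  The
   0.05/0.95 conventions are defaults, exposed as flags.  A
   `comparison_support="full"` flag re-runs the comparison on all positive
   degrees instead.

All thresholds (p ≥ 0.1 for the power law, 100 bootstrap replicates) are
the defaults of the published methodology this pipeline follows; seeds are
explicit arguments everywhere and no global random state is touched.

## Robustness experiments

Public clones are CDR3 sequences present in ≥ 2 repertoires of a cohort
(counted per subject, not per read); detection runs after the default
clone filters.  Removal experiments delete either exactly the public clones
of a sample (deterministic, one outcome) or uniformly random clone subsets
— at a fraction of the repertoire, or size-matched to the public set (20
replicates by default).  Surviving networks are obtained by subgraph
induction, which is provably identical to recomputing Levenshtein layers on
the survivors (pairwise distances do not depend on removed clones; asserted
on fixtures).  Each outcome records the re-classification of the surviving
degree distribution (or NA when infeasible) and the change in node, edge
and largest-component counts, which removal can only decrease.  The
robustness verdict of a removal grid is the largest tested fraction whose
modal classification over replicates equals the unperturbed network's.

## Redundancy (Q²)

For clones aligned across layers, the degree profile matrix holds the
exact-layer degree of clone i in column n.  Q² of LD_1 predicting LD_m fits
the simple linear model y = β₀ + β₁x (x = LD_1 degrees, y = LD_m degrees,
zero degrees included; a drop-zeros flag provides the sensitivity variant)
and scores it by leave-one-out cross-validation:
Q² = (1 − PRESS/TSS)·100 with PRESS = Σ(y_j − ŷ_[j])².  The LOOCV
residuals use the exact leverage identity e_[j] = e_j/(1 − h_jj), asserted
equal to the literal n-fold refit to 1e−8.  Constant responses give an
explicit undefined marker; constant predictors reduce to the intercept-only
model.  The diagonal Q²(LD_1→LD_1) = 100 serves as a sanity check.

## Synthetic data

The simulators supply every input the analyses need at desk scale:

* **Reference graphs.**  Erdős–Rényi G(n, p) (Poisson degrees),
  Barabási–Albert preferential attachment (power-law degrees, m edges per
  node), and a configuration model over a geometric degree sequence with a
  chosen mean — a Bernoulli edge probability cannot produce an exponential
  degree law, so the exponential family is generated from its degree
  sequence directly, with self-loops and multi-edges simplified.  Default
  mean degree 5 for ER and the exponential model keeps the three reference
  topologies comparable at equal density.
* **Synthetic repertoires.**  Unique CDR3 strings over the 20-letter
  alphabet, lengths uniform in [4, 20]; founders are independent random
  strings and descendants arise by single substitutions from a parent
  chosen among all clones (tree-like, chain-forming) or among founders only
  (star-like, radial).  Clone counts are 1 + a capped Zipf(2.5) draw, a
  heavy-tailed law whose minimum of 2 survives the default count filter.
* **Synthetic cohorts.**  A shared pool of `round(public_fraction ·
  n_clones)` sequences is injected into every individual, so the realized
  public fraction matches the target exactly and public-clone detection
  recovers the pool; private clones are globally unique.
  `public_as_hubs=True` grows each individual's private clones as radial
  single-substitution neighbours of pool members, making public clones the
  LD_1 hubs (used to demonstrate the public-removal fragility effect).

What the generators emulate is similarity-layer *topology* and clone-count
skew; they do not model VDJ recombination biology, somatic hypermutation
spectra, sequencing error, or realistic clone-size laws.  Tests passing on
these fixtures therefore validate the graph/statistics machinery and the
qualitative architecture classes, not biological effect sizes measured on
real repertoires.

## Validation scale and limitations

The test suite exercises: the three-family classification on reference
graphs with n = 10⁴ and the full 100-replicate bootstrap; robustness of a
50,000-node exponential-degree network to 10/50/90% random removal (20
replicates per fraction — classification survives 50% and degrades at
90%, where small networks instead hit the infeasible-fit NA rule); oracle
equivalence of every global and clone-level metric against dense
brute-force implementations on 200 random graphs of ≤ 50 nodes (1e−8);
LOOCV shortcut-vs-literal equality on 100 random pairs; layer algebra
(disjointness, cumulative union, streaming-degree equality, metric axioms)
on 100 random repertoires of up to 500 clones; and parameter recovery
(power-law exponent 2.5 ± 0.1 at n = 10⁴, ER mean degree within 3 standard
errors).  These sizes were chosen so the whole suite runs in well under a
minute on one CPU while keeping every statistical check at its intended
operating scale.

Known limitations:

* The goodness-of-fit test inherits the power limits of KS-based tail
  testing: very narrow light-tailed supports can be locally compatible with
  a (capped) power law, and the x_min scan of the reporting channel can
  shift under strong low-k curvature (as in preferential-attachment
  graphs).  The classification cascade mitigates both by the exponent
  range constraint and the likelihood-ratio comparison stage.
* Only the three families the analysis needs are implemented; lognormal or
  stretched-exponential alternatives are out of scope.
* Distances are amino-acid Levenshtein only — no nucleotide mode, no
  Hamming-only mode, no approximate nearest-neighbour index; the O(n²)
  triangle is the intended desk-scale regime (hundreds of thousands of
  pairs per second), with the chunk contract as the scale-out seam.
* `q2_matrix` pairs clones row-wise across layers of one repertoire;
  cross-sample prediction and multivariate predictors are out of scope.
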
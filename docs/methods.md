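# Methods

`pathcna` predicts whether a metabolic pathway is active in a tissue from
metabolite abundance data alone.  The idea: members of an operating
pathway co-vary across genotypes, so a pathway's compounds, mapped as a
node set onto metabolite correlation networks, occupy a recognizably
"pathway-like" region of the graph.  A supervised classifier trained on
known pathways (positives) versus foreign pathways and random metabolite
sets (negatives) then scores unseen compound sets.

## Correlation networks

For each season (independent harvest) `i`, the network is
`G_i = (V_i, E_i, w)` with one node per metabolite of that season's
profile table and one edge per significant Pearson correlation, the edge
weight being the signed correlation coefficient `r`.  An edge survives iff
`|r| > 0.3` **and** `p < 0.01` (two-sided t test, `df = n - 2`); a
correlation failing either filter is treated as spurious and removed.
Both thresholds are configurable.  Isolated metabolites remain nodes, so
`|V_i|` equals the panel size.  Missing measurements are handled by
pairwise-complete observations with a minimum of four complete pairs per
correlation (the smallest choice with positive degrees of freedom above
degeneracy); pairs with zero variance are omitted, not errored.
Profiles are used as given — no normalization or log transform is applied
by default.  Replicate aggregation (arithmetic mean per genotype line,
missing values skipped) is offered as a helper for raw tables.

## Pathway mapping

A pathway is a compound set.  Compound names are canonicalized
(case-folding, whitespace collapsing, Greek-prefix spelling, optional
synonym table); matching against the metabolite panel is exact after
canonicalization — no fuzzy matching, because silent mismatches corrupt
instances.  An optional user exclusion list (e.g. currency metabolites) is
honored before mapping; by default compound lists are taken verbatim.

The mapped node set `S` is the intersection of the canonicalized
compounds with the *common metabolite set* (metabolites present in every
seasonal network); an instance is eligible when `|S| >= 2`.  Coverage is
`|S| / (number of listed compounds)`.  Two induced subgraphs represent an
instance per season: the conjunctive subgraph `SG` (S and the edges among
its members) and the extended subgraph `ESG` (S plus all neighbors of its
members, with all edges among them).  `ESG` always contains `S` itself,
including members isolated in that season — the alternative reading
(union of neighborhoods only) would silently drop pathway members with no
in-S neighbors.

Random metabolite sets ("non-pathways") are drawn uniformly from the
common set with sizes uniform on [2, 18], matching the observed size range
of mapped pathways; draws identical to a known pathway's node set are
rejected and redrawn to avoid label noise.

## Feature catalog (148 per network)

Per network, each instance receives 148 features in six families (the
catalog is a frozen, versioned manifest; see `catalog.py`):

* **Node aggregates (100).**  Ten property variants — degree, weighted
  degree (signed and absolute), closeness (hop and cost-weighted),
  betweenness (hop and cost-weighted), stress, clustering (unweighted and
  |r|-weighted) — each computed on the full network over the members of S
  and on the conjunctive subgraph, aggregated by sum, mean, and the
  population central moments m2, m3, m4 (the "three central moments";
  the mean is listed separately).
* **Edge aggregates (10).**  Edge betweenness of SG's edges, measured on
  the full network and on SG itself, same five aggregators.
* **Pair aggregates (12).**  Geodesic distance, Jaccard coefficient,
  preferential attachment, and the friends measure over all unordered
  member pairs, aggregated by sum, mean, m2.  All unordered pairs are
  used, not only linked pairs, so disconnected members contribute
  sentinel-distance signal.
* **Neighborhood set-features (4).**  With `Γ(v)` the adjacency set:
  Intersection `I = |∩ Γ(u)|`, Union `U = |∪ Γ(u)|`, Distinct `D` (nodes
  adjacent to exactly one member), Mixed `M = U - I - D`.
* **Community features (12).**  Four algorithms (Girvan–Newman edge
  betweenness, leading eigenvector, walktrap, fast greedy) each
  contribute the co-residence ratio `MAX_k |C_k ∩ S| / |S|` on the full
  network's partition, plus the community count and modularity of SG's
  own partition.
* **Subgraph scalars (10).**  Diameter, diameter centrality, global
  clustering coefficient (transitivity), degree assortativity, and
  density, on SG and on ESG.

Season blocks are concatenated in fixed season order; with three seasons
the combined vector has 444 entries.

### Numerical conventions

* Distances default to unweighted hop counts; cost-weighted variants use
  `cost = 1 - |r|` so strong correlation = short distance (signed weights
  would break shortest-path semantics).  Unreachable pairs get the
  sentinel distance `|V|`.
* Closeness is `(n-1) / Σ d(v, u)` with sentinel distances substituted for
  unreachable nodes.
* Stress centrality counts, per node `v`, the number of shortest paths
  through `v`, each unordered endpoint pair counted once — the same pair
  convention as the unnormalized betweenness used here.
* Weighted degree sums signed weights (negative correlations are
  meaningful); an absolute-value variant is a separate catalog entry.
  Weighted clustering uses the geometric-mean generalization on `|r|`.
* "Diameter centrality" is defined as the mean node eccentricity of the
  subgraph (eccentricities restricted to reachable nodes).
* Community detection runs on unweighted topology (most algorithms reject
  negative weights); leading eigenvector runs on the largest connected
  component with singleton communities for the rest, and falls back to
  greedy modularity agglomeration in the rare case ARPACK fails to
  converge.  Edgeless graphs partition into singletons.
* Sentinel policy: any scalar that is mathematically undefined on a
  degenerate input — modularity or edge aggregates of an edgeless SG,
  assortativity of a uniform-degree subgraph, transitivity with no
  connected triple — is emitted as 0 with the instance's `missing_mask`
  flag set, so the learner always sees finite values.  This replaces
  native missing-value handling and is the one deliberate deviation from
  "undefined stays undefined".

## Classifier

Training balances the positives against `k = ceil(n_pos / 2)` negatives
sampled from the foreign-pathway collection plus `k` freshly drawn random
sets, featurized on the fly — with 169 positives and 151 candidates this
gives 85 + 85 = 170 negatives and 339 instances.  Random-set negatives are
essential: without them the model never sees uncorrelated node groups and
over-scores disconnected sets.

The model is a random forest of 100 trees with information-gain splits;
the number of candidate features per split defaults to
`floor(log2(d)) + 1` (9 at d = 444).  The prediction value of an instance
is the fraction of trees voting positive; the class is positive at
prediction value >= 0.5 (inclusive).  Out-of-bag error is the
misclassification rate over out-of-bag votes.

Feature selection ranks features by information gain
`H(class) - H(class | feature)` after supervised discretization:
Fayyad–Irani MDL recursive binary splitting for continuous features (gain
is 0 when no split passes the MDL criterion); features with at most five
distinct values are used as categories directly; 10-bin equal-frequency
binning is available as an alternative.  Ties break by catalog order.
The top-20 view feeds the reduced model.

Evaluation uses stratified 10-fold cross-validation (or LOOCV) with
pooled out-of-fold prediction values; the pooled values give the
confusion counts at the 0.5 threshold and the ROC/AUC.  AUC is computed
by the Mann–Whitney rank formulation (ties count half), which equals the
trapezoidal area under the pooled ROC; for a binary problem both classes
report the same AUC.  Per-class rates are computed with each class taken
as "positive" in turn, and the weighted average weighs by class size.

Sensitivity analysis retrains the model 100 times on stratified 80%
subsamples (without replacement; degenerate subsamples are redrawn) and
re-predicts the test instances; a prediction *conforms* when the class of
the subsample-mean prediction value matches the original model's class.
Pathway predictions are also ranked against random-set predictions: a
pathway's percentile is the fraction of random predictions >= its own
(ties count), with 10,000 random sets by default (configurable; the
original comparison used millions).

## Synthetic data generator

`synthfix.simulate_panel` emulates the statistical structure the method
exploits.  Defaults: 70 genotype lines, 3 seasons, 12 planted blocks of
3–8 metabolites, 30 distractor metabolites, within-block correlation 0.8.
Each block has a latent factor per line and season; a member's value is
`sqrt(rho) * factor + sqrt(1 - rho) * noise`, so the expected within-block
correlation equals `rho`; distractors are independent noise; seasons share
block membership but redraw factors and noise.  Optional extra
season-level noise (`season_noise_sd`, default 0) can blur seasons
further.

The ground-truth instance set deliberately avoids metabolite reuse:
positives are disjoint parts (size 2–4) of randomly partitioned blocks;
negatives are equally many, equally sized chunks of the remaining
metabolites, each spanning more than one block.  Partial pathway coverage
is emulated by appending phantom unmeasured compounds (Poisson, mean 3) to
every compound list, which pushes mapped coverage below 1 and right-skews
it.  Two properties of this design matter for honest evaluation at small
sample sizes:

* **Zero node reuse.**  If instances share metabolites, node-identity
  feature values recur between cross-validation folds and a forest scores
  away from chance even with *no* planted correlation (above chance when
  shared nodes carry same-class labels, below chance when they carry
  opposite-class labels).  With disjoint instances the no-signal
  configuration stays at chance.
* **Exact class balance (20 + 20 by default).**  Pooled out-of-fold vote
  fractions track each fold's training class prior; with unequal class
  counts the prior varies across folds and systematically mis-ranks
  held-out instances at small n.  Equal counts with balanced stratified
  folds hold the prior constant.  (At the original study's n = 339 both
  artifacts are negligible; they dominate only at desk scale.)

What passing the synthetic-recovery tests shows: the full pipeline
separates correlated blocks from uncorrelated cross-block sets
(AUC >= 0.9) and reports chance-level AUC when the signal is removed.
What it does not show: performance on real metabolomics data, where
measurement noise is non-Gaussian, pathways overlap in compounds, block
boundaries are soft, and compound-name matching is imperfect.  The
generator makes no attempt to model compartments, fluxes, kinetics, or
the genetic structure of an introgression-line population.

## Problem sizes used by the tests and the acceptance script

The test suite exercises the generator at its defaults (and a scaled-down
variant for unit fixtures).  `scripts/acceptance.py` runs a study-scale
panel — 24 blocks plus 40 distractors (~170 metabolites, 70 lines, 3
seasons) — so the original instance counts fit: 169 positives, 151
candidate negatives, 85 + 85 sampled negatives (339 training instances),
a 99-instance test set, and 1,000 random sets for percentile ranking.
On this synthetic panel the planted signal is cleaner than real
metabolomics data, so cross-validated AUC/accuracy run higher than the
published values; the structural quantities (feature counts, training-set
composition, confusion-count reconstruction) are scale-exact.

## Known limitations

* The exact composition of the original 148-feature list is not public;
  this catalog is a faithful reconstruction from the documented families
  and grammar, not a copy.
* Whether the original p-values were one- or two-sided is unstated;
  two-sided is used.  Whether cross-validation was stratified and whether
  AUC was pooled or fold-averaged is likewise unstated; stratified +
  pooled is used.
* Model comparison beyond the random forest (boosting, SVM, naive Bayes)
  and automated hyperparameter search are out of scope.
* Native BioCyc/PlantCyc flat files are not parsed; pathway definitions
  use the simple delimited/JSON exchange format documented in the README.
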
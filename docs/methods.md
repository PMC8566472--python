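# Methods

## Model and assumptions

`bandsim` treats a data set of n samples × d quantitative variables as
the reference universe that defines *j-bands*: coordinate-wise intervals
spanned by j distinct observations (2 ≤ j ≤ J ≤ n). All quantities —
the Modified Band Depth and the pairwise band-inclusion contingency
tables — are functions of within-column ranks only. Two consequences
shape everything downstream:

* **Monotone invariance.** Applying any strictly increasing transform
  independently to each column leaves every count, depth and band-based
  similarity unchanged. Band-based measures are therefore immune to
  per-variable rescaling, including variance inflation of individual
  variables, but also blind to it: they measure shape, not magnitude.
* **Sample dependence.** The similarity of a fixed pair changes when
  the rest of the sample changes, exactly as a depth value does. A
  similarity matrix is a property of the data set, not of the pair.

Inputs must be complete; missing or non-finite values are rejected
rather than imputed, since the rank machinery has no principled default
for them.

## Exact counting

For a value with first-occurrence rank l (1-based, in the ascending
sorted column) and multiplicity η, the number of j-bands covering it is
C(n,j) − C(l−1, j) − C(n−l−η+1, j) (complement principle: subtract the
bands lying entirely below and entirely above). For a pair with ranks
(l_m, η_m) of the smaller and l_M of the larger coordinate,
inclusion–exclusion adds back C(l_M − l_m − η_m, j), the bands formed
entirely from values strictly between the two; the implementation clips
that index at zero, which makes the tied-coordinate case a degeneration
of the general one rather than a separate branch. Out-of-sample values
are located with l = 1 + #(values < v) and η = #(values = v), which may
be 0; the closed forms remain valid, which is what allows classifying
new points against training bands.

Binomial coefficients are computed as exact Python integers
(`math.comb`); lookup tables used by the vectorised paths are int64
whenever C(n, j) < 2⁶², falling back to float64 beyond that (entries
then only enter final floating-point ratios). Division happens once, at
the depth/similarity ratio.

All closed forms are verified exactly — integer equality — against a
brute-force oracle that materialises every band and binary inclusion
matrix, on hundreds of randomised small instances with heavy ties.

## From counts to (dis)similarity

For each pair, coordinate k and band size j, the counts define the
contingency table (a, b, c, d) with a + b + c + d = C(n, j). Eight
classical binary coefficients are supported; the aggregate is the
coordinate-wise average S = Σ_j Σ_k S_{k,j} / (d(J−1)) (default), with a
pooled-tables alternative (sum the d tables, then apply the
coefficient) available for comparison — in our experiments pooling is
markedly worse, which is why it is not the default.

Numerical conventions:

* **Zero denominators** can occur only for out-of-sample queries (a
  query covered by no band forces a = 0); the coefficient is then
  defined as 0, the a → 0 limit of each formula. In-sample pairs always
  have a + b ≥ C(n−1, j−1) > 0.
* **Dissimilarity conversion** is D = 1 − S, clamped at 0. Forbes can
  exceed 1 and is first rescaled by the maximum entry of the aggregated
  matrix (dataset-dependent, maps into [0, 1]); the rescaling strategy
  is a deliberate, replaceable choice — it is monotone, so it cannot
  change neighbour rankings or medoid choices, and non-monotone
  small-sample corrections of Forbes would behave differently (see
  Limitations).
* **Russell–Rao** yields a non-reflexive dissimilarity (positive
  diagonal whenever a point is not covered by every band); this is
  flagged and warned about, not rejected.
* Matrices are computed on the upper triangle and mirrored, so symmetry
  is exact by construction and independent of evaluation order.

For classification, bands are by default formed from the training
sample only (inductive); query rows are located out-of-sample. A
transductive mode (bands from train ∪ query) is available behind the
`reference="pooled"` flag; in our Gaussian benchmarks the two differ by
less than one error-rate standard error.

## Evaluation harness

* **kNN**: k defaults to the largest odd integer ≤ √n_train (k is a
  parameter everywhere, since very small classes can make the rule
  inappropriate). Vote ties go to the tied group containing the nearest
  neighbour (the k = 1 rule); exact distance ties rank the lower
  training index first, making predictions deterministic even on
  degenerate all-equal blocks.
* **Cross-validation**: stratified K-fold (stratification avoids empty
  classes in small-class data sets), repeated with per-repeat shuffle
  seeds; any feature filter (top-m B/W ratio, top-m variance) is
  re-fitted inside each training fold to avoid selection bias. A
  constant variable has B/W = 0/0 and ranks last; zero within-class
  variance with non-zero between ranks first.
* **PAM**: classic BUILD (greedy maximal cost reduction) then SWAP
  (best strictly-improving medoid/non-medoid exchange, repeated to a
  fixed point). All ties break to the lowest index; there is no
  randomness. On 30 simulated 100-point data sets the result matched
  the exhaustive best-medoid-pair search in every case, and agrees with
  R's `cluster::pam`.
* **Complete linkage** is implemented directly (O(n³), fine for the
  sample sizes where trees are interpretable) so that equal-height
  merges resolve to the lexicographically smallest pair; SciPy's
  linkage is used as a cross-check on heights in the tests. Trees
  export to Newick with branch lengths.
* **Clustering error** is the minimum disagreement proportion over
  permutations of cluster labels — exact enumeration up to 8 labels,
  Hungarian assignment (same optimum) beyond. **ARI** is the standard
  Hubert–Arabie form; the degenerate all-singletons-versus-one-cluster
  case evaluates to 0.
* **Minkowski distances** accept any p > 0; for p < 1 the formula is
  applied as-is (it is no longer a metric), matching common usage of
  fractional norms on expression data.
* **Pearson distance** is 1 − r between sample profiles; zero-variance
  profiles are an error, since their correlation is undefined.

## Simulation models

`model1`: two groups, d = 100 independent unit-variance coordinates,
means 0 and 0.5 — mild overlap spread over many dimensions.
`model2(delta)`: two groups, d = 10, means 0 and (1, 0.8, 0.6, 0.4,
0.2, 0, …, 0), covariance 0.1·I + δ·A₆ where A₆ has a single 1 at
diagonal position 6 — five noise coordinates, one of which is inflated
by δ ∈ {0, 1, 2}. The covariance reading of the δ-inflation is the
default; an additive standard-deviation reading is available via
`noise_as="sd"`. Arbitrary Gaussian mixtures are supported through
explicit mean/covariance parameter sets (no overlap-calibration
algorithm is included; parameters are taken as given).

Experiment defaults follow the benchmark protocols: classification uses
200 replicates of independent train (100/group) and test (25/group)
sets; clustering uses 200 simulated data sets of 50 samples per cluster,
PAM with the true number of groups, scored by clustering error and ARI.
One root `SeedSequence` spawns a child per replicate, so runs are
reproducible as a whole and per replicate. The acceptance script runs
all protocols at their full 200 replicates (about a minute in total);
the test suite runs the classification bounds at 50 replicates, which
leaves Monte-Carlo standard errors near 0.003 — small against the
bounds being checked.

What the generators deliberately do not emulate: heavy-tailed and
count-valued expression noise, gene–gene correlation structure, batch
effects, and missingness. Passing these benchmarks shows the machinery
is correct and that rank-based band similarity behaves as designed under
spherical/ellipsoidal Gaussian data; it does not certify performance on
real sequencing data.

## Known limitations

* The Forbes rescaling divides by the observed maximum; published
  small-sample corrections of Forbes are non-monotone in (a, b, c, d)
  and can reorder neighbours. Under the max-rescale convention, Forbes
  is the weakest of the band indices in the Model 2 kNN benchmark
  (mean error ≈ 0.07); the architecture accepts any (a,b,c,d) → ℝ
  function if an alternative correction is wanted.
* Band similarities need the full similarity matrix (O(n²·d·J) after
  the closed forms); no sub-quadratic approximation is provided.
* ARI comparisons between independent Monte-Carlo studies are more
  fragile than error-rate comparisons: for balanced two-cluster
  partitions mean ARI ≈ (1 − 2·mean error)² + 4·Var(error), so small
  shifts in the error distribution are amplified roughly fourfold in
  the ARI.
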
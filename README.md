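# bandsim

Band-based (dis)similarity measures for multivariate quantitative data —
gene expression in particular — built on the combinatorics of the
Modified Band Depth (MBD), with a classification/clustering evaluation
harness and Gaussian simulation benchmarks.

## The problem and the method

Clustering or classifying expression profiles requires a notion of
proximity between samples. The Euclidean distance assumes noise-free
magnitudes; correlation distance assumes linear relationships. `bandsim`
instead transfers quantitative profiles into a space of binary band
inclusions and measures proximity there, which makes the resulting
(dis)similarities rank-based, shape-oriented and *sample-dependent* (the
proximity of two samples depends on the rest of the data set, just as a
depth value does).

Given a sample **y**₁, …, **y**ₙ ∈ ℝᵈ, a *j-band* is the coordinate-wise
interval spanned by *j* distinct observations. For each coordinate *k*
and band size *j* (2 ≤ j ≤ J), let N⁽ʲ⁾ₖ(**y**) be the number of the
C(n, j) bands whose *k*-th interval contains y_k, and
N⁽ʲ⁾ₖ(**y**₁, **y**₂) the number containing both coordinates of a pair.
The MBD of a point is

    MBD_{n,J}(yᵢ) = Σ_{j=2}^{J} (1 / (d·C(n,j))) Σ_k N⁽ʲ⁾ₖ(yᵢ),

and for each pair, coordinate and band size, the counts define a 2×2
contingency table over the bands:

    a = N⁽ʲ⁾ₖ(y₁, y₂),   b = N⁽ʲ⁾ₖ(y₁) − a,
    c = N⁽ʲ⁾ₖ(y₂) − a,   d = C(n,j) − N⁽ʲ⁾ₖ(y₁) − N⁽ʲ⁾ₖ(y₂) + a.

Eight classical binary similarity coefficients are evaluated on these
tables — simple matching SM = (a+d)/n, Jaccard J = a/(a+b+c), Simpson
S = a/min(a+b, a+c), Forbes F = a·n/((a+b)(a+c)), Dice D = 2a/(2a+b+c),
Anderberg A = a/(a+2(b+c)), Ochiai O = a/√((a+b)(a+c)), Russell–Rao
RR = a/n — and averaged as 𝒮 = Σ_j Σ_k 𝒮_{k,j} / (d(J−1)), then
converted to a dissimilarity 𝒟 = 1 − 𝒮 (Forbes is first rescaled into
[0, 1]; Russell–Rao yields a non-reflexive 𝒟, which is flagged).

None of the exponentially many bands is ever enumerated: with *l* the
rank of the first occurrence of a value in its sorted column and *η* its
multiplicity, the counts follow in closed form from the complement
principle and inclusion–exclusion, e.g.

    N⁽ʲ⁾ₖ(y) = C(n,j) − C(l−1, j) − C(n−l−η+1, j),

so the cost scales linearly in J. A brute-force enumeration oracle is
included and the closed forms are tested against it exactly.

The evaluation harness provides kNN on precomputed dissimilarity blocks
(k = largest odd integer ≤ √n_train, vote ties resolved by the nearest
neighbour), repeated stratified 10-fold cross-validation with per-fold
feature selection (B/W ratio or variance filters), deterministic PAM
(BUILD + SWAP), complete-linkage trees with Newick export, the
label-permutation clustering error rate and the adjusted Rand index,
plus the classical Euclidean / Manhattan / Minkowski(p) / Pearson
baselines.

## Worked example

Simulate two 10-dimensional Gaussian groups whose separation lives in
five signal coordinates while one noise coordinate has its variance
inflated by δ = 2 (the built-in Model 2 scenario), then race the
Euclidean distance against the band-based Simpson index under PAM:

```python
from bandsim import (model2, ExperimentConfig, DistanceSpec,
                     run_clustering_experiment)

cfg = ExperimentConfig(
    task="clustering",
    model=lambda n, s: model2(delta=2.0, n_per_group=n, seed=s),
    specs=(DistanceSpec.euclidean(), DistanceSpec.band("S", J=2)),
    B=50, n_per_cluster=50, seed=0,
)
print(run_clustering_experiment(cfg).summary().round(4))
```

prints

```
           error_mean  error_std  ari_mean  ari_std
method
euclidean      0.3814     0.0704    0.0667   0.0779
S_2            0.0734     0.0305    0.7289   0.1056
```

The inflated noise coordinate wrecks the Euclidean clustering (38%
error, ARI ≈ 0.07: barely better than chance), while the band-based
Simpson dissimilarity — invariant to any monotone rescaling of a
coordinate — keeps a 7% error and ARI ≈ 0.73.

The same operations are available from the shell:

```sh
bandsim depth  --input expr.csv --j-max 3 --out depths.csv
bandsim dissim --input expr.csv --measure S --j-max 2 --out dsim.csv
bandsim cluster --input expr.csv --measure S --method hclust \
    --out merges.csv --newick-out tree.nwk
```

For a small 8-sample matrix the first command writes per-sample MBD
values such as `s2,1.455357143` (deep, central profile) versus
`s4,0.9732142857` (peripheral); the second writes a symmetric CSV with
zero diagonal, e.g. `s1,0,0.1192630899,…` — sample pairs within a group
sit around 0.1–0.25, across groups around 0.4–0.6. Expression files with
genes in rows are read with `--orientation samples-in-columns`.

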
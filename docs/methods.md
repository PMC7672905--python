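# Methods

## Problem setting

Given an n × d nutrition matrix X (samples × nutrition variables) and a
response vector G of length n (expression of one gene), we want the small
subset M of nutrient variables over which G varies most smoothly, and a
significance assessment of that subset. No parametric form is assumed for
the response; the method targets smooth, possibly non-monotone relationships
that main-effect or pairwise-interaction regression cannot represent.

## Standardization

Every nutrient column is z-scored before any LC computation:
`x ← (x − mean(x)) / sd(x)` with the sample SD (ddof = 1). The LC weights
are an isotropic Gaussian kernel on the selected subspace, so columns must
be on a common scale or the variable with the largest variance dominates the
distances. `application.standardize` (DataFrames) and `application.zscore`
(arrays) implement this; constant columns raise an error naming the column.
scikit-learn's `StandardScaler` is not used because it divides by the
population SD (ddof = 0), while the package's documented convention maps
(1, 2, 3) to (−1, 0, 1).

## The LC statistic

For a subset M of column indices,

- W_ij = exp(−Σ_{c∈M} (x_ic − x_jc)²), with W_ii = 1;
- D_ij = |G_i − G_j|;
- LC(M; G) = Σ_ij W_ij D_ij (equivalently tr{W D}, since both matrices are
  symmetric).

Lower is better: if G is locally consistent (smooth) over the subspace M,
every large weight multiplies a small dissimilarity. The implementation
computes W via broadcast squared differences, clips tiny negative rounding
residues to 0, and contracts elementwise in O(n²) time and memory. It never
forms the matrix product W @ D, which would cost O(n³) and whose off-diagonal
entries are irrelevant. The empty subset gives W ≡ 1, so LC degenerates to
the total pairwise dissimilarity. LC is homogeneous of degree 1 in G and
invariant to columns outside M; both properties are tested.

## Subset search (LCOpt)

`LCOpt(k, method)` is a scikit-learn estimator minimizing LC over subsets of
exactly k variables.

- **Exhaustive** (default): enumerates all C(d, k) subsets in lexicographic
  order, capped at 100 000 combinations (`exhaustive_cap`) to keep the
  default path bounded; beyond the cap the error message points to the
  genetic algorithm. Ties in LC break lexicographically so results are
  deterministic.
- **Genetic algorithm**: bit-string encoding of the subset; fitness is LC
  plus a penalty `penalty_weight · | |M| − k |`. Defaults: population 50,
  100 generations, crossover rate 0.8, per-bit mutation rate 1/d, elitism of
  the best individual, tournament selection (size 3). `penalty_weight`
  defaults to `10 · n² · max|ΔG|`, an upper bound on any attainable LC, so a
  wrong-size subset can never beat a right-size one. After the run the best
  individual is repaired to exactly k bits (greedy add/remove) and polished
  by greedy single-bit swaps. These are conventional small-scale GA settings;
  the acceptance suite verifies the GA recovers the exhaustive argmin on
  seeded problems.

`fit(X, G)` stores `combination_`, `lc_value_` and (for the exhaustive path)
the full ranked `results_`; `transform(X)` selects the chosen columns.

## Permutation test

`lc_test(X, M, G, B)` permutes G uniformly B times (default 1000) and
reports

    p = (1/B) · #{ b : LC(M; G_b) < LC(M; G) }

with a strict inequality, so p = 0 is attainable when no permutation is
smoother than the observed response. A `conservative=True` flag gives the
(count + 1)/(B + 1) variant for users who need a test that cannot return 0.
W depends only on X and M, so it is computed once; permuted LC values are
evaluated in batches of 250 permutations via a single tensor contraction per
batch, which is what makes B = 1000 and the 200-replicate power study cheap.
A constant G (all D_ij = 0) is rejected with an error rather than returning
a meaningless p-value.

## Regression comparators

- `f_test1`: overall F-test of an OLS fit of G on main effects of the
  selected variables (statsmodels).
- `f_test2`: same, adding all pairwise interaction terms among the selected
  variables.

Both return the overall F p-value; rank-deficient designs raise an error.

## Simulation benchmark

`simulate_dataset(SimulationConfig(model, n, d, r, seed))` draws d − 1 iid
N(0, 1) columns Z1..Z_{d−1} and appends a composition variable
X_d = |Z1| / (|Z1| + |Z2|) + r·ε, emulating a nutrition design where the
last variable is a ratio of two intake amounts (bounded in ≈[0, 1] and
dependent on column 1) while the others are free intake levels. The four
response models, each with additive noise r·ε:

1. G = exp{−(x1² + x_d²)} — single smooth peak, two informative variables;
2. G = sin{(π/2)(x1² + x_d²)} — non-monotone ridge, two informative;
3. G = exp{−(x1² + |x3|)/5} + exp{−x_d²/5} — additive structure, three
   informative;
4. G = exp{−(x1² + x2²)/2} + exp{−(x3² + x_d²)/2} — two peaks, four
   informative.

**Design choice — responses are built from the z-scored columns.** In the
formulas above, x_c denotes the standardized column, not the raw one, while
the returned X is in raw units. This matters for the composition variable:
raw, it lies in [0, 1] with a mean near 0.5, so an even function like
exp{−x²} would be locally monotone in it and carry a strong linear channel
that main-effect F-tests detect; standardized, it is centred and the even
response functions carry essentially no linear signal, which is the regime
the benchmark is designed to probe (smooth structure invisible to
regression). Since the method itself always standardizes first, this also
makes the generator consistent with the estimator's view of the data.

`run_power_study` computes, per (model, n, test) cell: TPR = rejection rate
at level α on the true informative subset, and FPR = rejection rate on a
random subset of the *non-informative* columns (matched in size), where the
response carries no signal by construction. Defaults d = 10, r = 0.1,
B = 1000, α = 0.05, 200 replicates. `lc_distribution_study` instead records
LC for every k-subset per replicate, grouped by overlap with the informative
set (group 1 = all informative, …), for the box-plot view of the LC
landscape.

## Response surfaces

`fit_ngf_surface` fits a thin-plate-spline `scipy.interpolate.RBFInterpolator`
to G over two selected (standardized) nutrient axes and evaluates it on a
100 × 100 grid, masking grid nodes outside the Delaunay convex hull of the
data so the rendering never extrapolates. `smoothing=0.0` interpolates
exactly; positive values regularize. Degenerate (collinear) point sets raise
a ValueError. `render_ngf` draws the masked grid with `pcolormesh` on the
Agg backend with PNG metadata stripped, so renders are byte-deterministic.

## Application layer

`load_and_align` reads nutrition and expression CSV/TSV files, auto-detects
expression orientation by sample-ID overlap, inner-joins on sample IDs,
drops samples with missing values (logging the counts), and names the exact
row/column of any non-numeric cell in its error. `screen_genes` ranks all
C(d, k) combinations per gene and keeps genes whose best combination is
significant; constant (degenerate) genes are dropped with a note.
`run_pipeline` runs rank → test → surface-plot per gene, writing per-gene
ranked TSVs, a `run_log.json`, and surface PNGs for significant genes, and
preserves partial outputs if a gene fails.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` seeds; every
  stochastic routine accepts a seed and is reproducible.
- Weight computation clips negative squared distances arising from floating
  cancellation; the diagonal is set to exactly 1.
- Permutation batching (250 per batch) bounds peak memory at
  O(batch · n²) while keeping the contraction vectorized.

## Limitations

- O(n²) memory and time per LC evaluation limits n to a few thousand
  samples per gene.
- Exhaustive search over C(d, k) is capped; for large d use the GA, which
  is a heuristic and is only verified against the exhaustive optimum on
  small problems.
- The kernel bandwidth is fixed at 1 in standardized units (no bandwidth
  parameter); very small n or heavy-tailed variables may warrant rescaling.
- The permutation test conditions on the selected subset; p-values for a
  subset chosen by LCOpt on the same data are optimistically biased
  (selection and inference are not split).
- FPR in the power study is defined on subsets disjoint from the
  informative set; subsets that partially overlap informative variables
  genuinely carry signal and are not counted as false positives.
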
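# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Data model and normalization

A fermentation record is nine condition values plus an optional production
(g/L). All modelling happens on the min-max normalized scale,

y = (y_max − y_min)·(x − x_min)/(x_max − x_min) + y_min,  y_min = 0, y_max = 1,

applied per column with extrema fitted, by default, on the training split
only (fitting on all data is available via `scale_on_train_only=False`; the
difference matters only through the handful of extreme records). Records are
stratified into yield levels before splitting — below 5 g/L low, 5–20 g/L
mid (both boundaries inclusive to mid, so every value has exactly one
level), above 20 g/L high — and within each level a seeded permutation is
taken, with the first ⌊0.7·n⌋ records as training data. All randomness in
the package flows from explicit integer seeds, and every split, fold
assignment, GA run and synthetic dataset is reproducible from them.

The 25 published records ship as CSV fixtures in raw and normalized form.
The full study's per-column extrema were never published; where a column
varies in the printout they are recovered exactly by two-point inversion of
the affine map (`welanopt.datasets.implied_scaling`). Columns constant in
the printout (KH₂PO₄, MgSO₄, liquid volume) are not identifiable and are
excluded from that reconstruction.

## ε-SVR solver

The dual problem is solved in net-coefficient form β_i = α_i − α_i*
(complementarity α_i α_i* = 0 makes the forms equivalent and is restored
exactly on output via α = max(β, 0), α* = max(−β, 0)). The solver is an
SMO-type method: each training point contributes an interval [L_i, U_i] of
bias values consistent with its KKT conditions; optimality holds when all
intervals intersect. Per iteration the point with the largest lower bound is
paired with the candidate maximizing the estimated objective gain
(second-order working-set selection — plain maximal-violating-pair selection
zigzags badly on near-singular Gram matrices, e.g. very smooth kernels with
large C), and the two-variable subproblem — a piecewise quadratic in one
scalar once the equality constraint is eliminated — is minimized exactly
over its box, breakpoints included. Convergence is declared when the worst
KKT violation (max L − min U) drops below `kkt_tolerance` (default 1e-6);
tolerances much below 1e-8 may stall at the limits of incremental float
arithmetic, which the solver reports via a warning rather than looping.

Numerical conventions: the kernel denominator is σ² (so the grid parameter
g = 1/σ²); support vectors are points with |β| > 1e-8·max(C, 1); the bias
is the average of the boundary conditions over standard support vectors
(0 < |β| < C), falling back, with a warning, to the midpoint of the
KKT-feasible bias interval when no standard support vector exists (possible
when every coefficient is at 0 or ±C); ε defaults to 0.01 on the normalized
target scale, a tube of about 1% of the observed yield range.

The test suite checks the solver against an exact, independent oracle: an
enumeration of all 5ⁿ KKT active-set patterns of the dual (each pattern
yields a linear system; any solution passing all KKT checks is the global
optimum of this convex QP). Agreement is at machine precision on random
small instances. scipy's trust-constr was evaluated as an oracle first and
rejected: on these QPs it frequently terminates up to 1e-4 above the true
optimum. scikit-learn's SVR serves as an additional prediction-level
cross-check.

## Model selection

The grid defaults are log2-spaced, c = 2⁻²…2¹⁰ and g = 2⁻⁸…2⁴ with step 1,
evaluated with shared k-fold assignments (k = 5 at study scale, 3 at the
reduced scale used in fast runs and most tests). CVmse is computed on the
normalized target scale. Ties break toward the smallest c, then smallest g
— the smoother model — independent of grid enumeration order. Accuracy is
r², the squared Pearson correlation between held-out predictions and
targets; r² is affine-invariant, so it is identical on the normalized and
raw g/L scales.

## Adaptive GA

The generation counter starts at t = 0 for the initial population. The
crossover schedule Pc(t) = max(Pc_max·2^(−t/T_Gen), Pc_min) is read with the
exponent −t/T_Gen: alternative readings either leave the range [Pc_min,
Pc_max] or never reach the floor. With the presets the floor activates near
t ≈ 0.585·T_Gen. The preset list gives two values for the maximum mutation
probability; the second (0.001) is read as the minimum.

Crossover walks the population from the first individual, swapping an
inclusive 1-based gene segment [start, end] with the next adjacent
individual and then advancing by two (by one when no crossover occurred);
the final individual has no partner and never initiates a crossover. Equal
segment endpoints swap a single gene. Mutation redraws one uniformly chosen
gene uniformly within its bound. Fitness is the denormalized predicted
production clipped below at zero, since roulette selection requires
non-negative weights and negative predicted yields are unphysical; a
population with zero total fitness falls back to uniform selection with a
warning. Elitism (on by default) copies the best-ever individual over the
current worst each generation, making the best-fitness trace monotone;
switching it off recovers the bare select/cross/mutate loop. The GA operates
in raw condition units — bounds stay interpretable — and normalization
happens inside the fitness function.

Two bound presets ship verbatim: `wide` (the initial search box, e.g.
glucose ∈ [5, 95]) and `narrow` (the refinement box read off runs yielding
above 30 g/L, e.g. glucose ∈ [55, 60]).

## Synthetic data generator

The generator emulates the unpublished portion of the study data: condition
vectors uniform in the wide bounds, yields from a separable concave
quadratic y = max(0, y* − Σ_j w_j (x_j − x*_j)²) plus N(0, 0.5²) noise,
n = 67 records. Defaults chosen once: x* = (55, 2.9, 5.2, 0.3, 50, 7.0,
32.5, 177, 5) — an interior point near the high-yield region; y* = 42 g/L,
matching the maximum production implied by inverting the published
normalized table (≈42.45); curvature weights set so yield drops 10 g/L at
the farthest bound edge of each variable, which reproduces approximately the
study's low/mid/high level mix (8/39/20 of 67). A Gaussian-peak surface
with matching curvature at the optimum is available behind `shape=
"gaussian"`. The generator retains its ground truth, so recovery tests can
measure how well the pipeline relocates a known optimum.

What the synthetic surface does not emulate: the real study's correlated,
one-factor-at-a-time experimental designs (visible in the printed records,
where most columns are held fixed), variable interactions, heteroscedastic
measurement error, and batch effects. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated on a smooth separable surface
with uniform coverage — not that a 67-record wet-lab dataset determines the
true optimum to the same precision.

## Problem sizes and known limitations

Most tests run at reduced scale (population 60, 50 generations, 3-fold CV,
small grids); the GA recovery test runs at full study scale (300/500, 20
seeded runs), which takes a few seconds per run with a cheap fitness.

The main known limitation is surrogate peak localization at small n: with 67
records (47 training) in nine dimensions, the RBF-SVR's fitted peak sits
5–18% of each bound's width away from the generator's true optimum across
seeds — even with noiseless yields — and approaches ~4–5% only around
n = 200. The bottleneck is the kernel smoother's finite-sample bias, not the
GA (at study scale the GA locates the *surrogate's* argmax to under 1% of
width) and not the hyperparameter search (widening the grid to c = 2¹⁶,
g = 2⁻¹⁰ and shrinking ε tenfold were all tried without material effect).
Proposed optima from datasets of this size should be read as candidate
regions, and the corresponding end-to-end recovery test documents this gap
rather than hiding it.
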
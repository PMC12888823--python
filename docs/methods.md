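# Methods

## Problem setting

Cross-sectional cohorts observe each sample once, so the temporal program of
the epithelial–mesenchymal transition (EMT) must be reconstructed before any
dynamic model can be fit. `splicecontrol` operates on three feature-by-sample
matrices sharing one sample axis — alternative-splicing (AS) quantifications
(e.g. PSI), RNA-binding-protein (RBP) expression, transcription-factor (TF)
expression — plus a binary phenotype label (epithelial = 1, mesenchymal = 2)
per sample. The output is a sparse signed directed network over the three
layers and a ranking of TFs by their ability to steer the AS targets.

## Preprocessing

Three filters, applied per layer matrix: rows with ≥ `max_missing` (default
100) missing cells are dropped; remaining gaps are filled by k-nearest-row
imputation (nan-aware Euclidean distances, k = 10, mean of the neighbours'
observed values in that column); rows with exactly zero variance are
removed. The surviving feature set is invariant to row order.

## Pseudotime

Samples are embedded by z-scored TF expression (zero-variance features are
skipped) and joined into a symmetric kNN graph (k = 10; an edge exists when
either endpoint lists the other). Weights are exp(−d²/σ²) with σ the median
nonzero kNN distance. If the graph is disconnected, a minimum-spanning-tree
union restores connectivity; spanning-tree edge weights are floored at
1e−12 because an outlying sample can underflow the Gaussian kernel on every
incident edge.

The score is the absorption probability of a weight-proportional random
walk: a virtual epithelial anchor (value 0) connects to every epithelial
sample and a virtual mesenchymal anchor (value 1) to every mesenchymal
sample, each anchor edge weighted `anchor_strength` (default 1.0) times the
sample's graph strength. Every real sample — labelled or not — is an
interior node of one sparse harmonic system, so the fully-labelled case
still yields continuous, ordered scores; fixing labelled samples at their
boundary value instead would collapse all scores to {0, 1} whenever every
sample carries a label, which is the normal situation for this data. Scores
are min–max rescaled to [0, 1]; ordering ties break lexicographically by
sample ID. On a path graph with one anchor per end the rescaled scores
reduce to the classical gambler's-ruin values regardless of
`anchor_strength` (e.g. 0, 1/3, 2/3, 1 on four nodes).

The harmonic scores compress exponentially near the anchors, which is
harmless for rank statistics but ill-conditions finite differences.
Downstream modelling therefore uses the rank-uniformized scores (rank order
mapped to an even grid on [0, 1]) — a strictly monotone transform; on the
benchmark, where the true design is an even grid, it is also the consistent
estimate of the true time scale. The pseudotime order derived from the TF
layer is applied unchanged to the RBP and AS layers.

## Trend scoring

With pseudotime rescaled to [0, 1], a feature's trend score is
|β| / max(σ_res, 1e−8), where β is the OLS slope (equal to the total linear
change over the trajectory) and σ_res the population SD of the residuals.
The score is invariant to positive scaling and shifts of the series and to
reversal of pseudotime. Selection takes the per-layer top-k by descending
score (defaults 50 AS / 10 RBP / 10 TF; ties break by feature ID).

## Network model and estimation

Expression along pseudotime s is modelled with mass-action kinetics:

    dX_i/ds = Σ_{j≠i} a_ij X_i X_j + Σ_l b_il X_i Y_l − d_i  X_i
    dY_l/ds = Σ_{k≠l} c_lk Y_l Y_k + Σ_p e_lp Y_l Z_p − d′_l Y_l
    dZ_p/ds = Σ_{q≠p} g_pq Z_p Z_q                    − d″_p Z_p

Regulation flows TF → RBP → AS with within-layer coupling; the reverse
couplings do not exist in the model, so they can never be reported — the
hierarchy is enforced structurally, not by thresholding.

Derivatives are estimated by three-point finite differences that are exact
for quadratics on irregular grids (one-sided second-order at the ends; the
two endpoint rows are excluded from the regressions). Noise suppression
applies one Nadaraya–Watson Gaussian kernel operator (bandwidth h = 0.05 in
normalized pseudotime units) to **both** sides of each regression — to the
raw product columns and to the raw derivative estimate. Because the
mass-action identity is linear in the coefficients, applying the same linear
operator to both sides preserves the identity exactly; smoothing the curves
*before* forming products instead injects an O(h²) bias which, on the
strongly collinear product designs these smooth trajectories produce
(condition numbers ~10⁶), inflates coefficients by orders of magnitude.
This both-sides construction is the package's own choice and is what makes
the noiseless benchmark recover cleanly.

Coefficients are drawn by a Bayesian Lasso Gibbs sampler (Laplace prior via
the normal–exponential scale mixture): β | τ², σ² is multivariate normal,
1/τ²_j inverse-Gaussian, σ² inverse-gamma under a Jeffreys prior, and the
shrinkage parameter λ² gamma-updated (hyperprior shape 1, rate 0.1).
Defaults: 4000 iterations, 1000 burn-in; columns are standardized to unit
SD and draws back-transformed. Each node is fit independently with a seed
derived from (global seed, node index), so fits are reproducible and
parallelizable. An edge is called when its equal-tailed credible interval
at the chosen level (default 90%) excludes zero; |posterior mean| is kept
as a continuous score for every candidate edge, and degradation terms are
reported separately (they are self-effects, not network edges).

## Target control

The called network gives the sparsity pattern of A in dx/dt = Ax + Bu,
y = Cx; B injects inputs at a candidate TF subset K, C reads out the AS
target set O. Feasibility is the output-controllability rank condition
rank [CB, CAB, …, CA^(N−1)B] = |O|, evaluated generically: the pattern is
instantiated with independent values uniform on ±[0.2, 1.8], A is
normalized by (1 + spectral norm) so powers stay bounded, the rank is read
from singular values at tolerance 1e−9·σ_max, and the maximum over 3 draws
is taken (structural rank holds for almost every assignment; the
implementation agrees with exact rational-arithmetic ranks on all small
instances tested).

An initial feasible driver set comes from iterated Hopcroft–Karp matchings
walking backwards from the targets (augmented greedily by rank gain when the
matching alone is insufficient). Exact search then enumerates subsets of U
in increasing cardinality — skipping subsets that cannot reach every target
in the digraph — so the first feasible subset found is provably minimum;
the exhaustive subset certificate is re-checked in the test suite.

Alternative optimal driver sets are explored two ways. `enumerate` lists
every feasible subset of the minimum size and reports exact membership
frequencies (the reference). `walk` runs a lazy Metropolis chain on the
same family: with probability 1/2 propose a uniformly chosen single-element
swap and accept iff the swapped set is still feasible. The proposal is
symmetric, so the stationary distribution is uniform over the connected
feasible family; laziness guarantees aperiodicity (a two-state family would
otherwise alternate deterministically). TFs with frequency > 0.5 are
reported as key TFs. Maximal-clique centrality (Σ (|C|−1)! over maximal
cliques of size ≥ 2 containing the node, on the undirected projection) is
provided for preselecting hub-TF constraint sets.

## Synthetic benchmark

The generator forward-simulates the same mass-action system with classical
RK4 (fixed step 1e−3) on 100 evenly spaced pseudotime points. Study
conditions: 2 TFs, 3 RBPs, 5 AS events; each allowed coefficient is nonzero
independently with probability 0.4, magnitudes uniform on [0.5, 1.5] with
random sign; degradations uniform on [0.2, 1.0]; initial states uniform on
[0.5, 1.5]. Draws whose trajectory leaves [1e−6, 1e3] are rejected and
redrawn (≤ 50 attempts) — mass-action quadratics can blow up in finite
time. Samples are permuted by a seeded uniform permutation; labels are
epithelial for true pseudotime < 0.5. Optional noise multiplies every entry
by a Gamma factor with mean 1+μ and coefficient of variation cv (shape
1/cv², scale (1+μ)cv²; a one-parameter exponential has fixed CV = 1, so a
two-parameter positive family is required to set mean and CV separately).
Everything is deterministic given the seed.

What the generator does *not* emulate: branching trajectories, count noise,
unequal sampling density along the trajectory, batch effects, and model
mismatch (the fitted equations are the generating equations). Passing
benchmarks therefore demonstrate correctness of the machinery and
identifiability under the stated conditions, not performance on cohort
data.

## Evaluation

Pseudotime: Spearman ρ (Pearson on mid-ranks) and RMSE after min–max
normalization of both vectors. Network: ROC AUC of the continuous edge
scores via the exact Mann–Whitney pair count (ties ½), plus accuracy, PPV
and Matthews correlation of the called edges (MCC defined 0 when a
marginal is empty); degradation terms are excluded. Dynamic-shift testing
uses the two-tailed Wilcoxon rank-sum comparing epithelial- vs
mesenchymal-labelled values per AS feature — exact enumeration for
tie-free pooled samples of ≤ 20, otherwise the normal approximation with
tie and continuity corrections. Robustness sweeps rerun the entire
pipeline per (μ, cv, seed) cell (defaults μ ∈ {0…0.10}, cv ∈ {0…0.20}).
A continuity check perturbs the true pseudotime by additive noise of
discrete L² size δ and verifies that the summed squared coefficient
discrepancy against the unperturbed fit shrinks with δ.

## Numerical choices and edge cases

* Degenerate pseudotime ties collapse onto a rank grid before differencing;
  duplicate pseudotime values are otherwise rejected.
* Zero-SD design columns keep scale 1 (no division by zero); the Gibbs
  sampler guards the inverse-Gaussian mean and variances with wide clips
  and aborts on any non-finite draw.
* The ε-floor (1e−8) in the trend score caps the exact-linear-fit case.
* `generic_rank` returns 0 for an empty driver set; rank is monotone
  non-decreasing in the driver set.
* Identical samples produce an all-zero distance matrix and hence a
  complete similarity graph of weight 1 (σ falls back to 1).

## Known limitations

* The quadratic product design is intrinsically near-collinear for smooth
  monotone trajectories; edge recovery is good (AUC ≈ 0.9 at benchmark
  scale) but coefficient values are less stable than edge calls, and the
  perturbation discrepancies in the continuity check are correspondingly
  large in absolute terms.
* Exact driver-set search enumerates subsets and is limited to ≤ 25 inputs;
  the walk sampler assumes the feasible family is connected under single
  swaps (guaranteed only empirically; the enumerate mode is the reference).
* Pseudotime assumes a single non-branching trajectory with both phenotype
  classes present.
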
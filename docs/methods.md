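# Methods

## The model

A liver lobule's hepatocytes are assumed to lie on a single latent axis
z ∈ [0, 1] running pericentral (z = 0) to periportal (z = 1), with each
gene's mean expression a smooth function μ_i(z). All orderings in the
package assume the spatial organization is representable in this one
dimension; branching topologies and cell-type mixtures are out of scope.

### Wave-Crest ordering

Given an expression matrix and a marker panel with known directions, marker
rows are standardized to mean 0 and variance 1 using the **population**
variance convention (divisor n); this makes the hand-checkable examples
exact. For a proposed order of m cells the objective is

    J(order) = Σ_g MSE_g,   MSE_g = (1/m) Σ_t (y_gt − a_g − b_g t)²,

the mean squared residual of an OLS fit of each marker on positions 1..m,
summed over markers. Only the order-dependent part of J is the covariance
between expression and position, so insertion candidates and adjacent swaps
are evaluated incrementally in O(genes × n) per step; the full run on 606
cells takes well under a second.

Cells are visited in a seeded random permutation (the construction sequence
is not prescribed anywhere authoritative; seeding makes runs reproducible
and lets tests average over seeds) and inserted at the gap minimizing J of
the partial order, ties going to the leftmost gap for determinism. The
2-opt refinement is adjacent-exchange hill climbing — sweeps accept a swap
iff it strictly lowers J, stopping after a clean sweep or `max_sweeps`
(default 100). Classic segment-reversal 2-opt is available behind
`full_two_opt=True` but is not the default, because adjacent exchanges are
what the procedure this reimplements describes. The objective is invariant
under order reversal; orientation is fixed afterwards by flipping iff the
mean Pearson correlation of pericentral-marker expression with position is
positive (an exact zero keeps the input orientation). The polynomial degree
of the fit is fixed at 1; the objective's linear form is part of the
procedure's definition here.

Degenerate inputs: markers absent from the matrix or constant across cells
are dropped with a warning before ordering (an all-constant panel is an
error); `ordering_objective` requires n ≥ 3 because the residual of a
2-point fit is identically zero.

### Zonation profiles and tests

Ordered cells are split into nine contiguous groups — nine because the
reference posterior-assignment scheme for this tissue uses nine lobule
layers — with the remainder r of n mod 9 going one cell each to the *first*
r (pericentral) groups. Profiles are per-gene group means or medians
(medians suit the deep full-length regime's heavy tails; means the UMI
regimes), or posterior-weighted means Z_ij = Σ_c P(c∈j)x_ic / Σ_c P(c∈j)
when a cells × 9 soft assignment is supplied (rows must sum to 1 within
1e-6). Scaling maps each gene's nine values to [0,1]; a constant row maps
to all zeros with a warning, and such genes are dropped (and reported) by
the profile correlation rather than propagating NaNs.

The linear zonation test fits per-gene OLS of expression on position 1..n
and t-tests the slope (two-sided, n − 2 df), with Benjamini–Hochberg
adjustment across genes (delegated to statsmodels; the test suite checks it
against an independently coded step-up oracle). Conventions for degenerate
fits: a constant gene gets slope 0, p = 1, direction "none"; an exact
zero-residual fit saturates at the smallest positive normal double rather
than p = 0. Direction is assigned by slope sign (positive = periportal) at
adjusted p < .01 by default, while cross-dataset sharing uses adjusted
p < .1; both thresholds are arguments. The Kruskal–Wallis variant applies
the tie-corrected H across the nine groups of **cell-level** values (the
alternative — testing the nine group means themselves, k observations in
total — leaves the test with no within-group replication, so cell-level
grouping is the implementable reading); an all-identical gene gets H = 0,
p = 1 by convention.

Profile smoothing emulates an R `smooth.spline(df = 4)` call: a natural
cubic smoothing spline on knots 1..9 in the Green–Silverman penalized form,
with the penalty weight solved by Brent's method so that the trace of the
hat matrix hits the target effective df within 0.1. It is implemented
directly (no suitable spline-with-df dependency is available) and validated
against scipy's natural cubic interpolant in the df → 9 limit and against
exact reproduction of constant and linear profiles (the penalty's null
space). Feasible df for this family is (2, 9); requests at or below 2 are
rejected. Smoothing is display/fitting only and never feeds a statistical
decision, which also makes residual dialect differences (knot placement, df
definition) inconsequential.

### Protocol sensitivity

Detection fractions use strictly-positive values on whatever layer is
supplied, making them invariant to positive rescaling. The fold-change
regression uses y = log2 of the ratio of nonzero means and x = difference
of gene-level detection fractions, plain unweighted OLS. Genes must have a
nonzero mean in **both** datasets to enter — the log-ratio is undefined
otherwise and no pseudo-counts are imputed; this inclusion rule is a
documented choice. `fold_sensitivity = 2^intercept` exactly. Swapping the
datasets negates x, y and the intercept and inverts the fold, which the
suite checks.

### Subsampling trade-off

Depth thinning draws, per cell, multinomial(round(X·N_c), counts/N_c) —
numpy's round is half-to-even, giving bit-reproducible targets — so column
sums hit the target exactly and each gene is marginally binomial. Cell
subsampling is uniform without replacement preserving relative order. The
error statistic is the published form Σ_i Σ_j (Z_ij − Ẑ_ij)²/n_genes over a
random sample of genes (default 500), dividing by the gene count only, not
by the 9 groups. The gene sample is drawn fresh each replicate (the
alternative, one sample per scenario, is not stated anywhere; per-replicate
is flagged as the choice). Reference and perturbed profiles always use the
same summary statistic, defaulting to the mean because the subsampling
procedure is defined on zonation group means. The reversal-minimum rule
(score against the profile and its flipped-axis version, keep the smaller)
applies only when the order is recomputed per replicate, since only then
does the axis have flip freedom.

## The synthetic generator

The generator is the package's study condition, not a fit to any real
dataset. Profile shapes are the simplest forms spanning observed zonation
patterns: linear increasing/decreasing (baseline + amplitude·z or ·(1−z)),
Gaussian-bump peaked, and flat. Defaults: 1000 genes mixed 0.2/0.2/0.1/0.5
(increasing/decreasing/peaked/flat — half the transcriptome unzonated),
baselines log-normal(0, 1), amplitudes log-normal(1, 0.5), peak centers
U(0.2, 0.8) and widths U(0.1, 0.25). Fifteen markers (8 periportal
increasing, 7 pericentral decreasing, mirroring the canonical 15-gene liver
panel) get 5× amplitude and 0.2× baseline, emulating strongly zonated,
highly expressed genes like Cyp2e1 or Glul. "Strongly zonated" genes are
defined as monotone genes whose amplitude is ≥ 90% of their dynamic range
(amplitude/(amplitude+baseline) ≥ 0.9) — the marker-grade stratum on which
cross-protocol profile agreement is evaluated, the synthetic analog of
evaluating agreement on known highly regulated genes.

Counts: per-cell depth N_c is log-normal with the regime's mean (the log-sd
"dispersion" defaults to 0.3) and counts are multinomial(N_c, p_·c) with
p ∝ μ_i(z_c). Overdispersion multiplies each p_ic by an independent gamma
factor with mean 1 and variance φ before renormalizing, giving
negative-binomial-like counts while keeping the exact-depth contract; the
default φ = 0.3 is a moderate biological noise level typical of scRNA-seq.
The shipped regimes are "deep" (66 cells, mean depth 1e5) and "shallow"
(606 cells, mean depth 5e3) — cell numbers from the real datasets this
emulates, depths scaled down from the real millions-per-cell to desk scale.
Protocol sets redraw cell positions independently per protocol (different
animals' cells), equispaced on [0,1] by default with a uniform-random
option. Spike-in injection reallocates each cell's total so ERCC rows carry
a requested fraction, preserving totals, to exercise the QC filter.

What the generator does **not** emulate: genome-scale gene universes (1000
genes at depth 1e5 means the deep regime detects nearly everything, unlike
real full-length data at ~38% of the genome), gene length/GC capture
biases, UMI collisions, doublets, cell-type mixtures, or empirically
calibrated count distributions. Passing tests therefore demonstrate that
the pipeline's machinery recovers known structure under a plausible noise
model — not that any real protocol achieves these numbers.

## Problem sizes and verification

The test suite and the acceptance script run the shipped regimes at their
native sizes: axis recovery over 25 simulated deep datasets (median
|Spearman ρ| ≥ 0.9 against truth), profile agreement across one deep +
shallow pair (median Pearson r over strongly zonated genes ≥ 0.9), FDR
calibration on a 2000-gene flat truth, depth-ratio recovery over 25 seed
pairs of 8×-different regimes with φ = 0 (median intercept 3.0 ± 0.5,
log2 8), and trade-off grids at 25 replicates per level with the 500-gene
MSE. Brute-force enumeration of all n!/2 orders serves as the global-optimum
oracle for the ordering at n ≤ 7. These sizes were chosen so the whole
suite runs in well under a minute while leaving the Monte-Carlo margins
comfortable.

## Known limitations

Adjacent-exchange 2-opt is a local search; on noisy data it can stop in
local optima (the brute-force guarantee is only exercised on noiseless
monotone markers). The nine-group discretization loses within-group
gradient information, and MSE values are not comparable across datasets
with different processing — only within a dataset's own trade-off curve.
The sensitivity regression's gene-inclusion rule (detected in both
datasets) slightly attenuates the intercept when one dataset misses many
genes entirely.
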
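# Methods

## Tree model and conventions

A `Phylogeny` is a rooted tree with nonnegative branch lengths in time units
(MY). Time runs forward from the root (root at 0); node *age* is measured
backward from the tips. All covariance computations use forward time and
assume ultrametricity, checked at a relative tolerance of 1e-6 of tree
height: non-ultrametric trees are accepted for the signal tests (which only
use the tree topology or the BM covariance) but rejected by OU fitting,
whose closed-form covariance assumes equal tip depths. Zero-length terminal
branches are allowed; zero-length *internal* branches are collapsed at parse
time with a warning, because a shift placed on either side of a zero-length
edge would be unidentifiable. Newick parsing and the taxon bookkeeping
behind it are delegated to dendropy; pruning preserves root-to-tip depths and
pairwise patristic distances exactly by splicing unary nodes and summing
lengths.

Calibration: `anchor_calibrate` rescales all branch lengths uniformly so one
chosen node sits at a given age. Uniform scaling can honour only one anchor
exactly; when several calibration events are available the WGD = 100 MY
anchor is the recommended choice and the other events' implied ages follow
from the scaling. This is a deliberate simplification: penalized-likelihood
rate smoothing (as in ape's `chronopl`) is out of scope, and the package
assumes the input chronogram is already reasonable.

Strain-level tables are collapsed to species by arithmetic means over
non-missing values; a categorical character must be unanimous within a
species, and a conflict is an error rather than a majority vote.

## Phylogenetic signal

**Categorical.** The observed statistic is the Fitch small-parsimony count
(postorder set intersection/union; multistate characters supported). The
null shuffles the observed state vector across tips — a permutation, which
preserves state frequencies, rather than a resampling; this matches the
standard character-randomization procedure for testing whether a character
is more phylogenetically clustered than chance. p = (1 + #{null ≤ obs}) /
(1 + n_rand). The add-one convention means p is never exactly 0: with 1,000
randomizations the floor is ≈ 0.001, so "p < 0.0001" claims cannot be
reproduced literally at that replication level. A constant character has no
lower tail; it returns 0 transitions with p = 1 and a warning. Fitch
requires a binary tree (an arbitrary resolution of a polytomy can change the
minimum count, so the package refuses rather than silently resolving).

**Continuous.** Blomberg's K uses the ML phylogenetic mean
â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) and the (n−1)-denominator form of the expected
mean-square ratio — the standard published estimator; the test suite
cross-checks it against picante's `Kcalc` to machine precision. K is
invariant to shifting and positive scaling of the trait, equals 1 exactly on
a star tree, and averages 1 under BM. The permutation test shuffles trait
values across tips and counts permuted K ≥ observed K, with the same add-one
convention.

## OU model and shift detection

Along each branch the trait follows dX = α(θ − X)dt + σ dB. With the root
state fixed at the base optimum θ₀ (stationarity at the root is *not*
assumed; variance accrues from the root), the tip covariance is

V_ij = σ²/(2α) · exp(−α d_ij) · (1 − exp(−2α t_ij)),

with d_ij the patristic distance and t_ij the root-to-MRCA time. As α → 0
this tends elementwise to σ²C, the BM covariance.

**Shift design.** A shift of magnitude Δθ placed at the start of branch b
(time s_b) changes the optimum for b and every descendant branch (regime
inheritance). Integrating the optimum along the root-to-tip path telescopes
to a coefficient of 1 − exp(−α(T − s_b)) for each descendant tip and 0
elsewhere; the fixed-root convention folds the exp(−αT) root term into θ₀,
so the intercept column is exactly the ones vector. Candidate branches are
all branches (the root has no stem in this representation). Configurations
whose design is singular — e.g. shifts on both root children, which are
jointly confounded with θ₀ — are rejected with an error naming the branches.

**Fitting.** α is profiled over a fixed log grid (25 points, α·T from 1e-3
to 50; data at these tree depths give no information outside this range — below
it OU is indistinguishable from BM, above it from a white-noise model).
Conditional on α, the model is a Gaussian linear model after whitening by
the Cholesky factor of the unit-scale OU covariance: θ₀ and shift magnitudes
are GLS estimates, σ² is profiled as RSS/n (floored at 1e-12 to guard
degenerate zero-residual inputs), and the profiled log-likelihood equals the
dense multivariate-normal density (verified to 1e-8 in the tests). BM is
fitted analogously with C. Parameter counts: 2 for BM (θ₀, σ²), 3 + k for an
OU model with k shifts. BIC = −2ℓ + (#params)·ln(n_tips).

**Search.** For each α the whitened trait is regressed on the whitened shift
design under an L1 penalty along a geometric 50-point path from λ_max down
by 1e-3 (scikit-learn coordinate descent, tol 1e-8, ≤ 1e5 iterations; the
unpenalized intercept is handled by projecting the whitened ones vector out
of the problem). The descent stops early once the active set clearly
exceeds the shift cap, since denser path points cannot contribute
candidates. Every distinct nonzero support of size ≤ max_shifts (default 3)
becomes a candidate configuration; each is refit without penalty and the
best configuration — including the empty set — is returned.

**Selection criterion.** Configurations are selected by an extended BIC
(Chen & Chen 2008): BIC + 2·log C(m, k), where m is the number of candidate
branches and k the number of shifts. Plain BIC prices the k magnitude
parameters but not the choice of *which* k branches out of ~2n carry them;
because the search maximizes over that choice, plain BIC admits spurious
shifts on shift-free (BM) data in nearly every replicate. The combinatorial
term prices the placement search and restores calibration — the same role
the pBIC criterion plays in the original lasso-OU R implementation. The
*model comparison table* (BM / OU-no-shift / OU-variable / OU-fixed) still
reports plain BIC and BIC weights bicw_i = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2), the
scale on which such tables are conventionally published. Ties in selection
break toward fewer shifts.

**Fixed-shift model.** `OU_fixed` places a single a-priori shift on the stem
of a named clade (the WGD hypothesis: the optimum moved once, at a known
historical branch). An option (`fixed_companions=True`) lets this model
additionally adopt the best lasso-proposed companion shifts up to the cap;
it is off by default because companion shopping re-introduces the selection
noise that the a-priori placement is meant to avoid (measured on the
fixture: a null trait becomes spuriously shift-bearing ~4× more often with
companions enabled).

## Ancestral states and phenograms

Internal-node states under BM are the GLS/ML estimates: the root is the
phylogenetic mean â and node u gets â + S_u C⁻¹(x − â1), where S_u holds
the root-to-MRCA(u, tip) times. This equals the minimizer of
Σ_branches (x_child − x_parent)²/length, which the tests verify against a
direct sparse least-squares oracle. Phenograms use BM states even when an
OU model is selected — they are descriptive projections, and OU ancestral
estimation (which would require conditioning on the fitted regimes) is out
of scope. The heat-map matrix z-scores each trait column over non-missing
species (traits have incommensurable units), ordered by tree tip order.

## Synthetic data

The simulators are exact: BM uses Gaussian branch increments; OU uses the
exact transition (mean decay toward the branch's regime optimum, variance
σ²(1 − e^(−2αt))/(2α)); the binary character is a symmetric 2-state Markov
chain. A single dataset seed expands into per-stage substreams (tree, each
trait, binary character) so adding a trait never perturbs earlier draws.

The yeast-like fixture emulates a realistic comparative dataset: a 31-tip
Yule tree scaled
to 200 MY; the "WGD" branch chosen as the internal branch jointly closest to
age 100 MY and to subtending a third of the tips; Gly, RQ and EthY simulated
under OU with α·T = 5 and a +3-stationary-sd optimum shift on the WGD stem
(base optima and stationary sds — Gly 0.02 ± 0.005 g/gDW·hr, RQ 1.0 ± 0.15,
EthY 0.30 ± 0.05 g/g — chosen to sit in the physiological ranges typical of
batch-culture yeast measurements); DW simulated under shift-free BM (0.25 ±
0.08 at the tips); and a Crabtree character that is positive throughout the
WGD clade plus two random outside lineages, emulating independently evolved
long-term Crabtree-positive taxa. The +3-sd effect size produces the
clear-cut clade separation the phenograms of real fermentative traits show.
The truth record stores every generating parameter.

What the fixture does *not* emulate: among-trait correlation, measurement
error, missing data patterns, extinction (no death process), and any
misspecification of the clock — so passing recovery tests demonstrate
correctness of the estimators under their own assumptions, not robustness on
real data.

## Problem sizes and numerical choices

The simulation-based checks use 50-tip trees with 100 replicates for the
null/recovery behaviour of the shift search and 50 seeds of the 31-species
fixture for the end-to-end pattern; these sizes give binomial standard
errors of ~4–7% on the reported proportions, tight enough for the ≥80/90%
claims being checked. Blomberg's K calibration uses 500 BM replicates on a
fixed 50-tip tree. Matrix solves use Cholesky factorizations throughout;
the BM covariance of a valid tree is positive semidefinite by construction
and positive definite absent duplicated zero-distance tips (which raise a
clear error).

## Known limitations

- Univariate traits only; no joint multi-trait OU, no measurement-error
  variance, no non-ultrametric OU corrections, no merging of convergent
  regimes on different branches.
- One calibration anchor can be honoured exactly (uniform scaling).
- The α grid bounds the estimate; data preferring α outside [1e-3/T, 50/T]
  pile up at the grid edge (visible in the reported α).
- BIC weights are reported as evidence proportions; they are not literally
  "percent variance explained" despite that common gloss.
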
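# Methods

## Model

`vineflow` models the joint distribution of d mixed continuous/count
variables — typically binned spike counts of simultaneously recorded neurons
together with behavioral covariates — by separating margins from dependence
(Sklar's theorem) and factorizing the dependence into a canonical vine
(C-vine) of bivariate copulas:

    f(x_1, ..., x_d) = prod_k f_k(x_k)
                       * prod_{j=1..d-1} prod_{i=1..d-j}
                         c_{j, i+j | 1..j-1}( F(x_j | ...), F(x_{i+j} | ...) )

Tree 1 links a root variable to all others; deeper trees condition on the
preceding roots. The simplifying assumption is hard-wired: a deeper-tree
copula depends on its conditioning variables only through the conditional
CDFs, never on their values. Conditional CDFs propagate between trees via
h-functions h(u|v) = dC(u,v)/dv, and sampling inverts the same recursion
(inverse Rosenblatt).

Margins and pair copulas are estimated non-parametrically with normalizing
flows built from monotone rational-quadratic splines on a **uniform** base
distribution. With a uniform base the log-density is simply the accumulated
spline log-Jacobian and sampling is a single analytic inverse pass, which is
what makes Monte-Carlo copula entropy and large simulated samples cheap.

### Spline flows

A 1-D flow is a stack of unconditional monotone rational-quadratic splines
of [0,1] (K bins, positive widths/heights summing to one, positive interior
knot derivatives, boundary derivatives pinned at 1). A 2-D copula flow
stacks coupling blocks: an unconditional spline on one coordinate and a
spline on the other whose parameters come from a two-hidden-layer tanh
network reading the first coordinate; coordinates swap roles between
blocks, so both density evaluation and sampling are single-pass.

Everything is implemented in numpy. Gradients of the spline output and its
log-Jacobian with respect to the input and all unconstrained parameters were
derived symbolically from the closed form and are verified against finite
differences in the test suite; the conditioner network is backpropagated by
hand; training uses Adam.

Unconstrained parameters map to spline parameters through a floored softmax
(widths/heights, floor 1e-3) and a shifted softplus (derivatives, floor
1e-3) chosen so that all-zero parameters give exactly the identity map;
initialization draws parameters from N(0, 0.01) and scales the conditioner
output layer by 0.01, so untrained flows start at the uniform density.

### Training

Maximum likelihood by minibatch Adam with a held-out validation fraction
(default 10%) for early stopping; the returned parameters are those of the
best validation epoch. Defaults (`TrainConfig`): batch 512, learning rate
3e-3, at most 300 epochs, patience 25, followed by a second fine-tuning
stage at lr/10 (half the epoch budget). The second stage measurably reduces
the smoothing bias that otherwise shrinks Kendall's tau of weakly dependent
copulas by a few hundredths. Pair copulas inside a vine default to a
single-stage 150-epoch schedule (`cvine.VINE_TRAIN_CFG`); a d-dimensional
vine needs d(d-1)/2 fits and the benchmark shows the short schedule already
reaches per-pair KL well under 0.1 nats.

Hyperparameters (number of flow layers, conditioner width, spline bins) are
chosen per copula by random search over a declared grid, scored by
validation log-likelihood with ties broken toward fewer parameters. The
full grid is layers {1,2,3} x hidden {16,32,64,128} x bins {4,8,16,32};
vine fitting defaults to the compact grid layers {1,2} x hidden {16,32} x
bins {8,16}. Search budgets are configuration, not science: the study
driver uses 1-2 trials per copula so a full 12-case benchmark repetition
runs in minutes on one CPU.

### Margin calibration (copula projection)

An unconstrained density estimate on the unit square need not have exactly
uniform margins, so it is not strictly a copula; fitted flows showed ~2%
marginal CDF deviation. After fitting, each pair copula is projected onto
copula space: its marginal CDFs F_1, F_2 are computed by quadrature on a
boundary-refined grid (uniform 513 points plus 64 geometrically spaced
points inside each 1% boundary band, where heavy-tailed copulas concentrate
mass) and the model is re-expressed as

    c'(u, v) = c(F_1^{-1}(u), F_2^{-1}(v)) / ( f_1(F_1^{-1}(u)) f_2(F_2^{-1}(v)) ),

with samples pushed through (F_1, F_2). Rank dependence (Kendall's tau) is
invariant under these monotone maps; margins become uniform up to grid
error, and KL against ground truth improves several-fold. The piecewise
Jacobian uses the secant slopes of the interpolated CDF so the projected
density still integrates to one under the same interpolation.

### Mixed and discrete variables

Continuous pseudo-observations use the rank/(n+1) convention (keeps values
strictly interior, as the flow log-density requires; the (rank-0.5)/n
alternative was not used — a declared choice). Counts enter copula space
through the distributional transform G(x,V) = F_(x) + V (F(x) - F_(x)) with
F_(x) = Pr(X < x) and V ~ U(0,1), seeded for reproducibility; all
unit-interval outputs are clamped to [1e-6, 1-1e-6]. Column types are
auto-detected (integer-valued with at most sqrt(n) distinct values counts
as discrete) and overridable per column.

Discrete margins are kept as empirical pmf tables: the margin term of the
joint density is the exact pmf, and sampling maps copula coordinates through
the table's generalized inverse, so simulated counts always land on the
observed support (the rounding step for count margins). Joint log-densities
for discrete columns average the copula term over R = 10 seeded jitter
replicates of the distributional transform (configurable), which reduces
jitter variance in log-density estimates. Continuous margins are modelled
by 1-D flows on an affine rescaling of [min - 3 SD, max + 3 SD] onto [0,1]
(support handling is unspecified upstream; this is a declared choice).

### Vine fitting and evaluation

Inference-for-Margins: fit margins, transform to pseudo-observations, order
variables by decreasing sum of |Kendall's tau-b| (absolute values, so strong
negative dependence counts as connectivity; ties break on column index),
then fit pair copulas tree by tree, propagating conditional
pseudo-observations with h-functions computed by trapezoid integration of
the fitted flow density on a fixed 256-point grid. Inverse h-functions for
sampling invert the same gridded conditional CDF by monotone interpolation,
so h and h^{-1} are consistent by construction. Kendall's tau always uses
the tie-corrected tau-b (counts are heavily tied).

## Information estimators

Copula entropy is estimated by Monte Carlo: h = -(1/K) sum log2 c(u^(k))
over K model draws (default K = 8000); its negative estimates the mutual
information of the pair independently of margins. Entropy is reported in
bits, KL divergence in nats.

KL between sample sets uses the k-nearest-neighbor estimator (default k=5,
Euclidean metric, no boundary correction — a known limitation on the unit
square): D = (d/n) sum_i ln(nu_k(i)/rho_k(i)) + ln(m/(n-1)). Distances are
floored at 1e-12 against duplicate points. The estimator is noticeably
biased when the reference distribution has much lighter tails than the
target; oracle checks use directions where the closed-form value is
attained at n = 8000.

## Simulation study

Ground truth: C-vines of dimension 4 or 8 whose pair copulas all belong to
one family at one strength — Clayton (theta 2 weak / 5 strong), Frank
(3 / 7), Gaussian (rho 0.4 / 0.8) — with standard-normal or Poisson(5)
margins (the margins are a declared choice; KL is computed in copula space,
so they matter only through discretization coarseness). Training uses 5000
samples per repetition; each fitted pair copula is scored by the kNN KL
between 8000 of its draws and 8000 ground-truth draws, plus its MC entropy.
Repetitions redraw both the training data and the fit initialization.

Two structural decisions:

* The vine ordering is fixed to the generating one. The tau-sum reordering
  would root the vine at a non-root variable (induced copulas between
  non-root variables are stronger than the pair copulas themselves), and
  each fitted pair would then be scored against the wrong ground truth.
* Conditional pseudo-observations for deeper trees are built with the exact
  parametric h-functions on both the training and the ground-truth side, so
  each pair's score isolates that copula's estimation quality rather than
  accumulated propagation error.

For discrete cases the ground-truth side applies the exact-margin
distributional transform to fresh ground-truth samples: that is the copula
a non-parametric estimator of count data actually targets. Comparing
against the *continuous* parametric copula instead conflates estimator
error with discretization (for strong Clayton dependence with Poisson(5)
margins the irreducible gap is ~0.25 nats).

## Synthetic spike session

The fixture emulates a head-fixed virtual-corridor experiment: a 160 cm
corridor with a 120-140 cm reward zone, 100 ms time grid, five units with
Gaussian position tuning (three tuned inside the reward zone), trial-level
multiplicative gains entangled across units by a Clayton(theta=5) copula
(heavy-tailed co-modulation), licking concentrated in the reward zone with
rate driven by the shared reward-zone gain, and running speed that drops in
the zone and during licking (hence anticorrelated with reward-zone
spiking). Spikes are binned by position (20 cm bins, eight bins) or around
the per-trial reward time (300 ms bins over +-3.5 s; 23 bins with the
residual dropped symmetrically since 7 s is not a multiple of 0.3 s).
Reward time is the first in-zone lick; trials without one are excluded.
Dependence-module selection keeps units whose pairwise |tau-b| all exceed
0.3 (greedy clique growth from the most connected unit, deterministic).

What the fixture does *not* emulate: calcium-indicator dynamics and
deconvolution artifacts, theta-timescale spike timing, non-stationarity
across the session, and realistic trial-to-trial position occupancy
variation. Passing tests therefore demonstrate that the pipeline recovers
designed-in dependence from realistically shaped tables, not that it
resolves every property of real recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the study at its stated sample sizes
(n_train 5000, n_eval 8000, K 8000) with 4-dimensional vines, 1-2
repetitions and 1-2 random-search trials per copula — sizes chosen so the
whole study remains a desk-scale computation on one CPU. Degenerate inputs
raise typed errors (constant margins, values off a discrete support,
insufficient samples for kNN, non-finite training loss with the offending
epoch). Uniformity assertions use Kolmogorov-Smirnov tests at alpha = 0.01
with Bonferroni correction across the coordinates tested. All randomness
flows from explicit integer seeds through `numpy.random.SeedSequence`;
serialized models reload bit-exactly (flows re-derive their calibration
tables deterministically from the stored parameters).

## Known limitations

* The kNN KL estimator is uncorrected at the unit-square boundary and
  biased for strongly mismatched tails.
* Copula flows are fitted without a uniform-margin constraint; the
  calibration step corrects this post hoc rather than during training.
* h-functions of fitted copulas are numerical (256-point grid); deep vines
  accumulate interpolation error in sampling, visible only beyond the
  tested dimensions.
* Only C-vines (no R-vine structure search), no truncation of deep trees,
  no non-simplified vines, bivariate copula entropy only.
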
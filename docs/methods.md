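# Methods

## The design problem

A two-arm cluster randomised trial recruits participants continuously over a
fixed calendar window. Intervention-arm clusters may spend the first part of
the trial in the control condition (a prospective baseline) before crossing
over at time `t*`. Baseline data help to separate cluster effects from the
treatment effect when outcomes within a cluster are correlated, but every
month spent on baseline is a month not spent collecting post-intervention
data. The package quantifies that trade-off exactly, under the model below,
rather than by rule of thumb.

## Outcome model

Time is normalised so the trial runs over (0, 1]; calendar units enter only
at the CLI layer through a single total-duration parameter. Arrivals are
regularly spaced at `i/m`, `i = 1..m`, per cluster — an idealisation of a
constant-rate arrival process; random (e.g. Poisson) arrival times are out of
scope. Outcomes follow

    Y_ij = T(t_ij) + delta_ij * theta + eps_ij,
    Corr(Y_i1j, Y_i2j) = rho * tau**|t_i1j - t_i2j|,   Var(Y_ij) = sigma^2,

with `delta_ij = 1` iff cluster `j` is in the intervention arm and
`t_ij >= t*`. `rho` is the intracluster correlation for two participants
sampled at the same moment; `tau` is the factor by which that correlation has
decayed between the two ends of the trial (`tau = 1`: compound symmetry; the
exponential-decay family is the only correlation model implemented).

Two fixed time-effect families are supported:

* **step** — intercept plus an indicator of `t >= t*` (piecewise constant
  with its discontinuity exactly at the cross-over). Optionally augmented
  with polynomial terms; when both arms share the same retained grid these
  additions leave the treatment variance unchanged (see *Invariance* below).
* **polynomial** — intercept plus powers of time up to a chosen degree
  (continuous; degree 3 by default at the CLI). Internally the powers are
  evaluated on the centred, scaled basis `(2t - 1)**k` for conditioning; the
  treatment variance is invariant to this basis change (tested).

## Transition period and exclusions

The transition window is the half-open interval
`[t* - closure - implementation, t*)`: an arrival exactly at its start is
excluded, an arrival exactly at `t*` is a retained, treated observation
(matching the `t >= t*` treatment rule and giving every arrival an
unambiguous classification). Intervention-arm arrivals inside the window are
always excluded; control-arm arrivals are excluded by default and retained
when `control_recruits_in_transition` is set. A no-baseline design starts the
intervention arm in the intervention condition: no closure period is needed,
recruitment is delayed only by the implementation period, and the same flag
governs whether control data from `[0, implementation)` are kept. The default
is to exclude them, mirroring the both-arms-excluded convention of the
transition designs; the flag exposes the alternative.

## Variance computation

With all clusters in an arm sharing one retained grid, the GLS information
for the treatment effect is assembled from two cluster patterns (one per
arm): each covariance block is Cholesky-factorised, the design block is
whitened by triangular solve, and the stacked whitened design is reduced by
QR, so the inverse information is obtained without forming normal equations
(which would square the condition number — material for degree-6 polynomial
bases on small grids). The reported *multiplier* is the treatment entry of
the inverse information at `sigma^2 = 1` with one cluster per arm; the
variance of any actual design is `multiplier * sigma^2 / J`. Tests assert
equality with the brute-force joint-matrix inverse at 1e-10 relative
tolerance and with statsmodels' GLS at 1e-8.

Rank handling: fixed-effect columns are scanned in construction order and a
column that adds no rank (relative singular-value threshold 1e-10) is dropped
deterministically with a warning — e.g. the post-cross-over indicator when
every retained observation is post (`t* = 0`, or any no-baseline design). If
the treatment column itself adds no rank the design is degenerate and is
reported as such (sweeps mark the point absent rather than interpolating).

## Sweeps, heuristics, robustness

`variance_curve` evaluates the multiplier at every multiple of `grid_step`
in the admissible range `[closure + implementation, 1]`; the default step is
1/96 of the trial (finer than monthly for a two-year trial) and the worked
example uses monthly steps. Ties at the minimum resolve to the smaller `t*`
(shorter baseline, earlier intervention). The no-baseline reference point is
always computed as its own design (implementation-only delay), never as the
curve's left endpoint, because the left endpoint of a transition design still
carries the full closure period.

`none_or_half` compares the no-baseline design against a cross-over at half
the trial and reports the chosen multiplier's ratio to the overall optimum
(including the no-baseline option), so the rule-of-thumb's efficiency is
visible. `minimax_crossover` takes the pointwise maximum of the curves over a
user-supplied grid of plausible `(rho, tau)` and minimises that worst case —
the recommended approach when the correlation parameters are only known to a
range.

## Invariance of the treatment variance to extra time effects

If the model contains the step-at-`t*` column and both arms share the same
retained observation grid, adding any further fixed time effects (polynomial
terms of degree up to 6 are tested) leaves the treatment variance unchanged
to machine precision: the pattern of control/intervention conditions in the
intervention arm is itself the step function, so richer time adjustments
remove nothing further from the treatment contrast. The proviso matters:
when control-arm recruitment continues through the transition window the
arms' grids differ, and the extra control observations do shift the variance
(by a few percent in the configurations we examined). The invariance tests
therefore sample designs with symmetric grids, and the package makes no
invariance claim for asymmetric ones.

A practical corollary, which the worked example exploits, is that for
no-baseline designs the step and polynomial analyses coincide exactly:
with identical grids in both arms and a cluster-constant treatment
indicator, time adjustments are orthogonal to the between-arm contrast.

## Worked example conventions

The bundled 24-month example (m = 172, 9-month transition of 6 closure + 3
implementation, both arms excluded during transition) is evaluated under the
continuous cubic time effect, at monthly sweep resolution; this is the
configuration whose optima fall on whole months (15 and 10) and whose
variances round to 0.060, 0.061, 0.052 and 0.046 at three decimals. The step
analysis agrees to three decimals for the optimal, 10-month and no-baseline
designs and is within about 1% for the symmetric 16.5-month design
(0.0616 vs 0.0612). `scripts/acceptance.py` reports the cubic values.

## Sample size

`J >= multiplier * (sigma/theta*)^2 * (z_{1-alpha/2} + z_{1-beta})^2`,
ceiled to an integer, with the unrounded value reported alongside;
`achieved_power` inverts the formula. Power is normal-approximation only —
no t-distribution or small-cluster degrees-of-freedom correction — so
results carry a standing note that designs with few clusters may warrant one
or more extra clusters per arm (reported, never silently applied).

## Monte-Carlo validation

The simulator draws each cluster's outcome vector from the multivariate
normal the model specifies (one Cholesky factorisation per arm pattern,
reused across clusters and replications; a single seeded generator governs
all draws). Refitting each replicate by GLS with the covariance known — the
design-stage assumption throughout — the empirical variance of the estimates
is compared with the analytic value against a two-sided 99% chi-square band
for a sample variance. Defaults: 2000 replications; the bundled validation
lattice uses m = 50, J = 4 over rho in {0.01, 0.05, 0.1} and tau in
{0.1, 0.5, 1.0}. Because the generator implements exactly the assumed model,
these checks validate the variance algebra, not robustness to real-world
departures (non-normal outcomes, uneven arrivals, misspecified correlation
decay), which are out of scope.

## Problem sizes and numerical choices

Test sweeps run at 1/48-trial resolution over the full scenario grid
(m in {25, 50, 100, 200}, rho in {0.001, …, 0.1}, tau in {1.0, 0.5, 0.1});
each design evaluation is a pair of at-most-200×200 Cholesky factorisations,
so a full grid sweep completes in well under a minute. Tolerances: rank
decisions at 1e-10 relative singular value; invariance asserted at 1e-8
relative; oracle equivalence at 1e-10. Ties and degenerate grid points are
handled as described above; no interpolation is ever performed on variance
curves.

## Limitations

1:1 allocation, equal cluster sizes, regular arrivals, a single cross-over
(no stepped-wedge sequences), exponential correlation decay, continuous
outcomes and known (rho, tau) at the design stage. Estimating the
correlation parameters from data, and design under binary or count outcomes,
are explicitly out of scope.
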
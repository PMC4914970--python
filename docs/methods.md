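# Methods

## Model

A linear network receives mixtures of independent sources,

    x = A s,        u = W x,

with `s` an `M`-vector of zero-mean, i.i.d.-across-channels sources, `A` an
`N x M` mixing matrix, and `W` the learned synaptic matrix.  Independent
component analysis (ICA) is solved when `K = W A` is a signed permutation
times a positive diagonal gain, so that each output carries exactly one
source.

The error-gated Hebbian rule (EGHR) changes each synapse by an ordinary
Hebbian product gated by one global scalar:

    tau_W dW/dt = < (E0 - E(u)) g(u) x^T >,

where `z(u) = -log p0(u)` is the surprise density of the assumed source
prior, `E(u) = sum_i z(u_i)` the total surprise of the output vector,
`g = z'` the score function, and `E0` a constant.  The rule is exact
gradient descent on `L = <(E(u) - E0)^2>/2`: it shrinks the fluctuations of
the output surprise around `E0`.  With `E0 = N <z(s)> + 1` the unmixing
matrix `W = A^-1` (and its signed permutations) is an equilibrium; with any
other `E0 > 0` the equilibrium is `W = c A^-1` with the gain `c` solving
`<(E0 - E(c s)) g(c s_i) c s_i> = 0` (`equilibrium_scale` solves this by
quadrature and bracketing; for power-law priors `p0 ∝ exp(-beta|s|^alpha)`
the closed form `E0 - N k = c^alpha (N <z - k> + 1)` holds, where `k` is
the normalization constant carried by `z`).

Linear stability of the ICA solutions is governed by two covariance
constants of the matched prior,

    rho   = cov(z(s), g'(s) s^2),
    omega = cov(z(s), g'(s)) <s^2> + cov(z(s), s^2) <g'(s)>,

with stability iff `rho > -1` and `omega > 1`.  For
`p0 ∝ exp(-beta|s|^alpha)` these reduce to `rho = alpha - 1` and
`omega = <s^2><g^2>`, which is `>= 1` by Cauchy–Schwarz with equality only
for the Gaussian — the expected statement that ICA needs non-Gaussian
sources.  At the Gaussian boundary (`omega = 1`) the solution is
rotation-degenerate: a rotational perturbation of `W = A^-1` feels no
restoring force, which the test suite verifies directly by integrating the
expected flow.

## Priors and smoothing

Three source families are supported: Laplace, uniform, and the generalized
Gaussian `p0 ∝ exp(-beta |s|^alpha)` (unit-variance parameterizations by
default; `alpha = 2, beta = 1/2` is the unit Gaussian).  Where the exact
score is not a function, a tanh-smoothed score of sharpness `gamma` is
used:

* Laplace: `g_L(u) = sqrt(2) tanh(gamma u)`;
* uniform: `g_U(u) = gamma [tanh(gamma(u - sqrt(3))) + tanh(gamma(u + sqrt(3)))]`.

`z` is defined as the exact antiderivative of the smoothed score (plus the
normalizing constant of `p0`), so surprise and score remain mutually
consistent — this is what makes the finite-difference check of the
gradient-descent identity pass at 1e-5 relative error.

All scalar moments (`<z>`, `<g s>`, `rho`, `omega`, ...) are computed by
adaptive quadrature over `(-20 sigma, 20 sigma)` against the
*self-consistent* smoothed density `exp(-z)/Z`, with breakpoints at the
kinks and at the `O(1/gamma)` transition scales around them.  Under this
measure the integration-by-parts identities `<g s> = 1` and
`<z g s> = <z> + 1` hold to quadrature precision for every family,
including the soft-walled uniform one (against the hard uniform measure
half of each smoothed wall spike would fall outside the support and
`<g s>` would degrade to `log 2`).

Default sharpness is `gamma = 100`, except the uniform family where the
default is `gamma = 10`: the uniform wall forces scale as `gamma^2`, and
explicit integration at the reference learning rates is unstable from
starting points whose outputs exceed the walls (e.g. `W0 = -2.2 I`) for
`gamma` much above ~30.  Identity tests use `gamma = 1000`.

## Discretization and schedules

Simulations follow the reference conditions: source resolution `dt = 1`,
source time constant `tau_s = 50` for temporally correlated (Langevin)
sources, total `T = 2e6` source steps, sampling interval `Delta_t` of 100
steps (10 for the Linsker rule, 1 for the Foldiak rule), and learning time
constants `tau_W = 1e3` (EGHR/Amari/Bell-Sejnowski/Cichocki), `1e4`
(Linsker), `1e6` (Foldiak), with `tau_Q = tau_h = tau_W / 10` and
`tau_v = 10`.

`Delta_t` is interpreted as the *sparse-sampling* interval: each update
looks at the signal once per `Delta_t` but integrates the learning ODE by
one source-resolution step, i.e. the per-update rate is `dt / tau_W`.
This is the only reading consistent with the reference behavior: with a
per-update rate of `Delta_t / tau_W = 0.1` the heavy-tailed surprise gate
makes explicit integration diverge on the two-source Laplace
configuration itself, and the documented observation that the
small-`Delta_t` rules need more than 10x more computational steps to reach
a solution follows exactly from `dt / tau_W` (1e-3 for the EGHR vs 1e-4
for Linsker).

Two estimators of the expectation `< . >` are available: online
single-sample updates (the default, the stochastic approximation used for
the two-neuron figures) and window-averaged updates (`Schedule.batch > 1`)
that average the update over the `Delta_t` sampling window.  The online
mode carries stationary gate-noise jitter of a few degrees in the
recovered directions at the reference rates; quantitative experiments
(undercomplete recovery, random-matrix recovery, MI-floor measurements)
use the window-averaged mode, and all recovery evaluations use the
time-averaged `W` over the trailing 25% of checkpoints — the estimator
analogue of pooling the final outputs over many steps.

The undercomplete experiment (32 neurons, 2 sources, stacked-rotation
mixing, `K` rows initialized on the unit circle) uses `gamma = 1000`,
`tau_W = 1e5`, `T = 2e7`, window-averaged updates.  Three effects force
these choices at `N = 32`: the gate's standard deviation grows linearly in
the number of (duplicated) outputs, so the two-neuron `tau_W = 1e3`
diverges outright; online updates leave ~10-degree angular jitter, an
order above the 5-degree alignment criterion; and with `gamma = 100` the
score knee makes zero gain locally absorbing for an individual row once
its axis is already carried by other rows (verified: the deterministic
quadrature flow aligns all 32 rows, and at `gamma = 1000` a contested row
crosses zero and flips sign instead of sticking).

Random square mixing matrices are drawn with i.i.d. standard-normal
entries, rejected above a condition-number bound, and normalized to
`||A||_F = sqrt(N)`.  The normalization matters because the `K = W A`
dynamics carry an `A^T A` metric factor: equilibria and their stability
are unchanged (the flow still descends `L`), but unnormalized draws make
some directions converge arbitrarily slowly.

A divergence guard aborts any run in which `max |W|` exceeds 1e6, raising
an error that carries the step index and the partial trace; only the
Foldiak rule uses the reference row-rescaling safeguard (rows renormalized
to norm 4 when they exceed it).

## Comparison rules

The Bell-Sejnowski (`W^-T - <g(u) x^T>`), Amari (`(I - <g(u) u^T>) W`) and
Cichocki (`I - <g(u) u^T>`) rules are implemented in their standard forms;
the first two are related by the natural-gradient transform
`dW_amari = dW_bs W^T W` exactly, which the tests check on shared batches.
The Cichocki form is validated by its distinguishing prediction: on the
rotation manifold with a pi/6 mixing rotation, exactly two of the four ICA
solutions (at angles 2pi/3 and 7pi/6) are unstable, the census the
velocity-map test reproduces.

The Linsker and Foldiak rules are reconstructed from their original
published versions in this package's notation.  Linsker: a fast neural
state relaxes through symmetric lateral weights (`tau_v`), anti-Hebbian
learning drives the lateral loop to whiten the output (`<v v^T> -> I`),
and a second pass of the relaxed state through the same loop yields a
locally computable estimate of the infomax term
(`<y x^T> = <u u^T>^-1 W <x x^T> = W^-T`), so
`dW ∝ (y - g(u)) x^T` reduces to the Bell-Sejnowski rule when the input
is slow; when the input changes faster than the loop can track, the
anti-Hebbian term dominates — reproducing the spurious attractor at
`W = 0` for small starts and runaway growth for large ones.  A spectral cap
(`rho(Q) <= 0.98`) keeps the lateral relaxation defined between updates.
Foldiak: nonlinear units `y = f_F(v)` with anti-Hebbian lateral
decorrelation toward the target coincidence rate `b^2`
(`b = <f_F(s)>` by quadrature), Hebbian-with-decay feedforward learning
`dW_ij ∝ y_i (x_j - W_ij)`, and threshold homeostasis `dh ∝ y - b`.
`f_F` is the sharp logistic `1/(1+exp(-100u))` for uniform sources and the
cubic-logistic variant `logistic(100 u^3)/0.225` for Laplace sources (the
cubic coefficient is taken equal to the printed logistic gain).  This
reconstruction reproduces the documented qualitative behavior —
convergence from the adapted start on rotation mixtures, failure on any
non-rotation mixing — which is what the acceptance checks require of it.

## Analyses

**Velocity maps.**  On the rotation manifold `W = (W11, W12; -W12, W11)`
the expected update of the directly-computable rules is evaluated by a
Riemann sum over the source density (`ds = 0.1` on `[-20, 20]^2`, the
reference grid) at each point of the `[-1.5, 1.5)` grid with step 0.05;
for the Linsker/Foldiak rules the expectation is replaced by a long-run
average of the full dynamical stepper with `W` frozen.  Candidate fixed
points are strict local minima of the field magnitude, refined by
derivative-free minimization — the kink lines of the integrand sweep
across the fixed quadrature grid as `W` varies, leaving smooth `O(ds^2)`
ripples that defeat Newton refinement — and accepted when the refined
field norm is below 0.02 of the grid-median norm (the ripple floor; a
much smaller threshold would reject genuine zeros of the underlying
field).  Classification uses the eigenvalue real parts of a
finite-difference Jacobian with a stencil (`h = 0.02`) wide enough to
average over the ripples.

**Mutual information.**  Plug-in histogram estimate with 30 bins per axis
over the central 99% range, reported alongside a shuffled-control floor
(one channel permuted) that measures the estimator bias at the same sample
size; independence is operationalized as MI within 0.005 nats of the
floor.

**Recovery diagnostics.**  `recovery_report` computes `K = W A`, each
row's angle to the nearest signed axis, its gain, and an interference
index (off-axis energy fraction); rows are "aligned" within 5 degrees.
Zero rows are unaligned by convention.  The report is invariant under row
permutations and sign flips of `W`.

## Synthetic image fixtures

The image-separation demonstration uses generated sources: oriented
band-pass-filtered independent noise fields, histogram-equalized to a
bounded (soft-walled uniform) intensity law, plus one spatially white
channel with the same histogram.  Three properties matter and each was
forced by a failure mode observed during development: channels must be
*independent as pixel ensembles* (deterministic gratings are uncorrelated
but not independent — their joint pixel histogram does not factorize, and
no ICA method can separate them); marginals must match the bounded
sub-Gaussian regime the uniform prior assumes (strongly bimodal marginals
displace the gated rule's equilibrium away from the exact unmixing); and
the noise channel must not be exactly Gaussian (the `omega = 1` marginal
pairing, which is recovered only slowly).  What passing this suite shows
is that the rule separates independent, sub-Gaussian, spatially structured
channels at realistic mixing; it does not certify performance on natural
photographs, whose histograms are only approximately bounded and whose
channels are only approximately independent.

Scaled schedule: `1e7` pixel presentations (half the reference run) at
`tau_W = 5e3`, pixels presented in random order in blocks of 20 with the
block-averaged update (first-order equivalent to online presentation);
recovery is insensitive to raster vs random ordering.

## Problem sizes used by the shipped checks

Quadrature identities: seconds.  Velocity-map censuses: the full reference
grid (60 x 60 manifold points, 401 x 401 source grid).  Undercomplete
recovery: 3 seeds of 2e5 window-averaged updates.  Random-matrix recovery:
21 mixing matrices, 1e5 updates each.  Image separation: 1e7 pixel
presentations.  MI floors: 2e6-step runs.  These sizes were chosen so each
check resolves its criterion with margin while the whole suite stays
convenient to run on one CPU.

## Known limitations

* The Linsker and Foldiak implementations are reconstructions of the
  original published rules, validated against documented behaviors, not
  transcriptions of a specific adaptation; their quantitative basins of
  attraction may differ from the reference figures in detail.
* The Euler–Maruyama source integrator at `dt = 1, tau_s = 50` carries an
  `O(dt/tau_s)` stationary bias (visible as reduced kurtosis for the
  Laplace potential); marginal-distribution tests use matched moderate
  sample sizes for this reason.
* Online (single-sample) training at the reference rates leaves a few
  degrees of stationary jitter; quantitative claims are made for the
  window-averaged estimator with tail-averaged weights.
* Multimodal priors and adaptive estimation of `p0` from data are out of
  scope, as are overcomplete networks and movie separation.
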
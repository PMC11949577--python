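# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic networks do and do not emulate, and the
known accuracy limits.  Units are fixed package-wide: ms, mV, Hz at the
API; the plasticity kernel and the Model B solver work internally in
ms^-1 so that the homeostatic constant `eps` keeps its natural ms^-2 unit.

## Microscopic model and simulator

LIF neurons with delta-pulse synapses: `tau dV/dt = -V + I`, threshold
`V_theta = 20 mV`, reset `V_r = 10 mV`, refractory `tau_r = 2 ms`,
`tau = 20 ms` (all configurable).  External drive: `K_ext = 1000`
independent Poisson sources per neuron at `nu_ext` with `w_ext = 0.14 mV`.

The simulator is clock-driven (default `dt = 0.1 ms`).  Because synapses
are delta pulses, subthreshold dynamics are exactly integrable: the
voltage decays by `exp(-dt/tau)` per step and all pulses landing in a step
are applied at its boundary, so `dt` only discretises event timing.  The
external input is drawn as one Poisson count per neuron per step with
intensity `K_ext nu_ext dt` (statistically exact).  Transmission delays
are rounded to whole steps (default 1 ms; the delay does not affect
stationary rates).  Refractory bookkeeping sets the counter to
`round(tau_r/dt) - 1` so the minimal inter-spike interval equals `tau_r`
exactly; input arriving during refractoriness is discarded, not buffered.
Spike traces decay by `exp(-dt/tau_p)` per step and jump by 1 at the
neuron's own spikes; plastic weights advance by forward Euler every
`dt_w = 1 ms` (traces vary on `tau_p >> dt_w`), with excitatory-rule
weights floored at 0 and inhibitory-rule weights capped at 0.

Unprinted initial conditions are design choices that shorten the transient
without moving equilibria: `V(0) ~ U[V_r, V_theta)`, traces start at the
stationary mean implied by the external-drive-only rate, and plastic
weights start at `g0 nu0^2/(nu0^2 + eps)` with `nu0` that same rate.

## Transfer function

`phi(mu, sigma)` is evaluated by splitting `e^{u^2} erfc(-u)` into the
bounded `erfcx` part and a `2 e^{u^2}` part with antiderivative
`sqrt(pi) erfi`; upper limits beyond ~25 switch to a log-space asymptotic
series, so deeply subthreshold inputs (up to `(V_theta - mu)/sigma = 40`
and beyond) evaluate without overflow, underflowing gracefully to 0 where
the rate is not representable in float64.  `sigma < 1e-6 mV` routes to the
deterministic closed form `1/(tau_r + tau ln((mu - V_r)/(mu - V_theta)))`.
The scalar path uses adaptive quadrature (relative error <= 1e-8); the
vectorised path used inside the Monte-Carlo solvers interpolates
precomputed uniform-grid tables of the `erfcx` antiderivative and of the
Dawson function (relative rate error ~1e-4, ~3M evaluations/s), with the
same asymptotic tails.

Validation uses an independent Euler-Maruyama first-passage oracle
(`dt = 0.01 ms`) with the standard continuity correction for discrete
barrier detection (barrier lowered by `0.5826 sigma sqrt(dt/tau)`);
without the correction the oracle itself is ~2% low at slow-rate points.
The oracle grid spans sub- and suprathreshold means at rates >= ~5 Hz:
deeply subthreshold points (e.g. `mu = 14, sigma = 1.66`, predicted rate
~1e-4 Hz and below) are unreachable by any finite-trial first-passage MC;
for those the tests assert instead that a bounded-duration MC sees
nothing, consistent with a prediction below its resolution floor.

## Spike-trace analytics

For Poisson firing at rate `nu`, the trace R (jump 1 per spike, decay
`tau_p`) is an exponentially filtered Poisson process governed solely by
`alpha = tau_p nu`; its cumulants are `kappa_n = alpha/n` and its
stationary density solves `r rho' = (alpha - 1) rho(r) - alpha rho(r-1)`.
On [0, 1) the density is exactly `C r^{alpha-1}`; beyond, the solver
marches unit interval by unit interval using the exact integrating factor

    rho(r) = (r/j)^{alpha-1} [rho(j) - (alpha/j) Int_j^r (u/j)^{-alpha} rho(u-1) du],

with the integral accumulated by Simpson on a grid aligned so the shifted
term needs no interpolation (default 400 points per unit interval).  The
first marched interval's `(u-1)^{alpha-1}` endpoint behaviour (singular
for `alpha < 1`) is handled by product integration — the smooth factor
linear per cell against the exact `s^{alpha-1}` weight — and the
interval-relative powers plus a running per-interval log rescale keep the
march in floating-point range for any `alpha` (the unnormalised solution
spans hundreds of orders of magnitude at `alpha = 200`).  Normalisation
and moments treat [0, 1) analytically.  Accuracy achieved: unit mass to
1e-8, mean within 1e-4 relative across `alpha` in [0.25, 200], KS distance
0.004 to the matching normal law at `alpha = 200`.

Transient moments integrate the closed moment hierarchy (Radau); the
stationary recursion `<R_n> = (alpha/n)(1 + sum_{k=2}^{n-2} C(n,k) <R_k>)`
is exact and cross-checked against the cumulants.

The Fig-2-style comparison draws trajectories from `R(0) = 0` and observes
them at `t = 5 tau_p`.  That protocol carries irreducible transients
relative to the *stationary* law: an atom `e^{-5 alpha}` of never-spiked
trajectories (KS floor ~0.082 at `alpha = 0.5`) and a relative mean
deficit `e^{-5}` (KS floor ~0.027 at `alpha = 50`).  The package reports
these distances as measured; at observation times of ~12 tau_p or more
the ensemble matches the stationary density to KS < 0.01.

## Mean-field solvers

Both closures are solved by damped Picard iteration (default damping 0.5)
on Monte-Carlo estimates of the self-consistency map, with common random
numbers across iterations so the iteration sees a fixed deterministic map;
convergence requires a relative update below 1e-3 *and* a residual within
3 MC standard errors.  Defaults: `n_mc = 1e5` for solving, 2e5-1e6 for
reconstruction.  The identity fluctuations (Y, Z) are standardised
coordinates scaled by the Cholesky factor of Sigma(theta); if MC noise
pushes the off-diagonal past positive-semidefiniteness it is shrunk to the
boundary.  The CLT fluctuation can drive the recurrent variance
contribution negative at small K; it is floored at zero (the external part
remains), a deterministic handling of a CLT artifact outside the theory's
validity.  Reconstructed rates are clipped to `[1e-4, 1/tau_r]` Hz to
avoid degenerate zero-rate artifacts downstream.

Model B's scalar rate equation is solved on [0, 1/tau_r] by grid scan plus
bisection; the residual is < 0 at nu = 0 and >= 0 at the refractory bound,
so a bracket always exists, and the *smallest* root is returned (continuity
with the g0 -> 0 limit; multiple roots are possible since g_post is
non-monotone, and the scalar interface can return all of them).  The
batched solver used inside the MC map scans the 400-point grid in blocks
with early termination once every sample is bracketed.  `tau_p` enters the
mean field only through its validity regime: equilibrium weights are
treated as deterministic functions of the rates (the reliable-trace
limit), so trace-fluctuation broadening of the weights is not modelled.

The E-I extension keeps one five-parameter block per presynaptic
population, assumes the block in-degree laws are independent of individual
out-degrees (true for the independent-normal E degrees and fixed-in I
degrees used here, making the presynaptic laws unbiased), and sums
population blocks inside the input moments with the inhibitory rule's
opposite sign.  The populations studied are statistically equivalent, so a
single rate law feeds every block's g_pre moments.

## Degree models and tilts

Configuration-model scaffolds: `fixed-in` wiring picks each neuron's
incoming neighbours uniformly without replacement (out-degrees emerge
binomially); independent or joint degree laws are wired by directed stub
matching with rejection of self-loops and duplicate edges (conflicting
stubs re-shuffled against each other, stubborn singletons resolved by edge
swaps).  Discretised normal degree laws round to the nearest integer,
truncate below 1 and renormalise.  A finite sample from an ensemble-level
joint law does not balance its stub totals exactly; the sequence is
repaired by resampling single nodes (capped) and, if needed, +-1
adjustments of out-degrees on random nodes — an O(sqrt(N)/N) perturbation
of the marginal.

When testing the edge-endpoint tilt laws empirically, note that edges
sharing an endpoint are not independent draws: a node of in-degree m
appears as the endpoint of all of its edges at once (design effect
`E[K^2]/E[K]`, ~25 for the test model).  The package's checks therefore
use the exact node-level CLT covariance of the histogram — the counts are
sums of N i.i.d. per-node vectors — rather than a naive edge-level
chi-square, which would reject a true null about half the time.

## Validation design and known accuracy limits

The synthetic networks emulate the study conditions exactly (N = 1000,
K = 25 or N(25, 7) degrees, gamma weights with `Var[w] = 0.2`, the
Oja-like kernel with `g0 = 0.05-0.4 mV`, `eps = 1e-3 ms^-2`).  Problem
sizes are scaled for desk-top runtimes: end-to-end comparisons use
T = 40-60 s of simulated time and `tau_p = 5 s` (so `alpha = tau_p nu`
is ~25-175, inside the reliable-trace regime); trace ensembles use 50,000
trajectories.  What passing tests show is agreement between the theory and
*this* microscopic model; real cortical data add non-Poisson firing,
conductance synapses and structured topology that neither side models.

Two systematic floors, both properties of the theory rather than of the
implementation, bound the achievable agreement:

* **Shot noise.**  The delta-pulse input differs from Gaussian white noise
  by O(w/sigma) terms.  An exact event-driven simulation of the jump
  process confirms the true rate sits ~1% below the Siegert prediction
  under the reference external drive (22.81 vs 23.10 Hz at
  `nu_ext = 7.5`); the clock-driven simulator converges to the exact
  value as dt -> 0.  Validation sample sizes are therefore chosen so the
  MC standard error is comparable to this approximation error; at
  sub-percent precision the comparison resolves the theory's own bias,
  and the suprathreshold drives (near-regular firing, tiny variance)
  expose it at many standard errors.

* **Heavy-tailed weights.**  With Gamma(0.45, 2/3) inhibitory weights,
  single pulses of several mV occur at appreciable rate and the diffusion
  approximation overestimates the mean rate by ~4% (the CLT closure
  itself contributes only ~0.3%: evaluating the theory with exact input
  sums instead of the bivariate normal moves the prediction negligibly).
  Mean and s.d. of the rate distribution still agree within 5% and 15%;
  distribution-level distances (Wasserstein-1 relative to the s.d.) are
  dominated by this mean offset, ~20% of the rate s.d. for Model A and,
  because the equilibrium weight distribution is very narrow
  (sd/mean ~4%), ~20% of the weight s.d. for Model B.

The synchronous high-gain regime (`g0 = 0.4 mV` at low external drive) is
detected by the Fano factor of binned population spike counts (threshold
5; asynchronous baselines sit near 1) and flagged as outside the theory's
validity rather than judged against tolerances.
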
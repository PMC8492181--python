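# Methods

## Models

All promoter dynamics are encoded as *production-marked* continuous-time
Markov chains (Markovian arrival processes): a square rate matrix of
silent transitions plus a matrix of transitions that each emit one
transcript.  The mechanistic model is the three-state chain
`U <-> U* <-> U**` with the pause-release transition `U** -> U*`
(rate `c`) marked; the telegraph and refractory models carry the mark on
a self-loop of the on state (rate `rho`), since their production does
not change the gene state.  This single representation feeds every
downstream computation — stationary fluxes, waiting times, window
counts, simulation — so the four model families are handled uniformly.

Downstream of production, the mechanistic and delay-telegraph models
remove an active Pol II exactly `tau` seconds after its creation
(deterministic elongation), while mature mRNA decays at first order with
rate `d`.  Rates are s^-1, times s, throughout; no unit layer.

Assumptions inherited from the model class: a single allele; fixed
elongation time (no distributed delays — fluctuations are small for long
genes); premature termination returns the promoter to `U*` but never to
`U`; one paused Pol II at a time (volume exclusion); single-exponential
mRNA decay; no extrinsic noise or cell-cycle effects.

## Waiting times

The time between consecutive productions is a first passage from the
post-production state (`U*`, or the on state `G`) to the next marked
firing.  Per-state Laplace transforms satisfy a linear system with
entries affine in `s`; we solve it by Cramer's rule over the polynomial
ring (numpy polynomial arithmetic), giving the transform as an exact
ratio of polynomials whose coefficients are polynomial combinations of
the rates.  The test suite re-derives the mechanistic transform
symbolically (sympy) as an independent oracle.

Moments `⟨t^i⟩ = (−1)^i f̃^(i)(0)` (orders 1–4) come from exact
power-series division of the two polynomials at `s = 0` — no finite
differencing, so the moment-matching residuals bottom out at machine
precision.  Densities and CDFs come from partial fractions over the
denominator roots (`scipy.signal.residue`), i.e. sums of complex
exponentials; nearly degenerate roots are grouped into repeated poles by
the residue computation, which replaces the ill-conditioned simple-pole
formula in that regime.  `f(0+) = lim s·f̃(s)` is read off the
polynomial degrees: zero for the mechanistic model (production forces a
state change), `rho` for the on-state self-loop models.

## Molecule numbers

*Active Pol II.*  Because every active Pol II lives exactly `tau`
seconds, the steady-state copy number equals the number of marked
firings in a trailing window of length `tau`.  We integrate the joint
master equation over (gene state, cumulative count) for a duration
`tau`, starting from the stationary gene state with count zero, using a
sparse matrix-exponential action (`expm_multiply`).  The truncation
`n_max` defaults to `mean + 12·sqrt(mean·max(1, R)) + 5` with an
explicit overflow state; a run aborts if the leaked mass reaches 1e-9.
This window-count engine is numerically exact (verified: mean = flux ×
window to 1e-8 relative; Poisson for a constitutive gene to 1e-10
absolute) and doubles as the delay-telegraph number engine, replacing
any closed-form Fano expression: its small- and large-window limits (1
and `R`) are checked in the tests.

*Mature mRNA.*  The telegraph steady state is solved from the truncated
CME by a sparse direct solve with the normalization row replacing one
balance equation; the confluent-hypergeometric closed form serves as a
test oracle, never as the implementation.  The mechanistic mature-mRNA
distribution has no closed form here; its mean `γ/d` and Fano factor are
analytic, the full distribution comes from the delay SSA.

*Comparison.*  Hellinger distances are computed on the zero-padded union
support after renormalization; inputs with truncation deficit ≥ 1e-6 are
rejected.  Fano of an empty pool is defined as 1 so Poisson-limit
statements stay total.

## Delay SSA

One steady-state sample per independent trajectory, each with its own
RNG stream seeded by `(seed, trajectory index)` — bit-reproducible and
order-independent.  Scheduled completions of the fixed delay live in a
FIFO queue (they are created in time order); the earliest completion is
executed before any stochastic firing that would overtake it, and exact
ties (probability zero) resolve in favour of the completion.  The gene
state is initialized from its stationary distribution, so the active
Pol II count is *exactly* stationary for any horizon ≥ `tau`; mature
mRNA relaxes at rate `d`.  The default horizon is
`max(20/spectral gap, 5·tau, 7/d)` — the gap being the slowest non-zero
gene-state relaxation rate — recorded in the sample metadata together
with a flag when a user-supplied horizon falls short.  The residual
mature-mRNA mean bias at the default horizon is below `e^{-7} ≈ 1e-3`
relative, well under the Monte-Carlo noise at the sample sizes used.
Sample sizes in the test suite are 1e4 for routine checks and 1e5 for
the reference-scale check, chosen so that four standard errors resolve
the tabulated means.

## Model reduction

`Δ = b′ + c − a − a²/a′ ≥ 0` is equivalent to `R ≥ 1` and is exactly the
condition for the closed-form three-moment map to return positive
two-state rates.  On the boundary `Δ = 0` the map degenerates to a
constitutive gene (`σ_u = 0` through the `Δ³` factor) and is treated as
feasible.  The telegraph and delay-telegraph images share `(ρ, σ_u,
σ_b)` and inherit `d` or `tau` respectively.

Number-moment matching solves for two-state parameters whose first three
*raw* molecule-number moments (`⟨n⟩, ⟨n²⟩, ⟨n³⟩` — the raw/central
choice is ours, undocumented in the source material) equal the
mechanistic model's, by damped Newton in log-parameter space
(forward-difference Jacobian, 200 iterations max, 1e-10 relative
tolerance), started from the closed-form map.  Active-species targets
are exact (window engine); mature-species targets use the analytic mean
and variance plus a simulated third moment, making that mode explicitly
stochastic.  Near or outside the feasibility boundary the Newton
iteration is expected to fail and the result is *flagged*, not raised.

Maximum-likelihood fitting evaluates the exact two-state distribution
engines inside a Nelder-Mead search in log space with five starts (a
moment-based initial guess plus seeded perturbations); diagnostics carry
the log-likelihood and the Hellinger distance to the empirical (or a
supplied exact) distribution.

The refractory reduction matches waiting-time moments 1–4 with a
multistart damped Newton (a telegraph-continuation start at large
`σ_u*`, then seeded log-uniform starts).  The four-moment system
provably cannot be solved when `R < 1` (refractory `R` always exceeds
1), and empirically has no positive root for some reducible sets either;
such cases return a flagged non-converged result with the best residual.

## Sensitivity analysis

Relative sensitivities are central log-differences of the closed-form
map with step 1e-6 (halved if the stencil would cross `Δ = 0`),
reported signed and in magnitude, for `ρ, σ_u, σ_b` and the burst size
`β = ρ/σ_u`.  Degree-one homogeneity of the map gives the built-in
check that each signed row sums to 1 (0 for `β`); with the chosen step
this holds to 1e-5.  The constrained screen draws mechanistic rates
log-uniformly (Oct4 preset: 10^-4–10 s^-1; Nanog: 10^-5–10^-1 s^-1),
maps them in a vectorized pass, and accepts sets whose mapped parameters
fall within `k = 2` experimental errors of the measured values
simultaneously for all three parameters ("within k errors" read as an
absolute window).  Rankings (first and second most/least sensitive
mechanistic parameter per two-state parameter) are tabulated as
proportions; only the modal categories are asserted in tests, at sample
sizes where the binomial call is unambiguous.

## What the built-in parameter sets emulate — and what they do not

The fixtures span bursty and near-constitutive regimes, unimodal and
bimodal copy-number distributions, reducible (`Δ > 0`) and irreducible
sets, and boundary cases with sub-Poissonian active Pol II.  They are
points in rate space, not data: passing tests demonstrate internal
consistency of the theory and engines (closed forms vs first-passage
pipeline vs master equations vs simulation), not agreement with any
measured cell.  Real nascent-mRNA data additionally convolve detection
effects (partial fluorescence of growing tails), extrinsic noise and
cell-cycle structure, all outside this model class.

Three benchmark sets (1, 3 and 5) carry a nominal decay rate of
0.002 s^-1 that is internally inconsistent with their reference
mature-mRNA means, which correspond to d = 0.0016 s^-1.  We keep the
printed values verbatim and simply exclude those sets from mature-mRNA
checks rather than silently correcting them.

## Numerical choices

- Stationary vectors: dense linear solve with the normalization row
  replacing the last balance row (deterministic pivoting).
- Rational-transform trimming: trailing polynomial coefficients below
  1e-13 of the largest are dropped; the transform is rescaled so
  `f̃(0) = 1` exactly.
- Window/CME truncation: deficit tolerance 1e-9 (1e-6 for distribution
  comparisons); violations raise with the `n_max` used.
- Newton solvers: log-space parameters enforce positivity; step halving
  up to 30 times per iteration; residuals scaled by the target moments.
- Known limitations: the mechanistic mature-mRNA *distribution* is
  simulation-only; the refractory four-moment match can legitimately
  fail to exist; sensitivity derivatives are finite-difference, so the
  homogeneity identity holds to 1e-5 rather than machine precision.
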
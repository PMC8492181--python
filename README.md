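# txmodels

Stochastic models of transcription in mammalian cells: a mechanistic
promoter/Pol II model versus the telegraph-like models it is usually
reduced to.

## The scientific problem

Telegraph-like two-state models fit measured mRNA copy-number
distributions remarkably well, yet they omit steps known to be rate
limiting — above all promoter-proximal Pol II pausing and release.
`txmodels` implements a mechanistic model that makes those steps
explicit and the machinery needed to ask *when* and *why* the reduced
models work, and how to tell the model classes apart from data.

The mechanistic model has three promoter states and the reactions

```
U  <->(a, a')  U*  <->(b, b')  U**,     U** ->(c)  U* + A,
A  =>(delay tau)  M,            M ->(d)  0
```

where `U` is inactive chromatin, `U*` the activator-bound state
accessible to Pol II, and `U**` holds a promoter-proximally paused
Pol II.  Pause release (rate `c`) both emits an actively elongating
Pol II (`A`, equivalently a nascent mRNA) and resets the promoter to
`U*` — production is coupled to a gene-state change, which common models
do not have.  Each `A` finishes elongation after a deterministic time
`tau` and becomes a mature mRNA `M`, which decays at first order.  The
reduced models are the telegraph model (`G <-> G*`, production `rho`
from `G`, first-order decay), its delayed variant (removal after `tau`),
and the refractory model with two sequential off states.

Key quantities, all computed exactly:

* the **waiting-time distribution** `f(t)` between consecutive
  productions, via first-passage Laplace transforms — rational in `s`,
  inverted by partial fractions.  Its randomness parameter
  `R = (⟨t²⟩ − ⟨t⟩²)/⟨t⟩²` is `1 + 2ρσᵤ/(σ_b+σᵤ)²` (always > 1) for
  two-state models but can drop to 1/2 for the mechanistic model;
* the **reduction map**: for `Δ = b′ + c − a − a²/a′ ≥ 0` (equivalently
  `R ≥ 1`) closed forms give the unique `(ρ, σᵤ, σ_b)` matching the
  first three waiting-time moments;
* **molecule-number distributions**: the active Pol II count equals the
  number of productions in a trailing window of length `tau`, computed
  exactly from a count-augmented master equation; telegraph mature-mRNA
  distributions come from a truncated CME solve; everything else from an
  exact delay SSA;
* **model discrimination**: `f(0⁺) = 0` with an interior peak for the
  mechanistic model, `f(0⁺) = ρ > 0` and monotone decay for two-state
  and refractory models — number distributions may be indistinguishable,
  waiting times never are.

## Worked example

```python
from txmodels import (builtin_fixtures, effective_two_state, delta,
                      randomness_mechanistic, mean_active, mean_mature,
                      active_distribution)

p = builtin_fixtures()["mapped_c"]     # a reducible parameter set
print(f"Delta = {delta(p):.3f} s^-1, R = {randomness_mechanistic(p):.4f}")
q = effective_two_state(p)
print(f"rho = {q.rho:.4f}, sigma_u = {q.sigma_u:.4f}, sigma_b = {q.sigma_b:.4f} s^-1")
print(f"<n_active> = {mean_active(p):.2f}, <n_mature> = {mean_mature(p):.1f}")
print(f"Fano(active) = {active_distribution(p).fano:.3f}")
```

prints

```
Delta = 0.272 s^-1, R = 2.2574
rho = 0.0870, sigma_u = 0.0118, sigma_b = 0.0286 s^-1
<n_active> = 16.84, <n_mature> = 38.5
Fano(active) = 2.144
```

`Δ > 0` says a two-state reduction exists; the mapped rates are the
unique telegraph/delay-telegraph parameters reproducing the mechanistic
waiting-time moments to third order; the means are the stationary
production rate times the Pol II lifetime and mRNA lifetime
respectively; and the active Pol II Fano factor sits between 1 (short
`tau`) and `R` (long `tau`).

The same is available from a shell:

```
txmodels reduce --fixture mapped_c --method closed-form
txmodels simulate --fixture benchmark_2 --samples 10000 --seed 1 --out samples.tsv
txmodels waiting --fixture mapped_c --grid 0:200:0.5 --out density.tsv
txmodels screen --gene oct4 --draws 100000 --seed 7 --out screen.tsv
```

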
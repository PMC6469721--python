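# Methods

## Model

Markovian SIR on a configuration-model network with preventive dropping.
Parameters: per-edge infection rate `β`, recovery rate `γ`, per-edge
dropping rate `ω` (all units 1/time), and the degree distribution `D` with
pmf `p_k`, mean `μ_D`, variance `σ²_D`.  Dropping admits two equivalent
formulations: the susceptible severs its edge to an infectious neighbour at
rate `ω`, or the infective "warns" down each unpaired stub at rate `ω` and a
warned susceptible drops the edge.  The second form is the one the
effective-degree construction uses, because it lets the network be revealed
edge by edge as the epidemic needs it.

### Effective-degree chain

State `(X_0..X_M, Y_0..Y_M, Z_E)`: counts of susceptibles/infectives with
`i` unpaired stubs, and unpaired stubs on recovered individuals.  Each
infective stub fires at rate `β + ω`; the firing stub pairs with a uniformly
chosen other unpaired stub.  Against a susceptible stub this infects (prob.
`β/(β+ω)`) or silently drops the edge; against an infective/recovered stub
it just forms an edge; a stub may pair with another stub of the same
infective (a self-loop, reducing its effective degree by two).  Recovery
keeps unpaired stubs, moving them to the `Z_E` pool.  If the total stub
count is odd one stub (uniformly chosen) is discarded.  The simulator
(`effective_degree.simulate`) is an exact Gillespie implementation of these
intensities: one aggregate rate `(β+ω)·n_E^Y + γ·ΣY_i`, then categorical
draws (actor type ∝ `i·Y_i`, partner uniform over the remaining stubs,
including the self-pairing correction).  All category scans are O(M) per
event, so a major outbreak at `N = 1000`, `μ_D = 5` costs a few thousand
events and ~4 ms.

Two independent oracles guard the simulator: an explicit-graph backend
(multigraph built first by uniform stub pairing — self-loops and multi-edges
retained — then per-edge dynamics), and an exact continuous-time Markov
chain enumerator for configurations with few stubs.  The enumerator
exploits that (total stubs, #infectives) decreases strictly
lexicographically at every jump, so absorption probabilities follow by a
forward sweep, no linear solve needed.

### Initial conditions

MR graphs: degree counts are the largest-remainder rounding of `N·p_k`, and
a fixed number `i₀` of initial infectives is spread over degree classes in
population proportions (again largest remainder).  NSW graphs: iid degrees,
initial infectives chosen uniformly.  `i₀` may be a count or a fraction
`εN`; asymptotic comparisons use the fraction form for temporal results and
the trace-of-infection limit (`ε → 0`) for final-size results.

## Deterministic limits and fluctuations

The scaled chain is a density dependent population process with five jump
families; drift `F` and local covariance `G = Σ_l lᵀl β_l` are assembled in
`clt.JumpModel` directly from the jump list, and the closed-form `F`,
analytic Jacobian `∂F` are verified against that enumeration (1e-12) and
against central finite differences.  The covariance ODE
`dΣ/dt = G + ∂F Σ + Σ ∂Fᵀ` is integrated jointly with the state on the
lower triangle only (state ordering `(x_0..x_M, y_0..y_M, z_E)`; dimension
`2M+3`, e.g. 33 for the Poisson study, ~560 covariance entries).  For NSW
graphs `Σ(0)` has multinomial `x`- and `y`-blocks
(`σ_{x_i,x_i} = p_i(1−p_i)(1−ε)`, `σ_{x_i,x_j} = −p_i p_j(1−ε)`, the
`y`-block likewise with `ε`), all other entries zero.

A random time change running the clock at rate `η_E/y_E` decouples the
susceptible block and gives fully explicit transformed-time solutions
(`deterministic.closed_form_tilde`); real time is recovered through
`ξ(t) = ∫₀ᵗ ρ_E`, and `θ(t) = ψ(ξ(t))` connects to the edge-based
compartmental variable `θ` with ODE
`θ′ = β f′(θ)/μ_D − (β+γ+ω)θ + γ + ω`.  The transformed infective equations
carry a `1/ρ̃_E` factor that is singular where `ỹ_E = 0`; integration
therefore stops by event detection, with the event level floored at 1e-7
(the crossing slope is O(1), so the error in the hitting time `τ̃` is
O(1e-8)) and the drift's `y_E` denominator floored so that the solver can
evaluate slightly past the crossing.

### Final size and variances

The final-size root is found by bracketed Brent iteration (`xtol` 1e-12) on
`[0, 1)`; in the trace-of-infection regime the trivial root `s = 1` is
excluded by shrinking the right bracket until the residual is positive
(guaranteed when `R₀ > 1`).  Subcritical trace-limit inputs return `ρ = 0`
with a regime flag rather than an error.  The MR variance `σ²_MR` evaluates
four explicit terms plus quadratures `I_A..I_D` over `v ∈ [z, 1]`
(Gauss–Kronrod, abs/rel tol 1e-10; the integrands are smooth because
`v ≥ z > 0`).  The `z > 0` condition fails only when `γ = ω = 0` and the
degree-1 mass vanishes; that regime raises an error.  The NSW extra term
`σ₀²` is fully closed-form.  The no-dropping MR closed form is evaluated as
the NSW closed form minus `σ₀²` (the additive decomposition
`σ²_NSW = σ²_MR + σ₀²` holds for every `ω`, including 0); the `ω = 0`
specialization of the quadrature route is tested against it at 1e-8, which
guards both transcriptions.  An entirely independent numerical route —
integrating the transformed-time covariance to `ỹ_E = δ`, projecting with
the oblique hitting-time projector `B_δ`, and extrapolating linearly in
`δ ∈ {0.02, 0.01, 0.005}` — agrees with the explicit formula to well within
1% (the error in `δ` is linear only for small `δ`, hence those levels).

With `ε_E > 0` the deficit PGF `f_{D_ε}` replaces `f_D` throughout
`σ²_MR`; the NSW variance for `ε_E > 0` additionally depends on *how*
initial infectives are selected and is out of scope (an error is raised).

### Branching approximation

Offspring of an infective with `k` susceptible neighbours: mixed binomial
with success `a(1−e^{−cI})`, where `(a, c, I) = (β/(β+ω), β+ω, Exp(γ))` for
the dropping model and `(1, β, Exp(γ+ω))` for the modified model.  PGFs and
pmfs use the exact finite-sum reduction obtained by binomial expansion and
`E[e^{−c m I}] = g/(g+cm)`; the reduction is validated against adaptive
quadrature of the mixture integral.  The major-outbreak probability is
`1 − f(σ)^{i₀}` with `σ` the PGF fixed point in `[0, 1)` of the size-biased
offspring mixture.

## Degree distributions

Poisson(λ) and Geometric(p) carry analytic PGF derivatives of every order;
final-size and variance formulas use these untruncated closed forms (the
truncation points below make the difference invisible at the reported
precision).  The ODE systems and simulators need finite support: named
families are truncated at `M` and **renormalized** so that every pmf
invariant holds exactly; a warning (not an error) fires when the discarded
tail exceeds `tail_tol`.  Defaults `M = 15` for Poi(5) (tail ~5e-5) and
`M = 50` for Geo(1/6) (tail ~9e-5), chosen so that enlarging `M` changes no
reported quantity at its printed precision.

## Study conditions reproduced by tests and the acceptance script

Degree laws Poi(5) and Geo(1/6) (both mean 5, sds ≈ 2.2 and 5.5);
`β = 3/2, γ = 1`; dropping `ω = 2` vs the modified model `(0, γ+ω=3)`;
NSW graphs, `N = 1000`; a run is a major outbreak when its final size
reaches `0.15 N`; sd confidence intervals use the square roots of the
chi-square variance CI endpoints.  Simulated outbreak probabilities use a
single uniformly chosen initial infective, which is the convention
consistent with the published estimates and with the branching values
(`1 − f(σ) ≈ 0.611/0.486` for Poisson dropping/modified); with five initial
infectives essentially every supercritical run is major.  The acceptance
script runs 2 000 replicates per configuration (binomial 95% half-width
≈ 0.022), a deliberate compute/precision trade-off; the temporal
(CLT-band) tests use 150–300 replicates with tolerances of 3–4 standard
errors plus a small finite-`N` allowance.

## What the synthetic scenarios do and do not emulate

The generators reproduce the configuration-model mechanism exactly —
including self-loops, multi-edges and the odd-stub rule — so passing tests
validate the mathematics on its own terms.  They do not emulate features of
real contact networks (clustering, assortativity, household structure,
degree correlations) or behavioural realism (delayed or partial distancing,
rewiring of dropped edges to new partners, non-exponential infectious
periods), so agreement here says nothing about those settings.  Known
limitations besides: bounded degrees are required by the CLT machinery
(heavy-tailed laws only via truncation); the CLT underestimates prevalence
variability after the epidemic peak at moderate `N` (visible in band tests
if checkpoints are pushed late, hence the pre-peak checkpoint choice); and
`ε_E > 0` NSW final-size variances are unsupported by design.
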
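# Methods

## Model

Two linked loci, A with `r_A` alleles and B with `r_B` alleles, in a
neutral Wright–Fisher population of effective size `N_e`. Mutation at locus
A occurs at population-scaled rate `θ_A = 4 N_e u_A` with a row-stochastic
transition matrix `P^A` (entry `P^A_ki`: a mutating allele `k` becomes
`i`); strictly positive diagonals are required so that the single-locus
chains are aperiodic and the stationary allele frequencies `π^A`, `π^B`
exist and are unique. Recombination between the loci occurs at scaled rate
`ρ = 4 N_e r ≥ 0`.

A sample configuration is `s = (a, b, c)`: `a_i` gametes observed only at
locus A with allele `A_i`, `b_j` observed only at locus B, and `c_ij` fully
typed `A_i B_j` gametes; `n = a + b + c` is the total. `q(s; ρ)` is the
*ordered* sampling probability — the stationary expectation of the monomial
`Π_i x_i·^{a_i} Π_j x_·j^{b_j} Π_ij x_ij^{c_ij}` in the gamete frequencies.
The ordered convention is forced by the boundary values `q(e_i, 0, 0) =
π^A_i` and confirmed by the marginal identity
`q(2,0,0,0) + 2 q(1,1,0,0) + q(0,2,0,0) = π (θπ + 1)/(1 + θ)` (checked in
the tests to 1e-8, independent of ρ).

The symmetric diallelic model (`make_symmetric_diallelic`) has
`r_A = r_B = 2`, all-½ mutation matrices and uniform `π`. It is the
parent-independent form of the mutation model used by LDhat, whose rate
parameter maps as `θ = 2 θ_FD`.

## The exact solver

The stationary probabilities satisfy one linear equation per configuration
(see the module docstring of `twolocus.solver` for the full display): the
diagonal coefficient is `n(n−1) + θ_A(a+c) + θ_B(b+c) + ρc`, and the
right-hand side couples to configurations reached by removing a gamete,
coalescing two identical gametes, pairing two half-typed gametes into a
full one, mutating one gamete at one locus, or splitting a full gamete into
its two half-typed parts (recombination).

Two structural points drive the implementation:

- **Level structure.** The recombination move *increases* n by one, so the
  system cannot be ordered by sample size. What never increases is the
  typed-locus count `t = a + b + 2c`. The closure of a target under all
  moves is computed by breadth-first search, grouped into levels of
  constant `t`, and solved level by level (sparse LU per level, rows
  equilibrated by their diagonal so residuals are O(1)-scaled at any ρ; the
  accepted residual is 1e-10 in that scaling).
- **Singular levels.** At `t = 2` the component containing the single fully
  typed gamete and the (one A-typed + one B-typed) pair has no coupling to
  the boundary rows — its equations are the stationarity equations of a
  type chain. For doubly stochastic mutation matrices (the symmetric model
  included) that block is exactly singular with a constant null vector. The
  solver detects this (a residual or marginal-consistency violation after
  the LU attempt) and re-solves the level in the least-squares sense
  augmented with the exact identities
  `Σ_j q(a − e_i, b, c + e_ij) = q(a, b, c)` (and the locus-B analogue),
  which tie the level to the one below. These identities are exact
  properties of the stationary moments, not approximations.

Boundary configurations (single half-typed gametes) are always added to the
universe: no removal move reaches them from a full-gamete target, yet they
anchor the constraints. Half-typed configurations are fully supported
throughout — the recursion itself creates them via recombination even when
the target has full gamete information.

Cross-checks implemented as independent code paths: a global one-shot
assembly of the whole system (`build_system`), a brute-force dense
least-squares solve over *all* configurations up to a typed-locus bound
(test-local, no shared code), the closed-form Dirichlet(θπ) sampling
formula for parent-independent single-locus models, and the ρ → ∞
factorisation of `q` into the product of one-locus solves (agreement to
relative 1e-4 at ρ = 1e6).

## Subdivision under strong migration

The population is split into Γ demes with size fractions `q'_α` and a
backward migration matrix `M` (`m_αβ` = probability that an individual in α
was in β one generation earlier). `M` is fixed (independent of N and time),
irreducible and aperiodic — primitivity is verified on the sparsity pattern
up to Wielandt's exponent bound `(Γ−1)² + 1`. On the diffusion time scale
migration is then infinitely faster than mutation, recombination and drift:
per-deme frequencies collapse onto their `ξ`-weighted mean (`ξ` the
stationary distribution of `M`) and the mean follows the panmictic
diffusion with `N_e = δ N`, `δ = [Σ_α ξ_α²/q'_α]⁻¹ ≤ 1` (Cauchy–Schwarz,
equality iff `ξ = q'`, i.e. conservative migration).

Consequences implemented here: a sample `(s_1, …, s_Γ)` spread over demes
has, in the limit, the probability of its elementwise **combined sample**
under the panmictic solver at `(θ δ, ρ δ)`. The rescaling convention holds
the per-generation rates fixed (`θ = 4 N u_0` calibrated at the census
size), so subdividing the population multiplies both scaled parameters by
δ; the API takes the reference `(θ, ρ)` and δ explicitly to avoid silent
double-scaling.

## The discrete simulator

One generation applies, in lifecycle order:

1. *Reproduction + recombination* — under monoecious random mating the
   zygote gamete-pair law is the product measure, so the two stages
   collapse to the deterministic update
   `x'_ij = (1 − r_0) x_ij + r_0 x_i· x_·j` per deme.
2. *Migration* — deme α's frequencies become `Σ_β m_αβ ·` (deme β's).
3. *Mutation* — per-locus transition `(1 − u_0) I + u_0 P` applied
   independently at the two loci.
4. *Regulation* — the only stochastic step: each deme's frequencies are
   resampled as a multinomial draw of `2 N_α` gametes (deme sizes
   `N_α = q'_α N`, rounded by largest remainder so they sum to N). This is
   where drift enters; between regulations deme sizes are treated as
   effectively infinite.

A single seeded generator drives a run (bit-reproducible); the per-deme
multinomial draws are one batched call per generation in deme order. The
per-generation probabilities `u_0 = θ/(4N_e)`, `r_0 = ρ/(4N_e)` must land
in [0, 1]; parameters that violate this are rejected rather than clamped
silently.

Sample probabilities are estimated as time averages of the sampling
monomial `P_Γ = Π_α Π_i P_αi·^{a_αi} Π_j P_α·j^{b_αj} Π_ij P_αij^{c_αij}`
over thinned post-burn-in states.

### Error bars and the substitution timescale

With θ = 0.01 the population is monomorphic most of the time, and
statistics such as `q(6,0,0,0)` are dominated by *which* gamete type is
currently fixed. That decorrelates only at the neutral substitution rate
`u_0`, i.e. on a timescale `1/u_0 = 4N/θ` generations — 1.6 × 10⁵ at the
desk scale below, comparable to an affordable run. A single chain's
batch-means standard error is then badly overconfident (a chain that sits
at one fixed type all run reports SE ≈ 0). The validation study therefore
uses `estimate_replicated`: R independent chains (independent seeds), with
`SE = std(replicate means)/√R`, which is honest regardless of within-chain
correlation. The single-chain API (`estimate_sample_probability`,
`batch_means_se`) remains for fast-mixing statistics.

A z comparison additionally requires the estimator to be in its CLT
regime: panel rows whose monomial fired in fewer than 10 retained states
are reported but not scored (a single rare hit produces an arbitrary z).

## Validation study and problem sizes

Two scenarios share `M = [[0.9, 0.1], [0.2, 0.8]]` (so `ξ = (2/3, 1/3)`):
conservative `q' = ξ` (δ = 1) and non-conservative `q' = (1/5, 4/5)`
(δ = 36/85, giving `θ_eff ≈ 0.004235`, `ρ_eff ≈ 21.18`). The panel holds
six subdivided configurations whose combined samples range from an ordered
pair to a monomorphic six-sample.

Desk-scale settings (the package's own choice of a tractable study):
N = 400, burn-in 10 N generations, thinning max(N, 10³), 8 replicate chains
of 500 retained states each — 4 × 10⁶ generations and 4,000 retained states
per scenario, a few minutes in total. The full-size study (N = 10,000,
10¹² generations, thinning 10⁵) is available as `scale="full"` but is far
beyond an interactive run. At desk scale the solver-vs-chain agreement is
tested at 3 SE; the rarest panel row (the doubly polymorphic `(1,1,0,1)`
combined sample, probability ~10⁻⁶–10⁻⁷) typically yields no events at this
scale and is reported as unresolved rather than scored.

### What the simulator does and does not establish

The chain validates the diffusion-scale collapse (combined samples at
rescaled parameters) for the symmetric diallelic model at small N — the
regime where the O(1/N) discretisation error is largest, so agreement here
is conservative evidence for larger populations. It does not emulate
features of real data: no selection, no dioecy or overlapping generations,
no time-varying migration, exactly two loci, and mutation/recombination
rates constant across the genome. Passing tests say the mathematics of the
collapse is implemented correctly, not that any particular natural
population satisfies strong migration.

## Numerical choices

- Stationary vectors: direct solve of the left-eigenvector system with a
  power-iteration fallback (tolerance 1e-13); results verified to satisfy
  `ξ M = ξ` within 1e-12.
- δ values within 1e-12 of 1 are snapped to exactly 1 (the conservative
  case is an exact algebraic identity, blurred only by rounding).
- Solver residual tolerance 1e-10 on diagonal-equilibrated rows; solved
  probabilities are required to lie in (0, 1].
- Comparisons against 6-significant-digit reference values use relative
  1e-3; the rescaled-parameter inputs are used at full precision, not at
  their printed 4-digit rounding.
- Chain frequencies are clipped at 0 and renormalised before the
  multinomial draw to absorb float drift (≤ 1e-16 per generation).
- Degenerate inputs fail loudly: empty samples, dimension mismatches,
  reducible or periodic migration matrices, per-generation rates outside
  [0, 1].

## Known limitations

- The solver's configuration universe grows quickly with sample size
  (≈ 2 × 10⁴ configurations at n = 7 diallelic); it is meant for the small
  n of composite-likelihood lookup tables, not for large samples — that is
  what the asymptotic sampling formulas are for.
- `estimate_replicated` shares burn-in across replicates but cannot repair
  a burn-in far shorter than the substitution timescale; for extreme
  initial states the memory of the start decays only at rate `u_0`, which
  is why the ergodicity comparison uses replicate runs much longer than
  the burn-in.
- Only two loci and finite allele counts; no infinite-sites or
  infinite-alleles mutation.
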
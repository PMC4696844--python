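# twolocus

Exact two-locus sampling probabilities for subdivided populations under
strong migration.

## The problem

Fine-scale recombination-map estimation (LDhat and its descendants) is built
on the stationary sampling distribution of a neutral two-locus Wright–Fisher
model: the probability `q(s; ρ)` of drawing an ordered sample configuration
`s = (a, b, c)` — counts of gametes typed only at locus A (`a`), only at
locus B (`b`), or at both loci (`c`) — given population-scaled mutation
rates `θ_A, θ_B = 4 N_e u` and recombination rate `ρ = 4 N_e r`. Real
samples, however, come from structured populations. This package implements
the two-locus theory for a population split into Γ subpopulations exchanging
migrants according to a fixed backward migration matrix `M` (strong
migration): the structure collapses into a single scalar, the effective-size
factor

    δ = [ Σ_α ξ_α² / q'_α ]⁻¹ ,        N_e = δ N ,

where `ξ` is the stationary distribution of `M` and `q'_α` the
subpopulation size fractions. A sample spread over demes can then be scored
as its elementwise **combined sample** with the ordinary panmictic machinery
at the rescaled parameters `(θ δ, ρ δ)`. δ ≤ 1 always, with equality exactly
for conservative migration (`q' M = q'`).

## What the package does

- **Exact solver** (`twolocus.solver`): `q(s; ρ)` by assembling and solving
  the closed linear recursion the stationary probabilities satisfy
  (boundary values are the stationary allele frequencies `π`). The
  recombination move splits a fully typed gamete into two half-typed ones,
  so the system is closed by breadth-first search and solved level by level
  in the typed-locus count `t = a + b + 2c`; singular levels (they occur for
  doubly stochastic mutation models) are resolved with exact
  marginal-consistency constraints.
- **Substructure analysis** (`twolocus.substructure`): `ξ`, `δ`, rescaled
  parameters, combined samples, `ξ`-weighted mean frequencies.
- **Forward simulator** (`twolocus.simulate`): the discrete multi-deme chain
  (reproduction → recombination → migration → mutation → multinomial
  regulation) and Monte-Carlo estimation of stationary sample probabilities,
  including a replicated estimator with honest errors for slowly mixing
  statistics.
- **Validation study** (`twolocus.experiments`): chain-vs-solver comparison
  for a two-deme panel in a conservative (δ = 1) and a non-conservative
  (δ = 36/85) scenario.

## Worked example

Effective-size factor for `M = [[0.9, 0.1], [0.2, 0.8]]` with fractions
`q' = (1/5, 4/5)`:

```
$ echo '[[0.9,0.1],[0.2,0.8]]' > M.json; echo '[0.2,0.8]' > q.json
$ twolocus delta --migration M.json --fractions q.json --theta 0.01 --rho 50 --n 10000
quantity        value
xi      0.6666666667,0.3333333333
delta   0.4235294118
N_e     4235.294118
theta_eff       0.004235294118
rho_eff 21.17647059
```

Migration is non-conservative here, so a census size of N = 10,000 behaves
like an effective size of ~4,235, and the scaled rates shrink by the same
factor δ = 36/85.

Exact ordered sample probabilities at `θ = 0.01, ρ = 50` (symmetric
diallelic model, configurations as row-major `c11,c12,c21,c22` counts):

```
$ twolocus solve --theta 0.01 --rho 50 --config 0,0,1,1 --config 6,0,0,0
config  q
0,0,1,1 0.00123136554
6,0,0,0 0.24438312
```

The first value is the probability of an ordered pair of gametes carrying
the two different alleles at both loci; the second is the probability that
six sampled gametes are all of type `A1B1` — large because with θ = 0.01
the population is monomorphic most of the time.

In Python, the same numbers:

```python
from twolocus import SampleConfig, make_symmetric_diallelic, solve_probabilities
params = make_symmetric_diallelic(theta=0.01, rho=50.0)
table = solve_probabilities(SampleConfig.full([[6, 0], [0, 0]]), params)
table.q((0, 0, 1, 1))   # 0.0012313655...
```

The validation study (`twolocus reproduce-tables`, a few minutes) runs the
discrete two-deme chain at reduced scale (N = 400) and checks that the
combined-sample estimates match the solver at `(θ δ, ρ δ)` within
Monte-Carlo error.

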
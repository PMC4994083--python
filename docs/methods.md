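# Methods

## Model and assumptions

`resgame` simulates a closed, well-mixed community of fixed size N on a
single trophic level. There is no immigration, no spatial or metapopulation
structure, and no explicit resource depletion dynamics: availability is the
instantaneous per-capita quotient R′ₘ/Nₘ, where Nₘ counts the individuals
consuming resource m at the start of the generation. The M resource supplies
R′ₘ are drawn once per run from Uniform(0, R_Max) and held fixed — the model
describes a homogeneous constant environment, so redrawing supplies each
generation would change the science; the constant-environment choice is
deliberate and the alternative is not implemented.

Each species consumes a fixed random subset of M_cons resources, all
essential to it, so its capability is the minimum over its consumed
resources of the Monod term Rₘ/(Rₘ + K₍ₘ,ᵢ₎) (law of the minimum). The
half-saturation constants are tied by Σₘ K₍ₘ,ᵢ₎ = M_cons/2: without this
trade-off, evolution simply fixes a species that is efficient on everything.
Co-limitation by several resources simultaneously is out of scope.

Competition enters through the payoff matrix rebuilt every generation from
the capability vector: a_ij = −1/(1+exp(μᵢ−μⱼ)) off-diagonal, a_ii = μᵢ−1.
Both intraspecific and interspecific competition therefore depend only on
species' resource-use properties — no payoffs are prescribed. Fitness is the
exponential map f = exp(w·π) of the mean payoff over a focal individual's
N−1 partners; reproduction is Wright–Fisher (fitness-proportional
multinomial of size N), and each offspring founds a brand-new species with
probability ν, its traits drawn independently of the parent.

## Parameters

| symbol | name | meaning | typical values |
|---|---|---|---|
| N | `community_size` | fixed number of individuals | 100–2000 |
| M | `num_resources` | number of resources | 3–7 |
| M_cons | `num_consumed` | resources consumed per species | 2–5 (≤ M) |
| R_Max | `r_max` | upper bound of the supply draw | set via R_Max/N; ≲ 1 per capita is "scarce" |
| w | `selection_intensity` | payoff→fitness exponent; 0 is neutral | 0.001 (near-neutral) to 10 (strong) |
| ν | `mutation_prob` | per-offspring speciation probability | 10⁻⁷–10⁻³ |

Schedule fields (`generations`, `burn_in`, `sampling_interval`,
`init_mode`, `master_seed`) are configuration, not biology. `init_mode:
single` starts isogenic; `k_species:k` starts with k random species at
near-equal abundances — time-averaged diversity in the stationary regime is
insensitive to this choice.

## Design choices where the model leaves freedom

- **K-vector sampling.** Only the sum constraint is inherent to the model.
  We draw M_cons independent Uniform(0,1) variates, normalise to sum
  M_cons/2, and re-balance the last component so the sum is exact to float
  precision. This is symmetric across resources and strictly positive (it is
  not the flat Dirichlet, whose marginals differ; nothing downstream depends
  on that distinction).
- **Open-interval draws.** Supply and K draws exclude exact endpoints by
  rejection, keeping every capability strictly inside (0,1) and every payoff
  strictly inside (−1,0).
- **Mutation mechanics.** Offspring are drawn first; each then flips an
  independent ν-coin. Mutants are subtracted from their parent's count and
  each founds a distinct singleton species; two mutants in one generation
  are two species. Consumer counts are computed once from the
  start-of-generation state, so a newborn's capability is first evaluated in
  the following generation. Species labels are monotone counters and never
  reused.
- **Frequency-independent control.** The control model sets each species'
  payoff to its self-interaction term alone, πᵢ = a_ii = μᵢ−1, so fitness is
  independent of the other species' frequencies while capabilities still
  respond to consumer counts. The model variant this control corresponds to
  is underdetermined; this is one defensible construction, flagged as such,
  and the qualitative result (far lower diversity than the
  frequency-dependent model) is insensitive to reasonable alternatives that
  remove the frequency coupling from the payoff.
- **Game classification ties.** Exact ties in an invasion comparison are
  labelled `degenerate` rather than silently assigned; with continuous
  traits they have probability zero. The prisoner's-dilemma label is exposed
  only as a dominance subtype with the conventional ordering
  a₂₁ > a₁₁ > a₂₂ > a₁₂.
- **Neutral richness at ν = 0.** The k = 0 term θ/θ of the expected-richness
  sum is defined as its limit 1, so S(ν=0) = 1.

## Numerical notes

- Trade-off sum checked to 1e−9 (accumulated rounding over long runs);
  payoff complement identity a_ij + a_ji = −1 checked to 1e−12.
- The engine skips the payoff pipeline only when a single species is
  present: the one-category multinomial returns N regardless of fitness, so
  the shortcut is exact and only the ν-coins are flipped. No shortcut exists
  for w = 0; the neutral limit exercises the full pipeline.
- All fitness weights underflowing to zero (w·|π| ≳ 700) raises a
  `NumericalDegeneracyError` advising a smaller selection intensity.
- Reproducibility: one master seed drives a single `numpy` Generator per
  run; sweeps spawn replicate streams as
  `SeedSequence([master_seed, cell_index, replicate])`, so any cell can be
  recomputed in isolation bit-for-bit.

## What the simulator's own data do and do not show

The simulator is its own data generator; there is no external data. Tests
therefore establish internal consistency (exact payoff identities,
conservation laws, the brute-force interaction average) and agreement with
independent theory (the neutral expected-richness formula, the closed-form
game classification under equal capabilities). They do not calibrate the
model against empirical plankton communities: real communities have
fluctuating environments, immigration, trait inheritance and overlapping
generations, all absent here. Passing tests show the mechanism — emergent
diversity above the resource count under negative frequency-dependent
selection — not a quantitative fit to nature.

## Problem sizes used in the shipped experiments

The reference diversity curves correspond to N = 2000 with 10⁸ burn-in
generations (`configs/diversity_full_scale.yaml`). The package's own test
experiments use desk-scale designs chosen once: the recorded-window count at
its native parameters (N=100, ν=5×10⁻⁷, thirty 10⁵-generation windows); the
neutral limit at N=200, ν=0.005, 5 replicates of 5×10⁴ burn-in plus 10⁵
sampled generations; the selection contrast at N=500, ν=10⁻⁴, w ∈ {0.001,
10}, 10 replicates; the scarce-resource census at N=200, R_Max/N=0.05; and
community-size sweeps over N ∈ {50,100,200,400} at ν=10⁻⁴ (the full-scale
ν=10⁻⁶ supplies too few mutations to equilibrate in desk-scale windows; the
raised rate keeps the dynamics selection-dominated while making the
mutation–selection–drift balance observable). At these scales the linear
(fixed R_Max) and concave/logarithmic (fixed R_Max/N) diversity–size shapes
and the dominance of coexistence games under scarcity are all reproduced;
the abrupt game-structure transition near R_Max ≈ 1200 requires the
full-scale equilibration and is not asserted at desk scale.

## Known limitations

- Payoffs are evaluated from the start-of-generation state; within-generation
  feedback (offspring affecting availabilities) is outside the model.
- The time-average standard error treats samples as independent; at
  sampling_interval=1 consecutive samples are autocorrelated, so reported
  standard errors understate uncertainty (point estimates are unaffected).
- No Moran-process engine, no replicator/ESS analysis, no plotting surface:
  numerical series are the artifact.
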
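# resgame

Stochastic eco-evolutionary simulator of multi-species resource competition,
formulated as an evolutionary game. It addresses a classic puzzle of
community ecology — the *plankton paradox*: stable communities routinely hold
far more species than the number of limiting resources, which the competitive
exclusion principle forbids at equilibrium. Here species are not predefined:
they arise by speciation mutations, compete through a payoff matrix that is
rebuilt every generation from their resource-use efficiencies, and go extinct
under selection and drift. Diversity is an emergent balance of mutation,
frequency-dependent selection and drift, and it can robustly exceed the
number of resources.

Intended users: theoretical ecologists and population geneticists studying
species coexistence, frequency-dependent selection, and neutral-theory
baselines.

## Model

A community of fixed size *N* lives on *M* resources with constant supplies
*R′ₘ* drawn once from Uniform(0, *R*_Max). Each species *i* consumes a random
subset of *M*_cons resources with half-saturation constants *K*₍ₘ,ᵢ₎ > 0
subject to the efficiency trade-off Σₘ *K*₍ₘ,ᵢ₎ = *M*_cons/2. With *N*ₘ
individuals consuming resource *m*, the per-capita availability is
*R*ₘ = *R′ₘ*/*N*ₘ, and the species' capability follows the law of the minimum
over Monod terms:

    μ_i = min_m  R_m / (R_m + K_{m,i})   ∈ (0, 1).

Pairwise competition payoffs are built from capabilities each generation:

    a_ij = −1 / (1 + exp(μ_i − μ_j))   (i ≠ j),      a_ii = μ_i − 1,

all lying in (−1, 0) with a_ij + a_ji = −1. A focal individual of species *i*
meets its *N* − 1 neighbours, giving the mean payoff

    π_i = [ Σ_j a_ij N_j − a_ii ] / (N − 1),

mapped to fitness f_i = exp(w·π_i) with selection intensity *w* ≥ 0.
Reproduction is Wright–Fisher: *N* offspring are drawn multinomially with
probabilities ∝ f_i·N_i, and each offspring independently founds a brand-new
species with probability ν (traits drawn afresh — speciation as point
mutation). At w = 0 the model reduces to the neutral infinite-alleles
community, whose expected richness is

    S = Σ_{k=0}^{N−1} θ/(θ + k),    θ = 2Nν,

the analytic baseline the simulator is checked against. Every unordered
species pair is also classified by its 2×2 subgame: *coexistence* when each
species invades the other when rare (a₂₁ > a₁₁ and a₁₂ > a₂₂), *bistability*
when each resident resists invasion, otherwise *dominance*.

## Worked example

Simulate a small community (N = 100, M = 3 resources, 2 consumed per
species, strong selection w = 10) for 10⁵ generations:

```bash
$ resgame simulate --config configs/trajectory_small.yaml --out demo_out
mean richness 4.0789 over 1001 samples; 506 mutation events; artefacts in demo_out/
```

The time-averaged richness (≈ 4.1 species) exceeds M = 3 — more coexisting
species than resources, sustained by negative frequency-dependent selection.
`demo_out/trajectory.tsv` holds the abundance trajectory
(`generation  species_id  abundance`), `events.jsonl` the per-generation
mutation/extinction log, and `manifest.json` the full configuration and seed
for bit-identical re-runs.

The neutral baseline for a community of 200 with ν = 0.005 (θ = 2):

```bash
$ resgame neutral -n 200 -u 0.005
9.7660
```

Scarce resources make coexistence games dominate. From Python:

```python
import resgame as rg

params = rg.ModelParams(community_size=200, num_resources=7, num_consumed=5,
                        r_max=10.0, selection_intensity=10.0, mutation_prob=1e-4)
sweep = rg.games_vs_rmax(params, [10.0], generations=30_000, burn_in=10_000,
                         sampling_interval=20, replicates=3, seed=1)
census = sweep.summaries[0]["games"]
div = sweep.summaries[0]["diversity"]
print(f"S = {div.mean_richness:.2f}, coexistence fraction = "
      f"{census.fractions['coexistence']:.3f} over {census.n_pairs} pairs")
```

prints

```
S = 12.55, coexistence fraction = 1.000 over 219666 pairs
```

— at R_Max/N = 0.05 every sampled species pair is a mutual-invasion
(coexistence) game and the community holds ~12.6 species on 7 resources.

`configs/diversity_full_scale.yaml` records the full-scale reference
parameterisation (N = 2000, 10⁸ burn-in) the headline diversity curves
correspond to; it is not a desk-scale run.

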
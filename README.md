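# ecovoi

**Value of information for managing food-web motifs coupled to an ecosystem
function and service.**

Managers of small ecosystems often know who eats whom, but not which species
benefit from an ecosystem function (pollination, nutrient cycling, water
filtration, ...). `ecovoi` asks: *is it worth finding out before deciding
which species to protect?* It answers with a dynamic value-of-information
analysis for both risk-neutral managers (expected value of perfect
information, EVPI) and risk-prone managers (minimax regret), across families
of four-species food-web motifs.

## The model in brief

A motif food web of `J` species (default `J = 4`: linear, apparent
competition, omnivory, or intraguild competition) has one *provider* species
whose presence generates an ecosystem function. A fraction `1 − α` of the
function flows to an ecosystem service; the feedback fraction `α` supports
the survival of an unknown subset `f` of species (the *feedback structure*,
2^J candidates under a uniform prior). The presence/absence state `x` evolves
as a Markov decision process: each step the manager protects one species,
then each extant species `j` survives with probability

```
p_j^0 · N_prey(j,x)/N_prey(j,x⁰) · (1 − b·N_pred(j,x)/N_pred(j,x⁰)) · EF_j(x,f,α)
```

(baseline survival, prey loss, predation pressure `b`, and function
feedback). Each candidate structure defines one MDP, solved exactly by policy
iteration; then

```
EVPI = EV_certainty − EV_uncertainty
     = E_f[ V_{δ*_f}(x⁰,f) ] − max_δ E_f[ V_δ(x⁰,f) ]
```

is the expected gain from learning `f` first, and the regret matrix
`V_{δ*_f}(x⁰,f) − V_δ(x⁰,f)` yields the maximum-regret statistics. The
standard experiment crosses five ecological features — motif, trophic level
of the provider, `α`, baseline survival `p0`, predation strength `b` — into a
10,368-configuration factorial sweep and ranks their influence with a
regression tree. See `docs/methods.md` for the full model, the switchable
model components, and their defaults.

## Worked example

```python
from ecovoi import EcosystemConfig, build_motif, compute_voi

web = build_motif("omnivory", provider=4)       # top predator provides the function
cfg = EcosystemConfig(web=web, alpha=0.8, p0=0.8, b=0.9, objective="service")
res = compute_voi(cfg)
print(f"EV_certainty   = {res.ev_certainty:.4f}")
print(f"EV_uncertainty = {res.ev_uncertainty:.4f}")
print(f"relative EVPI  = {100 * res.evpi_rel:.2f}%")
print(f"max regret     = {100 * res.max_regret_rel:.2f}%")
print("uninformed protects:",
      [a + 1 for a in res.uninformed_strategy.actions])
```

prints

```
EV_certainty   = 0.4317
EV_uncertainty = 0.4120
relative EVPI  = 4.78%
max regret     = 9.08%
uninformed protects: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 4, 4, 4, 4, 4, 4]
```

Reading: with the omnivory web's top predator providing the service, a
manager who learns the true feedback structure before acting improves the
expected discounted service value by 4.8% over the best uninformed strategy,
and by up to 9.1% in the worst-case structure. The uninformed strategy
protects the basal species (species 1) in most states — securing the bottom
of the web is the best hedge when you don't know which species the function
supports — and switches to the provider (species 4) once the lower web has
collapsed.

The same analysis from the shell:

```bash
voi make-example-configs configs/
voi run-config configs/example_run_config.yaml
voi sweep --objective service --out results/service.csv
voi rank-features results/service.csv
voi alpha-sweep --out results/alpha.csv
voi case-study configs/example_case_study_synthetic.yaml
voi validate            # exhaustive cross-check on reduced webs
```

`voi sweep` over the default grids reports, for the service objective, a
maximum relative EVPI of ~25% (attained at high feedback strength and high
baseline survival) and worst-case regrets in the low hundreds of percent,
while the biodiversity objective never gains more than 1% from the feedback
information — informed and uninformed managers protect essentially the same
species when the goal is species richness.

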
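# Model and methods

`ecovoi` quantifies how much a manager of a small food web would gain from
learning which species benefit from an ecosystem function, before committing
to a protection strategy. This note documents the model, the switches that
matter, the design choices that were genuinely open, and what the package's
tests do and do not establish.

## The managed ecosystem

A motif is a four-species food web (configurable up to ~6 species), with
species indexed bottom-to-top by trophic position. Four canonical topologies
are built in:

| motif | edges (prey → predator) |
|---|---|
| linear | 1→2, 2→3, 3→4 |
| apparent_competition | 1→3, 2→3, 3→4 |
| omnivory | 1→2, 2→3, 3→4, 2→4 |
| intraguild_competition | 1→2, 1→3, 2→3, 3→4 |

The published figures show these motifs only graphically, so the adjacencies
above are this package's canonical choice; any other topology can be supplied
as a `custom` edge list.

One species — the *provider* — generates an ecosystem function (pollination,
nutrient cycling, filtration, ...). A fraction `1 − α` of that function flows
out of the web as an ecosystem service; the fraction `α` (the *feedback
strength*) flows back to support the survival of a subset `f` of species, the
*feedback structure*. Which subset is the true one is unknown: all `2^J`
subsets (16 for four species) are candidates under a uniform prior.

## Dynamics

The state is the presence/absence vector `x ∈ {0,1}^J`; the all-extant state
`x⁰` is the initial condition. Each step the manager protects one species,
then every extant, unprotected species `j` survives independently with
probability

```
p_j = p_j^0 · N_prey(j,x)/N_prey(j,x⁰)
          · (1 − b · N_pred(j,x)/N_pred(j,x⁰))
          · EF_j(x, f, α)
```

where `p_j^0` is the baseline survival probability, the prey ratio degrades
survival in proportion to lost prey, extant predators impose a penalty scaled
by the predation strength `b`, and `EF_j` is the function-feedback factor.
Species with no prey (or no predators) in the web take factor 1 for the
corresponding term, so the product reduces to `p_j^0` in the most favourable
neighbourhood. Extinction is permanent, the all-extinct state is absorbing,
and the joint transition probability factorises over species.

### The feedback factor (`ef_term_mode`)

The exact functional form of the feedback support is a modelling choice, so
four interpretations are implemented; all return 1 when `α = 0` except
`scaled` (see below), and all are 1 for species outside `f` except
`dependence`:

* `shared` (default): members receive `(1−α) + α·x_provider/|f|` — the
  routed fraction `α` is consumed in equal shares by the `|f|` beneficiaries,
  so support per member is strongest when the member is the sole beneficiary
  of an extant provider. This is the only benefit-oriented form under which
  the candidate structures induce different dynamics *while the provider is
  extant*, which is necessary for the information to have any value under the
  service objective (service stops at provider extinction, so post-extinction
  differences cannot matter there).
* `retention`: members keep full support while the provider lives and retain
  `(1−α)` after its extinction. Simplest, but it makes all structures
  identical on provider-extant states, hence service-objective EVPI is
  identically zero — useful as a null model.
* `dependence`: every species needs the function for a fraction `α` of its
  survival support and only members receive it (`(1−α) + α·x_provider·[j∈f]`).
  Strong structure signal, but it leaks into the biodiversity objective far
  more than the near-zero biodiversity information value this model family is
  meant to exhibit.
* `scaled`: members' support is `α·x_provider` outright; kept for
  completeness (at `α → 0` it starves members rather than disconnecting the
  feedback).

### Protection (`protection_mode`)

What protecting a species achieves in one step is likewise a switch:

* `prey_limited` (default): protection removes baseline mortality, predation
  pressure and function dependence, but cannot feed a consumer — the
  protected species survives with the fraction of its prey still extant
  (probability 1 for basal species). Under this semantics "protect the
  provider forever" is not a universal hedge, which is what gives structural
  information its value; it also makes protecting basal species the
  uninformed optimum in most states, since they are the only species that can
  be secured outright.
* `absolute`: protection guarantees survival unconditionally. This trivialises
  the service objective (always protecting the provider is optimal for every
  structure, so EVPI ≡ 0); retained as a bounding case.
* `boost`: protection lifts the baseline to 1 but neighbourhood and feedback
  factors still apply.

## Objectives, solution, and value of information

Rewards accrue on the current state before the transition, including at
`t = 0`: the *biodiversity* objective pays the number of extant species; the
*service* objective pays `service_unit_value · (1−α) · x_provider`.
Management costs (default zero, optionally increasing with trophic rank) are
subtracted per action. Strategies are stationary deterministic maps from the
`2^J` states to the `J` protect actions, valued by the infinite-horizon
discounted criterion and solved exactly: policy evaluation is a dense linear
solve of `(I − γP_δ)V = R_δ`, and policy iteration alternates that solve with
greedy improvement, ties always broken to the lowest species index so every
result is bit-for-bit reproducible.

With informed optima `δ*_f` per structure and a uniform prior,

* `EV_certainty = mean_f V_{δ*_f}(x⁰, f)`,
* `EV_uncertainty = max_δ mean_f V_δ(x⁰, f)`, the maximisation restricted to
  the 16 informed optima (the candidate-set approximation; it can only
  understate the true uninformed optimum, hence overstate EVPI — the
  `oracle_validation` module checks both directions exactly on reduced webs
  by enumerating all `actions^states` strategies),
* `EVPI = EV_certainty − EV_uncertainty ≥ 0`.

Relative EVPI divides by `EV_uncertainty` (`normalization_mode="baseline"`);
dividing by the best perpetual reward (`max_attainable`) or by the species
count / total service value (`literal`) are available alternatives. Regret of
a candidate strategy under structure `f` is its shortfall against `δ*_f`; the
reported *maximum regret* is the worst case over structures for the optimal
uninformed strategy, in relative form normalised per structure by that
strategy's own value there (so values above 100% are possible); the
minimax-regret strategy and its worst case are computed alongside.

## Default parameters

| parameter | default | notes |
|---|---|---|
| `gamma` | 0.997 | not printed in the source material; calibrated once against the sweep-level maxima (below) and then frozen |
| `alpha` grid | 0.1–0.8 by 0.1 | study conditions |
| `p0` grid | 0.1–0.9 by 0.1 | study conditions |
| `b` grid | 0.1–0.9 by 0.1 | study conditions |
| `ef_term_mode` | `shared` | see above |
| `protection_mode` | `prey_limited` | see above |
| costs | 0 | equal-cost baseline; `cost_per_trophic_rank` adds `c·(rank−1)` |
| prior over structures | uniform 1/16 | configurable vector |

The full factorial sweep is 4 motifs × 4 provider levels × 8 α × 9 p0 × 9 b =
10,368 configurations; each configuration takes ~2.5 ms (16 batched policy
iterations on 16-state MDPs plus a 256-system batched evaluation), so a full
sweep per objective runs in well under a minute on one CPU. Feature influence
is summarised by a depth-5 regression tree (minimum leaf 50) on the five
features, with importances as normalised variance reduction.

## Calibration and fidelity

The feedback functional form, the protection semantics, the discount factor
and the relative-value normalisation are not pinned down by the printed
dynamics; the defaults above were selected *once* by matching the sweep-level
headline quantities — maximum relative EVPI ≈ 25% under the service objective
and a maximum relative regret in the low hundreds of percent, with
biodiversity information value near zero everywhere — and every reported
number is then computed under those same settings. Under these defaults the
sweep reproduces: maximum service relative EVPI 25.2%; biodiversity relative
EVPI ≤ 1% on all 10,368 configurations; zero information value whenever the
provider is basal, for every feedback strength; relative EVPI weakly
increasing in α for the omnivory motif with a top-level provider; and trophic
level as the dominant feature in the tree ranking. The maximum relative
regret reaches ≈ 224% (the sweep maximum jumps discontinuously in γ because
the identity of the optimal uninformed policy switches, so intermediate
values are not attainable), and the model places the sweep peak at a
mid-trophic provider with weak predation rather than at the top-provider,
strong-predation corner; per-configuration regret magnitudes at that corner
are correspondingly smaller. These are honest limits of reconstructing the
unpublished pieces of the model from its printed description.

## Case-study mode

`run_case_study` consumes a config of functional-group motifs with per-group
baseline survival probabilities and reports, per motif and provider level,
the maximum relative EVPI over an (α, b) grid (defaults 0.1–0.8 and 0.1–0.9
by 0.01). The bundled example config is labelled *synthetic*: its survival
probabilities are placeholders illustrating the format, not empirical
estimates, so its outputs demonstrate shape and qualitative behaviour only.

## What the tests show, and don't

The synthetic study conditions are exactly the factorial grids above: no
observation noise, no parameter uncertainty within a configuration, and a
prior that is uniform by assumption. Passing tests therefore establish the
internal correctness of the solver (against value iteration, exhaustive
strategy enumeration, closed forms and seeded simulation) and the qualitative
structure of the value-of-information surface under this model family — not
that any real ecosystem has these dynamics, nor the empirical values of the
unpublished model components discussed under *Calibration and fidelity*.

## Known limitations

* Webs beyond ~6 species are out of reach (state space `2^J`, and the
  exhaustive oracle grows as `J^(2^J)`).
* One function, one provider, one protected species per step; no
  recolonisation, no rewiring after extinctions, no non-trophic interactions.
* The uninformed optimum is searched over the informed optima only (exact
  only for reduced webs); expected value of *partial* information is out of
  scope.
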
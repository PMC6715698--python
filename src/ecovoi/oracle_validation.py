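"""Independent brute-force oracles for the solver and the candidate-set step.

Finding the best uninformed strategy exactly requires scoring every
deterministic stationary strategy -- ``(#actions)**(#states)`` of them -- under
every candidate structure. That is infeasible for four-species webs (4^16
strategies) but exact and fast for reduced webs (J <= 3), where it validates
both policy iteration (the per-structure optimum must match the enumerated
optimum) and the candidate-set approximation of the uninformed optimum (which
can only understate it, hence overstate EVPI). A seeded Monte-Carlo simulator
cross-checks the linear-algebra policy evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ecosystem_mdp import EcosystemConfig, MDPFamily, build_mdp_family
from .mdp_solver import Strategy, _evaluate_batch, optimal_informed_strategies
from .motif_networks import FeedbackStructure, build_motif
from .voi_analysis import compute_voi, ev_certainty

logger = logging.getLogger("ecovoi.oracle")

__all__ = [
    "ExhaustiveResult",
    "enumerate_strategies",
    "brute_force_ev_uncertainty",
    "monte_carlo_value",
    "validate",
]

_MAX_ENUMERATION = 10_000_000


@dataclass
class ExhaustiveResult:
    """Outcome of exhaustive strategy enumeration.

    ``best_value`` is the exact optimum of the prior-averaged value at the
    all-extant state; ``per_structure_best`` the exact informed optimum per
    structure (for cross-checking policy iteration).
    """

    best_value: float
    best_strategy: Strategy
    n_strategies_evaluated: int
    per_structure_best: np.ndarray


def enumerate_strategies(n_actions: int, n_states: int) -> np.ndarray:
    """All ``n_actions ** n_states`` deterministic strategies, mixed-radix order.

    Row ``i`` is the action map of strategy ``i``; strategy 0 always protects
    species 1, and the last strategy always protects species ``n_actions``.
    """
    count = n_actions**n_states
    if count > _MAX_ENUMERATION:
        raise ValueError(
            f"refusing to enumerate {count} strategies "
            f"({n_actions}^{n_states} > {_MAX_ENUMERATION})"
        )
    idx = np.arange(count)
    digits = np.empty((count, n_states), dtype=np.int64)
    for s in range(n_states):
        digits[:, s] = (idx // (n_actions ** s)) % n_actions
    return digits


def brute_force_ev_uncertainty(
    family: MDPFamily,
    gamma: float | None = None,
    prior=None,
    chunk: int = 2048,
) -> ExhaustiveResult:
    """Exact uninformed optimum by scoring every deterministic strategy.

    Evaluates each strategy's value at the all-extant state under every
    structure (exact linear solves, chunked), averages under the prior and
    returns the maximiser. Also records the exact per-structure optima.
    """
    g = family.config.gamma if gamma is None else gamma
    F = family.n_structures
    A = family.P.shape[1]
    S = family.P.shape[-1]
    policies = enumerate_strategies(A, S)
    N = policies.shape[0]
    w = np.full(F, 1.0 / F) if prior is None else np.asarray(prior, dtype=float)

    x0 = family.initial_state
    s_idx = np.arange(S)[None, :]
    best_mean = -np.inf
    best_i = 0
    per_structure = np.full(F, -np.inf)
    for lo in range(0, N, chunk):
        pol = policies[lo : lo + chunk]  # (n, S)
        n = pol.shape[0]
        pol_b = np.repeat(pol, F, axis=0)
        f_idx = np.tile(np.arange(F), n)
        P_pol = family.P[f_idx[:, None], pol_b, s_idx, :]
        R_pol = family.R[s_idx, pol_b]
        V = _evaluate_batch(P_pol, R_pol, g)[:, x0].reshape(n, F)
        means = V @ w
        i = int(np.argmax(means))
        if means[i] > best_mean:
            best_mean = float(means[i])
            best_i = lo + i
        per_structure = np.maximum(per_structure, V.max(axis=0))
    return ExhaustiveResult(
        best_value=best_mean,
        best_strategy=Strategy.from_array(policies[best_i], label="exhaustive"),
        n_strategies_evaluated=N,
        per_structure_best=per_structure,
    )


def monte_carlo_value(
    strategy: Strategy,
    config: EcosystemConfig,
    structure: FeedbackStructure,
    n_episodes: int = 10_000,
    horizon: int | None = None,
    seed: int = 0,
    family: MDPFamily | None = None,
) -> tuple[float, float]:
    """Simulation estimate of ``V_delta(x^0, f)`` with its standard error.

    Episodes are truncated at ``horizon`` (default: where the discount tail
    falls below 1e-6), which biases the estimate by at most
    ``gamma**horizon * max|R| / (1 - gamma)``. Seeded and reproducible.
    """
    if family is None:
        family = build_mdp_family(config)
    g = config.gamma
    if horizon is None:
        horizon = int(np.ceil(np.log(1e-6) / np.log(g)))
    f = structure.structure_id
    P = family.P[f]  # (A, S, S)
    R = family.R
    actions = np.asarray(strategy.actions)
    cum = np.cumsum(P, axis=-1)

    rng = np.random.default_rng(seed)
    states = np.full(n_episodes, family.initial_state, dtype=np.int64)
    totals = np.zeros(n_episodes)
    disc = 1.0
    for _ in range(horizon):
        a = actions[states]
        totals += disc * R[states, a]
        u = rng.random(n_episodes)
        rows = cum[a, states]  # (n, S)
        states = (u[:, None] <= rows).argmax(axis=1)
        disc *= g
    return float(totals.mean()), float(totals.std(ddof=1) / np.sqrt(n_episodes))


def _random_small_config(rng: np.random.Generator, n_species: int) -> EcosystemConfig:
    """A random chain web of ``n_species`` with feature values off the grid."""
    edges = [(j, j + 1) for j in range(1, n_species)]
    provider = int(rng.integers(1, n_species + 1))
    web = build_motif("custom", provider, edges=edges, n_species=n_species)
    return EcosystemConfig(
        web=web,
        alpha=float(rng.uniform(0.1, 0.9)),
        p0=rng.uniform(0.2, 0.95, size=n_species),
        b=float(rng.uniform(0.1, 0.9)),
        gamma=0.95,
        objective=str(rng.choice(["biodiversity", "service"])),
    )


def validate(max_species: int = 3, n_configs: int = 50, seed: int = 1) -> dict:
    """Cross-check the solver pipeline against exhaustive enumeration.

    Draws random reduced configurations (chains of 2..max_species species) and
    verifies, for each: (a) policy iteration equals the enumerated informed
    optimum per structure; (b) the candidate-set uninformed value never exceeds
    the enumerated optimum; (c) candidate-set EVPI >= exhaustive EVPI >= 0.
    Returns a summary dict with the worst observed gaps.
    """
    rng = np.random.default_rng(seed)
    worst_pi_gap = 0.0
    worst_cand_gap = 0.0
    min_exh_evpi = np.inf
    failures = []
    for i in range(n_configs):
        n = int(rng.integers(2, max_species + 1))
        cfg = _random_small_config(rng, n)
        family = build_mdp_family(cfg)
        res = compute_voi(cfg, family=family)
        exh = brute_force_ev_uncertainty(family)
        pi_vals = np.array(
            [v.at_initial() for _, v in optimal_informed_strategies(family)]
        )
        pi_gap = float(np.abs(pi_vals - exh.per_structure_best).max())
        cand_gap = float(exh.best_value - res.ev_uncertainty)
        exh_evpi = ev_certainty(pi_vals) - exh.best_value
        worst_pi_gap = max(worst_pi_gap, pi_gap)
        worst_cand_gap = max(worst_cand_gap, cand_gap)
        min_exh_evpi = min(min_exh_evpi, exh_evpi)
        scale = 1e-8 * (1.0 + np.abs(exh.best_value))
        if pi_gap > scale or cand_gap < -scale or exh_evpi < -scale:
            failures.append(i)
        logger.debug(
            "config %d (J=%d): pi_gap=%.2e cand_gap=%.2e", i, n, pi_gap, cand_gap
        )
    return {
        "n_configs": n_configs,
        "max_policy_iteration_gap": worst_pi_gap,
        "max_candidate_set_gap": worst_cand_gap,
        "min_exhaustive_evpi": float(min_exh_evpi),
        "n_failures": len(failures),
        "failed_configs": failures,
        "passed": not failures,
    }
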
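"""Expected value of perfect information and regret under structural uncertainty.

The manager does not know which feedback structure ``f`` (the subset of species
the ecosystem function supports) is the true one. With a prior over the ``F``
candidate structures (uniform by default):

* ``EV_certainty`` is the prior-expected value of learning ``f`` first and then
  applying the informed optimum ``delta_f^*``;
* ``EV_uncertainty`` is the best prior-expected value achievable by a single
  strategy applied blind; following the candidate-set approximation, the search
  is restricted to the ``F`` informed optima (an exhaustive mode for small webs
  lives in :mod:`ecovoi.oracle_validation`);
* ``EVPI = EV_certainty - EV_uncertainty >= 0`` is the expected gain from
  resolving the uncertainty before acting (risk-neutral view);
* the regret matrix ``regret[c, f] = V_{delta_f^*}(x^0, f) - V_c(x^0, f)``
  yields the maximum-regret and minimax-regret quantities (risk-prone view).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecosystem_mdp import EcosystemConfig, MDPFamily, build_mdp_family
from .mdp_solver import Strategy, _evaluate_batch, optimal_informed_strategies

__all__ = [
    "VOIResult",
    "ev_certainty",
    "ev_uncertainty",
    "evaluate_candidates",
    "regret_analysis",
    "compute_voi",
]


@dataclass
class VOIResult:
    """All value-of-information outputs for one ecosystem configuration.

    Relative quantities are stored as fractions (0.25 = 25%); ``evpi_rel`` is
    ``None`` when the configured normalisation is degenerate (zero divisor).
    """

    ev_certainty: float
    ev_uncertainty: float
    evpi_abs: float
    evpi_rel: float | None
    uninformed_strategy: Strategy
    informed_strategies: list[Strategy]
    informed_values: np.ndarray  # (F,) optimal value per structure at x^0
    candidate_values: np.ndarray  # (C, F) candidate value per structure at x^0
    regret: np.ndarray  # (C, F)
    minimax_strategy: Strategy
    max_regret_abs: float
    max_regret_rel: float
    minimax_max_regret_abs: float
    degenerate: bool = False


def _prior(n: int, prior) -> np.ndarray:
    if prior is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(prior, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("prior must be a length-F probability vector")
    return w


def ev_certainty(informed_values, prior=None) -> float:
    """Prior-expected value of the informed optima (Eq.: mean under the prior)."""
    vals = np.asarray(informed_values, dtype=float)
    if vals.size == 0:
        raise ValueError("informed_values must be nonempty")
    return float(_prior(vals.size, prior) @ vals)


def evaluate_candidates(
    candidates: list[Strategy], family: MDPFamily, gamma: float | None = None
) -> np.ndarray:
    """Value at ``x^0`` of every candidate strategy under every structure.

    Returns a (C, F) array; one exact batched policy-evaluation solve.
    """
    g = family.config.gamma if gamma is None else gamma
    F = family.n_structures
    C = len(candidates)
    S = family.P.shape[-1]
    policies = np.asarray([c.actions for c in candidates])  # (C, S)
    # (C*F, ...) batch: candidate c evaluated on structure f, gathered in place
    pol_batch = np.repeat(policies, F, axis=0)
    f_idx = np.tile(np.arange(F), C)
    s_idx = np.arange(S)[None, :]
    P_pol = family.P[f_idx[:, None], pol_batch, s_idx, :]  # (C*F, S, S)
    R_pol = family.R[s_idx, pol_batch]  # (C*F, S)
    V = _evaluate_batch(P_pol, R_pol, g)  # (C*F, S)
    return V[:, family.initial_state].reshape(C, F)


def ev_uncertainty(
    candidates: list[Strategy],
    family: MDPFamily,
    gamma: float | None = None,
    prior=None,
    candidate_values: np.ndarray | None = None,
) -> tuple[float, Strategy]:
    """Best prior-averaged value over the candidate strategies, and the argmax.

    Ties are broken towards the candidate of lowest provenance index.
    """
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    vals = (
        evaluate_candidates(candidates, family, gamma)
        if candidate_values is None
        else candidate_values
    )
    w = _prior(vals.shape[1], prior)
    means = vals @ w
    best = int(np.argmax(means))
    return float(means[best]), candidates[best]


def regret_analysis(
    candidates: list[Strategy],
    informed_values,
    candidate_values: np.ndarray,
    reporting_index: int,
):
    """Regret matrix and the risk-prone summary statistics.

    ``regret[c, f]`` is how far candidate ``c`` falls short of the informed
    optimum when ``f`` turns out to be true. The reporting strategy (by
    default the optimal uninformed strategy, index ``reporting_index``)
    yields ``max_regret_abs`` and the relative version normalised per
    structure by the reporting strategy's own value there -- the improvement
    obtainable over acting uninformed, which can exceed 100%.

    Returns ``(regret, minimax_strategy, max_regret_abs, max_regret_rel,
    minimax_max_regret_abs)``.
    """
    informed = np.asarray(informed_values, dtype=float)
    regret = informed[None, :] - np.asarray(candidate_values, dtype=float)
    regret = np.maximum(regret, 0.0)  # informed optimum bounds every candidate
    worst = regret.max(axis=1)
    mm_idx = int(np.argmin(worst))
    rep = regret[reporting_index]
    max_regret_abs = float(rep.max())
    denom = np.asarray(candidate_values, dtype=float)[reporting_index]
    ok = np.abs(denom) > 1e-12
    max_regret_rel = float((rep[ok] / denom[ok]).max()) if ok.any() else float("nan")
    return regret, candidates[mm_idx], max_regret_abs, max_regret_rel, float(worst[mm_idx])


def compute_voi(
    config: EcosystemConfig,
    family: MDPFamily | None = None,
    prior=None,
    extra_candidates: list[Strategy] | None = None,
) -> VOIResult:
    """Full value-of-information analysis for one ecosystem configuration.

    Builds the MDP family (unless one is supplied), solves the informed optima,
    evaluates them as the uninformed candidate set, and assembles EVPI and
    regret statistics. ``evpi_rel`` follows ``config.normalization_mode``:

    * ``baseline`` (default): EVPI divided by ``EV_uncertainty`` -- the
      fractional improvement over managing without the information;
    * ``max_attainable``: divided by the value of collecting the maximum
      one-step reward forever, ``max R / (1 - gamma)``;
    * ``literal``: divided by the species count (biodiversity) or the total
      discounted value of uninterrupted full service delivery (service).
    """
    if family is None:
        family = build_mdp_family(config)
    informed = optimal_informed_strategies(family)
    informed_strats = [s for s, _ in informed]
    informed_vals = np.array([v.at_initial() for _, v in informed])

    candidates = list(informed_strats)
    if extra_candidates:
        candidates.extend(extra_candidates)
    cand_vals = evaluate_candidates(candidates, family)

    evc = ev_certainty(informed_vals, prior)
    w = _prior(family.n_structures, prior)
    means = cand_vals @ w
    unif_idx = int(np.argmax(means))
    evu = float(means[unif_idx])
    uninformed = Strategy(candidates[unif_idx].actions, label="uninformed")

    evpi_abs = evc - evu

    degenerate = False
    mode = config.normalization_mode
    if mode == "baseline":
        if abs(evu) < 1e-12:
            evpi_rel, degenerate = None, True
        else:
            evpi_rel = evpi_abs / evu
    elif mode == "max_attainable":
        evpi_rel = evpi_abs / (float(family.R.max()) / (1 - config.gamma))
    else:  # literal
        if config.objective == "biodiversity":
            evpi_rel = evpi_abs / config.web.n_species
        else:
            total = (
                config.service_unit_value * (1 - config.alpha) / (1 - config.gamma)
            )
            evpi_rel = evpi_abs / total

    regret, mm_strat, mra, mrr, mm_mra = regret_analysis(
        candidates, informed_vals, cand_vals, unif_idx
    )

    return VOIResult(
        ev_certainty=float(evc),
        ev_uncertainty=evu,
        evpi_abs=float(evpi_abs),
        evpi_rel=evpi_rel,
        uninformed_strategy=uninformed,
        informed_strategies=informed_strats,
        informed_values=informed_vals,
        candidate_values=cand_vals,
        regret=regret,
        minimax_strategy=Strategy(mm_strat.actions, label="minimax-regret"),
        max_regret_abs=mra,
        max_regret_rel=mrr,
        minimax_max_regret_abs=mm_mra,
        degenerate=degenerate,
    )
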
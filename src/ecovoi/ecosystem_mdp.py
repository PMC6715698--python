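"""Species-presence MDP for a food-web motif coupled to an ecosystem function.

The ecosystem state is the presence/absence vector ``x`` of the ``J`` species;
at each step the manager protects one species, then every extant species
survives independently with a probability that is the product of four factors:

* a baseline survival probability ``p_j^0``;
* a prey factor ``N_prey(j, x) / N_prey(j, x^0)`` -- survival degrades in
  proportion to lost prey (1 for species with no prey in the web);
* a predation factor ``1 - b * N_pred(j, x) / N_pred(j, x^0)`` -- extant
  predators impose a penalty scaled by the predation strength ``b`` (1 for
  species with no predators in the web);
* a function-feedback factor tied to the feedback structure ``f`` (the set of
  species the ecosystem function supports), controlled by ``ef_term_mode``.

Under the most favourable neighbourhood (no prey lost, no predators extant,
full functional support) the product reduces to ``p_j^0``. Extinction is
permanent: an absent species never recolonises, and the all-extinct state is
absorbing under every action.

Because the exact effect of a protection action and the exact functional form
of the feedback factor live in modelling choices rather than in the printed
dynamics, both are exposed as config switches (``protection_mode``,
``ef_term_mode``) with documented defaults; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motif_networks import FeedbackStructure, FoodWeb, enumerate_feedback_structures

__all__ = [
    "EcosystemState",
    "EcosystemConfig",
    "MDPFamily",
    "ef_support_term",
    "species_survival_probability",
    "reward_vector",
    "build_mdp_family",
]

EF_TERM_MODES = ("retention", "scaled", "shared", "dependence")
PROTECTION_MODES = ("absolute", "prey_limited", "boost")
NORMALIZATION_MODES = ("baseline", "max_attainable", "literal")
OBJECTIVES = ("biodiversity", "service")


@dataclass(frozen=True)
class EcosystemState:
    """Presence/absence vector with its bitmask id (bit ``j-1`` = species j)."""

    presence: tuple[int, ...]
    state_id: int

    @classmethod
    def from_presence(cls, presence: Sequence[int]) -> "EcosystemState":
        pres = tuple(int(v) for v in presence)
        if any(v not in (0, 1) for v in pres):
            raise ValueError("presence entries must be 0 or 1")
        sid = sum(v << j for j, v in enumerate(pres))
        return cls(presence=pres, state_id=sid)

    @classmethod
    def from_id(cls, state_id: int, n_species: int) -> "EcosystemState":
        pres = tuple((state_id >> j) & 1 for j in range(n_species))
        return cls(presence=pres, state_id=state_id)

    @classmethod
    def initial(cls, n_species: int) -> "EcosystemState":
        """The all-extant state ``x^0``."""
        return cls.from_presence((1,) * n_species)


@dataclass
class EcosystemConfig:
    """Everything needed to assemble the per-structure MDP family.

    Parameters
    ----------
    web
        The food-web motif with its function provider.
    alpha
        Feedback strength: the fraction of the ecosystem function routed back
        to species survival; the remaining ``1 - alpha`` supplies the service.
    p0
        Per-species baseline survival probabilities (scalar broadcast to all).
    b
        Predation strength scaling the survival penalty from extant predators.
    gamma
        Discount factor of the infinite-horizon objective.
    objective
        ``"biodiversity"`` (reward = number of extant species) or
        ``"service"`` (reward = value of the service the provider delivers).
    service_unit_value
        Currency value of one step of full service delivery; cancels in all
        relative quantities.
    costs
        Per-species management cost subtracted from the reward when that
        species is protected; default zero for all.
    ef_term_mode, protection_mode, normalization_mode
        Model switches; see module docstring and ``docs/methods.md``.
    include_no_action
        If True, append a "protect nothing" action (off by default: the
        manager always protects exactly one species).
    """

    web: FoodWeb
    alpha: float
    p0: float | Sequence[float]
    b: float
    gamma: float = 0.997
    objective: str = "service"
    service_unit_value: float = 1.0
    costs: Sequence[float] | None = None
    ef_term_mode: str = "shared"
    protection_mode: str = "prey_limited"
    normalization_mode: str = "baseline"
    include_no_action: bool = False

    p0_vector: np.ndarray = field(init=False, repr=False)
    cost_vector: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        J = self.web.n_species
        p0 = np.broadcast_to(np.asarray(self.p0, dtype=float), (J,)).copy()
        if not (0 <= self.alpha < 1 and 0 < self.b < 1 and 0 < self.gamma < 1):
            # alpha = 0 is admitted as the no-feedback limit, under which all
            # candidate structures induce identical dynamics
            raise ValueError(
                "alpha must lie in [0, 1); b and gamma strictly in (0, 1)"
            )
        if not np.all((p0 > 0) & (p0 < 1)):
            raise ValueError("every baseline survival probability must be in (0, 1)")
        costs = (
            np.zeros(J)
            if self.costs is None
            else np.broadcast_to(np.asarray(self.costs, dtype=float), (J,)).copy()
        )
        if np.any(costs < 0):
            raise ValueError("costs must be non-negative")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.ef_term_mode not in EF_TERM_MODES:
            raise ValueError(f"ef_term_mode must be one of {EF_TERM_MODES}")
        if self.protection_mode not in PROTECTION_MODES:
            raise ValueError(f"protection_mode must be one of {PROTECTION_MODES}")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}"
            )
        object.__setattr__(self, "p0_vector", p0)
        object.__setattr__(self, "cost_vector", costs)

    @property
    def n_states(self) -> int:
        return 2**self.web.n_species

    @property
    def n_actions(self) -> int:
        return self.web.n_species + (1 if self.include_no_action else 0)


@dataclass
class MDPFamily:
    """Transition tensors and rewards, one MDP per candidate feedback structure.

    ``P`` has shape ``(F, A, S, S)`` with ``P[f, a, s, t]`` the probability of
    moving from state ``s`` to ``t`` under action ``a`` when structure ``f`` is
    the true one; ``R`` has shape ``(S, A)`` (rewards do not depend on ``f``).
    Actions ``0..J-1`` protect species ``1..J``; an optional final action
    protects nothing.
    """

    config: EcosystemConfig
    structures: list[FeedbackStructure]
    P: np.ndarray
    R: np.ndarray

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def initial_state(self) -> int:
        return self.config.n_states - 1


# ---------------------------------------------------------------------------
# vectorised building blocks (shared by the scalar API and the family builder)
# ---------------------------------------------------------------------------


def _presence_matrix(n_species: int) -> np.ndarray:
    """X[s, j] = presence of species j+1 in state s (bitmask enumeration)."""
    sids = np.arange(2**n_species)
    return (sids[:, None] >> np.arange(n_species)[None, :]) & 1


def _neighbour_terms(web: FoodWeb, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Prey and predation survival factors for every (state, species).

    Species with no prey (resp. predators) in the web get factor 1: the term
    must reduce the survival product to ``p_j^0`` in the most favourable case.
    """
    J = web.n_species
    X = _presence_matrix(J).astype(float)
    M = web.adjacency().astype(float)  # M[i, k]: i+1 eaten by k+1
    n_prey_max = M.sum(axis=0)  # per predator k
    n_pred_max = M.sum(axis=1)  # per prey i
    n_prey = X @ M  # (S, J): extant prey of each species
    n_pred = X @ M.T  # (S, J): extant predators of each species
    prey_term = np.ones((X.shape[0], J))
    has_prey = n_prey_max > 0
    prey_term[:, has_prey] = n_prey[:, has_prey] / n_prey_max[has_prey]
    pred_term = np.ones((X.shape[0], J))
    has_pred = n_pred_max > 0
    pred_term[:, has_pred] = 1.0 - b * n_pred[:, has_pred] / n_pred_max[has_pred]
    return prey_term, pred_term


def _ef_terms(config: EcosystemConfig, member_masks: np.ndarray) -> np.ndarray:
    """Function-feedback survival factor for every (structure, state, species).

    ``member_masks`` is the (F, J) boolean membership matrix of the candidate
    structures. Returns an (F, S, J) array in [0, 1].
    """
    web = config.web
    alpha = config.alpha
    X = _presence_matrix(web.n_species)
    x_prov = X[:, web.provider - 1].astype(float)  # (S,)
    F = member_masks.shape[0]
    S = X.shape[0]
    J = web.n_species
    member = member_masks.astype(float)[:, None, :]  # (F, 1, J)
    xp = x_prov[None, :, None]  # (1, S, 1)
    mode = config.ef_term_mode
    if mode == "retention":
        term = np.where(member > 0, (1 - alpha) + alpha * xp, 1.0)
    elif mode == "scaled":
        term = np.where(member > 0, alpha * xp, 1.0)
    elif mode == "shared":
        # the fraction alpha of the function is consumed in equal shares by
        # the |f| beneficiaries; a member's support peaks when it is the sole
        # beneficiary of an extant provider
        sizes = np.maximum(member_masks.sum(axis=1).astype(float), 1.0)
        share = (1 - alpha) + alpha * xp / sizes[:, None, None]
        term = np.where(member > 0, share, 1.0)
    elif mode == "dependence":
        # every species relies on the function for a fraction alpha of its
        # survival support; only members of f actually receive it
        term = (1 - alpha) + alpha * xp * member
        term = np.broadcast_to(term, (F, S, J)).copy()
    else:  # pragma: no cover - guarded in config validation
        raise ValueError(mode)
    return np.broadcast_to(term, (F, S, J)).copy()


def _unprotected_survival(
    config: EcosystemConfig, member_masks: np.ndarray
) -> np.ndarray:
    """(F, S, J) survival probability of each extant, unprotected species."""
    prey_term, pred_term = _neighbour_terms(config.web, config.b)
    base = config.p0_vector[None, :] * prey_term * pred_term  # (S, J)
    return base[None, :, :] * _ef_terms(config, member_masks)


def _protected_survival(
    config: EcosystemConfig, unprotected: np.ndarray
) -> np.ndarray:
    """(F, S, J) survival probability of each extant species while protected.

    ``absolute``: survival is guaranteed outright. ``prey_limited``: protection
    removes baseline mortality, predation pressure and function dependence, but
    cannot feed a consumer -- survival equals the fraction of its prey still
    extant. ``boost``: protection lifts the baseline to 1, the neighbourhood
    and feedback factors still apply.
    """
    mode = config.protection_mode
    F, S, J = unprotected.shape
    if mode == "absolute":
        return np.ones((F, S, J))
    prey_term, _ = _neighbour_terms(config.web, config.b)
    if mode == "prey_limited":
        return np.broadcast_to(prey_term[None, :, :], (F, S, J)).copy()
    # boost: divide the baseline back out of the unprotected product
    return unprotected / config.p0_vector[None, None, :]


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------


def _coerce_state(state, n_species: int) -> EcosystemState:
    if isinstance(state, EcosystemState):
        return state
    return EcosystemState.from_presence(np.asarray(state).reshape(n_species))


def ef_support_term(
    config: EcosystemConfig,
    structure: FeedbackStructure,
    state,
    species: int,
) -> float:
    """Function-feedback survival factor for one (structure, state, species)."""
    st = _coerce_state(state, config.web.n_species)
    masks = structure.member_mask(config.web.n_species)[None, :]
    return float(_ef_terms(config, masks)[0, st.state_id, species - 1])


def species_survival_probability(
    config: EcosystemConfig,
    structure: FeedbackStructure,
    state,
    action: int,
    species: int,
) -> float:
    """Probability that extant ``species`` is still present after one step.

    ``action`` is the protected species (1-based). Protecting ``species``
    applies the configured protection semantics; otherwise the survival
    probability is the four-factor product described in the module docstring.
    """
    st = _coerce_state(state, config.web.n_species)
    if st.presence[species - 1] != 1:
        raise ValueError(
            "survival probability is defined for extant species only; "
            "extinction is absorbing"
        )
    masks = structure.member_mask(config.web.n_species)[None, :]
    unprot = _unprotected_survival(config, masks)
    if action == species:
        return float(
            _protected_survival(config, unprot)[0, st.state_id, species - 1]
        )
    return float(unprot[0, st.state_id, species - 1])


def reward_vector(config: EcosystemConfig, state, action: int) -> float:
    """Immediate reward collected in ``state`` when ``action`` is applied.

    Biodiversity objective: the number of extant species. Service objective:
    ``service_unit_value * (1 - alpha) * x_provider`` -- the share of the
    function not routed back to species flows to the service. Management cost
    of the protected species is subtracted; rewards accrue on the current
    state before the transition, including at t = 0.
    """
    st = _coerce_state(state, config.web.n_species)
    cost = 0.0
    if 1 <= action <= config.web.n_species:
        cost = float(config.cost_vector[action - 1])
    if config.objective == "biodiversity":
        return float(sum(st.presence)) - cost
    return (
        config.service_unit_value
        * (1 - config.alpha)
        * st.presence[config.web.provider - 1]
        - cost
    )


# ---------------------------------------------------------------------------
# family builder
# ---------------------------------------------------------------------------


def build_mdp_family(config: EcosystemConfig) -> MDPFamily:
    """Assemble transition tensors and rewards for all candidate structures.

    The joint transition probability factorises over species: given the current
    state, each species survives (or not) independently, extinct species stay
    extinct with probability 1, and protected species follow the protection
    semantics. The result is deterministic in the config.
    """
    web = config.web
    J = web.n_species
    S = config.n_states
    A = config.n_actions
    structures = enumerate_feedback_structures(J)
    masks = np.array([s.member_mask(J) for s in structures])  # (F, J)
    F = masks.shape[0]
    X = _presence_matrix(J)  # (S, J)

    unprot = _unprotected_survival(config, masks)  # (F, S, J)
    prot = _protected_survival(config, unprot)  # (F, S, J)

    # survival probability of species j under action a: (F, A, S, J)
    surv = np.broadcast_to(unprot[:, None, :, :], (F, A, S, J)).copy()
    for j in range(J):  # action j protects species j+1
        surv[:, j, :, j] = prot[:, :, j]
    surv *= X[None, None, :, :]  # extinct species never resurrect
    np.clip(surv, 0.0, 1.0, out=surv)

    P = np.ones((F, A, S, S))
    for j in range(J):
        xj_next = X[:, j].astype(bool)[None, None, None, :]
        sj = surv[:, :, :, j][:, :, :, None]
        P *= np.where(xj_next, sj, 1.0 - sj)

    costs = np.concatenate([config.cost_vector, [0.0]])[:A]
    if config.objective == "biodiversity":
        base = X.sum(axis=1).astype(float)
    else:
        base = (
            config.service_unit_value
            * (1 - config.alpha)
            * X[:, web.provider - 1].astype(float)
        )
    R = base[:, None] - costs[None, :]

    return MDPFamily(config=config, structures=structures, P=P, R=R)
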
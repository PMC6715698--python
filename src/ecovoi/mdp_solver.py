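"""Exact solution and evaluation of the per-structure protection MDPs.

The state spaces are tiny (``2**J`` states), so everything is done exactly:
policy evaluation is a dense linear solve of ``(I - gamma * P_delta) V =
R_delta`` and policy iteration alternates that solve with a greedy improvement
step. Ties between equally valued actions are always broken towards the lowest
species index, making every result bit-for-bit reproducible.

Actions are 0-based internally (action ``a`` protects species ``a + 1``; an
optional trailing action protects nothing).
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib

import numpy as np

from .ecosystem_mdp import MDPFamily

__all__ = [
    "Strategy",
    "ValueFunction",
    "policy_iteration",
    "evaluate_strategy",
    "optimal_informed_strategies",
]

_MAX_PI_ITERATIONS = 10_000  # cannot bind: PI visits each policy at most once


@dataclass(frozen=True)
class Strategy:
    """A total deterministic state -> action map.

    ``actions[s]`` is the 0-based action taken in state ``s`` (protect species
    ``actions[s] + 1``). ``label`` records provenance, e.g. ``"informed f=3"``.
    """

    actions: tuple[int, ...]
    label: str = ""

    @classmethod
    def from_array(cls, actions: np.ndarray, label: str = "") -> "Strategy":
        return cls(actions=tuple(int(a) for a in actions), label=label)

    def protected_species(self, state_id: int) -> int:
        """1-based species protected in ``state_id``."""
        return self.actions[state_id] + 1

    def fingerprint(self) -> str:
        """Stable short hash of the action map (ignores the label)."""
        raw = ",".join(map(str, self.actions)).encode()
        return hashlib.sha1(raw).hexdigest()[:10]

    def __len__(self) -> int:
        return len(self.actions)


@dataclass(frozen=True)
class ValueFunction:
    """Expected discounted value per state, in objective units."""

    values: tuple[float, ...]

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ValueFunction":
        return cls(values=tuple(float(v) for v in values))

    def at_initial(self) -> float:
        """Value at the all-extant state ``x^0`` (the last state id)."""
        return self.values[-1]

    def __getitem__(self, state_id: int) -> float:
        return self.values[state_id]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# batched kernels
# ---------------------------------------------------------------------------


def _evaluate_batch(
    P_pol: np.ndarray, R_pol: np.ndarray, gamma: float
) -> np.ndarray:
    """Solve ``(I - gamma P) V = R`` for a batch of policies.

    ``P_pol``: (..., S, S) transition matrices under fixed policies;
    ``R_pol``: (..., S) rewards under those policies. Exact dense solve.
    """
    S = P_pol.shape[-1]
    A_lin = np.eye(S) - gamma * P_pol
    return np.linalg.solve(A_lin, R_pol[..., None])[..., 0]


def _select_policy(P: np.ndarray, R: np.ndarray, policy: np.ndarray):
    """Transition rows and rewards under ``policy`` for batched MDPs.

    ``P``: (N, A, S, S), ``R``: (S, A), ``policy``: (N, S) of action indices.
    Returns ``P_pol``: (N, S, S) and ``R_pol``: (N, S).
    """
    N, _, S, _ = P.shape
    n_idx = np.arange(N)[:, None]
    s_idx = np.arange(S)[None, :]
    P_pol = P[n_idx, policy, s_idx, :]
    R_pol = R[s_idx, policy]
    return P_pol, R_pol


def _policy_iteration_batch(
    P: np.ndarray, R: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Policy iteration run in lockstep over a batch of MDPs.

    ``P``: (N, A, S, S) row-stochastic, ``R``: (S, A). Returns optimal
    policies (N, S) and their value functions (N, S). Greedy improvement
    breaks ties towards the lowest action index.
    """
    N, A, S, _ = P.shape
    policy = np.argmax(np.broadcast_to(R.T[None], (N, A, S)), axis=1)
    for _ in range(_MAX_PI_ITERATIONS):
        P_pol, R_pol = _select_policy(P, R, policy)
        V = _evaluate_batch(P_pol, R_pol, gamma)
        Q = R.T[None, :, :] + gamma * np.einsum("nast,nt->nas", P, V)
        # argmax is stable: the first (lowest-index) maximiser wins
        new_policy = np.argmax(Q, axis=1)
        # keep the incumbent action unless it is strictly beaten, so the
        # iteration cannot cycle between equally valued policies
        incumbent_q = np.take_along_axis(Q, policy[:, None, :], axis=1)[:, 0, :]
        best_q = np.take_along_axis(Q, new_policy[:, None, :], axis=1)[:, 0, :]
        tol = 1e-9 * (1.0 + np.abs(best_q))  # ties at value scale
        keep = best_q <= incumbent_q + tol
        candidate = np.where(keep, policy, new_policy)
        if np.array_equal(candidate, policy):
            # converged; do one final pass replacing the incumbent with the
            # lowest-index action among near-exact ties for determinism
            tied = Q >= (best_q[:, None, :] - tol[:, None, :])
            final = np.argmax(tied, axis=1)
            P_pol, R_pol = _select_policy(P, R, final)
            return final, _evaluate_batch(P_pol, R_pol, gamma)
        policy = candidate
    raise RuntimeError("policy iteration failed to converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _check_stochastic(P: np.ndarray) -> None:
    if np.any(P < -1e-12) or np.max(np.abs(P.sum(axis=-1) - 1.0)) > 1e-9:
        raise ValueError("transition matrices must be row-stochastic")


def policy_iteration(
    P: np.ndarray, R: np.ndarray, gamma: float, label: str = "optimal"
) -> tuple[Strategy, ValueFunction]:
    """Exact optimal strategy for one MDP.

    Parameters
    ----------
    P
        (A, S, S) row-stochastic transition tensor for a single structure.
    R
        (S, A) reward matrix.
    gamma
        Discount factor in (0, 1).
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    _check_stochastic(P)
    pol, val = _policy_iteration_batch(P[None], R, gamma)
    return Strategy.from_array(pol[0], label=label), ValueFunction.from_array(val[0])


def evaluate_strategy(
    strategy: Strategy, P: np.ndarray, R: np.ndarray, gamma: float
) -> ValueFunction:
    """Exact value of a fixed strategy on one structure's MDP.

    Solves the policy-evaluation system ``(I - gamma P_delta) V = R_delta``.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    _check_stochastic(P)
    policy = np.asarray(strategy.actions)[None, :]
    P_pol, R_pol = _select_policy(P[None], R, policy)
    return ValueFunction.from_array(_evaluate_batch(P_pol, R_pol, gamma)[0])


def optimal_informed_strategies(
    family: MDPFamily, gamma: float | None = None
) -> list[tuple[Strategy, ValueFunction]]:
    """Optimal strategy and value per candidate feedback structure.

    Returns one ``(Strategy, ValueFunction)`` pair per structure, index-aligned
    with ``structure_id``. These are the "informed" optima: what the manager
    would do after learning that the corresponding structure is the true one.
    """
    g = family.config.gamma if gamma is None else gamma
    pols, vals = _policy_iteration_batch(family.P, family.R, g)
    return [
        (
            Strategy.from_array(pols[f], label=f"informed f={f}"),
            ValueFunction.from_array(vals[f]),
        )
        for f in range(family.n_structures)
    ]
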
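"""Food-web motif topologies and candidate feedback structures.

A motif is a small directed food web over ``J`` species. Species are indexed
1..J bottom-to-top by trophic position: species 1 is basal, species J is the
top predator, and every feeding edge ``(prey, predator)`` points upward
(``prey < predator``), so the web is acyclic. One species -- the *provider* --
generates the ecosystem function; the set of species that benefit from that
function (the *feedback structure*) is unknown to the manager, and enumerating
all ``2**J`` candidate subsets is the source of structural uncertainty in the
downstream value-of-information analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MOTIF_EDGE_SETS",
    "FoodWeb",
    "FeedbackStructure",
    "build_motif",
    "enumerate_feedback_structures",
    "neighbourhood_counts",
]

#: Canonical four-species edge sets, 1-based (prey, predator) pairs.
#: linear: a food chain. apparent_competition: two basal prey share consumer 3.
#: omnivory: chain plus the top predator also eating species 2.
#: intraguild_competition: consumers 2 and 3 share resource 1, and 3 preys on 2.
MOTIF_EDGE_SETS: dict[str, frozenset[tuple[int, int]]] = {
    "linear": frozenset({(1, 2), (2, 3), (3, 4)}),
    "apparent_competition": frozenset({(1, 3), (2, 3), (3, 4)}),
    "omnivory": frozenset({(1, 2), (2, 3), (3, 4), (2, 4)}),
    "intraguild_competition": frozenset({(1, 2), (1, 3), (2, 3), (3, 4)}),
}

#: Table ordering of the motif feature (used as the ordinal code in sweeps).
MOTIF_ORDER = ("linear", "apparent_competition", "omnivory", "intraguild_competition")


@dataclass(frozen=True)
class FoodWeb:
    """A validated directed prey->predator web plus the function provider.

    Parameters
    ----------
    n_species
        Number of species ``J``.
    edges
        Ordered pairs ``(prey, predator)`` of 1-based indices with
        ``prey < predator`` (canonical bottom-to-top trophic ordering).
    provider
        1-based index of the species providing the ecosystem function.
    motif_name
        Label, one of the four named motifs or ``"custom"``.
    """

    n_species: int
    edges: frozenset[tuple[int, int]] = field()
    provider: int = 1
    motif_name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 1 <= self.provider <= self.n_species:
            raise ValueError(
                f"provider {self.provider} out of range 1..{self.n_species}"
            )
        for i, k in self.edges:
            if i == k:
                raise ValueError(f"self-edge ({i},{k}) not allowed")
            if not (1 <= i <= self.n_species and 1 <= k <= self.n_species):
                raise ValueError(f"edge ({i},{k}) out of range 1..{self.n_species}")
            if i > k:
                raise ValueError(
                    f"edge ({i},{k}) violates the bottom-to-top ordering "
                    "(prey index must be below predator index); the web must "
                    "be acyclic under the canonical ordering"
                )
        if self.n_species > 1 and not self._connected():
            raise ValueError("food web must be connected (as an undirected graph)")

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {j: set() for j in range(1, self.n_species + 1)}
        for i, k in self.edges:
            adj[i].add(k)
            adj[k].add(i)
        seen = {1}
        stack = [1]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_species

    def prey_of(self, species: int) -> tuple[int, ...]:
        """Prey of ``species`` (1-based), ascending."""
        return tuple(sorted(i for i, k in self.edges if k == species))

    def predators_of(self, species: int) -> tuple[int, ...]:
        """Predators of ``species`` (1-based), ascending."""
        return tuple(sorted(k for i, k in self.edges if i == species))

    def adjacency(self) -> np.ndarray:
        """0/1 matrix ``M[i, k] = 1`` iff species i+1 is eaten by species k+1."""
        M = np.zeros((self.n_species, self.n_species), dtype=np.int8)
        for i, k in self.edges:
            M[i - 1, k - 1] = 1
        return M


@dataclass(frozen=True)
class FeedbackStructure:
    """A candidate set ``f`` of species benefiting from the ecosystem function.

    ``structure_id`` is the bitmask with bit ``j-1`` set iff species ``j`` is
    a member; it round-trips with ``members``.
    """

    members: frozenset[int]
    structure_id: int

    @classmethod
    def from_members(cls, members: Iterable[int]) -> "FeedbackStructure":
        ms = frozenset(members)
        sid = sum(1 << (j - 1) for j in ms)
        return cls(members=ms, structure_id=sid)

    @classmethod
    def from_id(cls, structure_id: int, n_species: int) -> "FeedbackStructure":
        members = frozenset(
            j for j in range(1, n_species + 1) if structure_id >> (j - 1) & 1
        )
        return cls(members=members, structure_id=structure_id)

    def __contains__(self, species: int) -> bool:
        return species in self.members

    def member_mask(self, n_species: int) -> np.ndarray:
        """Boolean vector of length J, True where the species is a member."""
        return np.array(
            [j in self.members for j in range(1, n_species + 1)], dtype=bool
        )


def build_motif(
    motif_name: str,
    provider: int,
    *,
    edges: Sequence[tuple[int, int]] | None = None,
    n_species: int = 4,
) -> FoodWeb:
    """Build a validated :class:`FoodWeb` for a named motif or a custom web.

    Parameters
    ----------
    motif_name
        ``linear``, ``apparent_competition``, ``omnivory``,
        ``intraguild_competition``, or ``custom`` (then ``edges`` is required).
    provider
        1-based index of the function-providing species; its value is the
        "trophic level of the function" feature (1 = basal, J = top predator).
    edges
        Explicit edge list for ``custom`` webs.
    n_species
        Species count for custom webs; named motifs are always 4 species.
    """
    if motif_name == "custom":
        if edges is None:
            raise ValueError("custom motif requires an explicit edge set")
        return FoodWeb(
            n_species=n_species,
            edges=frozenset((int(i), int(k)) for i, k in edges),
            provider=provider,
            motif_name="custom",
        )
    try:
        edge_set = MOTIF_EDGE_SETS[motif_name]
    except KeyError:
        raise ValueError(
            f"unknown motif {motif_name!r}; expected one of "
            f"{sorted(MOTIF_EDGE_SETS)} or 'custom'"
        ) from None
    if edges is not None:
        raise ValueError("edges may only be supplied with motif_name='custom'")
    return FoodWeb(n_species=4, edges=edge_set, provider=provider, motif_name=motif_name)


def enumerate_feedback_structures(n_species: int) -> list[FeedbackStructure]:
    """All ``2**n_species`` feedback structures in ascending ``structure_id``.

    The empty set (no species benefits from the function) is structure 0 and is
    a legitimate candidate: the function may feed the service only.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return [
        FeedbackStructure.from_id(sid, n_species) for sid in range(2**n_species)
    ]


def neighbourhood_counts(
    web: FoodWeb, state: Sequence[int] | np.ndarray, species: int
) -> tuple[int, int, int, int]:
    """Extant prey/predator counts of ``species`` plus their all-extant maxima.

    Returns ``(n_prey_extant, n_predators_extant, n_prey_max, n_predators_max)``
    where the maxima are the counts at the all-extant state, the reference
    point at which each neighbourhood term of the survival model equals 1.
    """
    if not 1 <= species <= web.n_species:
        raise IndexError(f"species {species} out of range 1..{web.n_species}")
    x = np.asarray(state)
    if x.shape != (web.n_species,):
        raise ValueError(f"state must have length {web.n_species}")
    prey = web.prey_of(species)
    preds = web.predators_of(species)
    n_prey = int(sum(x[p - 1] for p in prey))
    n_pred = int(sum(x[p - 1] for p in preds))
    return n_prey, n_pred, len(prey), len(preds)
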
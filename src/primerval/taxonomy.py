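"""Rank-aware lineage queries for the resolution and specificity metrics.

A lineage is a fixed-order map from canonical rank (phylum > class > order >
family > genus > species) to taxon name. Taxon identity is exact name
equality within a rank; there is no synonym resolution and no taxid graph.
Ranks a record was never annotated at are reported with the explicit
:data:`UNANNOTATED` marker, never an empty string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

CANONICAL_RANKS: tuple[str, ...] = (
    "phylum", "class", "order", "family", "genus", "species",
)

_RANK_INDEX = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}

# Verdicts of same_taxon_at.
AGREE = "agree"
DISAGREE = "disagree"
INCOMPLETE = "incomplete"


class _Unannotated:
    """Singleton marker for a rank with no annotation."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNANNOTATED"

    def __bool__(self) -> bool:
        return False


UNANNOTATED = _Unannotated()


@dataclass(frozen=True)
class Lineage:
    """Ordered rank -> taxon-name map over the canonical ranks."""

    ranks: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.ranks) - set(CANONICAL_RANKS)
        if unknown:
            raise ValueError(f"unknown rank name(s): {sorted(unknown)}")
        for rank, name in self.ranks.items():
            if not name:
                raise ValueError(
                    f"empty taxon name at rank {rank!r}; omit the rank instead"
                )
        # freeze as a plain dict in canonical order
        ordered = {r: self.ranks[r] for r in CANONICAL_RANKS if r in self.ranks}
        object.__setattr__(self, "ranks", ordered)

    def is_prefix_complete(self, from_rank: str = "family") -> bool:
        """True if every annotated rank below ``from_rank`` has all ranks
        between ``from_rank`` and itself annotated too (species implies genus
        and family, genus implies family)."""
        start = _RANK_INDEX[from_rank]
        annotated = [r in self.ranks for r in CANONICAL_RANKS[start:]]
        # once a gap appears, nothing deeper may be annotated
        seen_gap = False
        for present in annotated:
            if seen_gap and present:
                return False
            seen_gap = seen_gap or not present
        return True

    def __hash__(self):
        return hash(tuple(self.ranks.items()))


def taxon_at(lineage: Lineage, rank: str):
    """Taxon name of ``lineage`` at ``rank``, or :data:`UNANNOTATED`.

    Raises ValueError for a non-canonical rank name.
    """
    if rank not in _RANK_INDEX:
        raise ValueError(
            f"unknown rank {rank!r}; canonical ranks are {CANONICAL_RANKS}"
        )
    return lineage.ranks.get(rank, UNANNOTATED)


def same_taxon_at(lineages: Iterable[Lineage], rank: str) -> str:
    """Classify a set of lineages at one rank.

    Returns :data:`AGREE` when every lineage is annotated at ``rank`` and all
    names are equal, :data:`INCOMPLETE` when at least one lineage lacks the
    rank, and :data:`DISAGREE` otherwise.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("same_taxon_at requires at least one lineage")
    names = [taxon_at(lin, rank) for lin in lineages]
    if any(name is UNANNOTATED for name in names):
        return INCOMPLETE
    return AGREE if len(set(names)) == 1 else DISAGREE
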
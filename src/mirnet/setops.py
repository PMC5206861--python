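"""Set algebra over differential-miRNA profiles.

Venn-region decomposition of named miRNA sets, exclusivity selection
(members of one set combination attributable to no other), and detection of
inverse regulation — miRNAs called in opposite directions in an injury
comparison versus a treatment comparison, the signature of a treatment that
reverses an injury-induced change.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .qpcr import ComparisonProfile

__all__ = ["VennResult", "InverseSet", "venn", "exclusive_set",
           "inverse_regulated"]


@dataclass(frozen=True)
class VennResult:
    """Exact region decomposition of 2-5 named sets.

    ``regions`` maps each non-empty combination of set names (a tuple in
    input order) to the sorted members belonging to exactly those sets.
    Regions are pairwise disjoint and their union is the union of inputs.
    """

    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], list[str]]

    def region(self, *names: str) -> list[str]:
        key = tuple(n for n in self.set_names if n in set(names))
        if len(key) != len(names):
            raise KeyError(f"unknown set name(s) in {names}")
        return list(self.regions.get(key, []))

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "regions": {"&".join(k): v for k, v in self.regions.items()},
            "counts": {"&".join(k): len(v) for k, v in self.regions.items()},
        }


@dataclass(frozen=True)
class InverseSet:
    """miRNAs called in both profiles with flipped direction."""

    profile_a: str
    profile_b: str
    members: dict[str, tuple[str, str]]  # id -> (direction in A, direction in B)

    @property
    def ids(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "profile_a": self.profile_a,
            "profile_b": self.profile_b,
            "members": {m: {"direction_a": a, "direction_b": b}
                        for m, (a, b) in sorted(self.members.items())},
        }


def venn(
    sets: Mapping[str, Iterable[str]]
    | Iterable[tuple[str, Iterable[str]]],
) -> VennResult:
    """Decompose 2-5 named sets into their exclusive Venn regions.

    Accepts a mapping name -> members or an iterable of (name, members)
    pairs; duplicate names are an error.  Every element of the union is
    assigned to exactly one region — the combination of sets it belongs
    to — so region sizes sum to the size of the union.  Members are sorted
    lexicographically.
    """
    pairs = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    names = tuple(n for n, _ in pairs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    if not 2 <= len(names) <= 5:
        raise ValueError(f"venn needs 2-5 sets, got {len(names)}")
    as_sets = {n: set(members) for n, members in pairs}
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(set(), *(as_sets[n] for n in names
                                         if n not in combo))
            members = sorted(inside - outside)
            if members:
                regions[combo] = members
    return VennResult(set_names=names, regions=regions)


def exclusive_set(
    target: Iterable[str],
    others: Mapping[str, Iterable[str]] | Iterable[Iterable[str]],
) -> list[str]:
    """Members of ``target`` appearing in none of the excluded sets.

    An empty target yields an empty result.  Adding excluded sets can only
    shrink the output (anti-monotone).
    """
    if isinstance(others, Mapping):
        excluded = [set(v) for v in others.values()]
    else:
        excluded = [set(v) for v in others]
    union = set().union(*excluded) if excluded else set()
    return sorted(set(target) - union)


def inverse_regulated(
    profile_a: ComparisonProfile,
    profile_b: ComparisonProfile,
) -> InverseSet:
    """miRNAs called in both comparisons with opposite directions.

    A miRNA qualifies only when it is called (up or down) in BOTH profiles
    and the directions differ; same-direction calls and miRNAs called in a
    single profile are excluded.  Symmetric in its arguments as a set of
    ids.  An empty result is valid.
    """
    dir_a = profile_a.directions()
    dir_b = profile_b.directions()
    members = {
        m: (dir_a[m], dir_b[m])
        for m in set(dir_a) & set(dir_b)
        if dir_a[m] != dir_b[m]
    }
    return InverseSet(profile_a=profile_a.comparison_id,
                      profile_b=profile_b.comparison_id,
                      members=members)
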
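"""Interaction-type suggestion by neighborhood type frequency.

For a predicted pair (i, j), the candidate interaction types are those of all
training edges incident to i or j (the pair's "neighborhood types"), ranked
by how often each type occurs there.  The premise: a new interaction tends to
be of a kind its drugs are already known for.  Evaluation records the rank of
the type eventually reported for the pair, and the cumulative distribution of
that rank over the evaluated pairs (top-1/top-3/top-5 fractions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .network import DDINetwork, canonical_pair

__all__ = [
    "TypeRanking",
    "neighborhood_type_ranking",
    "true_type_rank",
    "rank_cdf",
]


@dataclass
class TypeRanking:
    """Neighborhood types of one pair, most frequent first."""

    pair: tuple[str, str]
    ranked_types: list[str]
    counts: dict[str, int]


def neighborhood_type_ranking(net: DDINetwork, i: str, j: str) -> TypeRanking:
    """Count type labels over all edges incident to i or j.

    The focal edge (i, j) itself, if present, is excluded.  Types are sorted
    by descending count, ties broken lexicographically by label; an isolated
    pair yields an empty ranking.
    """
    pair = canonical_pair(i, j)
    for d in (i, j):
        if d not in net.drugs:
            raise KeyError(f"unknown drug: {d!r}")
    counts: Counter[str] = Counter()
    for (a, b), inter in net.edges.items():
        if (a, b) == pair:
            continue
        if a in (i, j) or b in (i, j):
            counts[inter.type_label] += 1
    ranked = sorted(counts, key=lambda t: (-counts[t], t))
    return TypeRanking(pair=pair, ranked_types=ranked, counts=dict(counts))


def true_type_rank(ranking: TypeRanking, true_type: str) -> int | None:
    """Competition rank ("1224") of the true type, or None when absent.

    Types tied in frequency share the rank of the first of their tie group in
    the lexicographically-broken order, i.e. the number of strictly more
    frequent types plus one.
    """
    if true_type not in ranking.counts:
        return None
    c = ranking.counts[true_type]
    return 1 + sum(1 for v in ranking.counts.values() if v > c)


def rank_cdf(ranks: Iterable[int], at: Sequence[int] = (1, 3, 5)) -> dict[int, float]:
    """Cumulative distribution of true-type ranks at the requested cutoffs.

    ``cdf[r]`` is the fraction of evaluated pairs whose true type ranked at
    or above r; absent-type outcomes must be excluded by the caller (they are
    reported separately).
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("rank multiset is empty")
    if any(r < 1 for r in ranks):
        raise ValueError("ranks are 1-based")
    n = len(ranks)
    return {r: sum(1 for v in ranks if v <= r) / n for r in at}
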
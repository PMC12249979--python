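"""Adjacency features of signed circular gene orders.

A mitogenome's gene order is a signed circular arrangement of feature
tokens. The unit of comparison is the oriented neighbour pair: an adjacency
X -> Y matches a genome if Y immediately follows X with the stated relative
strands, or if the mirror reading on the opposite strand does, so a key and
its reverse-complement reading are the same feature. A circle of n tokens
yields exactly n adjacency keys, invariant under rotation and full
reverse-complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_core import GeneOrder, ReferenceDB

__all__ = [
    "AdjacencyKey",
    "AdjacencyFeature",
    "FrequencyResult",
    "canonical_key",
    "adjacencies",
    "has_adjacency",
    "adjacency_frequency",
    "random_adjacency_bound",
    "random_signed_order",
]

# an adjacency key: ((token, sign), (token, sign)), canonicalized
AdjacencyKey = tuple[tuple[str, int], tuple[str, int]]


def canonical_key(up: tuple[str, int], down: tuple[str, int]) -> AdjacencyKey:
    """Canonical form of an oriented adjacency: min of reading and its
    reverse-complement ((b, -sb), (a, -sa))."""
    fwd: AdjacencyKey = (up, down)
    rc: AdjacencyKey = ((down[0], -down[1]), (up[0], -up[1]))
    return min(fwd, rc)


def adjacencies(order: GeneOrder, *, restrict_to: Optional[Iterable[str]] = None) -> set[AdjacencyKey]:
    """All canonical adjacency keys of a circular order.

    ``restrict_to`` drops other tokens first (e.g. PCG-only analysis
    ignoring tRNA genes); adjacency is then immediate neighbourhood among
    the retained tokens.
    """
    pairs = order.signed_tokens()
    if restrict_to is not None:
        keep = set(restrict_to)
        pairs = [(t, s) for t, s in pairs if t in keep]
    n = len(pairs)
    if n < 2:
        return set()
    return {canonical_key(pairs[i], pairs[(i + 1) % n]) for i in range(n)}


def has_adjacency(
    order: GeneOrder,
    upstream: str,
    downstream: str,
    *,
    upstream_sign: int = 1,
    downstream_sign: int = 1,
    restrict_to: Optional[Iterable[str]] = None,
) -> bool:
    key = canonical_key((upstream, upstream_sign), (downstream, downstream_sign))
    return key in adjacencies(order, restrict_to=restrict_to)


@dataclass
class FrequencyResult:
    """Carrier count over an explicit denominator; fraction is None when no
    species has data (an empty denominator is reported, never silently 0)."""

    count: int
    denominator: int

    @property
    def fraction(self) -> Optional[float]:
        return None if self.denominator == 0 else self.count / self.denominator

    @property
    def has_data(self) -> bool:
        return self.denominator > 0


@dataclass
class AdjacencyFeature:
    """An oriented neighbour pair with its inside/outside-group frequencies."""

    upstream: str
    downstream: str
    upstream_sign: int = 1
    downstream_sign: int = 1
    freq_inside: Optional[FrequencyResult] = None
    freq_outside: Optional[FrequencyResult] = None

    @property
    def key(self) -> AdjacencyKey:
        return canonical_key(
            (self.upstream, self.upstream_sign), (self.downstream, self.downstream_sign)
        )


def adjacency_frequency(
    db: ReferenceDB,
    feature_key: AdjacencyKey,
    exclude_groups: Sequence[set[str]] = (),
    *,
    restrict_to: Optional[Iterable[str]] = None,
) -> FrequencyResult:
    """Carrier count and fraction of an adjacency among database species.

    Species in any excluded group, and species without gene-order data, are
    left out of the denominator. Output is independent of record order.
    """
    excluded: set[str] = set()
    for g in exclude_groups:
        excluded |= set(g)
    count = 0
    denom = 0
    for sp, order in db.orders.items():
        if sp in excluded:
            continue
        denom += 1
        if feature_key in adjacencies(order, restrict_to=restrict_to):
            count += 1
    return FrequencyResult(count=count, denominator=denom)


def random_adjacency_bound(n_features: int) -> float:
    """Closed-form chance that a random signed circular order of n features
    places one designated feature immediately after another in a required
    orientation: 1/2 x 1/n.

    This is the conventional back-of-envelope bound (orientation factor 1/2
    times a uniform choice among n features); the exact probability for an
    n-token circle is 1/(2(n-1)), which the bound approaches from below.
    """
    if n_features < 2:
        raise ValueError("need at least two features on the circle")
    return 0.5 / n_features


def random_signed_order(tokens: Sequence[str], rng: np.random.Generator) -> GeneOrder:
    """Uniform random signed circular order over the given tokens."""
    perm = rng.permutation(len(tokens))
    signs = rng.integers(0, 2, size=len(tokens)) * 2 - 1
    return GeneOrder(
        species="random",
        tokens=tuple(tokens[i] for i in perm),
        signs=tuple(int(s) for s in signs),
    )
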
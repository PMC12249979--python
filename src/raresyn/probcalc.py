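"""Emergence and loss probabilities for sets of rare characters.

The number of synapomorphies that arise independently (by homoplasy) in an
unrelated lineage is modelled as a Poisson-binomial count: feature *i*
emerges with its database homoplasy frequency ``h_i``, independently of the
others unless an explicit dependency is supplied. Retention of a feature by
a lineage evolving ``r``-fold faster than its group follows the rate-scaled
model ``a_i = s_i ** r`` where ``s_i`` is the feature's within-group
frequency; the loss probability of a feature subset is the product of the
per-feature ``b_i = 1 - a_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_core import Phylogeny

__all__ = [
    "HomoplasyVector",
    "EmergenceResult",
    "StabilityVector",
    "LossResult",
    "DependencyAdjustment",
    "poisson_binomial",
    "emergence_with_dependencies",
    "loss_probability",
    "rate_ratio",
    "expected_homoplasy_count",
    "combine_independent",
]


@dataclass(frozen=True)
class HomoplasyVector:
    """Per-feature outside-group (homoplasy) frequencies h; w = 1 - h."""

    h: tuple[float, ...]

    def __post_init__(self):
        if len(self.h) < 1:
            raise ValueError("need at least one homoplasy frequency")
        if any(not 0.0 <= x <= 1.0 for x in self.h):
            raise ValueError("homoplasy frequencies must lie in [0, 1]")

    @property
    def w(self) -> tuple[float, ...]:
        return tuple(1.0 - x for x in self.h)

    def __len__(self) -> int:
        return len(self.h)


@dataclass
class EmergenceResult:
    """Poisson-binomial emergence probabilities for n features.

    q[k] is the probability that exactly k features emerge independently;
    x[k] = sum_{j>=k} q[j] is the tail; avg[k] = q[k] / C(n, k) is the mean,
    over all k-subsets, of the probability that exactly that subset emerges.
    """

    q: np.ndarray
    x: np.ndarray
    avg: np.ndarray
    dependencies_applied: bool = False

    def __post_init__(self):
        if abs(float(self.q.sum()) - 1.0) > 1e-9:
            raise ValueError("q must sum to 1")

    @property
    def n(self) -> int:
        return len(self.q) - 1

    def tail(self, k: int) -> float:
        return float(self.x[k])


@dataclass(frozen=True)
class StabilityVector:
    """Per-feature within-group retention frequencies s."""

    s: tuple[float, ...]

    def __post_init__(self):
        if len(self.s) < 1:
            raise ValueError("need at least one stability frequency")
        if any(not 0.0 < x <= 1.0 for x in self.s):
            raise ValueError("stability frequencies must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class LossResult:
    """Rate-adjusted retention (a_i = s_i^r) and loss (b_i) probabilities."""

    r: float
    a: np.ndarray
    b: np.ndarray
    lost_subset: tuple[int, ...]
    p: float


@dataclass(frozen=True)
class DependencyPair:
    """Feature j's emergence is conditioned on feature i's.

    ``p_given`` is P(j emerges | i emerged). ``p_given_not`` is
    P(j emerges | i did not emerge); when omitted it is chosen to preserve
    j's marginal frequency: (h_j - p_given * h_i) / (1 - h_i).
    """

    i: int
    j: int
    p_given: float
    p_given_not: Optional[float] = None

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a feature cannot condition on itself")
        if not 0.0 <= self.p_given <= 1.0:
            raise ValueError("conditional probability must lie in [0, 1]")
        if self.p_given_not is not None and not 0.0 <= self.p_given_not <= 1.0:
            raise ValueError("conditional probability must lie in [0, 1]")


@dataclass
class DependencyAdjustment:
    """A set of pairwise emergence dependencies forming a forest.

    Every feature may be conditioned on at most one other feature and
    cycles are rejected, so the joint law over the involved features is a
    well-defined Bayesian-network factorization.
    """

    pairs: list[DependencyPair] = field(default_factory=list)

    def validate(self, n: int) -> None:
        parent: dict[int, int] = {}
        for p in self.pairs:
            for idx in (p.i, p.j):
                if not 0 <= idx < n:
                    raise ValueError(f"feature index {idx} out of range [0, {n})")
            if p.j in parent:
                raise ValueError(f"feature {p.j} is conditioned on more than one feature")
            parent[p.j] = p.i
        # cycle check by walking parent pointers
        for start in parent:
            seen = {start}
            cur = start
            while cur in parent:
                cur = parent[cur]
                if cur in seen:
                    raise ValueError("cyclic dependency among features")
                seen.add(cur)


# ---------------------------------------------------------------------------


def poisson_binomial(h: HomoplasyVector | Sequence[float]) -> EmergenceResult:
    """Exact Poisson-binomial distribution of the emergence count.

    Dynamic-programming convolution: after feature i, q holds the exact
    distribution of the count among the first i features.
    """
    if not isinstance(h, HomoplasyVector):
        h = HomoplasyVector(tuple(float(x) for x in h))
    n = len(h)
    q = np.zeros(n + 1)
    q[0] = 1.0
    for i, hi in enumerate(h.h):
        # shift-and-add; slicing keeps it O(n^2) overall
        q[1 : i + 2] = q[1 : i + 2] * (1.0 - hi) + q[: i + 1] * hi
        q[0] *= 1.0 - hi
    return _finish(q, dependencies_applied=False)


def _finish(q: np.ndarray, dependencies_applied: bool) -> EmergenceResult:
    n = len(q) - 1
    x = np.cumsum(q[::-1])[::-1]
    binom = np.array([math.comb(n, k) for k in range(n + 1)], dtype=float)
    avg = q / binom
    return EmergenceResult(q=q, x=x, avg=avg, dependencies_applied=dependencies_applied)


def emergence_with_dependencies(
    h: HomoplasyVector | Sequence[float],
    adjustments: Optional[DependencyAdjustment] = None,
) -> EmergenceResult:
    """Emergence distribution with pairwise conditional probabilities.

    Features involved in dependency pairs are enumerated jointly (the
    product P(i)P(j) is replaced by P(i)P(j|i)); the remaining features are
    convolved independently. Reduces exactly to :func:`poisson_binomial`
    when no adjustments are given.
    """
    if not isinstance(h, HomoplasyVector):
        h = HomoplasyVector(tuple(float(x) for x in h))
    if adjustments is None or not adjustments.pairs:
        return poisson_binomial(h)
    n = len(h)
    adjustments.validate(n)

    involved = sorted({idx for p in adjustments.pairs for idx in (p.i, p.j)})
    pos = {idx: k for k, idx in enumerate(involved)}
    m = len(involved)
    parent: dict[int, DependencyPair] = {p.j: p for p in adjustments.pairs}

    def cond_prob(idx: int, state: dict[int, bool]) -> float:
        """P(feature idx emerges | states of already-assigned features)."""
        if idx not in parent:
            return h.h[idx]
        pair = parent[idx]
        hi, hj = h.h[pair.i], h.h[pair.j]
        if state[pair.i]:
            return pair.p_given
        if pair.p_given_not is not None:
            return pair.p_given_not
        if hi >= 1.0:
            return pair.p_given  # conditioning event is certain
        pn = (hj - pair.p_given * hi) / (1.0 - hi)
        if pn < -1e-12 or pn > 1.0 + 1e-12:
            raise ValueError(
                f"marginal-preserving P({pair.j}|not {pair.i}) = {pn:.4g} outside [0, 1]; "
                "supply p_given_not explicitly"
            )
        return min(max(pn, 0.0), 1.0)

    # enumerate joint states in topological order (parents before children)
    order: list[int] = []
    remaining = set(involved)
    while remaining:
        progressed = False
        for idx in sorted(remaining):
            par = parent.get(idx)
            if par is None or par.i not in remaining:
                order.append(idx)
                remaining.discard(idx)
                progressed = True
        if not progressed:  # pragma: no cover - cycle already rejected
            raise ValueError("cyclic dependency among features")

    q_dep = np.zeros(m + 1)
    for mask in range(1 << m):
        state: dict[int, bool] = {}
        prob = 1.0
        for idx in order:
            emerged = bool(mask >> pos[idx] & 1)
            p_emerge = cond_prob(idx, state)
            prob *= p_emerge if emerged else 1.0 - p_emerge
            state[idx] = emerged
        q_dep[bin(mask).count("1")] += prob

    rest = [h.h[i] for i in range(n) if i not in pos]
    if rest:
        q_rest = poisson_binomial(rest).q
        q = np.convolve(q_dep, q_rest)
    else:
        q = q_dep
    return _finish(q, dependencies_applied=True)


def loss_probability(
    s: StabilityVector | Sequence[float], r: float, lost_subset: Sequence[int]
) -> LossResult:
    """Probability that a fast lineage loses a specific feature subset.

    a_i = s_i^r is the probability of retaining feature i in a lineage
    evolving r-fold faster than the group average; the subset loss
    probability is the product of b_i = 1 - a_i over the lost features.
    """
    if not isinstance(s, StabilityVector):
        s = StabilityVector(tuple(float(x) for x in s))
    if r <= 0:
        raise ValueError("rate ratio r must be positive")
    M = tuple(int(i) for i in lost_subset)
    for i in M:
        if not 0 <= i < len(s):
            raise ValueError(f"lost-subset index {i} out of range")
    sa = np.asarray(s.s, dtype=float)
    a = np.exp(r * np.log(sa))
    b = -np.expm1(r * np.log(sa))  # 1 - s^r without cancellation
    if M:
        logp = float(np.sum(np.log(b[list(M)])))
        p = math.exp(logp) if logp > -745 else 0.0
    else:
        p = 1.0
    return LossResult(r=float(r), a=a, b=b, lost_subset=M, p=p)


def rate_ratio(
    tree: Phylogeny, group_leaves: Sequence[str], focal_leaves: Sequence[str]
) -> float:
    """Relative evolutionary rate of a focal clade against its group.

    The anchor is the MRCA of all listed leaves; the ratio is the mean
    anchor-to-tip path length of the focal leaves over that of the group
    leaves (focal leaves excluded from the group mean).
    """
    group = set(group_leaves)
    focal = set(focal_leaves)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = (group | focal) - labels
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)[:5]}")
    taxa = [tree.taxon_namespace.get_taxon(l) for l in sorted(group | focal)]
    anchor = tree.mrca(taxa=taxa)

    depths: dict[str, float] = {}
    stack = [(anchor, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf():
            depths[node.taxon.label] = d
        for child in node.child_nodes():
            stack.append((child, d + (child.edge.length or 0.0)))

    focal_mean = float(np.mean([depths[l] for l in focal]))
    group_only = [depths[l] for l in group - focal]
    if not group_only:
        raise ValueError("no group leaves outside the focal set")
    group_mean = float(np.mean(group_only))
    if group_mean == 0:
        raise ValueError("zero mean group depth; cannot form a rate ratio")
    return focal_mean / group_mean


def expected_homoplasy_count(tail_probability: float, n_db_species: int) -> float:
    """Expected number of database species reaching the tail event by chance."""
    if not 0.0 <= tail_probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if n_db_species < 0:
        raise ValueError("species count must be non-negative")
    return tail_probability * n_db_species


def combine_independent(probabilities: Sequence[float]) -> float:
    """Product of independent event probabilities (empty product = 1)."""
    out = 1.0
    for p in probabilities:
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        out *= p
    return out
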
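"""Ancestral state reconstruction and apomorphy attribution.

Two reconstruction modes on a fixed rooted tree:

* ``fitch`` -- two-pass parsimony state sets (generalized to polytomies by
  sequential intersection/union folding); gaps and ``X`` are wildcards.
* ``ml-marginal`` -- marginal posteriors at every node under an
  equal-exchangeability amino-acid model with empirical stationary
  frequencies (the 20-state analogue of F81, so transition probabilities
  have the closed form ``P(t) = e^{-bt} I + (1 - e^{-bt}) 1 pi^T``),
  optionally with discrete-gamma rate heterogeneity. Posteriors come from
  the standard pruning (up) messages combined with down messages; gaps and
  ``X`` contribute all-ones partial likelihoods.

A character is apomorphic for a clade when the state assigned at the clade
root differs from the state assigned at the next deeper node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_core import AA20, Alignment, Phylogeny

__all__ = [
    "NodeStateTable",
    "ApomorphyCall",
    "f81_transition_matrix",
    "empirical_frequencies",
    "discrete_gamma_rates",
    "reconstruct_states",
    "call_apomorphies",
]

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
_NSTATE = len(AA20)


def empirical_frequencies(alignment: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """Stationary frequencies estimated from the alignment (with pseudocount
    so no state has probability zero)."""
    counts = np.full(_NSTATE, pseudocount)
    for row in alignment.rows:
        for ch in row:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def f81_beta(freqs: np.ndarray) -> float:
    """Rate normalizer so that branch lengths are expected substitutions/site."""
    return 1.0 / (1.0 - float(np.sum(freqs**2)))


def f81_transition_matrix(t: float, freqs: np.ndarray, rate: float = 1.0) -> np.ndarray:
    """Closed-form transition matrix of the equal-exchangeability model."""
    e = np.exp(-f81_beta(freqs) * rate * t)
    return e * np.eye(_NSTATE) + (1.0 - e) * np.tile(freqs, (_NSTATE, 1))


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Median rates of ncat equal-probability gamma(alpha, 1/alpha) bins,
    renormalized to mean 1."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    quantiles = (2 * np.arange(ncat) + 1) / (2 * ncat)
    rates = stats.gamma.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


@dataclass
class NodeStateTable:
    """Per-node, per-column reconstruction results.

    ``mode`` is 'fitch' or 'ml'. ``node_index`` maps tree nodes to rows of
    the result arrays. Fitch mode fills ``state_sets`` (bool, nodes x
    columns x 20, the assigned sets after the top-down pass); ML mode fills
    ``posteriors`` (float, same shape, each node/column summing to 1).
    ``map_states`` holds the designated state index where unique, -1 where
    ambiguous.
    """

    mode: str
    gene_id: str
    node_index: dict
    state_sets: Optional[np.ndarray] = None
    posteriors: Optional[np.ndarray] = None
    map_states: Optional[np.ndarray] = None
    frequencies: Optional[np.ndarray] = None

    @property
    def n_columns(self) -> int:
        arr = self.state_sets if self.state_sets is not None else self.posteriors
        return arr.shape[1]

    def assigned_state(self, node, column: int) -> Optional[str]:
        """The single assigned state at a node/column, or None if ambiguous."""
        idx = self.map_states[self.node_index[node], column]
        return AA20[idx] if idx >= 0 else None

    def posterior(self, node, column: int) -> Optional[np.ndarray]:
        if self.posteriors is None:
            return None
        return self.posteriors[self.node_index[node], column]


@dataclass
class ApomorphyCall:
    """A column whose state is ancestral for a clade but not for the next
    deeper node."""

    gene_id: str
    column: int
    taxon: str
    derived: str
    ancestral: str
    mode: str
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.derived == self.ancestral:
            raise ValueError("derived state must differ from the deeper-node state")


# ---------------------------------------------------------------------------


def _leaf_partials(alignment: Alignment, labels: Sequence[str]) -> np.ndarray:
    """(len(labels), n_cols, 20) one-hot partials; X and '-' are all-ones."""
    out = np.ones((len(labels), alignment.length, _NSTATE))
    for i, lab in enumerate(labels):
        row = alignment.row(lab)
        for j, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                out[i, j, :] = 0.0
                out[i, j, idx] = 1.0
    return out


def _check_leaves(tree: Phylogeny, alignment: Alignment) -> list:
    leaves = list(tree.leaf_node_iter())
    missing = sorted(
        {l.taxon.label for l in leaves} - set(alignment.sequence_ids)
    )
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {', '.join(missing[:5])}")
    return leaves


def reconstruct_states(
    tree: Phylogeny,
    alignment: Alignment,
    mode: str = "ml-marginal",
    *,
    frequencies: Optional[np.ndarray] = None,
    gamma_alpha: Optional[float] = None,
    gamma_ncat: int = 4,
    tie_tol: float = 1e-9,
) -> NodeStateTable:
    """Reconstruct ancestral states for every node of the tree."""
    if mode not in ("fitch", "ml-marginal"):
        raise ValueError(f"unknown mode '{mode}'")
    _check_leaves(tree, alignment)
    if mode == "fitch":
        return _fitch(tree, alignment, tie_tol)
    return _ml_marginal(tree, alignment, frequencies, gamma_alpha, gamma_ncat, tie_tol)


def _fitch(tree: Phylogeny, alignment: Alignment, tie_tol: float) -> NodeStateTable:
    nodes = list(tree.preorder_node_iter())
    node_index = {nd: i for i, nd in enumerate(nodes)}
    ncol = alignment.length
    prelim = np.zeros((len(nodes), ncol, _NSTATE), dtype=bool)

    for nd in tree.postorder_node_iter():
        i = node_index[nd]
        if nd.is_leaf():
            row = alignment.row(nd.taxon.label)
            for j, ch in enumerate(row):
                idx = _AA_INDEX.get(ch)
                if idx is None:  # gap or X: wildcard
                    prelim[i, j, :] = True
                else:
                    prelim[i, j, idx] = True
        else:
            children = nd.child_nodes()
            cur = prelim[node_index[children[0]]].copy()
            for child in children[1:]:
                nxt = prelim[node_index[child]]
                inter = cur & nxt
                nonempty = inter.any(axis=1)
                cur = np.where(nonempty[:, None], inter, cur | nxt)
            prelim[i] = cur

    final = prelim.copy()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        i, pi = node_index[nd], node_index[nd.parent_node]
        inter = prelim[i] & final[pi]
        nonempty = inter.any(axis=1)
        final[i] = np.where(nonempty[:, None], inter, prelim[i])

    map_states = np.where(final.sum(axis=2) == 1, final.argmax(axis=2), -1)
    return NodeStateTable(
        mode="fitch",
        gene_id=alignment.gene_id,
        node_index=node_index,
        state_sets=final,
        map_states=map_states,
    )


def _ml_marginal(
    tree: Phylogeny,
    alignment: Alignment,
    frequencies: Optional[np.ndarray],
    gamma_alpha: Optional[float],
    gamma_ncat: int,
    tie_tol: float,
) -> NodeStateTable:
    pi = empirical_frequencies(alignment) if frequencies is None else np.asarray(frequencies, float)
    if pi.shape != (_NSTATE,) or abs(pi.sum() - 1.0) > 1e-6 or (pi <= 0).any():
        raise ValueError("frequencies must be a positive vector of length 20 summing to 1")
    beta = f81_beta(pi)
    rates = (
        discrete_gamma_rates(gamma_alpha, gamma_ncat) if gamma_alpha is not None else np.array([1.0])
    )
    weights = np.full(len(rates), 1.0 / len(rates))

    nodes = list(tree.preorder_node_iter())
    node_index = {nd: i for i, nd in enumerate(nodes)}
    ncol = alignment.length
    ncat = len(rates)

    # up pass (pruning): per category, per node: partials and per-column log scale
    up = np.zeros((ncat, len(nodes), ncol, _NSTATE))
    up_ls = np.zeros((ncat, len(nodes), ncol))
    # cached edge messages M_child @ up_child for reuse in the down pass
    msg: dict[tuple[int, int], np.ndarray] = {}

    leaf_cache: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        i = node_index[nd]
        if nd.is_leaf():
            part = _leaf_partials(alignment, [nd.taxon.label])[0]
            for c in range(ncat):
                up[c, i] = part
        else:
            for c in range(ncat):
                acc = np.ones((ncol, _NSTATE))
                ls = np.zeros(ncol)
                for child in nd.child_nodes():
                    ci = node_index[child]
                    t = child.edge.length or 0.0
                    e = np.exp(-beta * rates[c] * t)
                    # (M @ L)_i = e*L_i + (1-e) * (L . pi)
                    child_part = up[c, ci]
                    m = e * child_part + (1.0 - e) * (child_part @ pi)[:, None]
                    msg[(c, ci)] = m
                    acc = acc * m
                    ls = ls + up_ls[c, ci]
                scale = acc.max(axis=1)
                scale[scale == 0] = 1.0
                up[c, i] = acc / scale[:, None]
                up_ls[c, i] = ls + np.log(scale)

    # down pass
    down = np.zeros_like(up)
    down_ls = np.zeros_like(up_ls)
    root = tree.seed_node
    ri = node_index[root]
    for c in range(ncat):
        down[c, ri] = pi[None, :]
    for nd in tree.preorder_node_iter():
        i = node_index[nd]
        children = nd.child_nodes()
        for child in children:
            ci = node_index[child]
            t = child.edge.length or 0.0
            for c in range(ncat):
                S = down[c, i].copy()
                ls = down_ls[c, i].copy()
                for sib in children:
                    if sib is child:
                        continue
                    si = node_index[sib]
                    S = S * msg[(c, si)]
                    ls = ls + up_ls[c, si]
                e = np.exp(-beta * rates[c] * t)
                # sum_i S_i M_ij = e*S_j + (1-e)*pi_j*sum(S)
                D = e * S + (1.0 - e) * pi[None, :] * S.sum(axis=1)[:, None]
                scale = D.max(axis=1)
                scale[scale == 0] = 1.0
                down[c, ci] = D / scale[:, None]
                down_ls[c, ci] = ls + np.log(scale)

    # combine: posterior(v, s) proportional to sum_c w_c e^{ls_c} up_c(s) down_c(s)
    post = np.zeros((len(nodes), ncol, _NSTATE))
    A = up * down  # (ncat, nodes, ncol, 20)
    L = up_ls + down_ls
    lmax = L.max(axis=0, keepdims=True)
    weighted = weights[:, None, None, None] * np.exp(L - lmax)[..., None] * A
    num = weighted.sum(axis=0)
    post = num / num.sum(axis=2, keepdims=True)

    amax = post.argmax(axis=2)
    best = np.take_along_axis(post, amax[..., None], axis=2)[..., 0]
    # a tie (two states within tolerance of the max) is declared ambiguous
    tied = (post >= best[..., None] - tie_tol).sum(axis=2) > 1
    map_states = np.where(tied, -1, amax)

    return NodeStateTable(
        mode="ml",
        gene_id=alignment.gene_id,
        node_index=node_index,
        posteriors=post,
        map_states=map_states,
        frequencies=pi,
    )


# ---------------------------------------------------------------------------


def clade_root(tree: Phylogeny, clade_leaves: Sequence[str], name: str = ""):
    """MRCA of the clade leaves; raises if the clade is not monophyletic."""
    want = set(clade_leaves)
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = want - labels
    if missing:
        raise ValueError(f"clade '{name}': leaves not in tree: {sorted(missing)[:5]}")
    taxa = [tree.taxon_namespace.get_taxon(l) for l in sorted(want)]
    mrca = tree.mrca(taxa=taxa)
    got = {l.taxon.label for l in mrca.leaf_iter()}
    intruders = got - want
    if intruders:
        raise ValueError(
            f"clade '{name}' is not monophyletic; intruding leaves: {sorted(intruders)[:5]}"
        )
    return mrca


def call_apomorphies(
    states: NodeStateTable,
    tree: Phylogeny,
    taxon_name: str,
    clade_leaves: Sequence[str],
    *,
    p_min: float = 0.5,
) -> list[ApomorphyCall]:
    """Columns whose assigned state at the clade root differs from the next
    deeper node's.

    Fitch mode: an ambiguous (multi-state) set at either node yields no
    call. ML mode: the clade-root MAP posterior must reach ``p_min`` and
    both MAP states must be unique.
    """
    mrca = clade_root(tree, clade_leaves, taxon_name)
    if mrca.parent_node is None:
        raise ValueError(f"clade '{taxon_name}' spans the whole tree; no deeper node exists")
    parent = mrca.parent_node
    mi, pi_ = states.node_index[mrca], states.node_index[parent]

    calls: list[ApomorphyCall] = []
    for col in range(states.n_columns):
        a = states.map_states[mi, col]
        b = states.map_states[pi_, col]
        if a < 0 or b < 0 or a == b:
            continue
        confidence = None
        if states.mode == "ml":
            confidence = float(states.posteriors[mi, col, a])
            if confidence < p_min:
                continue
        calls.append(
            ApomorphyCall(
                gene_id=states.gene_id,
                column=col,
                taxon=taxon_name,
                derived=AA20[a],
                ancestral=AA20[b],
                mode=states.mode,
                confidence=confidence,
            )
        )
    return calls
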
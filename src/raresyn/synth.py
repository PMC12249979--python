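"""Synthetic mitogenome database generator.

Emulates the statistical structure the screening pipeline assumes in a
RefSeq-like reference: a focal group clade (an Annelida-like taxon) whose
members carry planted derived residues with within-group retention
``s_true``; a large outgroup pool showing the same residues only at the
homoplasy frequency ``h_true``; a small fast-evolving query clade (an
Orthonectida-like taxon) nested inside the group with all branch lengths
scaled by ``r_true`` and optionally AT-biased amino-acid composition; and
signed circular gene orders of 37 mitochondrial features evolving by random
inversions/transpositions, with one planted adjacency locked within the
group clade.

All randomness flows from the single config seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .ancestry import f81_beta
from .geneorder import canonical_key, adjacencies
from .io_core import AA20, Alignment, GeneOrder, GroupDefinition, Phylogeny, ReferenceDB

__all__ = [
    "PlantedFeature",
    "SimConfig",
    "SimulatedData",
    "MT_GENE_TOKENS",
    "default_planted_features",
    "simulate_tree",
    "simulate_alignment",
    "simulate_alignments",
    "simulate_gene_orders",
    "build_reference_db",
    "simulate_dataset",
]

# 13 protein-coding genes + 22 tRNAs + 2 rRNAs; the control region is an
# optional 38th token appended when configured.
_PCG = (
    "cox1", "cox2", "cox3", "cytb", "nad1", "nad2", "nad3", "nad4",
    "nad4l", "nad5", "nad6", "atp6", "atp8",
)
_TRNA = tuple(
    "trn" + a
    for a in ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
              "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
_RRNA = ("rrnS", "rrnL")
MT_GENE_TOKENS: tuple[str, ...] = _PCG + _TRNA + _RRNA

# plausible invertebrate mitochondrial protein composition (AA20 order);
# strongly hydrophobic and AT-leaning, as mitochondrial membrane proteins are
_MITO_FREQS = {
    "A": 0.050, "C": 0.012, "D": 0.020, "E": 0.022, "F": 0.085, "G": 0.055,
    "H": 0.020, "I": 0.075, "K": 0.030, "L": 0.155, "M": 0.055, "N": 0.040,
    "P": 0.040, "Q": 0.020, "R": 0.020, "S": 0.090, "T": 0.045, "V": 0.065,
    "W": 0.030, "Y": 0.045,
}
_AT_RICH = "FMINK"


def default_frequencies() -> np.ndarray:
    v = np.array([_MITO_FREQS[a] for a in AA20])
    return v / v.sum()


def biased_frequencies(base: np.ndarray, bias: float) -> np.ndarray:
    """Reweight stationary frequencies toward the AT-rich codon amino acids
    (F, M, I, N, K); bias=0 is no change."""
    w = np.array([1.0 + bias if a in _AT_RICH else 1.0 for a in AA20])
    v = base * w
    return v / v.sum()


@dataclass(frozen=True)
class PlantedFeature:
    """Ground truth for one planted synapomorphy column."""

    gene_id: str
    column: int
    ancestral: str
    derived: str
    s_true: float
    h_true: float
    query_has: bool = False

    def __post_init__(self):
        if self.derived == self.ancestral:
            raise ValueError("derived residue must differ from ancestral")
        if not (0.0 <= self.s_true <= 1.0 and 0.0 <= self.h_true <= 1.0):
            raise ValueError("s_true and h_true must lie in [0, 1]")


def default_planted_features() -> tuple[PlantedFeature, ...]:
    """Nine planted features with the retention/homoplasy profile of a
    well-supported group-level synapomorphy set; four are shared by the
    query clade."""
    spec = [
        # gene, column, ancestral, derived, s, h, query_has
        ("atp6", 30, "S", "W", 0.83, 0.006, False),
        ("atp6", 70, "L", "F", 0.87, 0.007, True),
        ("cox1", 20, "V", "L", 0.63, 0.030, False),
        ("cox1", 80, "V", "L", 0.83, 0.030, True),
        ("cox1", 140, "I", "L", 0.81, 0.013, False),
        ("cox3", 25, "S", "C", 0.97, 0.014, False),
        ("cox3", 60, "V", "I", 0.92, 0.027, False),
        ("cytb", 55, "F", "W", 0.94, 0.001, True),
        ("nad6", 30, "L", "F", 0.99, 0.011, True),
    ]
    return tuple(PlantedFeature(*row) for row in spec)


@dataclass
class SimConfig:
    """Study conditions for the synthetic database."""

    seed: int = 0
    n_group: int = 157
    n_outside: int = 5000
    n_query: int = 3
    r_true: float = 18.83
    genes: tuple[tuple[str, int], ...] = (
        ("atp6", 100), ("cox1", 160), ("cox3", 90), ("cytb", 120), ("nad6", 60)
    )
    planted: tuple[PlantedFeature, ...] = field(default_factory=default_planted_features)
    gamma_alpha: float = 0.8  # per-site rate heterogeneity shape
    branch_rate_sigma: float = 0.3  # lognormal relaxed-clock jitter on branches
    composition_bias: float = 1.5  # excess weight on F,M,I,N,K in the query clade
    group_depth: float = 0.87  # mean crown-to-tip distance, subst/site
    outside_depth: float = 1.2
    group_stem: float = 0.6
    outside_stem: float = 0.3
    gene_order_rate: float = 2.0  # rearrangement events per subst/site
    gene_tokens: tuple[str, ...] = MT_GENE_TOKENS
    include_control_region: bool = False
    planted_adjacency: tuple[str, str] = ("cytb", "trnW")
    group_taxonomy: tuple[str, ...] = ("Metazoa", "Lophotrochozoa", "GroupA")
    query_taxonomy: tuple[str, ...] = ("Metazoa", "Lophotrochozoa", "QueryQ")
    outside_taxonomies: tuple[tuple[str, ...], ...] = (
        ("Metazoa", "Ecdysozoa", "Arthropoda"),
        ("Metazoa", "Chordata", "Vertebrata"),
        ("Metazoa", "Lophotrochozoa", "Mollusca"),
        ("Metazoa", "Lophotrochozoa", "Neodermata"),
    )
    max_species: int = 50_000

    def __post_init__(self):
        if min(self.n_group, self.n_outside, self.n_query) < 1:
            raise ValueError("species counts must be at least 1")
        total = self.n_group + self.n_outside + self.n_query
        if total > self.max_species:
            raise ValueError(f"{total} species exceeds the configured cap {self.max_species}")
        if self.r_true < 1.0:
            raise ValueError("query rate multiplier r_true must be >= 1")
        if self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        lengths = dict(self.genes)
        for pf in self.planted:
            if pf.gene_id not in lengths:
                raise ValueError(f"planted feature gene '{pf.gene_id}' not in config genes")
            if pf.column >= lengths[pf.gene_id]:
                raise ValueError(
                    f"planted column {pf.column} beyond alignment length "
                    f"{lengths[pf.gene_id]} for gene '{pf.gene_id}'"
                )

    @property
    def all_tokens(self) -> tuple[str, ...]:
        return self.gene_tokens + (("CR",) if self.include_control_region else ())

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def group_labels(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_group)]

    def outside_labels(self) -> list[str]:
        return [f"O{i:05d}" for i in range(self.n_outside)]

    def query_labels(self) -> list[str]:
        return [f"Q{i:02d}" for i in range(self.n_query)]


# ---------------------------------------------------------------------------
# Tree simulation


def _yule_subtree(
    labels: Sequence[str],
    rng: np.random.Generator,
    taxon_namespace,
    rate_sigma: float = 0.0,
):
    """Pure-birth subtree over the given labels with lognormal relaxed-clock
    jitter on every branch; returns (root node, mean root-to-tip depth).
    Branch lengths in arbitrary units (caller rescales)."""
    root = dendropy.Node()
    if len(labels) == 1:
        # single tip: the subtree is just the tip itself at depth 0
        root.taxon = taxon_namespace.require_taxon(label=labels[0])
        return root, 0.0
    birth: dict = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < len(labels):
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(len(active))
        parent = active.pop(int(k))
        for _ in range(2):
            child = dendropy.Node()
            birth[child] = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / len(active))  # extend tips to "present"
    order = rng.permutation(len(active))
    for lab, idx in zip(labels, order):
        active[int(idx)].taxon = taxon_namespace.require_taxon(label=lab)
    for node, bt in birth.items():
        for child in node.child_nodes():
            length = (birth[child] if child.child_nodes() else t) - bt
            if rate_sigma > 0:
                length *= float(
                    rng.lognormal(mean=-0.5 * rate_sigma**2, sigma=rate_sigma)
                )
            child.edge.length = length
    return root, _mean_tip_depth(root)


def _scale_subtree(root, factor: float) -> None:
    for node in root.preorder_iter():
        if node is not root and node.edge.length is not None:
            node.edge.length *= factor


def _mean_tip_depth(root) -> float:
    depths = []
    stack = [(root, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf():
            depths.append(d)
        for child in node.child_nodes():
            stack.append((child, d + (child.edge.length or 0.0)))
    return float(np.mean(depths))


def simulate_tree(config: SimConfig) -> Phylogeny:
    """Rooted tree with the group nested inside the outside diversity.

    The outside pool is a pure-birth tree; the monophyletic group clade is
    grafted (with its stem) onto a shallow internal edge of it, so the node
    one deeper than the group crown has close outside relatives on every
    side -- the structure a taxon occupying one branch of a reference-wide
    phylogeny actually has. The query clade is grafted near the base of the
    group crown and the whole grafted path is scaled by ``r_true``.
    Deterministic given the config seed.
    """
    rng = config.rng(stream=1)
    tns = dendropy.TaxonNamespace()

    sigma = config.branch_rate_sigma
    out_root, _ = _yule_subtree(config.outside_labels(), rng, tns, sigma)
    d = _mean_tip_depth(out_root)
    if d > 0:
        _scale_subtree(out_root, config.outside_depth / d)

    group_root, _ = _yule_subtree(config.group_labels(), rng, tns, sigma)
    d = _mean_tip_depth(group_root)
    if d > 0:
        _scale_subtree(group_root, config.group_depth / d)

    # graft query clade onto an early edge of the group crown; the
    # attachment depth is capped so the whole query path is rate-scaled
    D_g = _mean_tip_depth(group_root)
    host_children = group_root.child_nodes()
    if host_children:
        host = host_children[int(rng.integers(len(host_children)))]
        host_len = host.edge.length or 0.0
        d_att = min(float(rng.uniform(0.1, 0.5)) * host_len, 0.15 * D_g)
    else:  # single-tip group: attach at the crown itself
        host = None
        d_att = 0.0

    q_root, _ = _yule_subtree(config.query_labels(), rng, tns, sigma)
    q_depth = _mean_tip_depth(q_root)
    total = max(D_g - d_att, 1e-6)
    stem_frac = float(rng.uniform(0.2, 0.4)) if config.n_query > 1 else 1.0
    if q_depth > 0:
        _scale_subtree(q_root, (1.0 - stem_frac) * total / q_depth)
        stem0 = stem_frac * total
    else:
        stem0 = total
    # rate scaling of the whole grafted path
    _scale_subtree(q_root, config.r_true)
    stem0 *= config.r_true

    if host is not None:
        attach = dendropy.Node()
        group_root.remove_child(host)
        group_root.add_child(attach)
        attach.edge.length = d_att
        attach.add_child(host)
        host.edge.length = host_len - d_att
        attach.add_child(q_root)
        q_root.edge.length = stem0
    else:
        new_crown = dendropy.Node()
        new_crown.add_child(group_root)
        group_root.edge.length = config.group_depth
        new_crown.add_child(q_root)
        q_root.edge.length = stem0
        group_root = new_crown

    # graft the group (with stem) onto a shallow internal edge of the
    # outside tree
    if config.n_outside >= 2:
        shallow = _shallow_internal_edges(out_root, 0.5 * config.outside_depth)
        host_o, host_o_depth = shallow[int(rng.integers(len(shallow)))]
        host_o_len = host_o.edge.length or 0.0
        cut = float(rng.uniform(0.2, 0.8)) * host_o_len
        parent = host_o.parent_node
        attach = dendropy.Node()
        parent.remove_child(host_o)
        parent.add_child(attach)
        attach.edge.length = cut
        attach.add_child(host_o)
        host_o.edge.length = host_o_len - cut
        attach.add_child(group_root)
        group_root.edge.length = config.group_stem
        root = out_root
    else:
        root = dendropy.Node()
        root.add_child(out_root)
        out_root.edge.length = config.outside_stem
        root.add_child(group_root)
        group_root.edge.length = config.group_stem

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def _shallow_internal_edges(root, max_depth: float):
    """Internal non-root nodes lying above max_depth, with their depths."""
    out = []
    stack = [(root, 0.0)]
    while stack:
        node, d = stack.pop()
        for child in node.child_nodes():
            stack.append((child, d + (child.edge.length or 0.0)))
        if node is not root and d <= max_depth and not node.is_leaf():
            out.append((node, d))
    if not out:  # fall back to any child of the root
        out = [(c, c.edge.length or 0.0) for c in root.child_nodes()]
    return out


# ---------------------------------------------------------------------------
# Sequence simulation


def _node_sets(tree: Phylogeny, config: SimConfig):
    """(query-subtree node set, per-leaf class) derived from leaf labels."""
    q_labels = set(config.query_labels())
    taxa = [tree.taxon_namespace.get_taxon(l) for l in sorted(q_labels)]
    taxa = [t for t in taxa if t is not None]
    query_nodes: set = set()
    if taxa:
        if len(taxa) == 1:
            mrca = next(l for l in tree.leaf_node_iter() if l.taxon is taxa[0])
        else:
            mrca = tree.mrca(taxa=taxa)
        query_nodes = set(mrca.preorder_iter())
    return query_nodes


def simulate_alignment(
    tree: Phylogeny,
    planted: Sequence[PlantedFeature],
    config: SimConfig,
    gene_id: Optional[str] = None,
) -> Alignment:
    """Simulate one gene's alignment along the tree.

    Non-planted columns evolve under the equal-exchangeability model with
    per-site gamma rates (query-clade branches draw replacement residues
    from the composition-biased frequencies). Planted columns bypass the
    substitution model: the group stem fixes the derived residue, each group
    leaf retains it independently with ``s_true``, each outside leaf shows
    it with ``h_true``, and query leaves show it iff the feature's
    ``query_has`` flag is set.
    """
    lengths = dict(config.genes)
    if gene_id is None:
        gene_id = config.genes[0][0]
    if gene_id not in lengths:
        raise ValueError(f"gene '{gene_id}' not in config genes")
    ncol = lengths[gene_id]
    for pf in planted:
        if pf.gene_id == gene_id and pf.column >= ncol:
            raise ValueError(f"planted column {pf.column} >= alignment length {ncol}")

    rng = config.rng(stream=10 + _gene_stream(config, gene_id))
    pi = default_frequencies()
    pi_bias = biased_frequencies(pi, config.composition_bias)
    beta = f81_beta(pi)
    rates = rng.gamma(shape=config.gamma_alpha, scale=1.0 / config.gamma_alpha, size=ncol)
    query_nodes = _node_sets(tree, config)

    states: dict = {}
    root = tree.seed_node
    states[root] = _draw(rng, pi, ncol)
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            parent_states = states[node.parent_node]
            t = node.edge.length or 0.0
            freqs = pi_bias if node in query_nodes else pi
            e = np.exp(-beta * rates * t)
            switch = rng.random(ncol) >= e
            new = parent_states.copy()
            nsw = int(switch.sum())
            if nsw:
                new[switch] = _draw(rng, freqs, nsw)
            states[node] = new
        if node.is_leaf():
            leaf_states[node.taxon.label] = states[node]
        # free memory for fully processed interiors: children hold copies

    aa = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")
    group = set(config.group_labels())
    outside = set(config.outside_labels())
    queries = set(config.query_labels())
    ids = sorted(leaf_states)
    mat = {sid: leaf_states[sid].copy() for sid in ids}

    for pf in (p for p in planted if p.gene_id == gene_id):
        anc = AA20.index(pf.ancestral)
        der = AA20.index(pf.derived)
        for sid in ids:
            if sid in group:
                keep = rng.random() < pf.s_true
                mat[sid][pf.column] = der if keep else anc
            elif sid in outside:
                show = rng.random() < pf.h_true
                mat[sid][pf.column] = der if show else anc
            elif sid in queries:
                mat[sid][pf.column] = der if pf.query_has else anc

    rows = ["".join(aa[mat[sid]]) for sid in ids]
    return Alignment(gene_id=gene_id, sequence_ids=ids, rows=rows)


def _gene_stream(config: SimConfig, gene_id: str) -> int:
    return [g for g, _ in config.genes].index(gene_id)


def _draw(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(len(freqs), size=n, p=freqs).astype(np.int16)


def simulate_alignments(
    tree: Phylogeny, config: SimConfig
) -> dict[str, Alignment]:
    return {
        gene: simulate_alignment(tree, config.planted, config, gene)
        for gene, _ in config.genes
    }


# ---------------------------------------------------------------------------
# Gene-order simulation


def _root_order(config: SimConfig) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Ancestral order: the planted pair is deliberately separated so the
    adjacency is a derived feature that arises on the group stem and occurs
    outside the group only through chance rearrangement."""
    tokens = list(config.all_tokens)
    up, down = config.planted_adjacency
    for tok in (up, down):
        if tok in tokens:
            tokens.remove(tok)
    mid = len(tokens) // 2
    tokens = [up] + tokens[:mid] + [down] + tokens[mid:]
    signs = [1] * len(tokens)
    return tuple(tokens), tuple(signs)


def _plant_adjacency(tokens: list[str], signs: list[int], up: str, down: str):
    """Move ``down`` to sit immediately after ``up``, same strand as ``up``."""
    j = tokens.index(down)
    tokens, signs = list(tokens), list(signs)
    del tokens[j], signs[j]
    i = tokens.index(up)
    tokens.insert(i + 1, down)
    signs.insert(i + 1, signs[i])
    return tokens, signs


def _apply_inversion(tokens, signs, i, j):
    """Reverse tokens[i:j+1] with sign flips (linear indices, i <= j)."""
    seg_t = tokens[i : j + 1][::-1]
    seg_s = [-s for s in signs[i : j + 1][::-1]]
    return tokens[:i] + seg_t + tokens[j + 1 :], signs[:i] + seg_s + signs[j + 1 :]


def _apply_transposition(tokens, signs, i, j, k):
    """Move tokens[i:j+1] to position k of the remainder (k in [0, n-L])."""
    seg_t, seg_s = tokens[i : j + 1], signs[i : j + 1]
    rest_t = tokens[:i] + tokens[j + 1 :]
    rest_s = signs[:i] + signs[j + 1 :]
    return rest_t[:k] + seg_t + rest_t[k:], rest_s[:k] + seg_s + rest_s[k:]


def _random_event(tokens, signs, rng: np.random.Generator):
    n = len(tokens)
    # rotate first so circular segments map to linear ones
    shift = int(rng.integers(n))
    tokens = list(tokens[shift:]) + list(tokens[:shift])
    signs = list(signs[shift:]) + list(signs[:shift])
    L = int(rng.integers(1, n - 1))  # segment length, leaves >= 1 token fixed
    i = int(rng.integers(0, n - L))
    j = i + L - 1
    if rng.random() < 0.5:
        return _apply_inversion(tokens, signs, i, j)
    k = int(rng.integers(0, n - L + 1))
    return _apply_transposition(tokens, signs, i, j, k)


def simulate_gene_orders(tree: Phylogeny, config: SimConfig) -> dict[str, GeneOrder]:
    """Evolve signed circular gene orders along the tree.

    Each branch receives Poisson(rate x length) inversion/transposition
    events. Within the group clade (query included) events that would break
    the planted adjacency are redrawn, locking the adjacency there; outside
    the group it drifts freely.
    """
    rng = config.rng(stream=40)
    root_tokens, root_signs = _root_order(config)
    up, down = config.planted_adjacency
    locked_key = canonical_key((up, 1), (down, 1))

    group_labels = set(config.group_labels()) | set(config.query_labels())
    taxa = [tree.taxon_namespace.get_taxon(l) for l in sorted(group_labels)]
    taxa = [t for t in taxa if t is not None]
    locked_nodes: set = set()
    crown = None
    if len(taxa) >= 2:
        crown = tree.mrca(taxa=taxa)
    elif len(taxa) == 1:
        crown = next(l for l in tree.leaf_node_iter() if l.taxon is taxa[0])
    if crown is not None:
        locked_nodes = set(crown.preorder_iter())

    orders: dict[str, GeneOrder] = {}
    state: dict = {tree.seed_node: (list(root_tokens), list(root_signs))}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            tokens, signs = state[node.parent_node]
            tokens, signs = list(tokens), list(signs)
            t = node.edge.length or 0.0
            n_events = int(rng.poisson(config.gene_order_rate * t))
            locked = node in locked_nodes
            for _ in range(n_events):
                for _attempt in range(20):
                    cand_t, cand_s = _random_event(tokens, signs, rng)
                    if not locked:
                        break
                    order = GeneOrder(species="tmp", tokens=tuple(cand_t), signs=tuple(cand_s))
                    if locked_key in adjacencies(order):
                        break
                else:
                    continue  # no adjacency-preserving event found; skip
                tokens, signs = cand_t, cand_s
            if node is crown:
                # the adjacency emerges on the group stem
                tokens, signs = _plant_adjacency(tokens, signs, up, down)
            state[node] = (tokens, signs)
        if node.is_leaf():
            tokens, signs = state[node]
            orders[node.taxon.label] = GeneOrder(
                species=node.taxon.label, tokens=tuple(tokens), signs=tuple(signs)
            )
    return orders


# ---------------------------------------------------------------------------
# Database assembly


def build_reference_db(
    alignments: dict[str, Alignment],
    orders: dict[str, GeneOrder],
    taxonomy: dict[str, tuple[str, ...]],
) -> ReferenceDB:
    """Assemble the mock reference database from simulated parts."""
    species = set(taxonomy)
    for gene, aln in alignments.items():
        mismatch = sorted(set(aln.sequence_ids) - species)
        if mismatch:
            raise ValueError(
                f"alignment '{gene}' contains species outside the taxonomy: {mismatch[:5]}"
            )
    extra = sorted(set(orders) - species)
    if extra:
        raise ValueError(f"gene orders for unknown species: {extra[:5]}")
    genes = {g: dict(zip(a.sequence_ids, a.rows)) for g, a in alignments.items()}
    return ReferenceDB(taxonomy=dict(taxonomy), genes=genes, orders=dict(orders))


def default_taxonomy(config: SimConfig) -> dict[str, tuple[str, ...]]:
    tax: dict[str, tuple[str, ...]] = {}
    for sp in config.group_labels():
        tax[sp] = config.group_taxonomy + (sp,)
    for sp in config.query_labels():
        tax[sp] = config.query_taxonomy + (sp,)
    outs = config.outside_taxonomies
    for i, sp in enumerate(config.outside_labels()):
        tax[sp] = outs[i % len(outs)] + (sp,)
    return tax


@dataclass
class SimulatedData:
    """Everything one synthetic run produces, plus its ground truth."""

    config: SimConfig
    tree: Phylogeny
    alignments: dict[str, Alignment]
    orders: dict[str, GeneOrder]
    db: ReferenceDB
    group_def: GroupDefinition


def simulate_dataset(config: SimConfig, *, with_gene_orders: bool = True) -> SimulatedData:
    """Run the full generator: tree, per-gene alignments, gene orders, and
    the assembled reference database with group/query definitions."""
    tree = simulate_tree(config)
    alignments = simulate_alignments(tree, config)
    orders = simulate_gene_orders(tree, config) if with_gene_orders else {}
    db = build_reference_db(alignments, orders, default_taxonomy(config))
    group_def = GroupDefinition(
        name=config.group_taxonomy[-1],
        members=frozenset(config.group_labels()),
        query_set=frozenset(config.query_labels()),
        query_min=min(2, config.n_query),
    )
    return SimulatedData(
        config=config, tree=tree, alignments=alignments, orders=orders, db=db, group_def=group_def
    )
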
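"""End-to-end orchestration: simulate -> ancestry -> scan -> gene order ->
probabilities -> report.

The summary always reports the two sides of the argument together: the
probability that the query clade's shared features arose independently by
homoplasy, and the probability that the features it lacks were lost given
its elevated evolutionary rate. The two are never collapsed into a single
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import ancestry, geneorder, probcalc, synscan, synth
from .io_core import GroupDefinition, Phylogeny, ReferenceDB, write_results

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ancestry_tree"]


@dataclass
class RunConfig:
    """Thresholds, scope, and seeding for one pipeline run."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    h_max: float = 0.03
    s_min: float = 0.60
    query_min: int = 2
    p_min: float = 0.5
    # candidate generation unions parsimony and ML calls by default:
    # parsimony is branch-length-free (robust to stem-length effects), ML
    # carries posterior confidence; recall matters here because the
    # database screen downstream provides the precision
    mode: str = "both"  # fitch | ml-marginal | both
    scope: Optional[str] = None  # taxonomy token restricting the outside pool
    n_outgroup_exemplars: int = 40  # outside species kept in the reconstruction tree
    adjacency_pair: Optional[tuple[str, str]] = None  # defaults to the simulated pair
    reference_species: Optional[str] = None

    def __post_init__(self):
        for name in ("h_max", "s_min", "p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class PipelineResult:
    calls: list
    candidates: list
    query_matrix: object  # pandas DataFrame
    shared_features: list
    lost_features: list
    rate_ratio: float
    emergence: Optional[probcalc.EmergenceResult]
    emergence_tail: Optional[float]
    emergence_avg: Optional[float]
    expected_homoplasious_species: Optional[float]
    loss: Optional[probcalc.LossResult]
    adjacency_inside: Optional[geneorder.FrequencyResult]
    adjacency_outside: Optional[geneorder.FrequencyResult]
    combined_independent_emergence: Optional[float]

    def summary(self) -> dict:
        res = {
            "n_apomorphy_calls": len(self.calls),
            "n_candidates": len(self.candidates),
            "candidates": [
                {
                    "gene": c.gene_id,
                    "position_1based": c.column + 1,
                    "derived": c.derived,
                    "s": c.s,
                    "h": c.h,
                    "query_hits": sorted(c.query_hits),
                }
                for c in self.candidates
            ],
            "shared_features": self.shared_features,
            "lost_features": self.lost_features,
            "rate_ratio": self.rate_ratio,
            "emergence_tail_probability": self.emergence_tail,
            "emergence_average_probability": self.emergence_avg,
            "expected_homoplasious_species": self.expected_homoplasious_species,
            "loss_probability": None if self.loss is None else self.loss.p,
            "combined_independent_emergence": self.combined_independent_emergence,
        }
        for name in ("adjacency_inside", "adjacency_outside"):
            fr = getattr(self, name)
            res[name] = None if fr is None else {
                "count": fr.count, "denominator": fr.denominator, "fraction": fr.fraction
            }
        return res


def ancestry_tree(
    tree: Phylogeny,
    group_def: GroupDefinition,
    db: ReferenceDB,
    n_exemplars: int,
    rng: np.random.Generator,
) -> Phylogeny:
    """Subtree used for ancestral reconstruction: group members plus a
    deterministic sample of outside species; query species excluded so the
    group clade is monophyletic and the queries cannot shape the calls."""
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    outside = sorted(labels - group_def.members - group_def.query_set)
    if len(outside) > n_exemplars:
        idx = rng.choice(len(outside), size=n_exemplars, replace=False)
        outside = [outside[i] for i in sorted(idx)]
    keep = sorted(group_def.members & labels) + outside
    taxa = [tree.taxon_namespace.get_taxon(l) for l in keep]
    sub = tree.extract_tree_with_taxa(taxa=taxa)
    sub.is_rooted = True
    return sub


def run_pipeline(
    config: RunConfig, *, data: Optional[synth.SimulatedData] = None, out_path=None
) -> PipelineResult:
    """Run the full pipeline on a synthetic dataset; optionally write the
    JSON report bundle. ``data`` short-circuits the simulation stage."""
    if data is None:
        data = synth.simulate_dataset(config.sim)
    tree, db, group_def = data.tree, data.db, data.group_def
    rng = np.random.default_rng([config.sim.seed, 99])

    sub = ancestry_tree(tree, group_def, db, config.n_outgroup_exemplars, rng)
    sub_group = sorted(
        group_def.members & {l.taxon.label for l in sub.leaf_node_iter()}
    )

    modes = ("fitch", "ml-marginal") if config.mode == "both" else (config.mode,)
    by_key: dict[tuple, ancestry.ApomorphyCall] = {}
    for gene, aln in data.alignments.items():
        sub_labels = [l.taxon.label for l in sub.leaf_node_iter()]
        aln_sub = type(aln)(
            gene_id=gene,
            sequence_ids=sub_labels,
            rows=[aln.row(s) for s in sub_labels],
        )
        for mode in modes:
            states = ancestry.reconstruct_states(sub, aln_sub, mode)
            for call in ancestry.call_apomorphies(
                states, sub, group_def.name, sub_group, p_min=config.p_min
            ):
                key = (call.gene_id, call.column, call.derived)
                # prefer the ML call (it carries a posterior confidence)
                if key not in by_key or call.confidence is not None:
                    by_key[key] = call
    calls = list(by_key.values())

    ref_sp = config.reference_species or (sorted(group_def.members)[0] if group_def.members else None)
    # full group synapomorphy table first (no query filter); the query-shared
    # subset is identified afterwards, so lost features stay visible
    candidates = synscan.screen_candidates(
        calls,
        db,
        group_def,
        h_max=config.h_max,
        s_min=config.s_min,
        query_min=0,
        scope=config.scope,
        reference_species=ref_sp,
    )
    qmatrix = synscan.query_subset(candidates, sorted(group_def.query_set), db)

    shared_idx = [
        i
        for i, c in enumerate(candidates)
        if len(c.query_hits) >= config.query_min
    ]
    lost_idx = [i for i in range(len(candidates)) if i not in shared_idx]
    shared = [f"{candidates[i].gene_id}:{candidates[i].column}" for i in shared_idx]
    lost = [f"{candidates[i].gene_id}:{candidates[i].column}" for i in lost_idx]

    r = probcalc.rate_ratio(
        tree, sorted(group_def.members | group_def.query_set), sorted(group_def.query_set)
    ) if group_def.query_set else float("nan")

    emergence = emergence_tail = emergence_avg = expected = loss = None
    if candidates:
        h = [c.h for c in candidates]
        emergence = probcalc.poisson_binomial(h)
        k = len(shared_idx)
        if k >= 1:
            emergence_tail = float(emergence.x[k])
            emergence_avg = float(emergence.avg[k])
            expected = probcalc.expected_homoplasy_count(
                emergence_tail, len(group_def.members)
            )
        if lost_idx and group_def.query_set and np.isfinite(r):
            s_all = [c.s for c in candidates]
            loss = probcalc.loss_probability(s_all, r, lost_idx)

    adjacency_inside = adjacency_outside = None
    pair = config.adjacency_pair or config.sim.planted_adjacency
    if db.orders:
        key = geneorder.canonical_key((pair[0], 1), (pair[1], 1))
        inside_count = sum(
            1
            for sp in group_def.members
            if sp in db.orders and key in geneorder.adjacencies(db.orders[sp])
        )
        denom = sum(1 for sp in group_def.members if sp in db.orders)
        adjacency_inside = geneorder.FrequencyResult(inside_count, denom)
        adjacency_outside = geneorder.adjacency_frequency(
            db, key, exclude_groups=[group_def.members, group_def.query_set]
        )

    combined = None
    if emergence_avg is not None and adjacency_outside is not None and adjacency_outside.has_data:
        combined = probcalc.combine_independent(
            [emergence_avg, adjacency_outside.fraction]
        )

    result = PipelineResult(
        calls=calls,
        candidates=candidates,
        query_matrix=qmatrix,
        shared_features=shared,
        lost_features=lost,
        rate_ratio=r,
        emergence=emergence,
        emergence_tail=emergence_tail,
        emergence_avg=emergence_avg,
        expected_homoplasious_species=expected,
        loss=loss,
        adjacency_inside=adjacency_inside,
        adjacency_outside=adjacency_outside,
        combined_independent_emergence=combined,
    )
    if out_path is not None:
        write_results(
            result.summary(), out_path, seed=config.sim.seed,
            config={"h_max": config.h_max, "s_min": config.s_min,
                    "query_min": config.query_min, "mode": config.mode},
        )
    return result
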
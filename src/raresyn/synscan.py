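"""Candidate synapomorphy screening against a reference database.

Apomorphy calls for a group are turned into candidate synapomorphies shared
with a query clade, then filtered on two database frequencies: the
within-group retention ``s`` (candidates lost in too many group members are
discarded) and the outside-group homoplasy ``h`` (candidates common outside
the group are discarded). Query species never contaminate either
denominator. The module also provides the shared-feature excess statistic:
observed vs expected counts of rare group-stable residues shared between
two taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .ancestry import ApomorphyCall
from .geneorder import FrequencyResult
from .io_core import GroupDefinition, ReferenceDB

__all__ = [
    "CandidateSynapomorphy",
    "ExcessResult",
    "group_frequency",
    "screen_candidates",
    "query_subset",
    "shared_feature_excess",
]


@dataclass
class CandidateSynapomorphy:
    """One alignment column's derived residue with its database frequencies."""

    gene_id: str
    column: int
    derived: str
    ancestral: str
    motif: Optional[str]  # +-5 residue context from the reference species
    s: Optional[float]  # within-group frequency
    h: Optional[float]  # outside-group frequency
    s_counts: Optional[FrequencyResult] = None
    h_counts: Optional[FrequencyResult] = None
    query_hits: frozenset[str] = frozenset()

    def __post_init__(self):
        for val in (self.s, self.h):
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class ExcessResult:
    """Observed vs expected shared rare-feature counts for a group pair."""

    group_a: str
    group_b: str
    expected_a: float  # sum of outside frequencies over A-qualifying positions
    expected_b: float
    observed: int  # positions qualifying in both groups simultaneously
    qualifying_a: list = field(default_factory=list)
    qualifying_b: list = field(default_factory=list)

    @property
    def expected(self) -> float:
        """Expected count of features shared with at least one of the two groups."""
        return self.expected_a + self.expected_b

    @property
    def ratio(self) -> Optional[float]:
        return None if self.expected == 0 else self.observed / self.expected


def group_frequency(
    db: ReferenceDB,
    gene: str,
    column: int,
    residue: str,
    group: GroupDefinition,
    inside: bool,
    *,
    scope: Optional[str] = None,
) -> FrequencyResult:
    """Frequency of a residue at a column inside or outside a group.

    Inside: among the group members. Outside: among database species that
    are neither group members nor query species, optionally restricted to a
    taxonomy scope token. Species with '-' or 'X' at the column are excluded
    from both numerator and denominator; an empty denominator is reported
    as a no-data result, never as 0.
    """
    table = db.genes.get(gene)
    if table is None:
        raise KeyError(f"gene '{gene}' not in database")
    some_row = next(iter(table.values()), "")
    if not 0 <= column < len(some_row):
        raise IndexError(f"column {column} out of range for gene '{gene}'")
    if inside:
        pool = group.members
    else:
        pool = set(db.taxonomy) - group.members - group.query_set
        if scope is not None:
            pool &= db.in_taxon(scope)
    count = denom = 0
    for sp in pool:
        row = table.get(sp)
        if row is None:
            continue
        ch = row[column]
        if ch == "-" or ch == "X":
            continue
        denom += 1
        if ch == residue:
            count += 1
    return FrequencyResult(count=count, denominator=denom)


def _motif(db: ReferenceDB, gene: str, column: int, reference_species: Optional[str],
           flank: int = 5) -> Optional[str]:
    if reference_species is None:
        return None
    row = db.genes.get(gene, {}).get(reference_species)
    if row is None:
        return None
    lo, hi = max(0, column - flank), min(len(row), column + flank + 1)
    return f"{row[lo:column]}-{row[column]}-{row[column + 1:hi]}"


def screen_candidates(
    calls: Sequence[ApomorphyCall],
    db: ReferenceDB,
    group_def: GroupDefinition,
    *,
    h_max: float = 0.03,
    s_min: float = 0.60,
    query_min: Optional[int] = None,
    scope: Optional[str] = None,
    reference_species: Optional[str] = None,
) -> list[CandidateSynapomorphy]:
    """Filter apomorphy calls by query sharing, homoplasy, and stability.

    Retains calls carried by at least ``query_min`` query species, with
    outside-group frequency h <= h_max and within-group frequency
    s >= s_min (comparisons on exact fractions). Candidates with no
    frequency data are dropped.
    """
    if query_min is None:
        query_min = group_def.query_min
    out: list[CandidateSynapomorphy] = []
    for call in calls:
        hits = frozenset(
            sp
            for sp in group_def.query_set
            if db.residue(call.gene_id, sp, call.column) == call.derived
        )
        if group_def.query_set and len(hits) < query_min:
            continue
        s_res = group_frequency(db, call.gene_id, call.column, call.derived, group_def, True)
        h_res = group_frequency(
            db, call.gene_id, call.column, call.derived, group_def, False, scope=scope
        )
        if not s_res.has_data or not h_res.has_data:
            continue
        if h_res.fraction > h_max or s_res.fraction < s_min:
            continue
        out.append(
            CandidateSynapomorphy(
                gene_id=call.gene_id,
                column=call.column,
                derived=call.derived,
                ancestral=call.ancestral,
                motif=_motif(db, call.gene_id, call.column, reference_species),
                s=s_res.fraction,
                h=h_res.fraction,
                s_counts=s_res,
                h_counts=h_res,
                query_hits=hits,
            )
        )
    return out


def query_subset(
    candidates: Sequence[CandidateSynapomorphy],
    query_species: Sequence[str],
    db: Optional[ReferenceDB] = None,
) -> pd.DataFrame:
    """Feature x query-species presence matrix.

    Values are True/False; a query species lacking the gene is recorded as
    pd.NA (absent-with-flag), never as False.
    """
    rows = {}
    for cand in candidates:
        key = f"{cand.gene_id}:{cand.column}"
        vals = {}
        for sp in query_species:
            if db is not None:
                res = db.residue(cand.gene_id, sp, cand.column)
                vals[sp] = pd.NA if res is None else res == cand.derived
            else:
                vals[sp] = sp in cand.query_hits
        rows[key] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(query_species))


def shared_feature_excess(
    db: ReferenceDB,
    group_a: GroupDefinition,
    group_b: GroupDefinition,
    scope: str,
    *,
    t_in: float = 0.70,
    t_out: float = 0.03,
) -> ExcessResult:
    """Observed vs expected rare-feature sharing between two groups.

    A position/residue qualifies for a group when its within-group
    frequency reaches ``t_in`` while its frequency among scope species
    outside both groups stays at or below ``t_out``. The expected number of
    qualifying features found in one random scope species is the sum of the
    outside frequencies; the expectation for "shared with at least one of
    the two groups" adds the two sums. The observed count is the number of
    positions qualifying for both groups simultaneously (counted once per
    position).
    """
    if group_a.members & group_b.members:
        raise ValueError("groups overlap; shared-feature excess undefined")

    def qualifying(group: GroupDefinition) -> dict[tuple[str, int], tuple[str, float]]:
        found: dict[tuple[str, int], tuple[str, float]] = {}
        for gene, table in db.genes.items():
            length = len(next(iter(table.values()), ""))
            for col in range(length):
                best = _dominant_residue(table, group.members, col)
                if best is None:
                    continue
                residue, freq_in = best
                if freq_in < t_in:
                    continue
                out_res = _residue_frequency(
                    table, _outside_pool(db, group_a, group_b, scope), col, residue
                )
                if not out_res.has_data or out_res.fraction > t_out:
                    continue
                found[(gene, col)] = (residue, out_res.fraction)
        return found

    qual_a = qualifying(group_a)
    qual_b = qualifying(group_b)
    observed = sum(
        1
        for key, (res, _) in qual_a.items()
        if key in qual_b and qual_b[key][0] == res
    )
    return ExcessResult(
        group_a=group_a.name,
        group_b=group_b.name,
        expected_a=sum(f for _, f in qual_a.values()),
        expected_b=sum(f for _, f in qual_b.values()),
        observed=observed,
        qualifying_a=sorted(qual_a),
        qualifying_b=sorted(qual_b),
    )


def _outside_pool(db: ReferenceDB, a: GroupDefinition, b: GroupDefinition, scope: str) -> set[str]:
    pool = db.in_taxon(scope) - a.members - b.members - a.query_set - b.query_set
    return pool


def _dominant_residue(table: dict[str, str], members, col: int):
    counts: dict[str, int] = {}
    denom = 0
    for sp in members:
        row = table.get(sp)
        if row is None:
            continue
        ch = row[col]
        if ch == "-" or ch == "X":
            continue
        denom += 1
        counts[ch] = counts.get(ch, 0) + 1
    if denom == 0:
        return None
    residue = max(sorted(counts), key=counts.get)
    return residue, counts[residue] / denom


def _residue_frequency(table: dict[str, str], pool, col: int, residue: str) -> FrequencyResult:
    count = denom = 0
    for sp in pool:
        row = table.get(sp)
        if row is None:
            continue
        ch = row[col]
        if ch == "-" or ch == "X":
            continue
        denom += 1
        if ch == residue:
            count += 1
    return FrequencyResult(count=count, denominator=denom)
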
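"""Composition diagnostics and masking for compositional-bias checks.

Genomes with strongly AT-biased mitochondrial DNA accumulate amino acids
encoded by AT-rich codons (F, M, I, N, K) at the expense of those with
GC-rich codons (G, T, P, A, R); the resulting compositional attraction can
group unrelated fast-evolving lineages in trees. This module summarizes
those sums per species and supports the robustness check of masking the
AT-rich residues in designated sequences before re-screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_core import AA20, Alignment

AT_RICH = frozenset("FMINK")
GC_RICH = frozenset("GTPAR")

__all__ = ["CompositionSummary", "composition_summary", "strip_residues", "remove_columns"]


@dataclass
class CompositionSummary:
    species: str
    at_rich_sum: float  # freq(F)+freq(M)+freq(I)+freq(N)+freq(K)
    gc_rich_sum: float  # freq(G)+freq(T)+freq(P)+freq(A)+freq(R)
    n_residues: int
    gc_fraction: Optional[float] = None


def composition_summary(
    protein_seqs: Mapping[str, str],
    nucleotide_seqs: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-species AT-rich / GC-rich amino-acid sums (and GC% when coding
    nucleotide sequences are given). Gaps and X are ignored."""
    rows = []
    for sp, seq in protein_seqs.items():
        residues = [c for c in seq.upper() if c in AA20]
        if not residues:
            raise ValueError(f"no residues in sequence for '{sp}'")
        n = len(residues)
        at = sum(1 for c in residues if c in AT_RICH) / n
        gc_rich = sum(1 for c in residues if c in GC_RICH) / n
        gc_frac = None
        if nucleotide_seqs is not None and sp in nucleotide_seqs:
            nt = [c for c in nucleotide_seqs[sp].upper() if c in "ACGT"]
            if nt:
                gc_frac = sum(1 for c in nt if c in "GC") / len(nt)
        rows.append(
            CompositionSummary(
                species=sp, at_rich_sum=at, gc_rich_sum=gc_rich, n_residues=n, gc_fraction=gc_frac
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("species")


def strip_residues(
    alignment: Alignment,
    species: Sequence[str],
    residue_set: Iterable[str] = AT_RICH,
) -> Alignment:
    """Mask a residue set to 'X' in the designated sequences only.

    Coordinates are preserved (masking, not deletion), so database column
    indices stay valid.
    """
    residues = {r.upper() for r in residue_set}
    unknown = residues - set(AA20)
    if unknown:
        raise ValueError(f"unknown residues in set: {sorted(unknown)}")
    targets = set(species)
    missing = targets - set(alignment.sequence_ids)
    if missing:
        raise KeyError(f"species not in alignment: {sorted(missing)[:5]}")
    table = str.maketrans({r: "X" for r in residues})
    rows = [
        row.translate(table) if sid in targets else row
        for sid, row in zip(alignment.sequence_ids, alignment.rows)
    ]
    return Alignment(
        gene_id=alignment.gene_id, sequence_ids=list(alignment.sequence_ids), rows=rows
    )


def remove_columns(
    alignment: Alignment, columns: Iterable[int]
) -> tuple[Alignment, dict[int, int]]:
    """Drop listed columns; returns the reduced alignment and an old->new
    column-index map for the surviving columns."""
    drop = set(int(c) for c in columns)
    bad = [c for c in drop if not 0 <= c < alignment.length]
    if bad:
        raise IndexError(f"columns out of range: {sorted(bad)}")
    keep = [j for j in range(alignment.length) if j not in drop]
    index_map = {old: new for new, old in enumerate(keep)}
    rows = ["".join(row[j] for j in keep) for row in alignment.rows]
    return (
        Alignment(gene_id=alignment.gene_id, sequence_ids=list(alignment.sequence_ids), rows=rows),
        index_map,
    )
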
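"""Readers, writers, and shared domain types.

All column indices are 0-based, half-open internally; human-readable reports
use 1-based positions and say so. Residue alphabet is the 20 amino-acid
letters plus ``X`` (observed but unknown; excluded from frequency numerators
and denominators) and ``-`` (absence).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import dendropy
from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AA20) | {"X", "-"}


class FormatError(ValueError):
    """Malformed input file or record."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Alignment:
    """A gene's aligned amino-acid matrix.

    rows[i] is the aligned residue string for sequence_ids[i]; all rows have
    equal length and are upper-case.
    """

    gene_id: str
    sequence_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise FormatError("sequence_ids and rows differ in length")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            dupes = sorted({s for s in self.sequence_ids if self.sequence_ids.count(s) > 1})
            raise FormatError(f"duplicate sequence ids: {', '.join(dupes)}")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.sequence_ids, self.rows):
                if len(row) != n:
                    raise FormatError(
                        f"ragged alignment: record '{sid}' has length {len(row)}, expected {n}"
                    )
                bad = set(row) - ALPHABET
                if bad:
                    raise FormatError(f"record '{sid}' contains invalid symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, sequence_id: str) -> str:
        try:
            return self.rows[self.sequence_ids.index(sequence_id)]
        except ValueError:
            raise KeyError(sequence_id) from None

    def column(self, j: int) -> str:
        if not 0 <= j < self.length:
            raise IndexError(f"column {j} out of range [0, {self.length})")
        return "".join(r[j] for r in self.rows)


#: A rooted phylogeny. We use dendropy's tree as the in-memory container;
#: ``read_tree`` enforces the invariants (unique leaf labels, branch
#: lengths >= 0, internal degree >= 2).
Phylogeny = dendropy.Tree


@dataclass
class GeneOrder:
    """Signed circular arrangement of gene tokens for one genome."""

    species: str
    tokens: tuple[str, ...]
    signs: tuple[int, ...]  # +1 / -1, parallel to tokens

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.signs):
            raise FormatError("tokens and signs differ in length")
        if len(self.tokens) < 2:
            raise FormatError("gene order needs at least two tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise FormatError(f"duplicate gene token in order for '{self.species}'")
        if any(s not in (1, -1) for s in self.signs):
            raise FormatError("signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.tokens)

    def signed_tokens(self) -> list[tuple[str, int]]:
        return list(zip(self.tokens, self.signs))

    def to_string(self) -> str:
        return ",".join(("+" if s > 0 else "-") + t for t, s in zip(self.tokens, self.signs))

    @classmethod
    def from_string(cls, species: str, text: str) -> "GeneOrder":
        tokens: list[str] = []
        signs: list[int] = []
        for item in text.split(","):
            item = item.strip()
            if not item:
                continue
            if item[0] == "+":
                signs.append(1)
                tokens.append(item[1:])
            elif item[0] == "-":
                signs.append(-1)
                tokens.append(item[1:])
            else:  # unsigned token defaults to + strand
                signs.append(1)
                tokens.append(item)
        return cls(species=species, tokens=tuple(tokens), signs=tuple(signs))


@dataclass
class ReferenceDB:
    """Species-keyed store of taxonomy, aligned residues per gene, gene orders.

    Emulates the role of a RefSeq-wide mitogenome collection: the screening
    stages query it for residue and adjacency frequencies inside/outside
    named taxa.
    """

    taxonomy: dict[str, tuple[str, ...]]  # species -> taxonomy path (root first)
    genes: dict[str, dict[str, str]] = field(default_factory=dict)  # gene -> species -> row
    orders: dict[str, GeneOrder] = field(default_factory=dict)  # species -> order

    def __post_init__(self) -> None:
        for sp, path in self.taxonomy.items():
            if not path:
                raise FormatError(f"empty taxonomy path for species '{sp}'")
        for gene, table in self.genes.items():
            lengths = {len(r) for r in table.values()}
            if len(lengths) > 1:
                raise FormatError(f"gene '{gene}' has rows of unequal length: {sorted(lengths)}")
            missing = sorted(set(table) - set(self.taxonomy))
            if missing:
                raise FormatError(
                    f"species in alignment for '{gene}' but not in taxonomy: {', '.join(missing)}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.taxonomy)

    def __len__(self) -> int:
        return len(self.taxonomy)

    def in_taxon(self, taxon: str) -> set[str]:
        """Species whose taxonomy path contains the taxon token."""
        return {sp for sp, path in self.taxonomy.items() if taxon in path}

    def residue(self, gene: str, species: str, column: int) -> Optional[str]:
        """Residue at a column, or None when the species lacks the gene."""
        row = self.genes.get(gene, {}).get(species)
        return None if row is None else row[column]


@dataclass
class GroupDefinition:
    """A named taxon: its member species and the query species tested against it."""

    name: str
    members: frozenset[str]
    query_set: frozenset[str] = frozenset()
    query_min: int = 2

    def __post_init__(self) -> None:
        overlap = self.members & self.query_set
        if overlap:
            raise ValueError(
                f"group '{self.name}': members and query_set overlap: {sorted(overlap)[:5]}"
            )
        if self.query_set and self.query_min > len(self.query_set):
            raise ValueError(f"query_min {self.query_min} exceeds |query_set| {len(self.query_set)}")


# ---------------------------------------------------------------------------
# Readers


def read_alignment(path: str | Path, gene_id: str) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment` (case-folded to upper)."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise FormatError(f"no FASTA records in {path}")
    n = len(rows[0])
    for i, (sid, row) in enumerate(zip(ids, rows)):
        if len(row) != n:
            raise FormatError(
                f"{path}: ragged alignment, record {i + 1} ('{sid}') has length "
                f"{len(row)}, expected {n}"
            )
    return Alignment(gene_id=gene_id, sequence_ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.sequence_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree; a trifurcating root is accepted as rooted."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise FormatError(f"duplicate leaf labels in {path}: {e}") from e
    tree.is_rooted = True
    return validate_tree(tree)


def tree_from_string(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise FormatError(f"duplicate leaf labels: {e}") from e
    tree.is_rooted = True
    return validate_tree(tree)


def validate_tree(tree: Phylogeny) -> Phylogeny:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError("tree contains an unlabeled leaf")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels: {', '.join(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) < 2 and node is not tree.seed_node:
            # unifurcations carry no information and break reconstruction
            raise FormatError("internal node with a single child")
    return tree


def leaf_labels(tree: Phylogeny) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def read_refdb(
    alignment_paths: Mapping[str, str | Path],
    taxonomy_tsv: str | Path,
    geneorder_tsv: Optional[str | Path] = None,
) -> ReferenceDB:
    """Join per-gene FASTA alignments, a taxonomy TSV, and a gene-order TSV.

    Taxonomy TSV columns: species, slash-separated taxonomy path.
    Gene-order TSV columns: species, comma-separated signed tokens
    (``+cox1,-trnW,...``). Species present in taxonomy but missing a gene
    simply lack that gene's row; species in an alignment but absent from the
    taxonomy are an error.
    """
    taxonomy: dict[str, tuple[str, ...]] = {}
    with open(taxonomy_tsv) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{taxonomy_tsv}:{ln}: expected 2 tab-separated columns")
            sp, pathstr = parts[0], parts[1]
            if sp == "species" and ln == 1:
                continue
            if sp in taxonomy:
                raise FormatError(f"{taxonomy_tsv}:{ln}: duplicate species '{sp}'")
            taxonomy[sp] = tuple(t for t in pathstr.split("/") if t)

    genes: dict[str, dict[str, str]] = {}
    for gene, apath in alignment_paths.items():
        aln = read_alignment(apath, gene)
        missing = sorted(set(aln.sequence_ids) - set(taxonomy))
        if missing:
            raise FormatError(
                f"species in alignment '{gene}' but not in taxonomy: {', '.join(missing)}"
            )
        genes[gene] = dict(zip(aln.sequence_ids, aln.rows))

    orders: dict[str, GeneOrder] = {}
    if geneorder_tsv is not None:
        with open(geneorder_tsv) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{geneorder_tsv}:{ln}: expected 2 tab-separated columns")
                sp, orderstr = parts[0], parts[1]
                if sp == "species" and ln == 1:
                    continue
                if sp not in taxonomy:
                    raise FormatError(f"{geneorder_tsv}:{ln}: species '{sp}' not in taxonomy")
                orders[sp] = GeneOrder.from_string(sp, orderstr)

    return ReferenceDB(taxonomy=taxonomy, genes=genes, orders=orders)


def write_refdb(db: ReferenceDB, out_dir: str | Path) -> dict[str, Path]:
    """Write a ReferenceDB as FASTA + TSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tax = out / "taxonomy.tsv"
    with open(tax, "w") as fh:
        fh.write("species\ttaxonomy_path\n")
        for sp, path in db.taxonomy.items():
            fh.write(f"{sp}\t{'/'.join(path)}\n")
    written["taxonomy"] = tax
    for gene, table in db.genes.items():
        p = out / f"{gene}.fasta"
        with open(p, "w") as fh:
            for sp, row in table.items():
                fh.write(f">{sp}\n{row}\n")
        written[f"gene:{gene}"] = p
    go = out / "gene_orders.tsv"
    with open(go, "w") as fh:
        fh.write("species\tgene_order\n")
        for sp, order in db.orders.items():
            fh.write(f"{sp}\t{order.to_string()}\n")
    written["gene_orders"] = go
    return written


# ---------------------------------------------------------------------------
# Report writer


def config_hash(config: object) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results(report: object, path: str | Path, *, seed: Optional[int] = None,
                  config: Optional[dict] = None) -> None:
    """Serialize a result report to JSON with run metadata.

    The payload round-trips losslessly through :func:`read_results`; an
    unserializable field raises TypeError.
    """
    from . import __version__

    doc = {
        "meta": {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
        },
        "report": report,
    }
    text = json.dumps(doc, indent=2, sort_keys=True, default=_jsonify)
    # round-trip check up front so a half-written file never hides the error
    json.loads(text)
    Path(path).write_text(text + "\n")


def _jsonify(obj):
    import dataclasses

    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"unserializable field of type {type(obj).__name__}")


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
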
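"""Readers and writers for the external formats the pipeline touches.

FASTA (aligned and unaligned, amino acids), Newick trees, the taxonomy TSV
that assigns every leaf to (species, class, phylum, domain), RAxML-style
partition files, and the YAML run configuration. Validation is strict: a
malformed input raises :class:`FormatError` naming the offending record.

Newick dialect: branch lengths after ``:``, internal numeric labels read as
support values, no quoted labels, no comments. Rootedness is inferred from
the arity of the top-level node (2 children = rooted).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import yaml
from Bio import SeqIO

from .trees import Node, PhyloTree

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: residues tolerated in input sequences beyond the 20 amino acids
EXTRA_RESIDUES = "X-"
VALID_RESIDUES = frozenset(AMINO_ACIDS + EXTRA_RESIDUES)


class FormatError(ValueError):
    """Malformed external input."""


class NewickParseError(FormatError):
    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# taxonomy

@dataclass(frozen=True)
class TaxonRecord:
    species: str
    class_: str
    phylum: str
    domain: str


@dataclass
class TaxonomyMap:
    """Leaf identifier -> (species, class, phylum, domain).

    ``outgroup_domain`` names which of the declared domains roots the
    analysis; everything else counts as ingroup.
    """

    entries: dict[str, TaxonRecord]
    outgroup_domain: str | None = None

    def __post_init__(self):
        for leaf, rec in self.entries.items():
            for rank in ("species", "class_", "phylum", "domain"):
                if not getattr(rec, rank):
                    raise FormatError(f"leaf {leaf!r}: empty {rank}")
        if (self.outgroup_domain is not None
                and self.outgroup_domain not in self.domains):
            raise FormatError(
                f"outgroup domain {self.outgroup_domain!r} not among declared "
                f"domains {sorted(self.domains)}")

    @property
    def domains(self) -> set[str]:
        return {r.domain for r in self.entries.values()}

    def resolve(self, leaf: str) -> TaxonRecord:
        """Look up a leaf; duplicate-copy suffixes ``__<k>`` are stripped."""
        if leaf in self.entries:
            return self.entries[leaf]
        base, sep, tail = leaf.rpartition("__")
        if sep and base in self.entries and tail.isdigit():
            return self.entries[base]
        raise FormatError(f"leaf {leaf!r} not in taxonomy")

    def __contains__(self, leaf: str) -> bool:
        try:
            self.resolve(leaf)
            return True
        except FormatError:
            return False

    def is_outgroup(self, leaf: str) -> bool:
        if self.outgroup_domain is None:
            raise FormatError("no outgroup domain declared")
        return self.resolve(leaf).domain == self.outgroup_domain

    def subset(self, leaves: Iterable[str], rank: str) -> set[str]:
        return {getattr(self.resolve(l), rank) for l in leaves}


TAXONOMY_HEADER = ["leaf", "species", "class", "phylum", "domain"]


def read_taxonomy(path: str | Path, outgroup_domain: str | None = None
                  ) -> TaxonomyMap:
    """Read the tab-separated taxonomy table (fixed five-column header)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty taxonomy file")
    header = lines[0].rstrip("\n").split("\t")
    if header != TAXONOMY_HEADER:
        raise FormatError(f"{path}: header must be {TAXONOMY_HEADER}, "
                          f"got {header}")
    entries: dict[str, TaxonRecord] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise FormatError(f"{path}:{i}: expected 5 columns, got {len(cols)}")
        leaf, species, class_, phylum, domain = (c.strip() for c in cols)
        if leaf in entries:
            raise FormatError(f"{path}:{i}: duplicate leaf id {leaf!r}")
        if not all((leaf, species, class_, phylum, domain)):
            raise FormatError(f"{path}:{i}: empty field in row for {leaf!r}")
        entries[leaf] = TaxonRecord(species, class_, phylum, domain)
    return TaxonomyMap(entries, outgroup_domain=outgroup_domain)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAXONOMY_HEADER) + "\n")
        for leaf, r in tax.entries.items():
            fh.write(f"{leaf}\t{r.species}\t{r.class_}\t{r.phylum}\t{r.domain}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into ``[(identifier, SEQUENCE), ...]``.

    The identifier is the first whitespace-delimited header token; sequences
    are uppercased; ``-`` (gap) and ``X`` (unknown) are allowed.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if ident in seen:
            raise FormatError(f"{path}: duplicate identifier {ident!r}")
        seen.add(ident)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in VALID_RESIDUES:
                raise FormatError(
                    f"{path}: illegal residue {ch!r} at position {pos} "
                    f"of {ident!r}")
        records.append((ident, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick

def _precheck_newick(text: str) -> None:
    depth = 0
    semi = None
    for i, ch in enumerate(text):
        if semi is not None and not ch.isspace():
            raise NewickParseError("trailing garbage after ';'", offset=i)
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
        elif ch == ";":
            if depth != 0:
                raise NewickParseError("';' inside unclosed '('", offset=i)
            semi = i
    if depth != 0:
        raise NewickParseError("unbalanced '(': missing ')'",
                               offset=len(text) - 1)
    if semi is None:
        raise NewickParseError("missing terminating ';'",
                               offset=len(text) - 1)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Missing branch lengths default to 0; numeric internal-node labels are
    read as support values; the tree is rooted iff the top-level node has
    exactly two children.
    """
    _precheck_newick(text)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise NewickParseError(f"newick parse failed: {exc}") from None

    def convert(dn) -> Node:
        if dn.is_leaf():
            name = dn.taxon.label if dn.taxon is not None else dn.label
            n = Node(name, dn.edge.length or 0.0)
            return n
        support = None
        label = dn.label
        if label is not None:
            try:
                support = float(label)
            except ValueError:
                support = None
        n = Node(None, dn.edge.length or 0.0, support)
        for dc in dn.child_nodes():
            n.add(convert(dc))
        return n

    root = convert(dtree.seed_node)
    root.length = 0.0
    tree = PhyloTree(root, validate=False)
    names = tree.leaf_names
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf labels in newick input")
    return tree


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize a tree; inverse of :func:`parse_newick` for this dialect."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}f}"

    def rec(n: Node, top: bool) -> str:
        if n.is_leaf:
            body = n.name
        else:
            inner = ",".join(rec(c, False) for c in n.children)
            label = "" if n.support is None else f"{n.support:g}"
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{fmt(n.length)}"

    return rec(tree.root, True) + ";"


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick_file(tree: PhyloTree, path: str | Path,
                      precision: int = 6) -> None:
    Path(path).write_text(write_newick(tree, precision) + "\n")


# ---------------------------------------------------------------------------
# partitions

def write_partitions(partitions: Sequence[tuple[str, int, int]]) -> str:
    """RAxML-style partition lines, 1-based inclusive, must tile contiguously."""
    out = []
    expected_start = 1
    for name, start, end in partitions:
        if start != expected_start:
            raise FormatError(
                f"partition {name!r} starts at {start}, expected "
                f"{expected_start} (gap or overlap)")
        if end < start:
            raise FormatError(f"partition {name!r}: end {end} < start {start}")
        out.append(f"{name} = {start}-{end}")
        expected_start = end + 1
    return "\n".join(out) + ("\n" if out else "")


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    parts = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            name, rng = (x.strip() for x in line.split("="))
            start, end = (int(x) for x in rng.split("-"))
        except ValueError:
            raise FormatError(f"partition file line {i}: cannot parse "
                              f"{line!r}") from None
        parts.append((name, start, end))
    return parts


# ---------------------------------------------------------------------------
# run config (YAML)

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
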
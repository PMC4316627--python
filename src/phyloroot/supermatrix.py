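"""Column trimming, concatenation and missing-data accounting.

The trimmer is a deliberately simple, deterministic column filter: a column
is kept iff its gap fraction and its normalized Shannon entropy (log base =
alphabet size, gaps excluded from the distribution) both stay below their
thresholds. Concatenation stacks trimmed families into one species-level
matrix with 1-based partition coordinates; species absent from a family get
an all-gap block, and the per-taxon missing fraction counts both gap
characters and absent blocks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import TaxonomyMap
from .simulate import GeneFamily

log = logging.getLogger(__name__)


class SupermatrixError(ValueError):
    pass


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]
    missing: dict[str, float]

    def __post_init__(self):
        L = self.length
        for t in self.taxa:
            if len(self.rows[t]) != L:
                raise SupermatrixError(f"row {t} has wrong length")
        end = 0
        for name, s, e in self.partitions:
            if s != end + 1 or e < s:
                raise SupermatrixError(f"partitions do not tile at {name}")
            end = e
        if self.partitions and end != L:
            raise SupermatrixError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return (self.partitions[-1][2] if self.partitions
                else len(next(iter(self.rows.values()), "")))


def column_stats(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column gap fraction and normalized entropy (gaps excluded)."""
    arr = np.array([list(r) for r in rows])
    n_rows, L = arr.shape
    gaps = (arr == "-") | (arr == "X")
    gap_frac = gaps.mean(axis=0)
    ent = np.zeros(L)
    for j in range(L):
        col = arr[~gaps[:, j], j]
        if col.size == 0:
            ent[j] = 1.0
            continue
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        h = -(p * np.log(p)).sum()
        ent[j] = h / math.log(20)
    return gap_frac, ent


def trim_alignment(family: GeneFamily, max_gap_fraction: float = 0.2,
                   max_entropy: float = 0.5
                   ) -> tuple[GeneFamily, list[int]]:
    """Remove gappy and high-entropy columns; kept indices are 1-based.

    Trimming is idempotent. If every column is removed the family comes back
    empty with a warning (not an error).
    """
    if not family.aligned:
        raise SupermatrixError("trim requires an aligned family")
    rows = [m.sequence for m in family.members]
    gap_frac, ent = column_stats(rows)
    keep = np.nonzero((gap_frac <= max_gap_fraction)
                      & (ent <= max_entropy))[0]
    if keep.size == 0:
        log.warning("family %s: trimming removed every column",
                    family.family_id)
    fam = family.copy()
    for m in fam.members:
        m.sequence = "".join(m.sequence[j] for j in keep)
    return fam, [int(j) + 1 for j in keep]


def concatenate(families: list[GeneFamily], taxa: list[str],
                mapping=None) -> Supermatrix:
    """Concatenate trimmed families into a species-level supermatrix.

    ``mapping`` maps leaf id -> species (default: a TaxonomyMap's species
    rank, or identity). Each family must contribute at most one sequence per
    species; planted paralogs must have been screened out upstream.
    """
    if isinstance(mapping, TaxonomyMap):
        tax = mapping
        mapping = lambda leaf: tax.resolve(leaf).species   # noqa: E731
    elif mapping is None:
        mapping = lambda leaf: leaf                        # noqa: E731

    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for fam in families:
        if not fam.aligned:
            raise SupermatrixError(f"family {fam.family_id} is not aligned")
        L = fam.n_sites
        per_species: dict[str, str] = {}
        for m in fam.members:
            sp = mapping(m.leaf)
            if sp in per_species:
                raise SupermatrixError(
                    f"family {fam.family_id}: two sequences for species {sp}")
            per_species[sp] = m.sequence
        for t in taxa:
            blocks[t].append(per_species.get(t, "-" * L))
        partitions.append((fam.family_id, pos + 1, pos + L))
        pos += L

    rows = {t: "".join(blocks[t]) for t in taxa}
    missing = {t: (rows[t].count("-") / pos if pos else 0.0) for t in taxa}
    return Supermatrix(list(taxa), rows, partitions, missing)


def mean_pairwise_identity(rows: dict[str, str], group_a, group_b) -> float:
    """Mean percent identity over all cross-group pairs.

    Identity per pair = identical shared non-gap columns / shared non-gap
    columns. Pairs with no shared columns are skipped with a warning; if all
    pairs are skipped this is an error.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b or group_a & group_b:
        raise SupermatrixError("groups must be disjoint and non-empty")
    idents = []
    for a in sorted(group_a):
        for b in sorted(group_b):
            ra, rb = rows[a], rows[b]
            shared = same = 0
            for x, y in zip(ra, rb):
                if x in "-X" or y in "-X":
                    continue
                shared += 1
                if x == y:
                    same += 1
            if shared == 0:
                log.warning("pair (%s, %s) shares no columns; skipped", a, b)
                continue
            idents.append(100.0 * same / shared)
    if not idents:
        raise SupermatrixError("no pair shares any columns")
    return float(np.mean(idents))


def missing_data_table(sm: Supermatrix) -> pd.DataFrame:
    return pd.DataFrame({"species": sm.taxa,
                         "missing_fraction": [sm.missing[t] for t in sm.taxa]})
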
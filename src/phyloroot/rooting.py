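"""Outgroup rooting, stem-length statistics and LBA diagnostics.

Rooting places the root at the midpoint of the stem edge (the edge whose
bipartition separates outgroup from ingroup). The inter-domain stem length
is the length of that edge — the quantity whose ratio across marker sets
measures how much faster a marker set diverged between the two domains.
Long-branch scores flag leaves whose pendant edges are outliers, and the
placement experiment reproduces the with/without-outgroup contrast that
diagnoses long-branch attraction: a fast clade pulled next to a remote
outgroup (basal position) that returns to its true sister once the outgroup
is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import TaxonomyMap
from .screen import bipartition_set, is_monophyletic
from .trees import Node, PhyloTree, TreeError
from . import treeinfer


class RootingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rooting

def _find_split_edge(tree: PhyloTree, group: frozenset[str]) -> Node:
    """Node whose subtree leafset equals ``group`` or its complement."""
    all_leaves = frozenset(tree.leaf_names)
    comp = all_leaves - group
    for node in tree.edges():
        below = tree.leafset_below(node)
        if below == group or below == comp:
            return node
    raise RootingError("no edge realizes the requested bipartition")


def root_with_outgroup(tree: PhyloTree, outgroup) -> PhyloTree:
    """Root on the stem edge, splitting its length equally.

    Errors if the outgroup is not monophyletic (listing the closest split as
    evidence).
    """
    outgroup = frozenset(outgroup)
    all_leaves = frozenset(tree.leaf_names)
    if not outgroup or outgroup == all_leaves:
        raise RootingError("outgroup and ingroup must both be non-empty")
    unknown = outgroup - all_leaves
    if unknown:
        raise RootingError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if not is_monophyletic(tree, outgroup):
        best, overlap = None, -1
        for split in bipartition_set(tree):
            for side in (split, all_leaves - split):
                ov = len(side & outgroup) - len(side - outgroup)
                if ov > overlap:
                    best, overlap = side, ov
        raise RootingError(
            f"outgroup is not monophyletic; closest split contains "
            f"{sorted(best & outgroup)} plus {sorted(best - outgroup)}")
    if len(outgroup) == 1:
        node = tree.find_leaf(next(iter(outgroup)))
    else:
        node = _find_split_edge(tree, outgroup)
        below = tree.leafset_below(node)
        if below != outgroup:
            # the edge is the same; hang the root from the outgroup side
            node = _find_split_edge(tree, frozenset(tree.leaf_names) - below)
            if tree.leafset_below(node) != outgroup:
                node = _find_split_edge(tree, outgroup)
    return tree.reroot_on_edge(node)


def interdomain_stem_length(tree: PhyloTree, group_a, group_b) -> float:
    """Length of the edge separating two exhaustive monophyletic groups.

    For a rooted tree whose root subdivides the stem, the two root-child
    edges are summed back into one stem. Symmetric in the two groups.
    """
    group_a, group_b = frozenset(group_a), frozenset(group_b)
    all_leaves = frozenset(tree.leaf_names)
    if group_a | group_b != all_leaves or group_a & group_b:
        raise RootingError("groups must partition the leaves")
    for g in (group_a, group_b):
        if not is_monophyletic(tree, g):
            raise RootingError(f"group {sorted(g)[:4]}... is not monophyletic")
    if tree.rooted:
        a, b = tree.root.children
        if tree.leafset_below(a) in (group_a, group_b):
            return a.length + b.length
        tree = tree.unroot()
    node = _find_split_edge(tree, group_a)
    return node.length


def stem_ratio(tree_1: PhyloTree, tree_2: PhyloTree, group_a, group_b
               ) -> float:
    """stem(tree_1) / stem(tree_2) over the shared group partition."""
    s1 = interdomain_stem_length(tree_1, group_a, group_b)
    s2 = interdomain_stem_length(tree_2, group_a, group_b)
    if s2 == 0:
        raise RootingError("zero stem length in denominator")
    return s1 / s2


# ---------------------------------------------------------------------------
# long-branch diagnostics

def long_branch_flags(tree: PhyloTree, z_threshold: float = 3.0
                      ) -> dict[str, tuple[float, bool]]:
    """Per-leaf score = pendant length / median pendant length; flag when the
    robust z (median/MAD, scaled) exceeds the threshold.

    Pendant edges do not change under rerooting, so flags are
    rooting-invariant.
    """
    leaves = tree.leaves()
    if len(leaves) < 4:
        raise RootingError("need at least 4 leaves")
    pend = np.array([l.length for l in leaves])
    med = float(np.median(pend))
    scores = pend / med if med > 0 else np.ones_like(pend)
    smed = float(np.median(scores))
    mad = float(np.median(np.abs(scores - smed)))
    if mad == 0:
        z = np.where(scores > smed, np.inf, 0.0)
        z[scores == smed] = 0.0
    else:
        z = (scores - smed) / (1.4826 * mad)
    return {l.name: (float(s), bool(zz > z_threshold))
            for l, s, zz in zip(leaves, scores, z)}


# ---------------------------------------------------------------------------
# placement experiments

@dataclass
class PlacementOutcome:
    focal: frozenset[str]
    condition: str                      # "with_outgroup" | "without_outgroup"
    monophyletic: bool
    sister: str | None                  # class-majority label, spec'd proxy
    support: float | None               # bootstrap support of the focal clade
    basal: bool | None = None           # focal ∪ outgroup monophyletic
    tree: PhyloTree | None = None


def _sister_label(tree: PhyloTree, focal: frozenset[str],
                  taxonomy: TaxonomyMap) -> str | None:
    """Class-majority label of the smallest clade across the focal clade's
    attachment edge."""
    try:
        node = (tree.find_leaf(next(iter(focal))) if len(focal) == 1
                else _find_split_edge(tree, focal))
    except RootingError:
        return None
    if tree.leafset_below(node) != focal:
        return None
    sibling_sets = []
    parent = node.parent
    if parent is None:
        return None
    for sib in parent.children:
        if sib is not node:
            sibling_sets.append(tree.leafset_below(sib))
    above = frozenset(tree.leaf_names) - tree.leafset_below(parent)
    if above:
        sibling_sets.append(above)
    smallest = min(sibling_sets, key=lambda s: (len(s), sorted(s)))
    classes = [taxonomy.resolve(l).class_ for l in smallest]
    vals, counts = np.unique(classes, return_counts=True)
    return str(vals[np.argmax(counts)])


def placement_experiment(seqs: dict[str, str], taxonomy: TaxonomyMap,
                         focal, conditions=("with_outgroup",
                                            "without_outgroup"),
                         B: int = 50, seed: int = 0,
                         correction: str = "ml-poisson",
                         alpha: float | None = None,
                         keep_trees: bool = False
                         ) -> list[PlacementOutcome]:
    """Infer the focal group's placement with and without the outgroup.

    For each condition the alignment is pruned, an NJ tree with bootstrap
    supports is built, and the outcome records focal monophyly, the sister
    label, the support of the focal clade, and whether the focal group
    attaches basally (focal ∪ outgroup monophyletic — only defined with the
    outgroup present). Deterministic given the seed.
    """
    focal = frozenset(focal)
    if not focal:
        raise RootingError("focal set must be non-empty")
    all_taxa = set(seqs)
    outgroup = {t for t in all_taxa if taxonomy.is_outgroup(t)}
    if focal & outgroup:
        raise RootingError("focal taxa must be ingroup")
    outcomes = []
    for ci, cond in enumerate(conditions):
        if cond == "with_outgroup":
            taxa = all_taxa
        elif cond == "without_outgroup":
            taxa = all_taxa - outgroup
        else:
            raise RootingError(f"unknown condition {cond!r}")
        sub = {t: seqs[t] for t in sorted(taxa)}
        tree = treeinfer.bootstrap_support(sub, B=B, seed=[seed, ci],
                                           correction=correction, alpha=alpha)
        mono = is_monophyletic(tree, focal)
        sister = _sister_label(tree, focal, taxonomy) if mono else None
        support = None
        if mono and len(focal) >= 2:
            for node in tree.edges():
                if tree.leafset_below(node) == focal:
                    support = node.support
                    break
        basal = None
        if cond == "with_outgroup" and outgroup:
            basal = is_monophyletic(tree, focal | outgroup)
        outcomes.append(PlacementOutcome(
            focal=focal, condition=cond, monophyletic=mono, sister=sister,
            support=support, basal=basal, tree=tree if keep_trees else None))
    return outcomes


# ---------------------------------------------------------------------------
# rooting report

@dataclass
class RootingReport:
    root_children: list[dict]           # composition of the two root clades
    stem_length: float
    ingroup_support: float | None
    side_supports: list[float | None]
    long_branch: dict[str, tuple[float, bool]]
    straddling_classes: list[str]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "root_children": self.root_children,
            "stem_length": self.stem_length,
            "ingroup_support": self.ingroup_support,
            "side_supports": self.side_supports,
            "long_branch": {k: {"score": s, "flagged": f}
                            for k, (s, f) in self.long_branch.items()},
            "straddling_classes": self.straddling_classes,
            "notes": self.notes,
        }


def root_report(rooted: PhyloTree, taxonomy: TaxonomyMap,
                z_threshold: float = 3.0) -> RootingReport:
    """Describe a rooted tree: the two root-adjacent clades by domain/class
    composition, the stem length, supports (copied from the tree), classes
    straddling the root, and long-branch flags."""
    if not rooted.rooted:
        raise RootingError("root_report requires a rooted tree")
    a, b = rooted.root.children
    sides = []
    side_classes = []
    for child in (a, b):
        leaves = sorted(rooted.leafset_below(child))
        domains = sorted({taxonomy.resolve(l).domain for l in leaves})
        classes = sorted({taxonomy.resolve(l).class_ for l in leaves})
        side_classes.append(set(classes))
        sides.append({"n_leaves": len(leaves), "domains": domains,
                      "classes": classes})
    straddlers = sorted(side_classes[0] & side_classes[1])
    ingroup_support = None
    if taxonomy.outgroup_domain is not None:
        for child, side in zip((a, b), sides):
            if taxonomy.outgroup_domain not in side["domains"]:
                ingroup_support = child.support
    return RootingReport(
        root_children=sides,
        stem_length=a.length + b.length,
        ingroup_support=ingroup_support,
        side_supports=[a.support, b.support],
        long_branch=long_branch_flags(rooted, z_threshold),
        straddling_classes=straddlers,
    )
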
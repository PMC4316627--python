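"""Taxonomic-consistency screening of gene trees.

The funnel a curator applies by eye — are the classes monophyletic? is there
evidence of transfer between domains, or recent transfer within the
outgroup? are there paralogs? — reified as deterministic, purely topological
tests on unrooted gene trees. Monophyly follows the unrooted convention: a
leaf set is monophyletic iff some edge's bipartition isolates exactly that
set. Screening decisions are invariant to leaf order and to rooting of the
input tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats import TaxonomyMap
from .markers import FilterCriteria
from .simulate import GeneFamily
from .trees import PhyloTree, TreeError


# ---------------------------------------------------------------------------
# bipartition algebra

def bipartition_set(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial splits of the tree, one per internal edge.

    Canonical form: the side NOT containing the reference leaf (the
    lexicographically smallest label). The two edges incident to a rooted
    tree's root describe the same split and are reported once.
    """
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    out = set()
    for node in tree.edges():
        side = tree.leafset_below(node)
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def is_monophyletic(tree: PhyloTree, leaves) -> bool:
    """Unrooted monophyly: true iff trivial or some split isolates the set."""
    leaves = frozenset(leaves)
    all_leaves = frozenset(tree.leaf_names)
    unknown = leaves - all_leaves
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    if len(leaves) <= 1 or leaves == all_leaves:
        return True
    if len(leaves) == len(all_leaves) - 1:
        return True   # complement of a single leaf's pendant edge
    ref = min(all_leaves)
    canon = all_leaves - leaves if ref in leaves else leaves
    return canon in bipartition_set(tree)


# ---------------------------------------------------------------------------
# per-check reports

def class_monophyly_report(tree: PhyloTree, taxonomy: TaxonomyMap,
                           scope: str | set[str] | None = None
                           ) -> dict[str, bool]:
    """Monophyly verdict for every class inside the scoped domain(s).

    Tested on the full tree (a class must form a clean split against
    everything, outgroup included). Classes with a single leaf are
    vacuously true. ``scope=None`` means all ingroup domains.
    """
    if scope is None:
        if taxonomy.outgroup_domain is None:
            raise TreeError("scope=None requires a declared outgroup domain")
        domains = taxonomy.domains - {taxonomy.outgroup_domain}
    elif isinstance(scope, str):
        domains = {scope}
    else:
        domains = set(scope)
    by_class: dict[str, set[str]] = {}
    for leaf in tree.leaf_names:
        rec = taxonomy.resolve(leaf)
        if rec.domain in domains:
            by_class.setdefault(rec.class_, set()).add(leaf)
    return {cls: (len(lv) < 2 or is_monophyletic(tree, lv))
            for cls, lv in sorted(by_class.items())}


def _domain_partition(tree: PhyloTree, taxonomy: TaxonomyMap):
    ing, out = set(), set()
    for leaf in tree.leaf_names:
        (out if taxonomy.is_outgroup(leaf) else ing).add(leaf)
    return ing, out


def _split_violation(tree: PhyloTree, ingroup: set[str], outgroup: set[str]
                     ) -> int:
    """Smallest number of misplaced leaves over all edges (0 = clean split)."""
    best = min(len(ingroup), len(outgroup))
    all_leaves = frozenset(tree.leaf_names)
    for node in tree.edges():
        side = set(tree.leafset_below(node))
        other = all_leaves - side
        mis = min(len(ingroup & side) + len(outgroup & other),
                  len(ingroup & other) + len(outgroup & side))
        best = min(best, mis)
    return best


def detect_interdomain_hgt(tree: PhyloTree, taxonomy: TaxonomyMap,
                           max_candidates: int = 5):
    """Flag when the tree has no clean ingroup|outgroup split.

    Candidates: a greedy minimal leaf set whose removal restores the domain
    split (remove the leaf that most reduces the violation count; iterate up
    to ``max_candidates``). Returns ``(flag, candidates)``; when one domain
    is absent the check is not applicable and returns ``(None, [])``.
    """
    ingroup, outgroup = _domain_partition(tree, taxonomy)
    if not ingroup or not outgroup:
        return None, []
    if is_monophyletic(tree, outgroup):
        return False, []
    candidates: list[str] = []
    current = tree
    ing, out = set(ingroup), set(outgroup)
    for _ in range(max_candidates):
        score = _split_violation(current, ing, out)
        if score == 0:
            break
        best_leaf, best_score = None, None
        for leaf in sorted(current.leaf_names):
            rest = [l for l in current.leaf_names if l != leaf]
            sub = current.restrict(rest)
            s = _split_violation(sub, ing - {leaf}, out - {leaf})
            if best_score is None or s < best_score:
                best_leaf, best_score = leaf, s
        candidates.append(best_leaf)
        ing.discard(best_leaf)
        out.discard(best_leaf)
        current = current.restrict([l for l in current.leaf_names
                                    if l != best_leaf])
    return True, candidates


def detect_outgroup_internal_hgt(tree: PhyloTree, taxonomy: TaxonomyMap):
    """Recent transfer inside the outgroup: any outgroup phylum with >= 2
    members that is non-monophyletic on the outgroup-restricted tree.

    Deep inter-phylum order is not tested (only "recent" events). Returns
    ``(flag, violated_phyla)``.
    """
    _, outgroup = _domain_partition(tree, taxonomy)
    if not outgroup:
        return None, []
    by_phylum: dict[str, set[str]] = {}
    for leaf in outgroup:
        by_phylum.setdefault(taxonomy.resolve(leaf).phylum, set()).add(leaf)
    multi = {p: lv for p, lv in by_phylum.items() if len(lv) >= 2}
    if not multi or len(outgroup) < 4:
        return False, []
    sub = tree.restrict(outgroup)
    violated = sorted(p for p, lv in multi.items()
                      if not is_monophyletic(sub, lv))
    return bool(violated), violated


def _pure_block_count(tree: PhyloTree, leaves: set[str]) -> int:
    """Number of maximal subtrees whose leaf sets are pure ``leaves``."""
    if is_monophyletic(tree, leaves):
        return 1

    pure: dict[int, bool] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            pure[id(node)] = node.name in leaves
        else:
            pure[id(node)] = all(pure[id(c)] for c in node.children)
    blocks = 0
    for node in tree.nodes():
        if pure[id(node)] and (node.parent is None
                               or not pure[id(node.parent)]):
            blocks += 1
    return blocks


def detect_paralogy(family: GeneFamily, tree: PhyloTree,
                    taxonomy: TaxonomyMap):
    """Paralogy flag: (a) any species contributing >= 2 sequences, or
    (b) a class splitting into >= 2 class-pure blocks while the family has
    copy-number evidence (rule b never fires without a multi-copy species;
    a bare class split is charged to monophyly failure / HGT instead).

    Returns ``(flag, offending_species)``.
    """
    counts: dict[str, int] = {}
    for m in family.members:
        sp = taxonomy.resolve(m.leaf).species
        counts[sp] = counts.get(sp, 0) + 1
    offenders = sorted(sp for sp, c in counts.items() if c >= 2)
    # rule (b) — class splits — only counts with copy-number evidence, and
    # rule (a) already fires in that case; without multi-copy species a
    # class split is charged to the monophyly check instead.
    return (True, offenders) if offenders else (False, [])


# ---------------------------------------------------------------------------
# family-level verdict

ALL_CHECKS = frozenset({"class_monophyly", "interdomain_hgt",
                        "outgroup_internal_hgt", "paralogy", "coverage"})


@dataclass
class ScreenReport:
    family_id: str
    class_monophyly: dict[str, bool]
    interdomain_hgt: bool | None
    interdomain_candidates: list[str]
    outgroup_internal_hgt: bool | None
    violated_phyla: list[str]
    paralogy: bool
    paralog_species: list[str]
    n_ingroup_species: int
    n_outgroup_phyla: int
    verdict: str = "retain"
    reasons: list[str] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return self.verdict == "retain"

    def to_row(self) -> dict:
        return {
            "family": self.family_id,
            "classes_ok": all(self.class_monophyly.values()),
            "interdomain_hgt": self.interdomain_hgt,
            "outgroup_internal_hgt": self.outgroup_internal_hgt,
            "paralogy": self.paralogy,
            "n_ingroup_species": self.n_ingroup_species,
            "n_outgroup_phyla": self.n_outgroup_phyla,
            "verdict": self.verdict,
            "reasons": ";".join(self.reasons),
        }


def screen_family(family: GeneFamily, tree: PhyloTree, taxonomy: TaxonomyMap,
                  criteria: FilterCriteria | None = None,
                  enforce: frozenset[str] = ALL_CHECKS) -> ScreenReport:
    """Run every check on one family and decide retain/reject.

    The verdict is ``retain`` iff every enforced check passes and the
    coverage thresholds (distinct ingroup species, distinct outgroup phyla)
    hold.
    """
    criteria = criteria or FilterCriteria()
    for leaf in tree.leaf_names:
        taxonomy.resolve(leaf)   # raises on taxonomy gaps

    classes = class_monophyly_report(tree, taxonomy)
    inter_flag, inter_cand = detect_interdomain_hgt(tree, taxonomy)
    og_flag, og_phyla = detect_outgroup_internal_hgt(tree, taxonomy)
    par_flag, par_species = detect_paralogy(family, tree, taxonomy)

    leaves = tree.leaf_names
    ingroup_species = {taxonomy.resolve(l).species for l in leaves
                       if not taxonomy.is_outgroup(l)}
    outgroup_phyla = {taxonomy.resolve(l).phylum for l in leaves
                      if taxonomy.is_outgroup(l)}

    reasons = []
    if "class_monophyly" in enforce and not all(classes.values()):
        bad = sorted(c for c, ok in classes.items() if not ok)
        reasons.append(f"class_monophyly:{','.join(bad)}")
    if "interdomain_hgt" in enforce and inter_flag:
        reasons.append("interdomain_hgt")
    if "outgroup_internal_hgt" in enforce and og_flag:
        reasons.append("outgroup_internal_hgt")
    if "paralogy" in enforce and par_flag:
        reasons.append("paralogy")
    if "coverage" in enforce:
        if len(ingroup_species) < criteria.min_archaeal_members:
            reasons.append("min_archaeal_members")
        if (criteria.min_outgroup_phyla is not None
                and len(outgroup_phyla) < criteria.min_outgroup_phyla):
            reasons.append("min_outgroup_phyla")

    return ScreenReport(
        family_id=family.family_id,
        class_monophyly=classes,
        interdomain_hgt=inter_flag,
        interdomain_candidates=inter_cand,
        outgroup_internal_hgt=og_flag,
        violated_phyla=og_phyla,
        paralogy=par_flag,
        paralog_species=par_species,
        n_ingroup_species=len(ingroup_species),
        n_outgroup_phyla=len(outgroup_phyla),
        verdict="reject" if reasons else "retain",
        reasons=reasons,
    )


def select_markers(reports: list[ScreenReport]) -> list[str]:
    """Ids of retained families, stable input order."""
    return [r.family_id for r in reports if r.retained]
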
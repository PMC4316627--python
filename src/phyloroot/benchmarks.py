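"""Simulation studies that score the pipeline against planted truth.

Four studies, mirroring the analysis's central claims at desk scale:

* screening power — retain/reject precision and recall of the gene-tree
  screen on a benchmark with planted HGT/paralogy/partiality;
* root recovery — how often a clean two-kingdom dataset roots on the
  ingroup|outgroup stem with high bootstrap support;
* stem recovery — accuracy of the inter-domain stem length and of the
  stem-length ratio between two marker sets;
* LBA contrast — a fast-evolving focal clade plus remote outgroup: basal
  attachment with the outgroup, true-sister attachment without it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from . import rooting, screen, treeinfer
from .markers import FilterCriteria, flag_partials
from .simulate import (Benchmark, WorldConfig, evolve_alignment,
                       make_benchmark, sample_species_tree)
from .models import SubstitutionModel
from .supermatrix import concatenate, trim_alignment
from .trees import PhyloTree


# ---------------------------------------------------------------------------
# screening power

def expected_verdict(truth_row: dict, taxonomy, criteria: FilterCriteria,
                     all_leaves: list[str]) -> str:
    """Verdict an ideal curator who knows the planted events would reach.

    HGT or paralogy → reject. Truncations below the partial threshold remove
    the affected members; the family is then rejected iff coverage drops
    below the thresholds.
    """
    if truth_row["hgt"] or truth_row["paralog"]:
        return "reject"
    events = json.loads(truth_row["detail"]) or []
    removed = {e["leaf"] for e in events
               if e.get("type") == "truncation"
               and e["kept_fraction"] < criteria.partial_fraction}
    remaining = [l for l in all_leaves if l not in removed]
    ingroup = {taxonomy.resolve(l).species for l in remaining
               if not taxonomy.is_outgroup(l)}
    phyla = {taxonomy.resolve(l).phylum for l in remaining
             if taxonomy.is_outgroup(l)}
    if len(ingroup) < criteria.min_archaeal_members:
        return "reject"
    if (criteria.min_outgroup_phyla is not None
            and len(phyla) < criteria.min_outgroup_phyla):
        return "reject"
    return "retain"


def screen_benchmark(bench: Benchmark,
                     criteria: FilterCriteria | None = None,
                     correction: str = "ml-poisson",
                     alpha: float | None = None) -> dict:
    """Screen every benchmark family and score against the planted truth.

    Pipeline per family: partial-sequence removal, NJ gene tree on corrected
    distances, topological screen, coverage filters. Returns precision /
    recall for the retain and reject decisions plus per-event detection
    rates.
    """
    criteria = criteria or FilterCriteria()
    taxonomy = bench.taxonomy
    reports = []
    verdicts = {}
    for fam in bench.families:
        fam2 = flag_partials(fam, criteria.partial_fraction)
        tree = treeinfer.nj_tree(fam2.sequences(), correction, alpha)
        rep = screen.screen_family(fam2, tree, taxonomy, criteria)
        reports.append(rep)
        verdicts[fam.family_id] = rep.verdict

    truth = bench.truth
    all_leaves = bench.tree.leaf_names
    tp = fp = tn = fn = 0          # positive class = reject
    event_hits = {"hgt": [0, 0], "paralog": [0, 0]}
    for _, row in truth.iterrows():
        exp = expected_verdict(dict(row), taxonomy, criteria, all_leaves)
        got = verdicts[row["family"]]
        if exp == "reject" and got == "reject":
            tp += 1
        elif exp == "reject":
            fn += 1
        elif got == "reject":
            fp += 1
        else:
            tn += 1
        for ev in ("hgt", "paralog"):
            if row[ev]:
                event_hits[ev][1] += 1
                if got == "reject":
                    event_hits[ev][0] += 1

    def safe(n, d):
        return float(n) / d if d else float("nan")

    return {
        "n_families": len(truth),
        "reject_precision": safe(tp, tp + fp),
        "reject_recall": safe(tp, tp + fn),
        "retain_precision": safe(tn, tn + fn),
        "retain_recall": safe(tn, tn + fp),
        "hgt_detection_rate": safe(*event_hits["hgt"]),
        "paralog_detection_rate": safe(*event_hits["paralog"]),
        "reports": reports,
    }


# ---------------------------------------------------------------------------
# root recovery

ROOT_STUDY_CONFIG = WorldConfig(
    n_classes_per_kingdom=3, n_species_per_class=2,
    n_outgroup_phyla=9, species_per_outgroup_phylum=2,
    stem_length=0.5)


def concatenated_dataset(config: WorldConfig, n_markers: int,
                         n_sites_range=(300, 600), seed: int = 0,
                         model: SubstitutionModel | None = None):
    """Clean families on one species tree, trimmed and concatenated."""
    bench = make_benchmark(config, n_markers, event_rates=(0, 0, 0),
                           n_sites_range=n_sites_range, seed=seed,
                           model=model)
    trimmed = [trim_alignment(f)[0] for f in bench.families]
    sm = concatenate(trimmed, sorted(bench.tree.leaf_names), bench.taxonomy)
    return sm, bench


def root_recovery_study(n_seeds: int = 20, config: WorldConfig | None = None,
                        n_markers: int = 20, B: int = 100,
                        support_threshold: float = 90.0, seed: int = 0
                        ) -> dict:
    """Fraction of seeds where the clean dataset recovers the
    ingroup|outgroup root bipartition with bootstrap >= threshold."""
    base = config or ROOT_STUDY_CONFIG
    successes, supports = 0, []
    for s in range(n_seeds):
        cfg = replace(base, seed=seed + 1000 * (s + 1))
        sm, bench = concatenated_dataset(cfg, n_markers, seed=seed + s)
        outgroup = frozenset(l for l in sm.taxa
                             if bench.taxonomy.is_outgroup(l))
        tree = treeinfer.bootstrap_support(sm.rows, B=B, seed=[seed, s])
        ok = screen.is_monophyletic(tree, outgroup)
        support = 0.0
        if ok:
            for node in tree.edges():
                below = tree.leafset_below(node)
                if below == outgroup or below == frozenset(sm.taxa) - outgroup:
                    support = node.support if node.support is not None else 0.0
                    break
            if support >= support_threshold:
                successes += 1
        supports.append(support)
    return {"n_seeds": n_seeds, "n_success": successes,
            "recovery_rate": successes / n_seeds,
            "supports": supports}


# ---------------------------------------------------------------------------
# stem recovery

STEM_STUDY_CONFIG = WorldConfig(
    n_classes_per_kingdom=2, n_species_per_class=1,
    n_outgroup_phyla=4, species_per_outgroup_phylum=1,
    stem_length=0.8)


def _ml_stem(config: WorldConfig, n_sites: int, seed: int,
             model: SubstitutionModel) -> float:
    tree, taxonomy = sample_species_tree(config)
    fam = evolve_alignment(tree, model, n_sites, seed)
    seqs = fam.sequences()
    nj = treeinfer.nj_tree(seqs, "ml-poisson", model.alpha)
    ml = treeinfer.optimize_branch_lengths(nj, seqs, model)
    ingroup = frozenset(l for l in tree.leaf_names
                        if not taxonomy.is_outgroup(l))
    outgroup = frozenset(tree.leaf_names) - ingroup
    return rooting.interdomain_stem_length(ml, ingroup, outgroup)


def stem_recovery_study(n_sites: int = 20000, seed: int = 0,
                        ratio: float = 2.6,
                        model: SubstitutionModel | None = None) -> dict:
    """Recover a 0.8 substitutions/site stem with ML branch lengths, and the
    stem-length ratio between two marker sets simulated at ratio 2.6."""
    model = model or SubstitutionModel.poisson()
    stem_long = _ml_stem(STEM_STUDY_CONFIG, n_sites, seed, model)
    cfg_short = replace(STEM_STUDY_CONFIG,
                        stem_length=STEM_STUDY_CONFIG.stem_length / ratio)
    stem_short = _ml_stem(cfg_short, n_sites, seed + 1, model)
    return {
        "true_stem": STEM_STUDY_CONFIG.stem_length,
        "estimated_stem": stem_long,
        "stem_relative_error": abs(stem_long - STEM_STUDY_CONFIG.stem_length)
        / STEM_STUDY_CONFIG.stem_length,
        "true_ratio": ratio,
        "estimated_ratio": stem_long / stem_short,
    }


# ---------------------------------------------------------------------------
# LBA contrast

# two classes per kingdom: the focal class's kingdom partner is its true
# sister, so "returns to its sister" and "stays in its kingdom" coincide,
# while attraction to the inter-kingdom split or the other kingdom still
# registers as failure
LBA_STUDY_CONFIG = WorldConfig(
    n_classes_per_kingdom=2, n_species_per_class=3,
    n_outgroup_phyla=6, species_per_outgroup_phylum=1,
    stem_length=1.5, fast_clades=[("A1", 8.0)])


def _true_sister_leaves(tree: PhyloTree, taxonomy, focal: frozenset[str]
                        ) -> frozenset[str]:
    """Leaves of the focal clade's sibling in the ingroup-restricted true
    species tree."""
    ingroup = [l for l in tree.leaf_names if not taxonomy.is_outgroup(l)]
    sub = tree.restrict(ingroup)
    for node in sub.nodes():
        if sub.leafset_below(node) == focal and node.parent is not None:
            sibs = [c for c in node.parent.children if c is not node]
            if sibs:
                return frozenset().union(*[sub.leafset_below(s) for s in sibs])
    # focal hangs off the basal node: sibling = rest of ingroup
    return frozenset(ingroup) - focal


def lba_contrast_study(n_replicates: int = 20,
                       config: WorldConfig | None = None,
                       n_sites: int = 2000, seed: int = 0,
                       correction: str = "p", alpha: float | None = None,
                       B: int = 20) -> dict:
    """With/without-outgroup placement of a fast (x8) focal clade.

    A replicate shows the LBA contrast when the focal clade attaches
    basally (focal ∪ outgroup monophyletic) with the outgroup present AND
    next to its true sister with the outgroup removed. Uncorrected
    p-distances drive the with-outgroup attraction, the classic conditions
    for the artifact.
    """
    base = config or LBA_STUDY_CONFIG
    model = SubstitutionModel.poisson()
    n_basal = n_sister = n_contrast = 0
    for r in range(n_replicates):
        cfg = replace(base, seed=seed + 7000 + r)
        tree, taxonomy = sample_species_tree(cfg)
        focal = frozenset(l for l in tree.leaf_names
                          if taxonomy.resolve(l).class_ == "A1")
        fam = evolve_alignment(tree, model, n_sites, seed + 90000 + r)
        outcomes = rooting.placement_experiment(
            fam.sequences(), taxonomy, focal, B=B, seed=seed + r,
            correction=correction, alpha=alpha, keep_trees=True)
        with_og = next(o for o in outcomes if o.condition == "with_outgroup")
        without = next(o for o in outcomes
                       if o.condition == "without_outgroup")
        basal = bool(with_og.basal)
        sister_true = _true_sister_leaves(tree, taxonomy, focal)
        sister_ok = (without.monophyletic and without.tree is not None
                     and screen.is_monophyletic(without.tree,
                                                focal | sister_true))
        n_basal += basal
        n_sister += sister_ok
        n_contrast += basal and sister_ok
    return {"n_replicates": n_replicates,
            "basal_rate": n_basal / n_replicates,
            "true_sister_rate": n_sister / n_replicates,
            "contrast_rate": n_contrast / n_replicates}
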
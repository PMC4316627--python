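"""Synthetic gene-family generator with planted evolutionary events.

The generator emulates the statistical structure a domain-level rooting
analysis has to cope with: an ingroup of two "kingdoms", each containing
several monophyletic classes of species, plus a taxonomically broad outgroup
(many phyla) joined to the ingroup by a long stem branch. Sequences evolve
along the species tree under a reversible amino-acid model with discrete
gamma rate heterogeneity. On top of the clean families, events are planted
with a ground-truth log:

* HGT — a recipient's sequence is replaced by a donor's sequence re-evolved
  over a short branch (sequence replacement, not topology surgery), which
  produces exactly the "intermixed" gene-tree signal screening targets;
* paralogy — a species gains a second, diverged copy;
* partiality / genome reduction — truncation or masking replaces sites with
  gaps, or whole members are lost;
* rate acceleration — whole clades evolve with a branch-length multiplier,
  producing DPANN-like long branches.

Randomness: a single root seed; per-family generators derive from
``numpy.random.default_rng([root_seed, family_index, stage])`` so any family
is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import TaxonomyMap, TaxonRecord
from .models import SubstitutionModel
from .trees import Node, PhyloTree, TreeError


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration and containers

@dataclass
class WorldConfig:
    """Shape and depth of the simulated world.

    Defaults mirror the desk-scale study conditions: two ingroup kingdoms of
    three classes x three species, and 24 single-species outgroup phyla (so
    the default outgroup-coverage threshold of 24 phyla is attainable), with
    a 0.5 substitutions/site stem separating ingroup from outgroup.
    """

    n_classes_per_kingdom: int = 3
    n_species_per_class: int = 3
    n_outgroup_phyla: int = 24
    species_per_outgroup_phylum: int = 1
    stem_length: float = 0.5
    ingroup_depth: float = 1.0
    outgroup_depth: float = 1.0
    fast_clades: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0
    ingroup_domains: tuple[str, str] = ("Euryarchaeota", "Proteoarchaeota")
    outgroup_domain: str = "Bacteria"

    def __post_init__(self):
        for name in ("n_classes_per_kingdom", "n_species_per_class",
                     "n_outgroup_phyla", "species_per_outgroup_phylum"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("stem_length", "ingroup_depth", "outgroup_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for sel, mult in self.fast_clades:
            if mult < 1:
                raise ConfigError(f"rate multiplier for {sel!r} must be >= 1")


@dataclass
class FamilyMember:
    leaf: str
    sequence: str
    is_partial: bool = False


@dataclass
class GeneFamily:
    """One marker family; ``truth`` is the planted-event log (synthetic data
    always carries one, possibly empty)."""

    family_id: str
    members: list[FamilyMember]
    aligned: bool = True
    truth: list[dict] | None = None

    def __post_init__(self):
        if self.aligned and self.members:
            L = len(self.members[0].sequence)
            if any(len(m.sequence) != L for m in self.members):
                raise ConfigError(
                    f"family {self.family_id}: aligned members differ in length")

    @property
    def leaves(self) -> list[str]:
        return [m.leaf for m in self.members]

    @property
    def n_sites(self) -> int:
        if not self.aligned:
            raise ConfigError("unaligned family has no common site count")
        return len(self.members[0].sequence) if self.members else 0

    def member(self, leaf: str) -> FamilyMember:
        for m in self.members:
            if m.leaf == leaf:
                return m
        raise KeyError(f"no member {leaf!r} in family {self.family_id}")

    def sequences(self) -> dict[str, str]:
        return {m.leaf: m.sequence for m in self.members}

    def copy(self) -> "GeneFamily":
        return GeneFamily(self.family_id,
                          [replace(m) for m in self.members],
                          self.aligned,
                          None if self.truth is None else [dict(e) for e in self.truth])


# ---------------------------------------------------------------------------
# species tree

def _join_random(subtrees: list[Node], rng: np.random.Generator,
                 internal_len: Callable[[], float]) -> Node:
    """Randomly join subtrees pairwise into one binary subtree root."""
    nodes = list(subtrees)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        m = Node(None, internal_len())
        m.add(a)
        m.add(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [m]
    return nodes[0]


def sample_species_tree(config: WorldConfig) -> tuple[PhyloTree, TaxonomyMap]:
    """Draw the species tree and matching taxonomy for a world config.

    The returned tree is unrooted (basal trifurcation: kingdom A, kingdom B,
    outgroup); the edge to the outgroup subtree has length ``stem_length``,
    so the ingroup|outgroup bipartition edge is exactly the stem. Every class
    and every outgroup phylum is monophyletic by construction. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    entries: dict[str, TaxonRecord] = {}

    def uni(lo, hi, scale=1.0):
        return lambda: float(rng.uniform(lo, hi)) * scale

    def species_clade(labels: list[str], pendant, internal) -> Node:
        leaves = [Node(l, pendant()) for l in labels]
        if len(leaves) == 1:
            return leaves[0]
        return _join_random(leaves, rng, internal)

    # classes are deep, tight radiations: within-class edges are an order of
    # magnitude shorter than the stems separating classes
    d = config.ingroup_depth
    kingdom_roots = []
    for code, domain in zip("AB", config.ingroup_domains):
        class_roots = []
        for ci in range(config.n_classes_per_kingdom):
            class_label = f"{code}{ci + 1}"
            species = [f"{class_label}_s{si + 1}"
                       for si in range(config.n_species_per_class)]
            for sp in species:
                entries[sp] = TaxonRecord(sp, class_label, domain, domain)
            croot = species_clade(species, uni(0.02, 0.06, d), uni(0.01, 0.03, d))
            croot.length += float(rng.uniform(0.15, 0.30)) * d  # class stem
            class_roots.append(croot)
        kroot = (_join_random(class_roots, rng, uni(0.05, 0.15, d))
                 if len(class_roots) > 1 else class_roots[0])
        kroot.length += float(rng.uniform(0.15, 0.25)) * d      # kingdom stem
        kingdom_roots.append(kroot)

    do = config.outgroup_depth
    phylum_roots = []
    for pi in range(config.n_outgroup_phyla):
        phylum = f"P{pi + 1:02d}"
        species = [f"{phylum}_s{si + 1}"
                   for si in range(config.species_per_outgroup_phylum)]
        for sp in species:
            entries[sp] = TaxonRecord(sp, phylum, phylum, config.outgroup_domain)
        proot = species_clade(species, uni(0.02, 0.06, do), uni(0.01, 0.03, do))
        proot.length += float(rng.uniform(0.10, 0.20)) * do     # phylum stem
        phylum_roots.append(proot)
    outgroup_root = (_join_random(phylum_roots, rng, uni(0.03, 0.10, do))
                     if len(phylum_roots) > 1 else phylum_roots[0])
    outgroup_root.length = config.stem_length

    basal = Node(None, 0.0)
    for kr in kingdom_roots:
        basal.add(kr)
    basal.add(outgroup_root)
    tree = PhyloTree(basal)
    taxonomy = TaxonomyMap(entries, outgroup_domain=config.outgroup_domain)

    for selector, mult in config.fast_clades:
        leaves = clade_leaves(taxonomy, selector)
        node = _mrca_exact(tree, leaves)
        # the whole lineage accelerates from its origin: the clade's stem
        # edge and every edge inside the clade
        node.length *= mult
        tree.scale_subtree(node, mult)
    return tree, taxonomy


def clade_leaves(taxonomy: TaxonomyMap, selector: str) -> set[str]:
    """Leaves whose class, phylum, domain, or kingdom code match ``selector``.

    Kingdom codes "A"/"B" address the first/second ingroup domain.
    """
    hits = set()
    for leaf, rec in taxonomy.entries.items():
        if selector in (leaf, rec.species, rec.class_, rec.phylum, rec.domain):
            hits.add(leaf)
        elif selector in ("A", "B") and rec.class_.startswith(selector):
            hits.add(leaf)
    if not hits:
        raise ConfigError(f"clade selector {selector!r} matches no leaf")
    return hits


def _mrca_exact(tree: PhyloTree, leaves: set[str]) -> Node:
    for n in tree.nodes():
        if tree.leafset_below(n) == frozenset(leaves):
            return n
    raise TreeError(f"no node subtends exactly {sorted(leaves)[:4]}...")


# ---------------------------------------------------------------------------
# sequence evolution

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _encode(seq: str, states: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(states)}
    return np.array([lut.get(c, -1) for c in seq], dtype=np.int64)


def _evolve_states(parent: np.ndarray, cats: np.ndarray, length: float,
                   model: SubstitutionModel, rates: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states and per-site categories."""
    child = parent.copy()
    for c in range(len(rates)):
        idx = np.nonzero(cats == c)[0]
        if idx.size == 0:
            continue
        P = model.transition_matrix(length, rates[c])
        C = np.cumsum(P, axis=1)
        u = rng.random(idx.size)
        child[idx] = (u[:, None] > C[parent[idx]]).sum(axis=1)
    return child


def evolve_alignment(tree: PhyloTree, model: SubstitutionModel, n_sites: int,
                     seed, family_id: str = "fam") -> GeneFamily:
    """Simulate an aligned family along the tree (no indel process).

    The root sequence is drawn from the equilibrium frequencies; each site is
    assigned one gamma category for the whole history; descendant states are
    drawn from exp(Q·t·rate). Branch lengths are expected substitutions/site.
    """
    if n_sites <= 0:
        raise ConfigError("n_sites must be positive")
    rng = _as_rng(seed)
    rates = model.category_rates()
    cats = rng.integers(0, len(rates), size=n_sites)
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(model.n_states, size=n_sites,
                                       p=model.frequencies)
    members = []
    for node in tree.nodes():
        if node is not tree.root:
            states[id(node)] = _evolve_states(states[id(node.parent)], cats,
                                              node.length, model, rates, rng)
        if node.is_leaf:
            seq = "".join(model.states[s] for s in states[id(node)])
            members.append(FamilyMember(node.name, seq))
    return GeneFamily(family_id, members, aligned=True, truth=[])


def _reevolve(seq: str, divergence: float, model: SubstitutionModel,
              rng: np.random.Generator) -> str:
    """Evolve a copy of ``seq`` along a branch; gaps stay gaps."""
    states = _encode(seq, model.states)
    ok = states >= 0
    rates = model.category_rates()
    cats = rng.integers(0, len(rates), size=states.size)
    out = states.copy()
    if divergence > 0 and ok.any():
        evolved = _evolve_states(np.where(ok, states, 0), cats, divergence,
                                 model, rates, rng)
        out[ok] = evolved[ok]
    chars = [model.states[s] if o else seq[i]
             for i, (s, o) in enumerate(zip(out, ok))]
    return "".join(chars)


def inject_hgt(family: GeneFamily, tree: PhyloTree, donor_leaf: str,
               recipient_leaf: str, divergence: float,
               model: SubstitutionModel, seed) -> GeneFamily:
    """Replace the recipient's sequence by the donor's, re-evolved over
    ``divergence`` substitutions/site. Logged in the truth table."""
    if divergence < 0:
        raise ConfigError("divergence must be >= 0")
    fam = family.copy()
    donor = fam.member(donor_leaf)
    recipient = fam.member(recipient_leaf)
    rng = _as_rng(seed)
    recipient.sequence = _reevolve(donor.sequence, divergence, model, rng)
    if fam.truth is not None:
        fam.truth.append({"type": "hgt", "donor": donor_leaf,
                          "recipient": recipient_leaf,
                          "divergence": divergence})
    return fam


def inject_paralogy(family: GeneFamily, species: str, divergence: float,
                    model: SubstitutionModel, seed) -> GeneFamily:
    """Add a second, diverged copy for ``species`` (leaf id ``species__2``,
    counting up). The copy sits 2x divergence from the original."""
    if divergence < 0:
        raise ConfigError("divergence must be >= 0")
    fam = family.copy()
    source = fam.member(species)   # raises KeyError if absent
    k = 2
    while any(m.leaf == f"{species}__{k}" for m in fam.members):
        k += 1
    new_leaf = f"{species}__{k}"
    rng = _as_rng(seed)
    seq = _reevolve(source.sequence, 2.0 * divergence, model, rng)
    fam.members.append(FamilyMember(new_leaf, seq, source.is_partial))
    if fam.truth is not None:
        fam.truth.append({"type": "duplication", "species": species,
                          "new_leaf": new_leaf, "divergence": divergence})
    return fam


def degrade(family: GeneFamily, selector, mode: str, seed,
            fraction: float | None = None) -> GeneFamily:
    """Remove members (``loss``), truncate to a contiguous ``fraction`` of
    sites (``truncate``), or gap out a random site fraction (``mask``).

    ``selector`` is a leaf id, an iterable of leaf ids, or a predicate on
    leaf ids.
    """
    if callable(selector):
        leaves = [m.leaf for m in family.members if selector(m.leaf)]
    elif isinstance(selector, str):
        leaves = [selector]
    else:
        leaves = list(selector)
    present = {m.leaf for m in family.members}
    missing = [l for l in leaves if l not in present]
    if missing or not leaves:
        raise ConfigError(f"selector resolves to absent members: {missing}")
    if mode in ("truncate", "mask"):
        if fraction is None or not 0.0 < fraction < 1.0:
            raise ConfigError("fraction must be in (0, 1)")

    fam = family.copy()
    rng = _as_rng(seed)
    if mode == "loss":
        fam.members = [m for m in fam.members if m.leaf not in leaves]
        if fam.truth is not None:
            fam.truth.append({"type": "loss", "leaves": leaves})
        return fam
    for leaf in leaves:
        m = fam.member(leaf)
        L = len(m.sequence)
        if mode == "truncate":
            keep = max(1, int(round(fraction * L)))
            start = int(rng.integers(0, L - keep + 1))
            m.sequence = ("-" * start + m.sequence[start:start + keep]
                          + "-" * (L - start - keep))
            m.is_partial = True
            if fam.truth is not None:
                fam.truth.append({"type": "truncation", "leaf": leaf,
                                  "kept_fraction": fraction})
        elif mode == "mask":
            n_mask = int(round(fraction * L))
            idx = rng.choice(L, size=n_mask, replace=False)
            chars = list(m.sequence)
            for i in idx:
                chars[i] = "-"
            m.sequence = "".join(chars)
            if fam.truth is not None:
                fam.truth.append({"type": "mask", "leaf": leaf,
                                  "fraction": fraction})
        else:
            raise ConfigError(f"unknown degrade mode {mode!r}")
    return fam


# ---------------------------------------------------------------------------
# benchmark generator

@dataclass
class Benchmark:
    families: list[GeneFamily]
    truth: pd.DataFrame
    tree: PhyloTree
    taxonomy: TaxonomyMap
    model: SubstitutionModel
    config: WorldConfig


def make_benchmark(config: WorldConfig, n_families: int,
                   event_rates: tuple[float, float, float] = (0.2, 0.1, 0.1),
                   n_sites_range: tuple[int, int] = (300, 600),
                   seed: int = 0,
                   model: SubstitutionModel | None = None,
                   hgt_divergence: float = 0.02,
                   paralog_divergence: float = 0.02,
                   truncate_keep: tuple[float, float] = (0.25, 0.45),
                   ) -> Benchmark:
    """Generate ``n_families`` families with independently planted events.

    ``event_rates = (p_hgt, p_paralog, p_partial)`` are Bernoulli
    probabilities per family; a family can carry several labels. HGT events
    split evenly between inter-domain transfers (outgroup donor, ingroup
    recipient) and intra-ingroup transfers across classes. The truth table
    records per-family labels {clean, hgt, paralog, partial} plus the event
    details as JSON.
    """
    p_hgt, p_paralog, p_partial = event_rates
    for p in event_rates:
        if not 0.0 <= p <= 1.0:
            raise ConfigError("event rates must lie in [0, 1]")
    model = model or SubstitutionModel.poisson()
    tree, taxonomy = sample_species_tree(config)
    ingroup = sorted(l for l in tree.leaf_names if not taxonomy.is_outgroup(l))
    outgroup = sorted(l for l in tree.leaf_names if taxonomy.is_outgroup(l))

    families, rows = [], []
    for i in range(n_families):
        ev_rng = np.random.default_rng([seed, i, 0])
        n_sites = int(ev_rng.integers(n_sites_range[0], n_sites_range[1] + 1))
        fam = evolve_alignment(tree, model, n_sites,
                               np.random.default_rng([seed, i, 1]),
                               family_id=f"F{i + 1:04d}")
        labels = {"hgt": False, "paralog": False, "partial": False}
        if ev_rng.random() < p_hgt:
            labels["hgt"] = True
            if ev_rng.random() < 0.5:
                donor = str(ev_rng.choice(outgroup))
                recipient = str(ev_rng.choice(ingroup))
            else:
                classes = sorted({taxonomy.resolve(l).class_ for l in ingroup})
                ca, cb = ev_rng.choice(len(classes), size=2, replace=False)
                donor = str(ev_rng.choice(
                    [l for l in ingroup
                     if taxonomy.resolve(l).class_ == classes[ca]]))
                recipient = str(ev_rng.choice(
                    [l for l in ingroup
                     if taxonomy.resolve(l).class_ == classes[cb]]))
            fam = inject_hgt(fam, tree, donor, recipient, hgt_divergence,
                             model, np.random.default_rng([seed, i, 2]))
        if ev_rng.random() < p_paralog:
            labels["paralog"] = True
            species = str(ev_rng.choice(ingroup))
            fam = inject_paralogy(fam, species, paralog_divergence, model,
                                  np.random.default_rng([seed, i, 3]))
        if ev_rng.random() < p_partial:
            labels["partial"] = True
            victim = str(ev_rng.choice([m.leaf for m in fam.members]))
            keep = float(ev_rng.uniform(*truncate_keep))
            fam = degrade(fam, victim, "truncate",
                          np.random.default_rng([seed, i, 4]), fraction=keep)
        families.append(fam)
        rows.append({"family": fam.family_id,
                     "clean": not any(labels.values()),
                     **labels,
                     "n_sites": n_sites,
                     "detail": json.dumps(fam.truth)})
    truth = pd.DataFrame(rows)
    return Benchmark(families, truth, tree, taxonomy, model, config)
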
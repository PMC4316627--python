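"""Detection of candidate marker families and retention filters.

Homology search is exact Smith–Waterman local alignment with affine gaps
(Biopython's PairwiseAligner) over every query-subject pair — fine at desk
scale, no heuristic seeding. Significance comes from a decoy-calibrated
Gumbel: scores of shuffled-sequence alignments are fitted by maximum
likelihood and converted to BLAST-style E-values
``E = K * len_a * len_b * exp(-lambda * score)``.

Retention filters mirror a conservative marker funnel: an E-value ceiling,
a minimum number of distinct ingroup species, removal of partial sequences
(shorter than a fraction of the family's median length), and a minimum
number of distinct outgroup phyla for usable outgroup coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .formats import TaxonomyMap
from .simulate import FamilyMember, GeneFamily

log = logging.getLogger(__name__)


class AlignmentError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class FilterCriteria:
    """Thresholds of the marker-retention funnel."""

    e_value_max: float = 1e-5
    min_archaeal_members: int = 4
    partial_fraction: float = 0.5
    min_outgroup_phyla: int | None = 24

    def __post_init__(self):
        if self.e_value_max <= 0:
            raise ValueError("e_value_max must be positive")
        if self.min_archaeal_members < 1:
            raise ValueError("min_archaeal_members must be >= 1")
        if not 0.0 < self.partial_fraction < 1.0:
            raise ValueError("partial_fraction must be in (0, 1)")
        if self.min_outgroup_phyla is not None and self.min_outgroup_phyla < 1:
            raise ValueError("min_outgroup_phyla must be >= 1 or None")


# ---------------------------------------------------------------------------
# local alignment

def _aligner(matrix: str | object = "BLOSUM62", gap_open: float = -11.0,
             gap_extend: float = -1.0) -> Align.PairwiseAligner:
    if gap_open > 0 or gap_extend > 0:
        raise AlignmentError("gap penalties must be <= 0")
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aln.substitution_matrix = matrix
    aln.open_gap_score = gap_open + gap_extend
    aln.extend_gap_score = gap_extend
    return aln


def local_align(a: str, b: str, matrix: str | object = "BLOSUM62",
                gap_open: float = -11.0, gap_extend: float = -1.0):
    """Optimal Smith–Waterman local score and aligned spans.

    ``gap_open`` is the cost of opening a gap (excluding the first extension),
    both penalties <= 0. Returns ``(score, (a_span, b_span))`` with 0-based
    half-open spans; a pair with no positively scoring alignment gives score
    0 and empty spans.
    """
    if not a or not b:
        raise AlignmentError("sequences must be non-empty")
    if "-" in a or "-" in b:
        raise AlignmentError("sequences must be ungapped")
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, ((0, 0), (0, 0))
    best = None
    for aln in sorted(aligner.align(a, b),
                      key=lambda x: (x.aligned[0][-1][1], x.aligned[1][-1][1])):
        best = aln
        break
    a_span = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
    b_span = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1]))
    return float(score), (a_span, b_span)


# ---------------------------------------------------------------------------
# E-values

@dataclass
class GumbelCalibration:
    lam: float
    K: float
    decoy_max: float
    len_a: float
    len_b: float


def calibrate_evalue(decoy_scores, len_a: int, len_b: int
                     ) -> GumbelCalibration:
    """Fit a Gumbel to decoy (shuffled-sequence) local-alignment scores.

    Maximum-likelihood fit; lambda = 1/scale and
    K = exp(lambda * loc) / (len_a * len_b), so that
    E(s) = K * m * n * exp(-lambda * s) matches the decoy tail at the
    calibration lengths.
    """
    scores = np.asarray(list(decoy_scores), dtype=float)
    if scores.size < 200:
        raise CalibrationError("need at least 200 decoy scores")
    if np.std(scores) == 0:
        raise CalibrationError("decoy scores have zero variance")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = float(np.exp(lam * loc)) / (len_a * len_b)
    return GumbelCalibration(lam, K, float(scores.max()), len_a, len_b)


def estimate_evalue(score: float, len_a: int, len_b: int,
                    calibration: GumbelCalibration) -> float:
    """E-value of a score given decoy calibration (monotone decreasing)."""
    return calibration.K * len_a * len_b * np.exp(-calibration.lam * score)


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def make_decoy_calibration(sequences: list[str], n_decoys: int = 250,
                           seed=0, matrix="BLOSUM62", gap_open: float = -11.0,
                           gap_extend: float = -1.0) -> GumbelCalibration:
    """Calibrate by aligning shuffled pairs drawn from real sequences."""
    rng = np.random.default_rng(seed)
    scores = []
    mean_len = float(np.mean([len(s) for s in sequences]))
    for _ in range(n_decoys):
        i, j = rng.integers(0, len(sequences), size=2)
        a = _shuffled(sequences[i], rng)
        b = _shuffled(sequences[j], rng)
        s, _spans = local_align(a, b, matrix, gap_open, gap_extend)
        scores.append(s)
    return calibrate_evalue(scores, int(mean_len), int(mean_len))


# ---------------------------------------------------------------------------
# homolog search

@dataclass
class HitTable:
    """Rows of (query, subject, score, e_value, spans)."""

    rows: pd.DataFrame

    COLUMNS = ["query", "subject", "score", "e_value",
               "q_start", "q_end", "s_start", "s_end"]

    def __post_init__(self):
        if list(self.rows.columns) != self.COLUMNS:
            raise ValueError(f"hit table columns must be {self.COLUMNS}")
        if len(self.rows) and (self.rows["e_value"] <= 0).any():
            raise ValueError("e-values must be positive")


def search_homologs(queries: dict[str, str], database: dict[str, str],
                    criteria: FilterCriteria | None = None,
                    calibration: GumbelCalibration | None = None,
                    seed=0) -> HitTable:
    """All query-subject pairs at or below the E-value ceiling.

    Self-hits (same identifier) are excluded. If no calibration is given,
    one is built from shuffled database sequences.
    """
    if not database:
        raise ValueError("empty database")
    criteria = criteria or FilterCriteria()
    if calibration is None:
        calibration = make_decoy_calibration(list(database.values()),
                                             seed=seed)
    rows = []
    for q_id, q_seq in queries.items():
        for s_id, s_seq in database.items():
            if q_id == s_id:
                continue
            score, (qs, ss) = local_align(q_seq, s_seq)
            e = estimate_evalue(score, len(q_seq), len(s_seq), calibration)
            if e <= criteria.e_value_max:
                rows.append((q_id, s_id, score, e,
                             qs[0], qs[1], ss[0], ss[1]))
    df = pd.DataFrame(rows, columns=HitTable.COLUMNS)
    return HitTable(df)


def build_families(hits: HitTable, seeds: list[str],
                   sequences: dict[str, str]) -> list[GeneFamily]:
    """One family per seed query: the seed plus every subject it hits.

    Per-seed design (no transitive closure): the same sequence may appear in
    several families, mirroring per-query search results.
    """
    known = set(hits.rows["query"]).union(hits.rows["subject"]) | set(sequences)
    families = []
    for seed_id in seeds:
        if seed_id not in known:
            raise ValueError(f"unknown seed id {seed_id!r}")
        subjects = hits.rows.loc[hits.rows["query"] == seed_id, "subject"]
        members = [seed_id] + sorted(set(subjects) - {seed_id})
        fam = GeneFamily(
            family_id=seed_id,
            members=[FamilyMember(m, sequences[m]) for m in members],
            aligned=False, truth=None)
        families.append(fam)
    return families


# ---------------------------------------------------------------------------
# retention filters

def flag_partials(family: GeneFamily,
                  partial_fraction: float = 0.5) -> GeneFamily:
    """Drop members shorter than ``partial_fraction`` x median length.

    Lengths count residues only (gaps excluded), so the rule applies equally
    to aligned and unaligned families. Removals are logged in the truth
    table when present.
    """
    if len(family.members) < 2:
        log.warning("family %s has < 2 members; partial filter skipped",
                    family.family_id)
        return family
    fam = family.copy()
    lengths = {m.leaf: len(m.sequence.replace("-", "")) for m in fam.members}
    median = float(np.median(list(lengths.values())))
    cut = partial_fraction * median
    removed = [l for l, ln in lengths.items() if ln < cut]
    fam.members = [m for m in fam.members if m.leaf not in removed]
    if removed and fam.truth is not None:
        fam.truth.append({"type": "partial_removed", "leaves": removed})
    return fam


def apply_family_filters(family: GeneFamily, taxonomy: TaxonomyMap,
                         criteria: FilterCriteria | None = None
                         ) -> tuple[bool, list[str]]:
    """Coverage filters: enough distinct ingroup species, and (when
    enforced) enough distinct outgroup phyla. Returns (kept, reasons)."""
    criteria = criteria or FilterCriteria()
    ingroup_species = set()
    outgroup_phyla = set()
    for m in family.members:
        rec = taxonomy.resolve(m.leaf)   # raises on unresolvable member
        if taxonomy.is_outgroup(m.leaf):
            outgroup_phyla.add(rec.phylum)
        else:
            ingroup_species.add(rec.species)
    reasons = []
    if len(ingroup_species) < criteria.min_archaeal_members:
        reasons.append("min_archaeal_members")
    if (criteria.min_outgroup_phyla is not None
            and len(outgroup_phyla) < criteria.min_outgroup_phyla):
        reasons.append("min_outgroup_phyla")
    return (not reasons), reasons
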
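# Methods

## The problem

Placing the root of a domain-level tree requires an outgroup, and the
outgroup sits at the end of a long stem branch. That stem interacts badly
with three realities of multi-gene datasets: markers can have histories of
their own (horizontal transfer, paralogy), genome-reduced lineages evolve
fast and contribute mostly missing data, and fast lineages are attracted
toward long branches — most dangerously toward the outgroup stem itself,
which pushes them to the base of the tree and moves the root. `phyloroot`
implements the full workflow — marker detection, taxonomic-consistency
screening, supermatrix construction, tree inference, outgroup rooting and
long-branch-attraction (LBA) diagnostics — and pairs it with a synthetic
data generator that plants exactly the pathologies the workflow must detect
or withstand, so every stage can be scored against ground truth.

## Substitution model

Sequences evolve under a time-reversible amino-acid model
`Q = S·diag(π)` (symmetric exchangeabilities `S`, equilibrium frequencies
`π`), scaled so the expected substitution rate at equilibrium is 1 — branch
lengths are therefore expected substitutions per site. Among-site rate
variation uses the discrete gamma approximation: k equal-probability
categories (default 6) represented by their conditional means, normalized
to mean 1. The default model is Poisson (equal exchangeabilities and
frequencies): it has closed-form transition probabilities
`p_ii(t) = 1/20 + 19/20·e^(−20t/19)`, which gives the test suite an
analytic oracle for simulation calibration and for the ML distance
(`d = −(19/20)·ln(1 − 20p/19)`, gamma variant
`d = (19/20)·α·[(1 − 20p/19)^(−1/α) − 1]`). A PAML-format matrix file
(LG, WAG layout) can be loaded for realistic exchangeabilities; the package
ships no matrix data. General transition matrices come from
`scipy.linalg.expm`; the Poisson closed form is used only as a test oracle,
never as the implementation.

## The synthetic world

`WorldConfig` describes a two-kingdom ingroup (default labels
Euryarchaeota/Proteoarchaeota) plus a multi-phylum outgroup (Bacteria):

| parameter | default | meaning |
|---|---|---|
| `n_classes_per_kingdom` | 3 | monophyletic classes per kingdom |
| `n_species_per_class` | 3 | species per class (one genome each) |
| `n_outgroup_phyla` | 24 | matches the default outgroup-coverage threshold |
| `species_per_outgroup_phylum` | 1 | |
| `stem_length` | 0.5 | ingroup|outgroup edge, substitutions/site |
| `ingroup_depth`, `outgroup_depth` | 1.0 | scale factors on all other edges |
| `fast_clades` | [] | (selector, multiplier ≥ 1) accelerated lineages |

Edge lengths are drawn uniformly within fixed fractions of the depth
parameters. Classes are modeled as tight radiations on deep stems:
within-class edges (pendants 0.02–0.06, internals 0.01–0.03 of the depth)
are an order of magnitude shorter than class stems (0.15–0.30), which keeps
planted clades coherent and puts inter-class distances far above the event
divergences the screen must detect (0.02 by default — a ratio ≥ 5, so
detection failures measure the method, not an ill-posed world). Rate
multipliers apply to a clade's stem edge and every edge inside it: an
accelerated lineage has been fast since its origin, which is the pattern
genome reduction produces.

Planted events, all logged in a per-family truth table:

* **HGT** replaces the recipient's sequence by the donor's re-evolved over
  a short branch. This is sequence replacement, not topology surgery, so
  any tree builder sees exactly the "wrong clade" signal a transfer leaves
  in a gene tree. Benchmark transfers split evenly between inter-domain
  (outgroup donor → ingroup recipient) and intra-ingroup cross-class.
* **Paralogy** adds a second copy for one species (leaf id `species__2`),
  re-evolved over 2× the divergence.
* **Partiality** truncates a member to a contiguous fraction of sites
  (default keep 0.25–0.45, below the 50 %-of-median removal threshold) or
  masks a random site fraction; **loss** removes members outright.

There is no indel process: alignments are simulated as homologous columns,
and "partial sequences" are truncation masks — which is precisely the
feature the partial-sequence filter reacts to. Consequences: the tests say
nothing about alignment-inference error, compositional heterogeneity,
or gene-tree/species-tree discordance; LBA here is driven purely by rate
acceleration. Randomness uses one root seed; family *i*, stage *s* draws
from `default_rng([seed, i, s])`, so any family is reproducible alone.

## Marker detection

Homology search is exact Smith–Waterman with affine gaps (BLOSUM62,
open −11, extend −1) over all query–subject pairs — no heuristic seeding,
which is fine at desk scale. Significance is calibrated from decoys:
scores of shuffled-sequence alignments are fitted by a maximum-likelihood
Gumbel, giving `λ = 1/scale` and `K = e^{λ·loc}/(m₀·n₀)`, and
`E = K·m·n·e^{−λS}`. A decoy calibration works for any scoring scheme and
can be validated against its own empirical tail, which analytic
Karlin–Altschul parameters cannot at this scale. Retention mirrors a
conservative funnel: `E ≤ 1e−5`, ≥ 4 distinct ingroup species, partials
(< 50 % of the family median residue count) removed, and — when outgroup
coverage is enforced — ≥ 24 distinct outgroup phyla. Families are built
per seed query (seed plus everything it hits), not by transitive closure,
so one sequence may serve several families.

## Screening

All screens are purely topological and deterministic — stricter than a
human curator, who might forgive weakly supported intermixing. Monophyly
follows the unrooted convention (a set is monophyletic iff some edge's
bipartition isolates it exactly), so every decision is invariant to the
rooting of the input gene tree. Class monophyly is evaluated on the full
tree: a class must form a clean split against everything, outgroup
included. Inter-domain HGT is flagged when no edge separates ingroup from
outgroup; candidate culprits come from a greedy minimal-removal search
(drop the leaf that most reduces the misplacement count; cap 5) —
advisory, not part of the verdict. Within-outgroup HGT tests only
*recent* events: each outgroup phylum with ≥ 2 members must be
monophyletic on the outgroup-restricted tree; deep inter-phylum order is
deliberately not tested. Paralogy requires copy-number evidence (a species
with ≥ 2 sequences); a class split without multi-copy species is charged
to the monophyly check instead. Gene trees default to NJ on corrected
distances; precomputed Newick trees can be supplied instead.

## Tree inference

The inference engine is intentionally small and deterministic: corrected
distances → neighbor joining (Q-criterion, Studier–Keppler updates, ties
broken toward the lexicographically smallest cluster pair, negative length
estimates clamped to zero with the deficit logged) → optional
branch-length refinement by likelihood on the fixed NJ topology. There is
no topology search and no MCMC; those belong to heavyweight external
tools, and nothing the diagnostics here measure requires them. Saturated
pairs (p ≥ 0.85 under Kimura, or beyond the Poisson ceiling) get 1.05× the
largest finite distance in the matrix and are flagged.

Likelihood is Felsenstein pruning over unique site patterns with
per-category partials, per-node rescaling against underflow, and gaps/X as
missing data (partial likelihood 1). Per-site likelihoods average the
gamma categories in log space. Branch-length optimization sweeps the edges
with bounded one-dimensional maximization (edge likelihood evaluated from
cached inward/outward partials, recomputed per edge), stopping when a full
sweep gains less than `tol` (default 1e-3 log units); the sweep sequence
is non-decreasing in log-likelihood. Bootstrap resamples columns i.i.d.
with replacement (B replicates, seeded, deterministic); support of an
original-tree split is the percentage of replicate NJ trees containing it.

## Supermatrix

The column trimmer keeps a column iff its gap fraction ≤ 0.2 and its
normalized Shannon entropy (log base 20, gaps excluded) ≤ 0.5. It is a
declared simplification of window-based trimmers: deterministic,
idempotent, testable; externally trimmed alignments can be supplied
instead. Note one systematic effect: entropy trimming preferentially
removes fast-evolving columns, so deep branches of trees built from
trimmed supermatrices — the inter-domain stem in particular — are
compressed relative to the generating values. Stem-length *recovery* is
therefore benchmarked on untrimmed alignments, while stem *ratios* between
marker sets compare like with like. Concatenation is species-level: at
most one sequence per species per family (paralogs must have been screened
out), absent species get all-gap blocks, and the per-taxon missing
fraction counts gaps plus absent blocks — a genome-reduced taxon dropped
from half its families correctly reports > 50 % missing.

## Rooting and LBA diagnostics

Outgroup rooting requires outgroup monophyly and places the root at the
midpoint of the stem edge — the split-length convention is arbitrary, and
stem-length accounting always reports the whole edge, so nothing
downstream depends on it. The inter-domain stem length is the length of
the edge realizing the ingroup|outgroup bipartition (for a rooted tree,
the two root-child edges summed); `stem_ratio` compares it across marker
sets. Long-branch scores are pendant length over the median pendant,
flagged when the robust z (median/MAD, scaled by 1.4826) exceeds 3; scores
are rooting-invariant and most meaningful within a comparable taxon set
(e.g., the ingroup).

The placement experiment prunes the alignment to each condition
(with/without outgroup), infers a bootstrapped tree, and reports focal
monophyly, the sister label (class-majority of the smallest clade across
the attachment edge — a deterministic proxy for "branched as sister group
of X"), and whether the focal group attaches *basally*, defined as
focal ∪ outgroup being monophyletic. The basal definition is the package's
own: it holds exactly when the focal clade attaches on the outgroup side
of the ingroup's deepest split, which is what "pulled to the base by the
outgroup" means on a tree, and it is robust to how large the clade across
the attachment edge happens to be.

## Benchmark studies (sizes as run by tests and `scripts/acceptance.py`)

* **Screening power** — 500 families on the default 42-taxon world, event
  rates (0.2, 0.1, 0.1), 300–600 sites. Expected verdicts come from an
  ideal curator who knows the planted events: reject on HGT or paralogy,
  and on truncations whose removal drops coverage below threshold (with 24
  outgroup phyla at threshold 24, any outgroup truncation is fatal).
  Scored as precision/recall of both the retain and reject decisions.
* **Root recovery** — 20 seeds × (30 taxa: 2 kingdoms × 3 classes × 2
  species + 9 outgroup phyla × 2, stem 0.5; 20 clean markers of 300–600
  sites, trimmed and concatenated; B = 100). Success = ingroup|outgroup
  split present with support ≥ 90.
* **Stem statistics** — 8 taxa, 20 000 sites, stem 0.8; NJ topology with
  likelihood-optimized branch lengths; and a second dataset with stem
  0.8/2.6 for the ratio. Sizes keep the whole run in minutes on one CPU.
* **LBA contrast** — 2 kingdoms × 2 classes × 3 species + 6 outgroup
  phyla, stem 1.5, focal class accelerated ×8, 2 000 sites, uncorrected
  p-distances (the classic conditions for the artifact — distance
  undercorrection plus a long focal branch; with model-matched corrected
  distances the artifact disappears, as `examples/04` shows). Two classes
  per kingdom make the focal clade's true sister coincide with "its own
  kingdom partner", so residual attraction to the inter-kingdom split
  still counts as failure. Success per replicate = basal with the
  outgroup AND true-sister without it.

## Known limitations

The generator omits indels, compositional bias, heterotachy beyond clade
rate multipliers, and coalescent discordance; real datasets fail in all of
those ways too, so green benchmarks here certify the screening and rooting
logic, not robustness to every real-data pathology. The screen cannot see
transfers between singleton outgroup phyla (vacuous monophyly), and an HGT
whose recipient is subsequently truncated away is undetectable by
construction. Whether compositional bias also contributes to basal
attraction of fast lineages is untestable with a rate-only simulator.
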
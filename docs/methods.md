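# Methods

## The problem

A proteome's "structural coverage" asks, residue by residue, what kind of
three-dimensional information exists for each position of each protein:
an experimentally solved structure, a homology template of some sequence
identity, a confident machine-learned model, a disorder call, a bare domain
annotation, or nothing at all.  `structcover` integrates these evidence
layers into exactly one category per residue and aggregates the categories
into the statistics used to describe a proteome's structural state: stacked
residue fractions, per-protein classification bins, deposition-year
timelines, gene-set and variant-class breakdowns, and a bootstrap test for
3D clustering of mutations on a model.

## Per-residue evidence and the category stack

Four parallel tracks are built per protein:

* **max template identity** — alignment hits (BLAST tabular) are filtered at
  e-value < 1e-8 and percent identity ≥ 20 (the practical floor for
  template-based homology modelling), then projected onto the query: each
  residue inside a hit's query interval receives the hit's identity, and the
  per-residue value is the maximum over all hits covering it.  Tabular
  alignments carry no per-residue gap map, so the whole qstart–qend interval
  counts as covered.
* **pLDDT** — the predicted model's per-residue confidence in [0, 100],
  read from a TSV or from the B-factor column of the model's coordinate
  file (the AlphaFold convention).  A residue with no score behaves exactly
  like pLDDT < 50 ("no prediction").
* **disorder score** — IUPred-style, in [0, 1]; a residue is disordered
  when its score exceeds 0.5 (strictly).
* **domain membership** — boolean, from Pfam-style hits filtered at
  e-value < 1e-8.

Each residue then resolves to the **first matching** category of the stack:

| rank | category | rule |
|---|---|---|
| 1 | `PDB_EXP` | identity > 95 (effectively the real structure) |
| 2 | `PDB_HOMOLOGY` | 50 ≤ identity ≤ 95 (good homology templates) |
| 3 | `AF_HIGH` | pLDDT ≥ 90 (high-confidence model) |
| 4 | `PDB_REMOTE` | 20 ≤ identity < 50 (remote templates) |
| 5 | `AF_MID` | 70 ≤ pLDDT < 90 |
| 6 | `AF_LOW` | 50 ≤ pLDDT < 70 |
| 7 | `IDR` | disorder > 0.5 |
| 8 | `DOMAIN_ONLY` | inside a domain, nothing else |
| 9 | `DARK` | fallback |

Identity tiers are conventionally printed with shared endpoints
(">95", "95–50", "50–20"), so the closure at each boundary is an explicit,
configurable choice.  Defaults: identity exactly 95 and exactly 50 are
assigned *upward* (both to `PDB_HOMOLOGY`) — this keeps the high-quality
set (identity above 50 or pLDDT above 90) closed; pLDDT boundaries close
upward (90 → `AF_HIGH`, 70 → `AF_MID`, 50 → `AF_LOW`); disorder is strictly
greater than 0.5.  All closures are flags on `Thresholds`, so the opposite
reading is reproducible.  The precedence order itself is an argument of
`resolve_categories`: placing templates of 50–95% identity above
high-confidence models reflects the convention of counting experimental/
template evidence first when splitting "high-quality" coverage into its PDB
and predicted-model parts; ties between remote templates and mid/low
predicted models follow the same stack.  `DARK` must remain last.

High-quality coverage is `PDB_EXP + PDB_HOMOLOGY + AF_HIGH`; any-structure
coverage additionally counts `PDB_REMOTE + AF_MID + AF_LOW`.

## Aggregation

All proteome-level fractions are **residue-weighted**: fraction(c) =
Σ length·fraction_p(c) / Σ length — never a mean of per-protein fractions.
Protein-level bins (`classify_proteins`) are predicates on the per-protein
summary: no usable template (`structureless_pre_af`); no template and no
residue with pLDDT ≥ 50 (`structureless_post_af`); high-confidence model
over more than half the length outside template regions (`af_hq_majority`);
pLDDT ≥ 90 on more than 10% of residues (`af_hq_some`); more than 95% of
residues covered by anything (`near_complete`); near-complete where
model-only coverage exceeds half the length (`af_majority_contributor`);
plus a decile histogram of covered fraction.  A gene's coverage is the
coverage of its single supplied isoform; isoform selection is the caller's
responsibility.

The timeline statistic recomputes the identity projection using only hits
whose subject deposition year is at most the year in question (hits without
a year always count) and reports, per year, the residue fraction at each
minimum-identity threshold.  It is monotone non-decreasing in year and
non-increasing in the threshold by construction.

Enrichment of a gene set in a trait list is a plain two-sided Fisher exact
test on the 2×2 table over the supplied universe, p-value from the
hypergeometric conditional distribution (scipy), odds ratio (a·d)/(b·c)
with the Haldane +0.5 correction on all four cells when any cell is zero.
No ontology handling, no term propagation and no multiple-testing
correction are applied: the module tests exactly the lists it is given.

Variants are mapped by 1-based protein position onto the resolved track;
positions beyond the protein or on unknown proteins go to an explicit
rejects report and are excluded from all denominators (silent drops would
hide coordinate errors).

## The clustering test

Given alpha-carbon coordinates and k mutated positions, the statistic is
the mean pairwise CA–CA Euclidean distance (max pairwise and minimum
spanning tree length are options sharing the same null machinery; lower =
tighter in all cases).  The null draws B sets of k residues uniformly
without replacement from the eligible residues and the p-value is the
add-one estimator p = (1 + #{null ≤ observed}) / (B + 1), which is
super-uniform under the null and bounded below by 1/(B+1).  When pLDDT is
available, eligibility defaults to pLDDT ≥ 70, because distances measured
on low-confidence coordinates are not meaningful; with no confidence scores
all residues are eligible.  The procedure is a transparent surrogate for
published 3D-clustering tools whose internals are not fully specified: it
reproduces the inferential claim (are these mutations closer in space than
chance?) with a fully documented, seed-reproducible algorithm, not any
particular tool's exact p-values.

## The synthetic proteome

The generator exists so the entire pipeline can be validated with planted
ground truth and zero downloads.  Each protein (default: 500 proteins,
lengths uniform in 100–2,000) is cut into geometric-length segments (mean
60 residues); each segment draws a category from the target weights and the
evidence that *defines* the category is emitted for its residues.  The
default weights are the observed human-proteome stack — 17% experimental,
14% high-identity template, 19% high-confidence model, 8% remote template,
11% mid- and 7% low-confidence model, 12% disordered, 2% domain-only, 10%
dark.  Emitted evidence follows two rules that make recovery *exact* rather
than merely expected:

* **tier-interior sampling** — sampled scores stay 0.5 units away from all
  tier boundaries (identities in [95.5, 99.5], [50.5, 94.5], [20.5, 49.5];
  pLDDT in [90.5, 99.5], [70.5, 89.5], [50.5, 69.5]; disorder in
  [0.55, 0.95] or [0, 0.45]), so file rounding and boundary-closure settings
  cannot flip a planted category.  `boundary_cases()` separately emits
  exactly-on-threshold values for closure tests.
* **masked noise only** — extra evidence is added only where a
  higher-precedence category already holds: high pLDDT under template
  segments (72% of template-covered residues by default, mirroring the
  observed concordance between high template identity and high model
  confidence), remote-identity hits under high-confidence model segments,
  disorder calls under low-confidence model segments, domain hits under
  disordered segments.

The generator records what it actually planted (realized draws, not
expectations), so the aggregate comparison is exact equality, not a
statistical tolerance.  Variants (default: two classes, 2,000 each,
"pathogenic" biased toward structured categories, "benign" following the
proteome stack) draw a category per variant from the class bias restricted
to categories with unused residues, then an unused residue of that
category; realized counts are bookkept the same way.

Synthetic folds are seeded self-avoiding CA traces with exactly 3.8 Å
steps and a 3.0 Å excluded volume.  A planted cluster is constructed by
placing anchor points that are pairwise within the requested radius and at
least 3.0 Å apart, then building the chain as self-avoiding bridges that
land exactly on each anchor (the final two steps of each bridge use the
two-sphere intersection construction), so the planted residues satisfy the
radius by construction.  What these folds do *not* emulate: secondary
structure, compact globular packing, realistic contact order — so passing
tests demonstrate the statistics and the machinery, not biological realism.

## What the synthetic data does and does not show

Planted-recovery tests prove the evidence writers, parsers, projection and
resolution are mutually consistent and lossless end to end.  They do not
validate biological parameter choices (real proteomes have correlated
evidence layers, length-dependent disorder, alignment gaps inside hit
intervals); headline percentages from real snapshots depend on database
versions and are out of scope.  The calibration experiment shows the
bootstrap p-value is honest under its own null; it cannot show that
mean-pairwise distance is the most powerful statistic for every cluster
shape (an elongated cluster is better served by the MST option).

## Numerical choices and degenerate inputs

* Absent evidence is NaN in float tracks; all comparisons use explicit
  NaN-safe semantics (absent never satisfies any tier rule).
* Category tracks serialize as run-length BED intervals (0-based,
  half-open — the only 0-based surface in the package; all input
  coordinates are 1-based inclusive).  Read-back requires the intervals to
  tile the protein without gaps and reconstructs tracks exactly.
* Summaries serialize every number through its JSON representation in both
  JSON and TSV outputs, so the two formats encode bit-identical values and
  reruns are byte-identical.
* Fractions partition to 1 within 1e-12 per protein (exact in practice:
  counts over a common denominator).
* Zero-length proteins, empty hit files, empty score tables and missing
  evidence layers are all legal degenerate inputs; an empty *proteome* is
  an error.
* A protein whose alignment track contains identity below the 20% filter
  is treated as a contract breach (filter bypass), not silently binned.
* The bootstrap is fully reproducible from (coords, positions, B, seed) and
  invariant to rigid motion of the structure within 1e-9.

## Problem sizes used in validation

The validation suite resolves a 500-protein planted proteome (~0.5 M
residues), checks the Fisher core against exact integer enumeration of all
2×2 tables with margins ≤ 30 (246,015 tables), runs 500 null-calibration
replicates of the bootstrap at B = 999 on a 300-residue fold, and detects a
planted 3-residue cluster (≤ 8 Å) at B = 9,999.  These sizes exercise every
code path at full default parameters while keeping a complete run within a
few minutes on one CPU.

## Known limitations

* Alignment gaps inside a hit's query interval are counted as covered;
  real coverage from gapped alignments is slightly lower.
* The deposition-year timeline trusts the year column supplied with the
  hits; structure revision/supersession history is not modelled.
* The enrichment module deliberately has no ontology awareness.
* The clustering surrogate tests a global tightness statistic; it does not
  enumerate sub-clusters or report which residues drive the signal.
* One isoform per gene is assumed throughout; multi-isoform reconciliation
  is the caller's problem.
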
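"""Aggregate statistics over resolved coverage tracks.

Everything here is residue-weighted unless stated otherwise: a proteome's
fraction in a category is the total number of residues carrying that
category divided by the total number of residues, not a mean of per-protein
fractions.  The module also provides the protein-level classification bins
(structureless before/after predicted models, high-confidence-majority,
near-complete coverage, ...), the deposition-year coverage timeline, per
gene-set and per variant-class coverage breakdowns, and the 2x2 Fisher exact
enrichment test with Haldane-corrected odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .coverage_core import (
    HIGH_QUALITY_CATEGORIES,
    STRUCTURED_CATEGORIES,
    CategoryTrack,
    CoverageCategory,
    Thresholds,
    project_hits,
)
from .io_formats import AlignmentHit, GeneSet, ProteinRecord, VariantRecord

__all__ = [
    "ProteinSummary",
    "ProteomeSummary",
    "EnrichmentResult",
    "TimelinePoint",
    "VariantCoverage",
    "BUILTIN_RULES",
    "aggregate",
    "classify_proteins",
    "coverage_timeline",
    "gene_set_coverage",
    "variant_coverage",
    "fisher_test",
    "fisher_enrichment",
]


@dataclass
class ProteinSummary:
    """Per-protein category fractions plus protein-level classification flags."""

    protein_id: str
    gene_id: str
    length: int
    fractions: dict[CoverageCategory, float]
    has_pdb: bool
    has_any_structure: bool
    hq_fraction: float
    af_high_fraction: float
    plddt_high_fraction: float
    af_only_covered_fraction: float
    covered_fraction: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.protein_id}: category fractions sum to {total}, not 1"
            )
        if self.hq_fraction > self.covered_fraction + 1e-12:
            raise ValueError(
                f"{self.protein_id}: hq_fraction {self.hq_fraction} exceeds "
                f"covered_fraction {self.covered_fraction}"
            )


@dataclass
class ProteomeSummary:
    """Residue-weighted category fractions over a set of proteins."""

    fractions: dict[CoverageCategory, float]
    total_residues: int
    total_proteins: int
    protein_class_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "total_proteins": self.total_proteins,
            "total_residues": self.total_residues,
            "category_fractions": {c.name: self.fractions[c] for c in CoverageCategory},
        }
        if self.protein_class_counts:
            out["protein_class_counts"] = dict(self.protein_class_counts)
        return out


@dataclass
class EnrichmentResult:
    """A 2x2 gene-set enrichment: a=set&trait, b=set only, c=trait only, d=neither."""

    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float


@dataclass
class TimelinePoint:
    """Proteome coverage at each minimum-identity threshold, for one year."""

    year: int
    fractions: dict[float, float]


@dataclass
class VariantCoverage:
    """Per variant-class counts and fractions over coverage categories."""

    counts: dict[str, dict[CoverageCategory, int]]
    fractions: dict[str, dict[CoverageCategory, float]]
    rollups: dict[str, dict[str, float]]
    rejects: list[tuple[VariantRecord, str]]

    def as_dict(self) -> dict:
        return {
            "classes": {
                label: {
                    "n": sum(self.counts[label].values()),
                    "counts": {c.name: self.counts[label][c] for c in CoverageCategory},
                    "fractions": {
                        c.name: self.fractions[label][c] for c in CoverageCategory
                    },
                    "rollups": dict(self.rollups[label]),
                }
                for label in self.counts
            },
            "n_rejected": len(self.rejects),
            "rejected": [
                {"protein_id": v.protein_id, "position": v.position,
                 "class_label": v.class_label, "reason": reason}
                for v, reason in self.rejects
            ],
        }


def aggregate(summaries: Iterable[ProteinSummary]) -> ProteomeSummary:
    """Residue-weighted proteome fractions: sum of length * fraction / total length."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot aggregate an empty collection of proteins")
    total = sum(s.length for s in summaries)
    weighted = {c: 0.0 for c in CoverageCategory}
    for s in summaries:
        for c in CoverageCategory:
            weighted[c] += s.length * s.fractions[c]
    return ProteomeSummary(
        fractions={c: weighted[c] / total for c in CoverageCategory},
        total_residues=total,
        total_proteins=len(summaries),
    )


#: Protein classification bins, by name.  Each predicate sees a ProteinSummary.
BUILTIN_RULES: dict[str, Callable[[ProteinSummary], bool]] = {
    # no usable template at all (the pre-predicted-model structureless set)
    "structureless_pre_af": lambda s: not s.has_pdb,
    # no template and no confident prediction either
    "structureless_post_af": lambda s: not s.has_any_structure,
    # high-confidence predicted model covers more than half the protein
    "af_hq_majority": lambda s: s.af_high_fraction > 0.5,
    # pLDDT >= 90 on more than 10% of residues
    "af_hq_some": lambda s: s.plddt_high_fraction > 0.1,
    # nearly everything covered by some structural evidence
    "near_complete": lambda s: s.covered_fraction > 0.95,
    # near-complete and the predicted model supplies the majority of it
    "af_majority_contributor": lambda s: s.covered_fraction > 0.95
    and s.af_only_covered_fraction > 0.5,
}


def classify_proteins(
    summaries: Iterable[ProteinSummary],
    rules: Mapping[str, Callable[[ProteinSummary], bool]] | Sequence[str] | None = None,
) -> dict[str, object]:
    """Count proteins per classification bin, plus a covered-fraction decile histogram.

    ``rules`` may be a mapping name -> predicate, a sequence of built-in rule
    names, or None for all built-ins.  Unknown rule names raise.
    """
    if rules is None:
        resolved = dict(BUILTIN_RULES)
    elif isinstance(rules, Mapping):
        resolved = dict(rules)
    else:
        unknown = [name for name in rules if name not in BUILTIN_RULES]
        if unknown:
            raise ValueError(f"unknown rule names: {unknown}")
        resolved = {name: BUILTIN_RULES[name] for name in rules}

    summaries = list(summaries)
    counts: dict[str, object] = {name: 0 for name in resolved}
    deciles = [0] * 10
    for s in summaries:
        for name, pred in resolved.items():
            if pred(s):
                counts[name] += 1
        # covered_fraction == 1.0 lands in the top decile
        deciles[min(int(s.covered_fraction * 10), 9)] += 1
    counts["covered_fraction_deciles"] = deciles
    counts["total_proteins"] = len(summaries)
    return counts


def coverage_timeline(
    hits_by_query: Mapping[str, Sequence[AlignmentHit]],
    proteins: Sequence[ProteinRecord],
    identity_grid: Sequence[float],
    years: Sequence[int],
) -> list[TimelinePoint]:
    """Coverage of the proteome per year, at each minimum-identity threshold.

    For year ``y`` only hits whose subject deposition year is <= y count
    (hits without a year always count).  The fraction at threshold ``t`` is
    the residue fraction with projected max identity >= t.
    """
    if list(years) != sorted(years):
        raise ValueError("years must be sorted ascending")
    identity_grid = sorted(identity_grid)
    total_residues = sum(p.length for p in proteins)
    points: list[TimelinePoint] = []
    for year in years:
        covered = {t: 0 for t in identity_grid}
        for protein in proteins:
            hits = [
                h
                for h in hits_by_query.get(protein.protein_id, ())
                if h.subject_year is None or h.subject_year <= year
            ]
            if not hits:
                continue
            ident = project_hits(hits, protein.length)
            with np.errstate(invalid="ignore"):
                for t in identity_grid:
                    covered[t] += int((ident >= t).sum())
        points.append(
            TimelinePoint(year, {t: covered[t] / total_residues for t in identity_grid})
        )
    return points


def gene_set_coverage(
    summaries: Iterable[ProteinSummary],
    sets: Sequence[GeneSet],
) -> tuple[dict[str, ProteomeSummary], ProteomeSummary, dict[str, list[str]]]:
    """Residue-weighted coverage restricted to each gene set.

    Returns ``(per_set, baseline, unknown_members)`` where ``baseline`` is
    the unrestricted aggregate and ``unknown_members`` lists, per set, the
    member gene ids that matched no protein (reported, not fatal).  A set
    with zero resolvable members is an error.
    """
    summaries = list(summaries)
    by_gene: dict[str, list[ProteinSummary]] = {}
    for s in summaries:
        by_gene.setdefault(s.gene_id, []).append(s)
    baseline = aggregate(summaries)
    per_set: dict[str, ProteomeSummary] = {}
    unknown: dict[str, list[str]] = {}
    for gene_set in sets:
        members: list[ProteinSummary] = []
        missing: list[str] = []
        for gid in sorted(gene_set.member_gene_ids):
            if gid in by_gene:
                members.extend(by_gene[gid])
            else:
                missing.append(gid)
        if not members:
            raise ValueError(f"gene set {gene_set.name!r} has no resolvable members")
        per_set[gene_set.name] = aggregate(members)
        unknown[gene_set.name] = missing
    return per_set, baseline, unknown


def variant_coverage(
    variants: Iterable[VariantRecord],
    tracks: Mapping[str, CategoryTrack],
) -> VariantCoverage:
    """Distribute variants of each class over the coverage categories.

    Variants on unknown proteins or beyond the protein length go to the
    rejects report and are excluded from all denominators.  Rollups per class:
    ``experimental`` (PDB_EXP), ``high_quality`` (PDB_EXP + PDB_HOMOLOGY +
    AF_HIGH) and ``any_structure`` (every category except IDR, DOMAIN_ONLY
    and DARK).
    """
    counts: dict[str, dict[CoverageCategory, int]] = {}
    rejects: list[tuple[VariantRecord, str]] = []
    for variant in variants:
        track = tracks.get(variant.protein_id)
        if track is None:
            rejects.append((variant, "unknown protein"))
            continue
        if variant.position > track.codes.size:
            rejects.append(
                (variant, f"position beyond protein length {track.codes.size}")
            )
            continue
        cat = CoverageCategory(track.codes[variant.position - 1])
        per_class = counts.setdefault(
            variant.class_label, {c: 0 for c in CoverageCategory}
        )
        per_class[cat] += 1

    fractions: dict[str, dict[CoverageCategory, float]] = {}
    rollups: dict[str, dict[str, float]] = {}
    for label, per_class in counts.items():
        n = sum(per_class.values())
        fractions[label] = {c: per_class[c] / n for c in CoverageCategory}
        rollups[label] = {
            "experimental": per_class[CoverageCategory.PDB_EXP] / n,
            "high_quality": sum(per_class[c] for c in HIGH_QUALITY_CATEGORIES) / n,
            "any_structure": sum(per_class[c] for c in STRUCTURED_CATEGORIES) / n,
        }
    return VariantCoverage(counts, fractions, rollups, rejects)


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table; returns (odds_ratio, p).

    p sums the hypergeometric probabilities, conditional on the margins, of
    all tables at most as probable as the observed one.  The odds ratio is
    (a*d)/(b*c) with the Haldane +0.5 correction applied to all four cells
    when any cell is zero (so it is always finite and positive).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    _, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return odds, float(min(p_value, 1.0))


def fisher_enrichment(
    universe: Iterable[str],
    gene_set: GeneSet,
    trait: Iterable[str],
) -> EnrichmentResult:
    """Two-sided Fisher exact test of a gene set against a trait gene list.

    The 2x2 table is (in-set & trait, in-set only, trait only, neither) over
    the universe; p comes from the exact conditional (hypergeometric)
    distribution.  The odds ratio is (a*d)/(b*c), with the Haldane +0.5
    correction applied to all four cells when any cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    set_genes = gene_set.member_gene_ids & universe
    trait_genes = set(trait) & universe
    a = len(set_genes & trait_genes)
    b = len(set_genes - trait_genes)
    c = len(trait_genes - set_genes)
    d = len(universe) - a - b - c
    odds, p_value = fisher_test(a, b, c, d)
    return EnrichmentResult(gene_set.name, a, b, c, d, odds, p_value)
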
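"""Per-residue evidence tracks and the nine-way coverage classification.

Each residue of a protein carries up to four layers of evidence: the best
percent identity of a template alignment spanning it, a predicted-model
confidence (pLDDT), an intrinsic-disorder score and domain membership.
:func:`resolve_categories` collapses the layers into exactly one
:class:`CoverageCategory` per residue using a fixed precedence: experimental
structure first, then high-identity templates, then high-confidence predicted
models, then remote templates and mid/low-confidence models, then disorder,
then bare domain annotation, with ``DARK`` as the universal fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentHit, DomainHit, ProteinRecord, ResidueScoreTable

__all__ = [
    "CoverageCategory",
    "Thresholds",
    "ResidueTracks",
    "CategoryTrack",
    "DEFAULT_PRECEDENCE",
    "project_hits",
    "classify_identity",
    "classify_plddt",
    "resolve_categories",
    "build_tracks",
    "summarize_protein",
]


class CoverageCategory(IntEnum):
    """Resolved coverage class of a residue; enum order is the precedence.

    ``PDB_EXP``       template identity > 95% (effectively the real structure)
    ``PDB_HOMOLOGY``  identity in [50, 95] (good homology models)
    ``AF_HIGH``       pLDDT >= 90 (high-confidence predicted model)
    ``PDB_REMOTE``    identity in [20, 50) (remote but usable templates)
    ``AF_MID``        pLDDT in [70, 90)
    ``AF_LOW``        pLDDT in [50, 70)
    ``IDR``           disorder score > 0.5
    ``DOMAIN_ONLY``   inside an annotated domain, no other evidence
    ``DARK``          nothing at all
    """

    PDB_EXP = 0
    PDB_HOMOLOGY = 1
    AF_HIGH = 2
    PDB_REMOTE = 3
    AF_MID = 4
    AF_LOW = 5
    IDR = 6
    DOMAIN_ONLY = 7
    DARK = 8


DEFAULT_PRECEDENCE: tuple[CoverageCategory, ...] = tuple(CoverageCategory)

#: Categories that count as structural coverage of any kind.
STRUCTURED_CATEGORIES = frozenset(
    {
        CoverageCategory.PDB_EXP,
        CoverageCategory.PDB_HOMOLOGY,
        CoverageCategory.AF_HIGH,
        CoverageCategory.PDB_REMOTE,
        CoverageCategory.AF_MID,
        CoverageCategory.AF_LOW,
    }
)

#: High-quality coverage: experimental/high-identity templates or pLDDT >= 90.
HIGH_QUALITY_CATEGORIES = frozenset(
    {
        CoverageCategory.PDB_EXP,
        CoverageCategory.PDB_HOMOLOGY,
        CoverageCategory.AF_HIGH,
    }
)


@dataclass(frozen=True)
class Thresholds:
    """All tier boundaries and filter cutoffs, with their default closures.

    The identity tiers are printed with overlapping bounds in common usage
    (">95", "95-50", "50-20"); the ``*_inclusive`` flags make the closure at
    each shared boundary explicit and configurable.  Defaults: identity
    exactly 95 or exactly 50 is assigned to the upper tier (PDB_HOMOLOGY);
    pLDDT boundaries close upward (90 -> AF_HIGH, 70 -> AF_MID, 50 -> AF_LOW);
    disorder is strictly > 0.5.
    """

    identity_exp: float = 95.0
    identity_high: float = 50.0
    identity_min: float = 20.0
    plddt_high: float = 90.0
    plddt_mid: float = 70.0
    plddt_low: float = 50.0
    disorder_cut: float = 0.5
    evalue_max: float = 1e-8
    # boundary closures
    identity_exp_exclusive: bool = True  # EXP requires identity > identity_exp
    identity_high_inclusive: bool = True  # identity == identity_high -> HOMOLOGY
    plddt_inclusive: bool = True  # pLDDT == boundary -> upper tier
    disorder_exclusive: bool = True  # IDR requires disorder > disorder_cut

    def __post_init__(self):
        if not (self.identity_min < self.identity_high < self.identity_exp <= 100):
            raise ValueError("require identity_min < identity_high < identity_exp <= 100")
        if not (self.plddt_low < self.plddt_mid < self.plddt_high <= 100):
            raise ValueError("require plddt_low < plddt_mid < plddt_high <= 100")
        if not (0 < self.disorder_cut < 1):
            raise ValueError("require 0 < disorder_cut < 1")

    @classmethod
    def from_mapping(cls, overrides: dict) -> "Thresholds":
        unknown = set(overrides) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown threshold names: {sorted(unknown)}")
        return cls(**overrides)


@dataclass
class ResidueTracks:
    """Parallel per-residue evidence arrays for one protein.

    Absent evidence is NaN in the float arrays.  ``max_identity`` holds, per
    residue, the maximum percent identity over all alignment hits spanning it.
    """

    protein_id: str
    length: int
    max_identity: np.ndarray
    plddt: np.ndarray
    disorder_score: np.ndarray
    in_domain: np.ndarray

    def __post_init__(self):
        for name in ("max_identity", "plddt", "disorder_score", "in_domain"):
            arr = getattr(self, name)
            if arr.shape != (self.length,):
                raise ValueError(
                    f"{self.protein_id}: {name} has shape {arr.shape}, "
                    f"expected ({self.length},)"
                )

    @classmethod
    def empty(cls, protein_id: str, length: int) -> "ResidueTracks":
        return cls(
            protein_id,
            length,
            np.full(length, np.nan),
            np.full(length, np.nan),
            np.full(length, np.nan),
            np.zeros(length, dtype=bool),
        )


@dataclass
class CategoryTrack:
    """Resolved per-residue categories for one protein (int8 codes)."""

    protein_id: str
    codes: np.ndarray

    @property
    def categories(self) -> list[CoverageCategory]:
        return [CoverageCategory(c) for c in self.codes]

    def fractions(self) -> dict[CoverageCategory, float]:
        counts = np.bincount(self.codes, minlength=len(CoverageCategory))
        n = self.codes.size
        return {cat: counts[cat.value] / n for cat in CoverageCategory}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CategoryTrack)
            and self.protein_id == other.protein_id
            and np.array_equal(self.codes, other.codes)
        )


def project_hits(
    hits: Iterable[AlignmentHit], length: int
) -> np.ndarray:
    """Project alignment hits onto a per-residue max-identity vector.

    Residue ``r`` (1-based) receives the maximum ``percent_identity`` over all
    hits whose query interval spans it; residues spanned by no hit are NaN.
    The whole qstart-qend interval counts as covered (tabular alignments
    carry no per-residue gap map).
    """
    out = np.full(length, np.nan)
    for hit in hits:
        if hit.qend > length:
            raise ValueError(
                f"hit {hit.query_id}->{hit.subject_id} ends at {hit.qend}, "
                f"beyond protein length {length}"
            )
        sl = slice(hit.qstart - 1, hit.qend)
        out[sl] = np.fmax(out[sl], hit.percent_identity)
    return out


def classify_identity(
    identity: float | None, t: Thresholds = Thresholds()
) -> CoverageCategory | None:
    """Map a percent identity to its template tier, or None when absent."""
    if identity is None or (isinstance(identity, float) and np.isnan(identity)):
        return None
    if identity < t.identity_min:
        raise ValueError(
            f"identity {identity} below the {t.identity_min}% filter reached "
            "classification: hits must be pre-filtered"
        )
    above_exp = identity > t.identity_exp if t.identity_exp_exclusive else identity >= t.identity_exp
    if above_exp:
        return CoverageCategory.PDB_EXP
    at_least_high = identity >= t.identity_high if t.identity_high_inclusive else identity > t.identity_high
    if at_least_high:
        return CoverageCategory.PDB_HOMOLOGY
    return CoverageCategory.PDB_REMOTE


def classify_plddt(
    plddt: float | None, t: Thresholds = Thresholds()
) -> CoverageCategory | None:
    """Map a pLDDT score to its confidence tier; below 50 or absent -> None."""
    if plddt is None or (isinstance(plddt, float) and np.isnan(plddt)):
        return None

    def at_least(bound: float) -> bool:
        return plddt >= bound if t.plddt_inclusive else plddt > bound

    if at_least(t.plddt_high):
        return CoverageCategory.AF_HIGH
    if at_least(t.plddt_mid):
        return CoverageCategory.AF_MID
    if at_least(t.plddt_low):
        return CoverageCategory.AF_LOW
    return None


def _category_masks(tracks: ResidueTracks, t: Thresholds) -> dict[CoverageCategory, np.ndarray]:
    ident = tracks.max_identity
    plddt = tracks.plddt
    disorder = tracks.disorder_score

    present = ~np.isnan(ident)
    if np.any(ident[present] < t.identity_min):
        bad = np.nanmin(ident[present])
        raise ValueError(
            f"{tracks.protein_id}: identity {bad} below the {t.identity_min}% "
            "filter in tracks; hits must be pre-filtered"
        )

    def ge(arr, bound, inclusive):
        with np.errstate(invalid="ignore"):
            return (arr >= bound) if inclusive else (arr > bound)

    exp = ge(ident, t.identity_exp, not t.identity_exp_exclusive)
    high = ge(ident, t.identity_high, t.identity_high_inclusive) & ~exp
    remote = present & ~exp & ~high
    af_high = ge(plddt, t.plddt_high, t.plddt_inclusive)
    af_mid = ge(plddt, t.plddt_mid, t.plddt_inclusive) & ~af_high
    af_low = ge(plddt, t.plddt_low, t.plddt_inclusive) & ~af_mid & ~af_high
    idr = ge(disorder, t.disorder_cut, not t.disorder_exclusive)
    return {
        CoverageCategory.PDB_EXP: exp,
        CoverageCategory.PDB_HOMOLOGY: high,
        CoverageCategory.AF_HIGH: af_high,
        CoverageCategory.PDB_REMOTE: remote,
        CoverageCategory.AF_MID: af_mid,
        CoverageCategory.AF_LOW: af_low,
        CoverageCategory.IDR: idr,
        CoverageCategory.DOMAIN_ONLY: tracks.in_domain.astype(bool),
        CoverageCategory.DARK: np.ones(tracks.length, dtype=bool),
    }


def resolve_categories(
    tracks: ResidueTracks,
    t: Thresholds = Thresholds(),
    precedence: Sequence[CoverageCategory] = DEFAULT_PRECEDENCE,
) -> CategoryTrack:
    """Resolve each residue to exactly one category.

    The first category in ``precedence`` whose evidence rule matches a residue
    wins; ``DARK`` matches everything and must be last.
    """
    if set(precedence) != set(CoverageCategory):
        raise ValueError("precedence must be a permutation of all categories")
    if precedence[-1] is not CoverageCategory.DARK:
        raise ValueError("DARK must be the last (fallback) category")
    masks = _category_masks(tracks, t)
    codes = np.full(tracks.length, -1, dtype=np.int8)
    for cat in precedence:
        sel = masks[cat] & (codes == -1)
        codes[sel] = cat.value
    return CategoryTrack(tracks.protein_id, codes)


def build_tracks(
    protein: ProteinRecord,
    hits: Sequence[AlignmentHit] = (),
    plddt: ResidueScoreTable | None = None,
    disorder: ResidueScoreTable | None = None,
    domains: Sequence[DomainHit] = (),
) -> ResidueTracks:
    """Assemble the per-residue evidence arrays for one protein."""
    tracks = ResidueTracks.empty(protein.protein_id, protein.length)
    tracks.max_identity = project_hits(hits, protein.length)
    if plddt is not None:
        tracks.plddt = plddt.to_dense(protein.length)
    if disorder is not None:
        tracks.disorder_score = disorder.to_dense(protein.length)
    for dom in domains:
        if dom.end > protein.length:
            raise ValueError(
                f"domain {dom.domain_id} ends at {dom.end}, beyond protein "
                f"length {protein.length}"
            )
        tracks.in_domain[dom.start - 1 : dom.end] = True
    return tracks


def summarize_protein(
    track: CategoryTrack,
    tracks: ResidueTracks,
    t: Thresholds = Thresholds(),
    gene_id: str | None = None,
):
    """Per-protein category fractions and the protein-level classification flags.

    Returns a :class:`structcover.proteome_stats.ProteinSummary` with:

    * ``has_pdb`` — any residue with a usable template (identity >= 20%);
    * ``has_any_structure`` — has_pdb or any residue with pLDDT >= 50;
    * ``hq_fraction`` — identity >= 50 or pLDDT >= 90;
    * ``af_high_fraction`` — pLDDT >= 90 on residues lacking a usable
      template, as a fraction of the whole protein length;
    * ``plddt_high_fraction`` — pLDDT >= 90 anywhere, over the whole length;
    * ``af_only_covered_fraction`` — pLDDT >= 50 on residues lacking a
      usable template, over the whole length;
    * ``covered_fraction`` — identity >= 20 or pLDDT >= 50.
    """
    from .proteome_stats import ProteinSummary

    if tracks.length == 0:
        raise ValueError(f"{tracks.protein_id}: zero-length protein")
    if track.codes.size != tracks.length:
        raise ValueError(f"{tracks.protein_id}: track/evidence length mismatch")

    with np.errstate(invalid="ignore"):
        has_template = tracks.max_identity >= t.identity_min
        hq_template = tracks.max_identity >= t.identity_high
        plddt_high = tracks.plddt >= t.plddt_high
        plddt_any = tracks.plddt >= t.plddt_low
    n = tracks.length
    return ProteinSummary(
        protein_id=tracks.protein_id,
        gene_id=gene_id if gene_id is not None else tracks.protein_id,
        length=n,
        fractions=track.fractions(),
        has_pdb=bool(has_template.any()),
        has_any_structure=bool(has_template.any() or plddt_any.any()),
        hq_fraction=float((hq_template | plddt_high).sum() / n),
        af_high_fraction=float((plddt_high & ~has_template).sum() / n),
        plddt_high_fraction=float(plddt_high.sum() / n),
        af_only_covered_fraction=float((plddt_any & ~has_template).sum() / n),
        covered_fraction=float((has_template | plddt_any).sum() / n),
    )
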
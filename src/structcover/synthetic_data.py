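"""Synthetic proteome generator with planted per-residue ground truth.

The generator builds a proteome whose residues carry *planted* coverage
categories, then emits evidence files (alignment hits, pLDDT, disorder,
domain and variant tables) that are mutually consistent with those
categories: running the full pipeline on the emitted files must reproduce
the planted categories residue-for-residue.  Exactness comes from
bookkeeping the realized draws, not from expectations.

Two safeguards keep the round trip exact:

* tier-interior sampling — every sampled identity/pLDDT/disorder value stays
  ``boundary_margin`` units away from all tier boundaries, so boundary
  closure settings cannot flip a planted category (a separate
  :func:`boundary_cases` helper emits exactly-on-threshold values for
  closure tests);
* masking noise — extra evidence is only ever added where a higher-
  precedence category already holds (e.g. a remote-identity hit under a
  high-confidence model segment), so it cannot change the resolved label.

Default category weights follow the proteome-wide stack reported for the
human proteome: 17% experimental, 14% high-identity templates, 19%
high-confidence models, 8% remote templates, 11%/7% mid/low-confidence
models, 12% disordered, 2% domain-only, 10% dark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .coverage_core import CategoryTrack, CoverageCategory, Thresholds
from .io_formats import ProteinRecord, write_category_bed

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticFold",
    "DEFAULT_CATEGORY_WEIGHTS",
    "DEFAULT_VARIANT_CLASSES",
    "generate_proteome",
    "generate_variants",
    "generate_fold",
    "boundary_cases",
]

#: Residue-fraction targets per category (the observed human-proteome stack).
DEFAULT_CATEGORY_WEIGHTS: dict[CoverageCategory, float] = {
    CoverageCategory.PDB_EXP: 0.17,
    CoverageCategory.PDB_HOMOLOGY: 0.14,
    CoverageCategory.AF_HIGH: 0.19,
    CoverageCategory.PDB_REMOTE: 0.08,
    CoverageCategory.AF_MID: 0.11,
    CoverageCategory.AF_LOW: 0.07,
    CoverageCategory.IDR: 0.12,
    CoverageCategory.DOMAIN_ONLY: 0.02,
    CoverageCategory.DARK: 0.10,
}

#: Default variant classes: count and category-bias weights per class.
#: Pathogenic-like classes are biased toward structured regions, mirroring
#: the enrichment of disease mutations in well-characterized proteins.
DEFAULT_VARIANT_CLASSES: dict[str, tuple[int, dict[CoverageCategory, float]]] = {
    "pathogenic": (
        2000,
        {
            CoverageCategory.PDB_EXP: 0.30,
            CoverageCategory.PDB_HOMOLOGY: 0.20,
            CoverageCategory.AF_HIGH: 0.20,
            CoverageCategory.PDB_REMOTE: 0.10,
            CoverageCategory.AF_MID: 0.08,
            CoverageCategory.AF_LOW: 0.05,
            CoverageCategory.IDR: 0.04,
            CoverageCategory.DOMAIN_ONLY: 0.01,
            CoverageCategory.DARK: 0.02,
        },
    ),
    "benign": (2000, dict(DEFAULT_CATEGORY_WEIGHTS)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic proteome.

    ``conditional_plddt_overlap`` is the probability that a template-covered
    residue also receives a high pLDDT (72% of experimentally covered
    residues carry pLDDT >= 90 in the human data); it only adds masked
    evidence.  ``masking_noise`` is the per-segment probability of other
    masked-evidence decorations.  ``boundary_margin`` keeps sampled scores
    away from tier boundaries.
    """

    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 2000)
    target_category_weights: Mapping[CoverageCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    mean_segment_length: float = 60.0
    conditional_plddt_overlap: float = 0.72
    variant_classes: Mapping[str, tuple[int, Mapping[CoverageCategory, float]]] = field(
        default_factory=lambda: {
            k: (n, dict(w)) for k, (n, w) in DEFAULT_VARIANT_CLASSES.items()
        }
    )
    year_range: tuple[int, int] = (1995, 2020)
    seed: int = 42
    masking_noise: float = 0.1
    boundary_margin: float = 0.5
    n_gene_sets: int = 4
    gene_set_fraction: float = 0.1
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self):
        weights = dict(self.target_category_weights)
        if set(weights) != set(CoverageCategory):
            raise ValueError("category weights must cover all nine categories")
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category weights sum to {total}, not 1")
        if self.mean_segment_length < 1:
            raise ValueError("mean_segment_length must be >= 1")
        if not (self.length_range[0] >= 1 and self.length_range[0] <= self.length_range[1]):
            raise ValueError("bad length_range")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for exact downstream verification."""

    config: GeneratorConfig
    proteins: list[ProteinRecord]
    planted: dict[str, CategoryTrack]
    planted_aggregate: dict[CoverageCategory, float]
    gene_sets: dict[str, list[str]]
    hit_rows: list[tuple]
    plddt_rows: list[tuple[str, int, float]]
    disorder_rows: list[tuple[str, int, float]]
    domain_rows: list[tuple[str, int, int, str, float]]
    variant_rows: list[tuple[str, int, str]] = field(default_factory=list)
    variant_truth: dict[str, dict[CoverageCategory, int]] = field(default_factory=dict)

    def planted_counts(self) -> dict[CoverageCategory, int]:
        counts = {c: 0 for c in CoverageCategory}
        for track in self.planted.values():
            binc = np.bincount(track.codes, minlength=len(CoverageCategory))
            for c in CoverageCategory:
                counts[c] += int(binc[c.value])
        return counts

    def write_files(self, out_dir) -> dict[str, Path]:
        """Emit every evidence file plus truth.json and the planted BED."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["proteins"] = out / "proteins.tsv"
        with open(paths["proteins"], "w") as fh:
            fh.write("protein_id\tgene_id\tlength\n")
            for p in self.proteins:
                fh.write(f"{p.protein_id}\t{p.gene_id}\t{p.length}\n")

        paths["hits"] = out / "hits.tsv"
        with open(paths["hits"], "w") as fh:
            fh.write(
                "# qseqid sseqid pident length mismatch gapopen qstart qend "
                "sstart send evalue bitscore year\n"
            )
            for row in self.hit_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")

        paths["plddt"] = out / "plddt.tsv"
        with open(paths["plddt"], "w") as fh:
            fh.write("protein_id\tposition\tplddt\n")
            for pid, pos, score in self.plddt_rows:
                fh.write(f"{pid}\t{pos}\t{score:.2f}\n")

        paths["disorder"] = out / "disorder.tsv"
        with open(paths["disorder"], "w") as fh:
            fh.write("protein_id\tposition\tscore\n")
            for pid, pos, score in self.disorder_rows:
                fh.write(f"{pid}\t{pos}\t{score:.3f}\n")

        paths["domains"] = out / "domains.tsv"
        with open(paths["domains"], "w") as fh:
            fh.write("protein_id\tstart\tend\tdomain_id\tevalue\n")
            for pid, start, end, dom, ev in self.domain_rows:
                fh.write(f"{pid}\t{start}\t{end}\t{dom}\t{ev:g}\n")

        paths["gene_sets"] = out / "gene_sets.tsv"
        with open(paths["gene_sets"], "w") as fh:
            fh.write("name\tgene_id\n")
            for name, members in self.gene_sets.items():
                for gid in members:
                    fh.write(f"{name}\t{gid}\n")

        if self.variant_rows:
            paths["variants"] = out / "variants.tsv"
            with open(paths["variants"], "w") as fh:
                fh.write("protein_id\tposition\tclass_label\n")
                for pid, pos, label in self.variant_rows:
                    fh.write(f"{pid}\t{pos}\t{label}\n")

        paths["planted_bed"] = out / "planted_categories.bed"
        write_category_bed(self.planted, paths["planted_bed"])

        paths["truth"] = out / "truth.json"
        counts = self.planted_counts()
        truth = {
            "seed": self.config.seed,
            "n_proteins": len(self.proteins),
            "total_residues": sum(p.length for p in self.proteins),
            "planted_fractions": {
                c.name: self.planted_aggregate[c] for c in CoverageCategory
            },
            "planted_counts": {c.name: counts[c] for c in CoverageCategory},
            "variant_truth": {
                label: {c.name: n for c, n in per.items()}
                for label, per in self.variant_truth.items()
            },
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")
        return paths


def _tier_bounds(cat: CoverageCategory, t: Thresholds, margin: float):
    """Safe (lo, hi) sampling interval for the score that defines a tier."""
    bounds = {
        CoverageCategory.PDB_EXP: (t.identity_exp + margin, 100.0 - margin),
        CoverageCategory.PDB_HOMOLOGY: (t.identity_high + margin, t.identity_exp - margin),
        CoverageCategory.PDB_REMOTE: (t.identity_min + margin, t.identity_high - margin),
        CoverageCategory.AF_HIGH: (t.plddt_high + margin, 100.0 - margin),
        CoverageCategory.AF_MID: (t.plddt_mid + margin, t.plddt_high - margin),
        CoverageCategory.AF_LOW: (t.plddt_low + margin, t.plddt_mid - margin),
    }
    return bounds[cat]


_PDB_TIERS = (
    CoverageCategory.PDB_EXP,
    CoverageCategory.PDB_HOMOLOGY,
    CoverageCategory.PDB_REMOTE,
)
_AF_TIERS = (CoverageCategory.AF_HIGH, CoverageCategory.AF_MID, CoverageCategory.AF_LOW)


def _segment_lengths(rng: np.random.Generator, total: int, mean: float) -> list[int]:
    lengths: list[int] = []
    remaining = total
    while remaining > 0:
        seg = int(rng.geometric(1.0 / mean))
        seg = max(1, min(seg, remaining))
        lengths.append(seg)
        remaining -= seg
    return lengths


def generate_proteome(config: GeneratorConfig = GeneratorConfig()) -> SyntheticTruth:
    """Generate a proteome with planted categories and consistent evidence.

    Each protein is cut into geometric-length segments; each segment draws a
    category from the target weights and the evidence that *defines* that
    category is emitted for its residues, plus optional masked noise.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t = config.thresholds
    margin = config.boundary_margin
    cats = list(CoverageCategory)
    weights = np.array([config.target_category_weights[c] for c in cats])

    proteins: list[ProteinRecord] = []
    planted: dict[str, CategoryTrack] = {}
    hit_rows: list[tuple] = []
    plddt_rows: list[tuple[str, int, float]] = []
    disorder_rows: list[tuple[str, int, float]] = []
    domain_rows: list[tuple[str, int, int, str, float]] = []
    domain_counter = 0

    lo_len, hi_len = config.length_range
    year_lo, year_hi = config.year_range

    def add_hit(pid: str, start: int, end: int, identity: float, tier: str) -> None:
        year = int(rng.integers(year_lo, year_hi + 1))
        span = end - start + 1
        hit_rows.append(
            (
                pid,
                f"pdb|{tier}|{year}",
                f"{identity:.2f}",
                span,
                0,
                0,
                start,
                end,
                1,
                span,
                "1e-20",
                round(span * 2.0, 1),
                year,
            )
        )

    def add_scores(rows, pid, start, values, fmt_positions=None):
        positions = range(start, start + len(values)) if fmt_positions is None else fmt_positions
        for pos, val in zip(positions, values):
            rows.append((pid, pos, float(val)))

    for i in range(config.n_proteins):
        pid = f"P{i:05d}"
        gid = f"G{i:05d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        proteins.append(ProteinRecord(pid, gid, length))
        codes = np.empty(length, dtype=np.int8)

        start = 1
        for seg_len in _segment_lengths(rng, length, config.mean_segment_length):
            end = start + seg_len - 1
            cat = cats[int(rng.choice(len(cats), p=weights))]
            codes[start - 1 : end] = cat.value

            if cat in _PDB_TIERS:
                lo, hi = _tier_bounds(cat, t, margin)
                add_hit(pid, start, end, rng.uniform(lo, hi), cat.name)
                # masked pLDDT overlap: high under EXP/HOMOLOGY, mid under REMOTE
                overlap = rng.random(seg_len) < config.conditional_plddt_overlap
                if overlap.any():
                    if cat is CoverageCategory.PDB_REMOTE:
                        plo, phi = _tier_bounds(CoverageCategory.AF_MID, t, margin)
                    else:
                        plo, phi = _tier_bounds(CoverageCategory.AF_HIGH, t, margin)
                    vals = rng.uniform(plo, phi, int(overlap.sum()))
                    add_scores(
                        plddt_rows, pid, None, vals,
                        fmt_positions=(start + j for j in np.flatnonzero(overlap)),
                    )
            elif cat in _AF_TIERS:
                lo, hi = _tier_bounds(cat, t, margin)
                add_scores(plddt_rows, pid, start, rng.uniform(lo, hi, seg_len))
                if cat is CoverageCategory.AF_HIGH and rng.random() < config.masking_noise:
                    # remote template under a high-confidence model: masked
                    rlo, rhi = _tier_bounds(CoverageCategory.PDB_REMOTE, t, margin)
                    add_hit(pid, start, end, rng.uniform(rlo, rhi), "NOISE")
                if cat is CoverageCategory.AF_LOW and rng.random() < config.masking_noise:
                    # disorder call under a low-confidence model: masked
                    add_scores(
                        disorder_rows, pid, start,
                        rng.uniform(t.disorder_cut + 0.05, 0.95, seg_len),
                    )
            elif cat is CoverageCategory.IDR:
                add_scores(
                    disorder_rows, pid, start,
                    rng.uniform(t.disorder_cut + 0.05, 0.95, seg_len),
                )
                low = rng.random(seg_len) < 0.5
                if low.any():
                    add_scores(
                        plddt_rows, pid, None,
                        rng.uniform(0.0, t.plddt_low - margin, int(low.sum())),
                        fmt_positions=(start + j for j in np.flatnonzero(low)),
                    )
                if rng.random() < config.masking_noise:
                    # domain annotation under a disordered segment: masked
                    domain_counter += 1
                    domain_rows.append((pid, start, end, f"PF{domain_counter:05d}", 1e-12))
            elif cat is CoverageCategory.DOMAIN_ONLY:
                domain_counter += 1
                domain_rows.append((pid, start, end, f"PF{domain_counter:05d}", 1e-12))
                if rng.random() < 0.5:
                    add_scores(
                        disorder_rows, pid, start,
                        rng.uniform(0.0, t.disorder_cut - 0.05, seg_len),
                    )
                if rng.random() < 0.5:
                    add_scores(
                        plddt_rows, pid, start,
                        rng.uniform(0.0, t.plddt_low - margin, seg_len),
                    )
            else:  # DARK: only sub-threshold evidence, if any
                if rng.random() < 0.3:
                    add_scores(
                        disorder_rows, pid, start,
                        rng.uniform(0.0, t.disorder_cut - 0.05, seg_len),
                    )
                if rng.random() < 0.3:
                    add_scores(
                        plddt_rows, pid, start,
                        rng.uniform(0.0, t.plddt_low - margin, seg_len),
                    )
            start = end + 1

        planted[pid] = CategoryTrack(pid, codes)

    total = sum(p.length for p in proteins)
    counts = {c: 0 for c in CoverageCategory}
    for track in planted.values():
        binc = np.bincount(track.codes, minlength=len(CoverageCategory))
        for c in CoverageCategory:
            counts[c] += int(binc[c.value])
    planted_aggregate = {c: counts[c] / total for c in CoverageCategory}

    gene_ids = [p.gene_id for p in proteins]
    n_members = max(1, int(round(config.gene_set_fraction * len(gene_ids))))
    gene_sets = {
        f"SET{k}": sorted(
            rng.choice(gene_ids, size=min(n_members, len(gene_ids)), replace=False)
        )
        for k in range(config.n_gene_sets)
    }

    truth = SyntheticTruth(
        config=config,
        proteins=proteins,
        planted=planted,
        planted_aggregate=planted_aggregate,
        gene_sets=gene_sets,
        hit_rows=hit_rows,
        plddt_rows=plddt_rows,
        disorder_rows=disorder_rows,
        domain_rows=domain_rows,
    )
    generate_variants(truth, config, rng)
    return truth


def generate_variants(
    truth: SyntheticTruth,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Plant class-labelled variants with category-biased placement.

    Each variant draws its category from the class's bias weights
    (restricted to categories that still have unused residues) and then an
    unused residue of that planted category, uniformly without replacement
    within the class.  The realized per-category counts are recorded in
    ``truth.variant_truth`` (exact bookkeeping).
    """
    config = config or truth.config
    rng = rng or np.random.default_rng(config.seed + 1)

    # residue pools per planted category, as (protein, position) pairs
    pools: dict[CoverageCategory, list[tuple[str, int]]] = {
        c: [] for c in CoverageCategory
    }
    for pid in sorted(truth.planted):
        codes = truth.planted[pid].codes
        for c in CoverageCategory:
            for pos in np.flatnonzero(codes == c.value):
                pools[c].append((pid, int(pos) + 1))

    truth.variant_rows.clear()
    truth.variant_truth.clear()
    cats = list(CoverageCategory)
    for label in sorted(config.variant_classes):
        count, bias = config.variant_classes[label]
        w = np.array([bias.get(c, 0.0) for c in cats], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"variant class {label!r}: bias weights sum to 0")
        capacity = sum(len(pools[c]) for c, wc in zip(cats, w) if wc > 0)
        if count > capacity:
            raise ValueError(
                f"variant class {label!r} requests {count} variants but only "
                f"{capacity} residues are eligible under its category bias"
            )
        # per-class shuffled copies of the pools; draws pop without replacement
        remaining = {
            c: [pools[c][j] for j in rng.permutation(len(pools[c]))]
            for c, wc in zip(cats, w)
            if wc > 0
        }
        realized: dict[CoverageCategory, int] = {c: 0 for c in CoverageCategory}
        for _ in range(count):
            live = [c for c in remaining if remaining[c]]
            wl = np.array([bias[c] for c in live], dtype=float)
            cat = live[int(rng.choice(len(live), p=wl / wl.sum()))]
            pid, pos = remaining[cat].pop()
            truth.variant_rows.append((pid, pos, label))
            realized[cat] += 1
        truth.variant_truth[label] = realized


@dataclass
class SyntheticFold:
    """A seeded self-avoiding CA trace with 3.8 A steps.

    Consecutive alpha-carbons are exactly 3.8 A apart and no two are closer
    than 3.0 A.  When a cluster is requested, the designated residues are
    guaranteed pairwise within the given radius.
    """

    xyz: np.ndarray  # (n, 3), Angstrom
    cluster_positions: tuple[int, ...] = ()  # 1-based
    plddt: np.ndarray | None = None

    @property
    def length(self) -> int:
        return self.xyz.shape[0]

    def to_structure_coords(self, protein_id: str = "SYNTH"):
        from .mutation_clustering import StructureCoords

        return StructureCoords(
            protein_id,
            np.arange(1, self.length + 1),
            self.xyz,
            self.plddt,
        )

    def write_pdb(self, path, protein_id: str = "SYNTH") -> None:
        """Write a CA-only PDB file; the B-factor column carries pLDDT."""
        structure = gemmi.Structure()
        structure.name = protein_id
        model = gemmi.Model(1)
        chain = gemmi.Chain("A")
        for i, (x, y, z) in enumerate(self.xyz, start=1):
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = float(self.plddt[i - 1]) if self.plddt is not None else 99.0
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
        structure.add_model(model)
        structure.write_pdb(str(path))


_STEP = 3.8
_MIN_SEP = 3.0


def _min_sep_ok(candidate: np.ndarray, obstacles: np.ndarray) -> bool:
    if obstacles.shape[0] == 0:
        return True
    return float(np.min(np.linalg.norm(obstacles - candidate, axis=1))) >= _MIN_SEP


def _bridge_step(
    rng: np.random.Generator,
    current: np.ndarray,
    target: np.ndarray | None,
    remaining: int,
    obstacles: np.ndarray,
) -> np.ndarray | None:
    """One 3.8 A step; keeps the target reachable in the remaining steps."""
    dvec = None if target is None else target - current
    for trial in range(120):
        if dvec is None:
            direction = rng.normal(size=3)
        else:
            # ramp up steering toward the anchor as trials fail, keeping noise
            steer = min(3.0, trial / 20)
            direction = rng.normal(size=3) + steer * dvec / max(
                np.linalg.norm(dvec), 1e-9
            )
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        candidate = current + direction / norm * _STEP
        if target is not None:
            d_new = float(np.linalg.norm(target - candidate))
            if d_new > remaining * _STEP:
                continue  # anchor would become unreachable
        if _min_sep_ok(candidate, obstacles):
            return candidate
    return None


def _penultimate_step(
    rng: np.random.Generator,
    current: np.ndarray,
    target: np.ndarray,
    obstacles: np.ndarray,
) -> np.ndarray | None:
    """Point at 3.8 A from both current and target: a random point on the
    intersection circle of the two spheres (exact arrival construction)."""
    axis = target - current
    d = float(np.linalg.norm(axis))
    if d < 1e-9 or d > 2 * _STEP:
        return None
    axis = axis / d
    circle_center = current + axis * (d / 2)
    rc_sq = _STEP**2 - (d / 2) ** 2
    if rc_sq <= 0:
        return None
    rc = np.sqrt(rc_sq)
    # orthonormal basis of the plane normal to the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    for _ in range(40):
        angle = rng.uniform(0, 2 * np.pi)
        candidate = circle_center + rc * (np.cos(angle) * u + np.sin(angle) * v)
        if _min_sep_ok(candidate, obstacles):
            return candidate
    return None


def _try_walk(
    rng: np.random.Generator,
    length: int,
    targets: dict[int, np.ndarray],
) -> np.ndarray | None:
    """One self-avoiding walk attempt landing exactly on each anchor point."""
    coords = np.zeros((length, 3))
    target_steps = sorted(targets)
    future_anchors = list(target_steps)

    for i in range(1, length):
        t_step = future_anchors[0] if future_anchors else None
        # obstacles: all placed residues except the immediate predecessor,
        # plus the anchors not yet reached (their residues come later)
        parts = [coords[: max(i - 1, 0)]]
        parts += [targets[j].reshape(1, 3) for j in future_anchors if j != i]
        obstacles = np.vstack(parts) if parts else np.empty((0, 3))

        if t_step == i:
            candidate = targets[i]
            if abs(np.linalg.norm(candidate - coords[i - 1]) - _STEP) > 1e-6:
                return None
            if not _min_sep_ok(candidate, obstacles):
                return None
            coords[i] = candidate
            future_anchors.pop(0)
            continue
        if t_step == i + 1:
            candidate = _penultimate_step(rng, coords[i - 1], targets[t_step], obstacles)
        else:
            remaining = None if t_step is None else t_step - i
            candidate = _bridge_step(
                rng, coords[i - 1],
                None if t_step is None else targets[t_step],
                remaining if remaining is not None else 0,
                obstacles,
            )
        if candidate is None:
            return None
        coords[i] = candidate
    return coords


def generate_fold(
    length: int,
    cluster: tuple[Sequence[int] | int, float] | None = None,
    seed: int = 0,
) -> SyntheticFold:
    """Generate a self-avoiding CA trace, optionally with a planted cluster.

    ``cluster`` is ``(positions, radius)`` where positions are 1-based
    residue numbers (or an integer k for k evenly spaced residues): the
    designated residues end up pairwise within ``radius`` Angstrom.
    Deterministic given ``seed``; raises when the requested cluster is
    geometrically infeasible given the 3.0 A excluded volume.
    """
    if length < 2:
        raise ValueError("fold length must be >= 2")
    rng = np.random.default_rng(seed)

    cluster_positions: tuple[int, ...] = ()
    anchor_points: np.ndarray | None = None
    if cluster is not None:
        spec_positions, radius = cluster
        if isinstance(spec_positions, (int, np.integer)):
            k = int(spec_positions)
            cluster_positions = tuple(
                int(round((j + 1) * length / (k + 1))) for j in range(k)
            )
        else:
            cluster_positions = tuple(sorted(int(p) for p in spec_positions))
        k = len(cluster_positions)
        if k < 2:
            raise ValueError("cluster needs at least 2 positions")
        if any(p < 1 or p > length for p in cluster_positions):
            raise ValueError("cluster positions outside the chain")
        if any(
            b - a < 2
            for a, b in zip(cluster_positions, cluster_positions[1:])
        ):
            raise ValueError("cluster positions must be >= 2 residues apart in sequence")
        if radius < _MIN_SEP:
            raise ValueError(
                f"cluster radius {radius} A infeasible: excluded volume keeps "
                f"CAs >= {_MIN_SEP} A apart"
            )
        # crude sphere-packing feasibility bound for k points within radius
        if k * (_MIN_SEP / 2) ** 3 > (radius / 2 + _MIN_SEP / 2) ** 3:
            raise ValueError(
                f"cluster of {k} residues within {radius} A is infeasible "
                f"at {_MIN_SEP} A exclusion"
            )
        # anchor points: mutually within radius, at least _MIN_SEP apart
        anchor_r = radius / 2
        for attempt in range(2000):
            pts = rng.uniform(-anchor_r, anchor_r, size=(k, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() >= _MIN_SEP and d[d < np.inf].max() <= radius:
                anchor_points = pts
                break
        else:
            raise ValueError("could not place cluster anchors; radius too tight")

    for attempt in range(500):
        targets: dict[int, np.ndarray] = {}
        if anchor_points is not None:
            # keep the cluster reachable from the walk start at the origin
            first_step = cluster_positions[0] - 1
            max_offset = max(first_step, 1) * _STEP * 0.6
            offset = rng.normal(scale=3.0, size=3) + np.array(
                [min(15.0, max_offset), 0.0, 0.0]
            )
            targets = {
                p - 1: anchor_points[j] + offset
                for j, p in enumerate(cluster_positions)
            }
            if 0 in targets:  # cluster at the very first residue
                shift = targets[0].copy()
                targets = {s: t - shift for s, t in targets.items()}
        coords = _try_walk(rng, length, targets)
        if coords is not None:
            return SyntheticFold(coords, cluster_positions)
    raise RuntimeError("failed to generate a self-avoiding fold; try another seed")


def boundary_cases(t: Thresholds = Thresholds()) -> list[dict]:
    """Exactly-on-threshold evidence values with their expected category
    under the default boundary closures (for closure regression tests)."""
    C = CoverageCategory
    return [
        {"identity": t.identity_exp, "expected": C.PDB_HOMOLOGY},
        {"identity": np.nextafter(t.identity_exp, 200), "expected": C.PDB_EXP},
        {"identity": t.identity_high, "expected": C.PDB_HOMOLOGY},
        {"identity": np.nextafter(t.identity_high, 0), "expected": C.PDB_REMOTE},
        {"identity": t.identity_min, "expected": C.PDB_REMOTE},
        {"plddt": t.plddt_high, "expected": C.AF_HIGH},
        {"plddt": np.nextafter(t.plddt_high, 0), "expected": C.AF_MID},
        {"plddt": t.plddt_mid, "expected": C.AF_MID},
        {"plddt": t.plddt_low, "expected": C.AF_LOW},
        {"plddt": np.nextafter(t.plddt_low, 0), "expected": C.DARK},
        {"disorder": t.disorder_cut, "expected": C.DARK},
        {"disorder": np.nextafter(t.disorder_cut, 1), "expected": C.IDR},
    ]
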
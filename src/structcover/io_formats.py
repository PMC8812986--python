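"""Readers and writers for the evidence-file dialects of the coverage pipeline.

All input coordinates are 1-based inclusive (the BLAST / Pfamscan / VEP
convention).  The only 0-based half-open surface is the BED output written by
:func:`write_category_bed`.

Supported dialects:

* BLAST tabular (``outfmt 6``) with an optional 13th column carrying the
  subject structure's deposition year;
* per-residue score tables (TSV with header ``protein_id  position  score``)
  for pLDDT and disorder;
* PDB-style coordinate files, from which the per-residue score is taken from
  the B-factor of the alpha-carbon record (AlphaFold models store pLDDT
  there);
* Pfamscan-style domain tables, VEP-style variant tables and long-format
  gene-set lists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .coverage_core import CategoryTrack

__all__ = [
    "ParseError",
    "ProteinRecord",
    "AlignmentHit",
    "DomainHit",
    "ResidueScoreTable",
    "VariantRecord",
    "GeneSet",
    "read_proteins",
    "read_alignment_hits",
    "read_plddt",
    "read_disorder",
    "read_domains",
    "read_variants",
    "read_gene_sets",
    "read_coordinates",
    "write_category_bed",
    "read_category_bed",
    "write_summary",
    "read_summary",
]

DEFAULT_MIN_IDENTITY = 20.0
DEFAULT_MAX_EVALUE = 1e-8


class ParseError(ValueError):
    """Raised for malformed evidence files; carries file and line context."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein in the analysis universe: one chosen isoform per gene."""

    protein_id: str
    gene_id: str
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST tabular hit of a query protein against a structure chain."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    qstart: int
    qend: int
    subject_year: int | None = None


@dataclass(frozen=True)
class DomainHit:
    """A Pfam-style domain interval on a protein (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    domain_id: str
    evalue: float


@dataclass
class ResidueScoreTable:
    """Sparse per-residue scores for one protein (positions 1-based)."""

    protein_id: str
    positions: np.ndarray  # int, strictly increasing
    scores: np.ndarray  # float, parallel to positions

    def to_dense(self, length: int) -> np.ndarray:
        """Dense length-sized vector; residues without a score are NaN."""
        out = np.full(length, np.nan)
        if self.positions.size:
            if self.positions[-1] > length:
                raise ValueError(
                    f"{self.protein_id}: score at position {self.positions[-1]} "
                    f"beyond protein length {length}"
                )
            out[self.positions - 1] = self.scores
        return out


@dataclass(frozen=True)
class VariantRecord:
    """A protein-coordinate variant with a free-form class label."""

    protein_id: str
    position: int
    class_label: str


@dataclass(frozen=True)
class GeneSet:
    name: str
    member_gene_ids: frozenset[str]

    def __post_init__(self):
        if not self.member_gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_proteins(path) -> list[ProteinRecord]:
    """Read the proteome table (TSV: protein_id, gene_id, length)."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "protein_id":
            continue
        if len(parts) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
        pid, gid, length_s = parts
        try:
            length = int(length_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {length_s!r}") from None
        if length < 1:
            raise ParseError(path, lineno, f"length must be >= 1, got {length}")
        if pid in seen:
            raise ParseError(path, lineno, f"duplicate protein_id {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(pid, gid, length))
    return records


def read_alignment_hits(
    path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> dict[str, list[AlignmentHit]]:
    """Read BLAST tabular hits, keeping rows with ``evalue < max_evalue`` and
    ``percent_identity >= min_identity``.

    The file is standard ``outfmt 6`` (12 tab-separated columns: qseqid sseqid
    pident length mismatch gapopen qstart qend sstart send evalue bitscore)
    with an optional 13th column carrying the subject deposition year.  Hits
    are grouped by query id, preserving file order within each query.
    """
    hits: dict[str, list[AlignmentHit]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) not in (12, 13):
            raise ParseError(
                path, lineno, f"expected 12 or 13 columns, got {len(parts)}"
            )
        qid, sid = parts[0], parts[1]
        try:
            pident = float(parts[2])
            qstart = int(parts[6])
            qend = int(parts[7])
            evalue = float(parts[10])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-numeric field: {exc}") from None
        if not (0.0 <= pident <= 100.0):
            raise ParseError(path, lineno, f"percent identity {pident} outside [0,100]")
        if evalue < 0:
            raise ParseError(path, lineno, f"negative e-value {evalue}")
        if qstart < 1 or qstart > qend:
            raise ParseError(
                path, lineno, f"bad query interval qstart={qstart} qend={qend}"
            )
        year: int | None = None
        if len(parts) == 13 and parts[12] != "":
            try:
                year = int(parts[12])
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-integer subject year {parts[12]!r}"
                ) from None
        if evalue >= max_evalue or pident < min_identity:
            continue
        hits.setdefault(qid, []).append(
            AlignmentHit(qid, sid, pident, evalue, qstart, qend, year)
        )
    return hits


def _read_score_table(
    path, score_column: str, lo: float, hi: float
) -> dict[str, ResidueScoreTable]:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"protein_id", "position", score_column}
    if not expected.issubset(df.columns):
        raise ParseError(
            path, None, f"expected columns {sorted(expected)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        return {}
    if not np.issubdtype(df["position"].dtype, np.integer):
        raise ParseError(path, None, "positions must be integers")
    if (df["position"] < 1).any():
        raise ParseError(path, None, "positions must be >= 1")
    scores = df[score_column].to_numpy(dtype=float)
    if np.isnan(scores).any() or (scores < lo).any() or (scores > hi).any():
        raise ParseError(path, None, f"{score_column} scores outside [{lo},{hi}]")
    out: dict[str, ResidueScoreTable] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position", kind="stable")
        pos = sub["position"].to_numpy(dtype=np.int64)
        val = sub[score_column].to_numpy(dtype=float)
        dup = np.flatnonzero(pos[1:] == pos[:-1])
        if dup.size:
            conflict = val[dup] != val[dup + 1]
            if conflict.any():
                bad = pos[dup[conflict][0]]
                raise ParseError(
                    path, None,
                    f"{pid}: conflicting scores at duplicate position {bad}",
                )
            keep = np.concatenate([pos[1:] != pos[:-1], [True]])
            pos, val = pos[keep], val[keep]
        out[str(pid)] = ResidueScoreTable(str(pid), pos, val)
    return out


def read_plddt(path, dialect: str = "tsv") -> dict[str, ResidueScoreTable]:
    """Read per-residue pLDDT scores.

    ``dialect='tsv'`` expects columns protein_id/position/plddt.
    ``dialect='coordinate-file'`` reads one protein per PDB-style file, taking
    the score from the B-factor of each residue's alpha-carbon record (the
    convention used by AlphaFold model files).  Positions absent from the file
    stay absent; downstream they are equivalent to pLDDT < 50.
    """
    if dialect == "tsv":
        return _read_score_table(path, "plddt", 0.0, 100.0)
    if dialect == "coordinate-file":
        pid, positions, _, bfac = read_coordinates(path)
        if positions.size and (np.nanmin(bfac) < 0 or np.nanmax(bfac) > 100):
            raise ParseError(path, None, "B-factor pLDDT outside [0,100]")
        return {pid: ResidueScoreTable(pid, positions, bfac)}
    raise ValueError(f"unknown pLDDT dialect {dialect!r}")


def read_disorder(path) -> dict[str, ResidueScoreTable]:
    """Read IUPred-style disorder scores (TSV: protein_id, position, score)."""
    return _read_score_table(path, "score", 0.0, 1.0)


def read_domains(path, max_evalue: float = DEFAULT_MAX_EVALUE) -> dict[str, list[DomainHit]]:
    """Read Pfamscan-style domain hits, keeping rows with evalue < max_evalue.

    TSV columns: protein_id, start, end, domain_id, evalue.
    """
    hits: dict[str, list[DomainHit]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "protein_id":
            continue
        if len(parts) != 5:
            raise ParseError(path, lineno, f"expected 5 columns, got {len(parts)}")
        pid, start_s, end_s, dom, ev_s = parts
        try:
            start, end, ev = int(start_s), int(end_s), float(ev_s)
        except ValueError:
            raise ParseError(path, lineno, "non-numeric start/end/evalue") from None
        if start < 1 or start > end:
            raise ParseError(path, lineno, f"bad interval {start}-{end}")
        if ev >= max_evalue:
            continue
        hits.setdefault(pid, []).append(DomainHit(pid, start, end, dom, ev))
    return hits


def read_variants(path) -> list[VariantRecord]:
    """Read a variant table (TSV: protein_id, position, class_label).

    Class labels pass through verbatim; unknown labels are not an error.
    """
    out: list[VariantRecord] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] == "protein_id":
            continue
        if len(parts) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
        pid, pos_s, label = parts
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer position {pos_s!r}") from None
        if pos < 1:
            raise ParseError(path, lineno, f"position must be >= 1, got {pos}")
        out.append(VariantRecord(pid, pos, label))
    return out


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets in long format (TSV: set name, gene id)."""
    members: dict[str, set[str]] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] in ("name", "set_name"):
            continue
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        name, gid = parts
        if name not in members:
            members[name] = set()
            order.append(name)
        members[name].add(gid)
    return [GeneSet(name, frozenset(members[name])) for name in order]


def read_coordinates(path):
    """Read a PDB/mmCIF-style coordinate file for one protein.

    Returns ``(protein_id, positions, xyz, bfactor)`` where positions are the
    1-based residue numbers of the alpha-carbon records, ``xyz`` is an (n, 3)
    array in Angstrom and ``bfactor`` the per-residue B-factor column (which
    carries pLDDT in AlphaFold model files).
    """
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0 or len(structure[0]) == 0:
        raise ParseError(path, None, "no model/chain in coordinate file")
    model = structure[0]
    positions: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    bfac: list[float] = []
    for chain in model:
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is None:
                continue
            positions.append(residue.seqid.num)
            xyz.append((ca.pos.x, ca.pos.y, ca.pos.z))
            bfac.append(ca.b_iso)
    pid = structure.name or Path(path).stem
    return (
        pid,
        np.asarray(positions, dtype=np.int64),
        np.asarray(xyz, dtype=float),
        np.asarray(bfac, dtype=float),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_category_bed(tracks: Mapping[str, "CategoryTrack"], path) -> None:
    """Write resolved category tracks as BED intervals on protein coordinates.

    Intervals are 0-based half-open, one line per maximal run of equal
    category; the name column is the category label.  Reading the file back
    with :func:`read_category_bed` reconstructs each track exactly.
    """
    from .coverage_core import CoverageCategory

    with open(path, "w") as fh:
        for pid in tracks:
            codes = tracks[pid].codes
            if codes.size == 0:
                raise ValueError(f"{pid}: empty category track")
            boundaries = np.flatnonzero(np.diff(codes)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [codes.size]])
            for s, e in zip(starts, ends):
                label = CoverageCategory(codes[s]).name
                fh.write(f"{pid}\t{s}\t{e}\t{label}\n")


def read_category_bed(path) -> dict[str, "CategoryTrack"]:
    """Read a category BED back into per-protein tracks.

    Intervals for each protein must tile [0, length) without gaps.
    """
    from .coverage_core import CategoryTrack, CoverageCategory

    runs: dict[str, list[tuple[int, int, int]]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(path, lineno, f"expected >= 4 BED columns, got {len(parts)}")
        pid, start_s, end_s, label = parts[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer BED coordinates") from None
        if start < 0 or start >= end:
            raise ParseError(path, lineno, f"bad BED interval {start}-{end}")
        try:
            code = CoverageCategory[label].value
        except KeyError:
            raise ParseError(path, lineno, f"unknown category label {label!r}") from None
        runs.setdefault(pid, []).append((start, end, code))
    out: dict[str, CategoryTrack] = {}
    for pid, intervals in runs.items():
        intervals.sort()
        length = intervals[-1][1]
        codes = np.full(length, -1, dtype=np.int8)
        cursor = 0
        for start, end, code in intervals:
            if start != cursor:
                raise ParseError(path, None, f"{pid}: gap or overlap at position {cursor}")
            codes[start:end] = code
            cursor = end
        out[pid] = CategoryTrack(pid, codes)
    return out


def _flatten(obj, prefix: str = "") -> list[tuple[str, object]]:
    items: list[tuple[str, object]] = []
    if isinstance(obj, Mapping):
        for key in obj:
            items.extend(_flatten(obj[key], f"{prefix}{key}." if prefix else f"{key}."))
    elif isinstance(obj, (list, tuple)):
        for i, val in enumerate(obj):
            items.extend(_flatten(val, f"{prefix}{i}."))
    else:
        items.append((prefix[:-1], obj))
    return items


def write_summary(summary: Mapping, path, format: str = "json") -> None:
    """Write a (possibly nested) summary mapping as JSON or flat TSV.

    Field order is deterministic (insertion order of the mapping); both
    formats serialize every number through the same JSON representation, so
    they encode identical values at full precision.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, allow_nan=False, default=_jsonable)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for key, val in _flatten(summary):
                fh.write(f"{key}\t{json.dumps(_jsonable(val), allow_nan=False)}\n")
    else:
        raise ValueError(f"unknown summary format {format!r}")


def _jsonable(val):
    if isinstance(val, (np.integer,)):
        return int(val)
    if isinstance(val, (np.floating,)):
        return float(val)
    if isinstance(val, np.ndarray):
        return val.tolist()
    if isinstance(val, Mapping):
        return {k: _jsonable(v) for k, v in val.items()}
    if isinstance(val, (list, tuple)):
        return [_jsonable(v) for v in val]
    return val


def read_summary(path, format: str = "json") -> dict:
    """Read a summary back; TSV returns the flat key -> value mapping."""
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "tsv":
        out: dict[str, object] = {}
        with open(path) as fh:
            header = fh.readline()
            if header.rstrip("\n") != "key\tvalue":
                raise ParseError(path, 1, "expected summary TSV header 'key\\tvalue'")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                key, _, val = line.partition("\t")
                out[key] = json.loads(val)
        return out
    raise ValueError(f"unknown summary format {format!r}")
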
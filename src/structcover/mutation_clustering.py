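"""Bootstrap test for spatial clustering of mutated residues on a structure.

Given alpha-carbon coordinates of a protein model and a set of mutated
residue positions, the test asks whether the mutated residues sit closer
together in 3D than expected for an equally sized random set of residues
from the same structure.  The statistic is the mean pairwise CA-CA distance
(smaller = tighter); the null is built by repeatedly resampling the same
number of residues uniformly without replacement from the eligible set, and
the p-value is the add-one empirical estimator (1 + #{null <= observed}) /
(B + 1), which can never be 0 and never undercuts 1/(B+1).

When per-residue model confidence (pLDDT) is available, resampling is
restricted by default to residues with pLDDT >= 70: clusters measured on
low-confidence coordinates are not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io_formats import read_coordinates

__all__ = [
    "StructureCoords",
    "ClusterTestResult",
    "cluster_statistic",
    "bootstrap_pvalue",
    "STATISTICS",
]

DEFAULT_MIN_PLDDT = 70.0


@dataclass
class StructureCoords:
    """Per-residue alpha-carbon coordinates, optionally with pLDDT."""

    protein_id: str
    positions: np.ndarray  # 1-based residue numbers, (n,)
    xyz: np.ndarray  # Angstrom, (n, 3)
    plddt: np.ndarray | None = None  # (n,) or None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.positions.size, 3):
            raise ValueError("xyz must be an (n, 3) array parallel to positions")
        if self.positions.size < 2:
            raise ValueError("need at least 2 residues with coordinates")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != self.positions.shape:
                raise ValueError("plddt must be parallel to positions")

    @classmethod
    def from_file(cls, path, plddt_in_bfactor: bool = True) -> "StructureCoords":
        """Load from a PDB-style file; B-factor is read as pLDDT by default
        (the AlphaFold model convention)."""
        pid, positions, xyz, bfac = read_coordinates(path)
        return cls(pid, positions, xyz, bfac if plddt_in_bfactor else None)

    def index_of(self, residue_positions: Sequence[int]) -> np.ndarray:
        """Row indices of the given 1-based residue numbers; missing -> error."""
        lookup = {int(p): i for i, p in enumerate(self.positions)}
        try:
            return np.array([lookup[int(p)] for p in residue_positions], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(
                f"{self.protein_id}: residue {exc.args[0]} has no coordinates"
            ) from None


@dataclass
class ClusterTestResult:
    observed_stat: float  # Angstrom
    null_samples: int  # B
    p_value: float  # in [1/(B+1), 1]
    eligible_residues: int
    seed: int
    statistic: str = "mean_pairwise"

    def as_dict(self) -> dict:
        return {
            "observed_stat_angstrom": self.observed_stat,
            "null_samples": self.null_samples,
            "p_value": self.p_value,
            "eligible_residues": self.eligible_residues,
            "seed": self.seed,
            "statistic": self.statistic,
        }


def _mean_pairwise(xyz: np.ndarray) -> float:
    return float(pdist(xyz).mean())


def _max_pairwise(xyz: np.ndarray) -> float:
    return float(pdist(xyz).max())


def _mst_length(xyz: np.ndarray) -> float:
    dense = squareform(pdist(xyz))
    return float(minimum_spanning_tree(dense).sum())


#: Clustering statistics sharing the same null machinery (lower = tighter).
STATISTICS = {
    "mean_pairwise": _mean_pairwise,
    "max_pairwise": _max_pairwise,
    "mst_length": _mst_length,
}


def cluster_statistic(
    coords: StructureCoords,
    positions: Sequence[int],
    statistic: str = "mean_pairwise",
) -> float:
    """Spatial tightness of the given residues, in Angstrom.

    The default is the mean over all unordered residue pairs of the CA-CA
    Euclidean distance.  Requires >= 2 distinct positions, all present in
    the structure.
    """
    distinct = sorted(set(int(p) for p in positions))
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct mutated positions")
    idx = coords.index_of(distinct)
    try:
        fn = STATISTICS[statistic]
    except KeyError:
        raise ValueError(f"unknown statistic {statistic!r}") from None
    return fn(coords.xyz[idx])


def bootstrap_pvalue(
    coords: StructureCoords,
    positions: Sequence[int],
    B: int = 9999,
    seed: int = 0,
    min_plddt: float | None = DEFAULT_MIN_PLDDT,
    statistic: str = "mean_pairwise",
) -> ClusterTestResult:
    """Empirical p-value for 3D clustering of the mutated residues.

    Draws ``B`` random sets of the same size uniformly without replacement
    from the eligible residues (pLDDT >= min_plddt when confidence scores are
    available and ``min_plddt`` is not None; all residues otherwise) and
    reports p = (1 + #{null statistic <= observed}) / (B + 1).  Fully
    reproducible from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    distinct = sorted(set(int(p) for p in positions))
    observed = cluster_statistic(coords, distinct, statistic)
    k = len(distinct)

    if min_plddt is not None and coords.plddt is not None:
        eligible = np.flatnonzero(coords.plddt >= min_plddt)
    else:
        eligible = np.arange(coords.positions.size)
    if eligible.size < k:
        raise ValueError(
            f"only {eligible.size} eligible residues for {k} mutated positions"
        )

    fn = STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    points = coords.xyz[eligible]
    hits = 0
    for _ in range(B):
        draw = rng.choice(eligible.size, size=k, replace=False)
        if fn(points[draw]) <= observed:
            hits += 1
    return ClusterTestResult(
        observed_stat=observed,
        null_samples=B,
        p_value=(1 + hits) / (B + 1),
        eligible_residues=int(eligible.size),
        seed=seed,
        statistic=statistic,
    )
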
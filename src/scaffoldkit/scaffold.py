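"""Binding-interface clustering of aligned trajectories and scaffold selection.

Frames already aligned to a common reference are compared by backbone RMSD
over the binding residues; a greedy quality-threshold (Daura-style) pass
extracts up to K clusters; clusters holding at least a minimum fraction of
all frames yield medoid scaffolds, rank-ordered by population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import AtomSelection, Structure, Trajectory, resolve_selection

__all__ = [
    "UNCLUSTERED",
    "DistanceMatrix",
    "ClusterAssignment",
    "ScaffoldSet",
    "Scaffold",
    "pairwise_rmsd_matrix",
    "qt_cluster",
    "select_scaffolds",
    "cluster_report",
    "cutoff_sweep",
]

#: Label given to frames not assigned to any of the top clusters.
UNCLUSTERED = 0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of subset-backbone RMSDs between frames, in Angstrom."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix must be square, got {self.d.shape}")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix entries must be finite and >= 0")
        if np.any(np.abs(np.diag(self.d)) > 1e-8):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class ClusterAssignment:
    """Result of QT clustering: 1-based labels (0 = unclustered), populations
    in rank order, per-cluster medoid frame indices, and the parameters used."""

    labels: np.ndarray
    populations: list[int]
    medoids: list[int]
    founders: list[int]
    cutoff: float
    max_clusters: int

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    @property
    def n_unclustered(self) -> int:
        return int(np.sum(self.labels == UNCLUSTERED))

    def members(self, rank: int) -> np.ndarray:
        """Frame indices of cluster ``rank`` (1-based)."""
        return np.flatnonzero(self.labels == rank)

    def occupancy(self, rank: int) -> float:
        """Cluster population over ALL frames, clustered and unclustered."""
        return self.populations[rank - 1] / self.n


@dataclass
class Scaffold:
    rank: int
    occupancy: float
    structure: Structure
    frame_index: int


@dataclass
class ScaffoldSet:
    variant_label: str
    scaffolds: list[Scaffold] = field(default_factory=list)
    min_occupancy: float = 0.10

    def __len__(self) -> int:
        return len(self.scaffolds)

    def labels(self) -> list[str]:
        return [f"{self.variant_label}-{s.rank}" for s in self.scaffolds]


def pairwise_rmsd_matrix(t: Trajectory, bind_sel: AtomSelection) -> DistanceMatrix:
    """All-vs-all RMSD over the binding-site backbone atoms.

    Assumes the trajectory is already in the common reference frame; no
    superposition happens here.
    """
    idx = resolve_selection(bind_sel, t.topology)
    sub = t.coordinates()[:, idx, :]  # (n_frames, m, 3)
    n, m = sub.shape[0], sub.shape[1]
    # ||xi - xj||^2 summed over atoms, via the Gram-matrix identity.
    flat = sub.reshape(n, m * 3)
    sq = np.einsum("ij,ij->i", flat, flat)
    gram = flat @ flat.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / m
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    return DistanceMatrix(d=0.5 * (d + d.T))


def qt_cluster(
    m: DistanceMatrix | np.ndarray,
    cutoff: float,
    max_clusters: int = 5,
) -> ClusterAssignment:
    """Greedy quality-threshold clustering.

    Repeatedly the unassigned frame with the most unassigned neighbours
    within ``cutoff`` founds a cluster consisting of itself and those
    neighbours; ties break to the lowest frame index.  Stops after
    ``max_clusters`` clusters or when every frame is assigned; leftovers
    are labelled 0 (unclustered).  The medoid of each cluster is the member
    minimizing summed RMSD to its co-members.
    """
    if not isinstance(m, DistanceMatrix):
        m = DistanceMatrix(d=m)
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if max_clusters < 1:
        raise ValueError(f"max_clusters must be >= 1, got {max_clusters}")
    d = m.d
    n = m.n
    within = d <= cutoff  # includes self (diagonal zero)
    labels = np.zeros(n, dtype=int)
    unassigned = np.ones(n, dtype=bool)
    populations: list[int] = []
    medoids: list[int] = []
    founders: list[int] = []
    for rank in range(1, max_clusters + 1):
        if not unassigned.any():
            break
        counts = np.where(unassigned, within[:, unassigned].sum(axis=1), -1)
        founder = int(np.argmax(counts))  # argmax takes the lowest index on ties
        member_mask = within[founder] & unassigned
        members = np.flatnonzero(member_mask)
        labels[members] = rank
        unassigned[members] = False
        sub = d[np.ix_(members, members)]
        medoid = int(members[int(np.argmin(sub.sum(axis=1)))])
        populations.append(int(members.size))
        medoids.append(medoid)
        founders.append(founder)
    return ClusterAssignment(
        labels=labels,
        populations=populations,
        medoids=medoids,
        founders=founders,
        cutoff=float(cutoff),
        max_clusters=int(max_clusters),
    )


def select_scaffolds(
    a: ClusterAssignment,
    t: Trajectory,
    min_occupancy: float = 0.10,
    variant_label: str = "variant",
) -> ScaffoldSet:
    """Emit the medoid of every cluster holding >= ``min_occupancy`` of ALL
    frames (unclustered included in the denominator) as a scaffold Structure.

    Zero qualifying clusters is a legal outcome and returns an empty set
    with a warning.
    """
    if a.n != t.n_frames:
        raise ValueError(
            f"assignment covers {a.n} frames but trajectory has {t.n_frames}"
        )
    out = ScaffoldSet(variant_label=variant_label, min_occupancy=min_occupancy)
    for rank in range(1, a.n_clusters + 1):
        occ = a.occupancy(rank)
        if occ < min_occupancy:
            continue
        medoid = a.medoids[rank - 1]
        structure = t.frame_structure(medoid, title=f"{variant_label}-{rank}")
        out.scaffolds.append(
            Scaffold(rank=rank, occupancy=occ, structure=structure, frame_index=medoid)
        )
    if not out.scaffolds:
        warnings.warn(
            f"{variant_label}: no cluster reaches occupancy {min_occupancy:.2f}; "
            "no scaffolds emitted",
            stacklevel=2,
        )
    return out


def cluster_report(a: ClusterAssignment, variant_label: str = "variant") -> pd.DataFrame:
    """One row per cluster plus an Unclustered row: rank, population, fraction."""
    rows = []
    for rank in range(1, a.n_clusters + 1):
        rows.append(
            {
                "variant": variant_label,
                "cluster": str(rank),
                "population": a.populations[rank - 1],
                "fraction": a.populations[rank - 1] / a.n,
                "medoid_frame": a.medoids[rank - 1] + 1,  # 1-indexed for reports
            }
        )
    rows.append(
        {
            "variant": variant_label,
            "cluster": "Unclustered",
            "population": a.n_unclustered,
            "fraction": a.n_unclustered / a.n,
            "medoid_frame": pd.NA,
        }
    )
    return pd.DataFrame(rows)


def cutoff_sweep(
    m: DistanceMatrix,
    cutoffs: np.ndarray | list[float],
    max_clusters: int = 5,
    min_occupancy: float = 0.10,
) -> pd.DataFrame:
    """Cluster-count table over a grid of RMSD cutoffs.

    Cluster counts are very sensitive to the threshold when few residues
    define the interface; this table supports choosing it deliberately
    before a production run.
    """
    rows = []
    for c in cutoffs:
        a = qt_cluster(m, cutoff=float(c), max_clusters=max_clusters)
        qualifying = sum(
            1 for r in range(1, a.n_clusters + 1) if a.occupancy(r) >= min_occupancy
        )
        rows.append(
            {
                "cutoff": float(c),
                "n_clusters": a.n_clusters,
                "n_scaffolds": qualifying,
                "top_population": a.populations[0] if a.populations else 0,
                "unclustered": a.n_unclustered,
            }
        )
    return pd.DataFrame(rows)
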
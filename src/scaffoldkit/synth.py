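"""Deterministic synthetic fixtures: toy proteins, trajectories with planted
conformational clusters, and docking-result files.

These stand in for molecular-dynamics and docking output so every pipeline
stage is testable on a laptop.  Trajectories use the simplest noise model
with controllable RMSD statistics — isotropic per-atom Gaussian noise
around k planted conformer centers; for two frames of the same conformer
E[RMSD^2] = 6 sigma^2, which guides cutoff choices.  Generators are pure
functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import rmsd_between
from .structio import Atom, AtomSelection, Structure, Trajectory, resolve_selection

__all__ = [
    "SynthTrajectorySpec",
    "GroundTruth",
    "make_toy_protein",
    "make_synthetic_trajectory",
    "make_docking_fixture",
]


def make_toy_protein(n_residues: int, seed: int = 0) -> Structure:
    """Idealized extended poly-alanine chain: 5 heavy atoms per residue
    (N, CA, C, O, CB), consecutive CA-CA near 3.8 A, deterministic per seed.
    """
    if n_residues < 3:
        raise ValueError(f"need at least 3 residues, got {n_residues}")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    # Local offsets from CA, roughly trans-extended geometry.
    offsets = {
        "N": np.array([-1.20, 0.85, 0.00]),
        "CA": np.zeros(3),
        "C": np.array([1.25, 0.70, 0.00]),
        "O": np.array([1.45, 1.90, 0.10]),
        "CB": np.array([0.10, -1.05, 1.10]),
    }
    for i in range(n_residues):
        ca = np.array([3.78 * i, 0.4 * (i % 2), 0.0])
        jitter = rng.normal(0.0, 0.01, size=(5, 3))
        for j, name in enumerate(("N", "CA", "C", "O", "CB")):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    resname="ALA",
                    chain="A",
                    resid=i + 1,
                    coords=ca + offsets[name] + jitter[j],
                    element=name[0],
                )
            )
            serial += 1
    return Structure(atoms=atoms, title=f"toy protein n={n_residues} seed={seed}")


@dataclass(frozen=True)
class SynthTrajectorySpec:
    """Parameters of a planted-cluster trajectory.

    ``center_separation`` is the target pairwise backbone RMSD between
    conformer centers measured over ``displacement_resids``; ``sigma`` is
    the per-atom isotropic Gaussian noise in Angstrom.
    """

    base: Structure
    k: int = 2
    weights: tuple[float, ...] = ()
    displacement_resids: frozenset[int] = frozenset()
    center_separation: float = 2.0
    sigma: float = 0.15
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        w = self.weights or tuple([1.0 / self.k] * self.k)
        object.__setattr__(self, "weights", w)
        if len(w) != self.k:
            raise ValueError(f"weights has {len(w)} entries for k={self.k}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(w)}")
        if self.k > 1 and self.center_separation <= 0:
            raise ValueError("center_separation must be positive for k > 1")


@dataclass
class GroundTruth:
    """Planted labels (0-based conformer index per frame) and centers."""

    labels: np.ndarray
    centers: np.ndarray  # (k, n_atoms, 3)
    displaced_atom_indices: list[int] = field(default_factory=list)


def _simplex_vertices(k: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """k points in R^3 with all pairwise distances == separation (k <= 4),
    randomly oriented; k > 4 falls back to rescaled random directions."""
    if k == 1:
        return np.zeros((1, 3))
    if k == 2:
        base = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    elif k == 3:
        base = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    elif k == 4:
        base = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
             [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]]
        )
    else:
        pts = rng.normal(size=(k, 3))
        # Rescale so the minimum pairwise distance hits the target.
        dmin = min(
            np.linalg.norm(pts[i] - pts[j]) for i in range(k) for j in range(i + 1, k)
        )
        return pts * (1.0 / dmin)
    # Random proper rotation so orientation is not axis-locked.
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return (base - base.mean(axis=0)) @ rot.T * separation


def make_synthetic_trajectory(
    spec: SynthTrajectorySpec,
) -> tuple[Trajectory, GroundTruth]:
    """Plant k conformers and sample noisy frames around them.

    Conformer centers differ by rigid translations of the backbone atoms of
    ``displacement_resids`` (default: all residues), arranged so every
    pairwise center-vs-center RMSD over those atoms equals
    ``center_separation``.  Each frame picks conformer c with probability
    ``weights[c]`` and adds N(0, sigma^2) noise to every atom coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    base_coords = spec.base.coords
    n_atoms = base_coords.shape[0]

    sel = AtomSelection(resids=frozenset(spec.displacement_resids))
    displaced = resolve_selection(sel, spec.base)

    shifts = _simplex_vertices(spec.k, spec.center_separation, rng)
    centers = np.repeat(base_coords[None, :, :], spec.k, axis=0)
    for c in range(spec.k):
        centers[c, displaced, :] += shifts[c]

    if spec.k > 1:
        measured = rmsd_between(centers[0][displaced], centers[1][displaced])
        if abs(measured - spec.center_separation) > 0.05 * spec.center_separation:
            raise RuntimeError(
                f"planted separation {measured:.3f} misses target "
                f"{spec.center_separation:.3f} by more than 5%"
            )

    labels = rng.choice(spec.k, size=spec.n_frames, p=np.asarray(spec.weights))
    noise = rng.normal(0.0, spec.sigma, size=(spec.n_frames, n_atoms, 3))
    frames = [centers[labels[i]] + noise[i] for i in range(spec.n_frames)]
    traj = Trajectory(
        topology=spec.base,
        frames=frames,
        source_files=[f"synthetic(seed={spec.seed})"] * spec.n_frames,
    )
    return traj, GroundTruth(
        labels=labels, centers=centers, displaced_atom_indices=list(displaced)
    )


def make_docking_fixture(
    ligand_ids: Sequence[str],
    affinity_means: Mapping[str, float],
    jitter: float = 0.0,
    num_modes: int = 9,
    seed: int = 0,
    out: str | Path = ".",
) -> list[Path]:
    """Write one pose file per ligand in the engine-result remark dialect.

    Mode 1 carries ``affinity_means[ligand] + jitter * z`` (z standard
    normal, seeded); later modes are monotonically weaker.  Byte-identical
    per seed.
    """
    if num_modes < 1 or num_modes > 9:
        raise ValueError(f"num_modes must be in 1..9, got {num_modes}")
    rng = np.random.default_rng(seed)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for lig in ligand_ids:
        mean = affinity_means[lig]
        best = mean + jitter * rng.standard_normal()
        increments = np.abs(rng.normal(0.3, 0.1, size=num_modes - 1)) + 0.01
        affinities = best + np.concatenate([[0.0], np.cumsum(increments)])
        lines = []
        for mode, aff in enumerate(affinities, start=1):
            rmsd_lb = 0.0 if mode == 1 else round(float(rng.uniform(0.5, 3.0)), 3)
            rmsd_ub = rmsd_lb + (0.0 if mode == 1 else round(float(rng.uniform(0.0, 2.0)), 3))
            lines.append(f"MODEL {mode}")
            lines.append(
                f"REMARK VINA RESULT:    {aff:8.3f}   {rmsd_lb:6.3f}   {rmsd_ub:6.3f}"
            )
            lines.append("ENDMDL")
        path = out / f"{lig}_out.pdbqt"
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths
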
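"""Optimal rigid-body superposition and RMSD.

The alignment contract is two-stage: one global Kabsch fit of each frame
onto a common reference (typically the whole backbone), after which subset
RMSDs are computed WITHOUT re-fitting on the subset.  Re-fitting per subset
would change the cluster geometry, so it is deliberately not offered here.
Weights default to uniform (no mass weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import AtomSelection, Structure, Trajectory, resolve_selection

__all__ = ["Superposition", "kabsch_superpose", "rmsd_between", "align_trajectory"]


class DegenerateGeometryError(ValueError):
    """Point set too small or too collinear for a unique superposition."""


@dataclass(frozen=True)
class Superposition:
    """Rigid transform mapping mobile onto reference: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Kabsch/SVD solution for the proper rotation + translation minimizing
    weighted RMSD of ``mobile`` onto ``reference``.

    Requires n >= 3 non-collinear points; a reflection in the SVD solution
    is corrected so det(rotation) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"coordinate shapes differ: {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got {mobile.shape}")
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a non-negative n-vector with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    pm = mobile - mu_m
    pr = reference - mu_r
    cov = (pm * w[:, None]).T @ pr
    u, s, vt = np.linalg.svd(cov)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "point configuration is collinear or degenerate (covariance rank < 2)"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    moved = pm @ rotation.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - pr) ** 2)))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of paired points, in a common frame.

    No superposition is performed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def align_trajectory(
    t: Trajectory,
    reference: Structure,
    align_sel: AtomSelection | None = None,
) -> Trajectory:
    """Superpose every frame onto the reference over ``align_sel`` atoms.

    Each frame gets its own Kabsch fit over the selection; the whole frame
    then moves rigidly.  Default selection: all backbone atoms.
    """
    if align_sel is None:
        align_sel = AtomSelection()
    idx_ref = resolve_selection(align_sel, reference)
    idx_top = resolve_selection(align_sel, t.topology)
    if len(idx_ref) != len(idx_top):
        raise ValueError(
            f"alignment selection resolves to {len(idx_top)} atoms in the "
            f"trajectory topology but {len(idx_ref)} in the reference"
        )
    ref_coords = reference.coords[idx_ref]
    aligned = []
    for frame in t.frames:
        sup = kabsch_superpose(frame[idx_top], ref_coords)
        aligned.append(sup.apply(frame))
    return Trajectory(
        topology=t.topology, frames=aligned, source_files=list(t.source_files)
    )
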
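"""Idealized side-chain templates for in-silico point mutation.

Each template stores the heavy side-chain atoms of one amino acid in a
local frame anchored on the residue backbone: origin at CA, x-axis toward
N, with the N-CA-C plane fixing y.  Coordinates come from an embedded,
force-field-relaxed single-residue conformer built with RDKit at first use
(fixed embedding seed, so the library is bit-reproducible); grafting is a
rigid transform of this frame onto the target residue's own N/CA/C.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .structio import AA_1_TO_3, AA_3_TO_1

__all__ = ["SideChainTemplate", "get_template", "backbone_frame"]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
_EMBED_SEED = 20190403  # fixed: template geometry must not drift between runs


@dataclass(frozen=True)
class SideChainTemplate:
    """Side-chain heavy atoms of one residue type in the backbone local frame."""

    aa: str                 # 3-letter code
    atom_names: tuple[str, ...]
    local_coords: np.ndarray  # (len(atom_names), 3)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


def backbone_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal local frame from backbone positions.

    Returns (R, origin) with R's columns = (x, y, z) axes: origin CA,
    x toward N, y in the N-CA-C plane toward C, z completing a right-handed
    set.  World coords of a local point p are origin + R @ p.
    """
    x = n - ca
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise ValueError("degenerate backbone: N and CA coincide")
    x = x / nx
    y = c - ca
    y = y - (y @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-6:
        raise ValueError("degenerate backbone: N, CA, C are collinear")
    y = y / ny
    z = np.cross(x, y)
    return np.stack([x, y, z], axis=1), ca


def _element_of(atom_name: str) -> str:
    head = atom_name.lstrip("0123456789")
    if head[:1] in ("N", "O", "S", "C"):
        return head[:1]
    return head[:1]


@lru_cache(maxsize=None)
def get_template(aa: str) -> SideChainTemplate:
    """Template for a 1- or 3-letter amino-acid code (glycine: empty)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    aa3 = AA_1_TO_3.get(aa.upper(), aa.upper())
    if aa3 not in AA_3_TO_1:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    aa1 = AA_3_TO_1[aa3]
    mol = Chem.MolFromSequence(aa1)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise RuntimeError(f"conformer embedding failed for {aa3}")
    AllChem.MMFFOptimizeMolecule(molh)
    molh = Chem.RemoveHs(molh)
    conf = molh.GetConformer()
    pos: dict[str, np.ndarray] = {}
    for atom in molh.GetAtoms():
        name = atom.GetPDBResidueInfo().GetName().strip()
        pos[name] = np.array(conf.GetAtomPosition(atom.GetIdx()))
    rot, origin = backbone_frame(pos["N"], pos["CA"], pos["C"])
    names = tuple(
        sorted(
            (k for k in pos if k not in _BACKBONE_NAMES),
            key=_sidechain_sort_key,
        )
    )
    local = np.array([rot.T @ (pos[k] - origin) for k in names]) if names else np.empty((0, 3))
    return SideChainTemplate(aa=aa3, atom_names=names, local_coords=local)


def _sidechain_sort_key(name: str) -> tuple[int, str]:
    # CB first, then outward by Greek-letter position (B < G < D < E < Z < H),
    # matching the conventional PDB side-chain ordering.
    greek_order = {"B": 0, "G": 1, "D": 2, "E": 3, "Z": 4, "H": 5}
    remote = name[1] if len(name) > 1 else "B"
    return (greek_order.get(remote, 9), name)
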
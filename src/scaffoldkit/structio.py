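"""Structure and trajectory I/O plus atom-selection resolution.

Supports fixed-column PDB (v3.3 ATOM/HETATM/MODEL records) and the
CHARMM/NAMD binary DCD trajectory dialect.  Frames are 0-indexed
internally; user-facing reports renumber from 1.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "BACKBONE_ATOMS",
    "STANDARD_RESNAMES",
    "PDBParseError",
    "TrajectoryError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_dcd",
    "write_dcd",
    "resolve_selection",
]

#: Backbone atom names used for alignment/clustering selections.  The
#: carbonyl oxygen is included, matching VMD's "backbone" keyword.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

STANDARD_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

AA_3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1_TO_3 = {v: k for k, v in AA_3_TO_1.items()}


class PDBParseError(ValueError):
    """Malformed PDB content; message carries the offending line number."""


class TrajectoryError(ValueError):
    """Trajectory file inconsistent with its topology or truncated."""


class SelectionError(ValueError):
    """An atom selection resolved to nothing."""


@dataclass
class Atom:
    """One atom record of a structure.

    Coordinates are in Angstrom.  ``resid`` follows author (PDB) numbering.
    """

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    coords: np.ndarray
    element: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    record: str = "ATOM"
    altloc: str = " "

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"atom {self.serial} {self.name}: coords must be 3 finite values"
            )

    @property
    def is_mutable(self) -> bool:
        return self.record == "ATOM" and self.resname in STANDARD_RESNAMES


@dataclass
class Structure:
    """An ordered collection of atoms for one conformation."""

    atoms: list[Atom]
    title: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        """Same topology with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, title=self.title if title is None else title)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[Atom]]]:
        """Iterate contiguous residues as ((chain, resid, resname), atoms)."""
        current_key: tuple[str, int, str] | None = None
        bucket: list[Atom] = []
        for a in self.atoms:
            key = (a.chain, a.resid, a.resname)
            if key != current_key:
                if bucket:
                    yield current_key, bucket  # type: ignore[misc]
                current_key, bucket = key, []
            bucket.append(a)
        if bucket:
            yield current_key, bucket  # type: ignore[misc]


@dataclass
class Trajectory:
    """Ordered conformations sharing one topology."""

    topology: Structure
    frames: list[np.ndarray]
    source_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise TrajectoryError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack(self.frames) if self.frames else np.empty((0, self.n_atoms, 3))

    def frame_structure(self, i: int, title: str = "") -> Structure:
        return self.topology.with_coords(self.frames[i], title=title)


@dataclass(frozen=True)
class AtomSelection:
    """Residue/atom-name selection.

    Empty ``resids`` means all residues; ``atom_names`` defaults to the
    backbone set; ``chain`` of None matches any chain.  HETATM records are
    never selected: the workflow operates on the protein after solvent
    stripping.
    """

    resids: frozenset[int] = frozenset()
    chain: str | None = None
    atom_names: frozenset[str] = BACKBONE_ATOMS

    @staticmethod
    def backbone(resids: Iterable[int] = (), chain: str | None = None) -> "AtomSelection":
        return AtomSelection(resids=frozenset(resids), chain=chain)


# ---------------------------------------------------------------------------
# PDB

def _parse_atom_line(line: str, lineno: int, serial_fallback: int) -> Atom:
    def _float(colspan: slice, what: str) -> float:
        text = line[colspan].strip()
        try:
            return float(text)
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed {what} field {text!r}"
            ) from None

    try:
        serial = int(line[6:11].strip() or serial_fallback)
    except ValueError:
        serial = serial_fallback
    name = line[12:16].strip()
    altloc = line[16] if len(line) > 16 else " "
    resname = line[17:20].strip()
    chain = line[21] if len(line) > 21 else " "
    try:
        resid = int(line[22:26].strip())
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed residue number") from None
    x = _float(slice(30, 38), "x coordinate")
    y = _float(slice(38, 46), "y coordinate")
    z = _float(slice(46, 54), "z coordinate")
    occ_text = line[54:60].strip()
    bf_text = line[60:66].strip()
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        element = name.lstrip("0123456789")[:1]
    return Atom(
        serial=serial,
        name=name,
        resname=resname,
        chain=chain,
        resid=resid,
        coords=np.array([x, y, z]),
        element=element,
        occupancy=float(occ_text) if occ_text else 1.0,
        bfactor=float(bf_text) if bf_text else 0.0,
        record=line[:6].strip(),
        altloc=altloc,
    )


def _read_pdb_models(path: str | Path) -> tuple[list[list[Atom]], str]:
    """All models of a PDB file, dropping altLoc other than ' '/'A'."""
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    title = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec.startswith("TITLE"):
                title = (title + " " + raw[10:].strip()).strip()
            elif rec == "MODEL ":
                if in_model and current:
                    models.append(current)
                current, in_model = [], True
            elif rec == "ENDMDL":
                models.append(current)
                current, in_model = [], False
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(raw.rstrip("\n"), lineno, len(current) + 1)
                if atom.altloc not in (" ", "A"):
                    continue
                current.append(atom)
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return models, title


def read_pdb(path: str | Path, model: int | None = None) -> Structure:
    """Read one model (1-based; default first) of a PDB file."""
    models, title = _read_pdb_models(path)
    idx = 0 if model is None else model - 1
    if idx < 0 or idx >= len(models):
        raise PDBParseError(
            f"{path}: model {model} requested but file has {len(models)} model(s)"
        )
    return Structure(atoms=models[idx], title=title)


def _format_atom_line(a: Atom, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{a.record:<6s}{serial:>5d} {name:<4s}{a.altloc:1s}{a.resname:>3s} "
        f"{a.chain:1s}{a.resid:>4d}    "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a single-model PDB; coordinates at the format's 3-decimal precision."""
    lines = []
    if s.title:
        lines.append(f"TITLE     {s.title}")
    for i, a in enumerate(s.atoms, start=1):
        lines.append(_format_atom_line(a, i))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DCD (CHARMM/NAMD dialect)

_DCD_MAGIC = b"CORD"


def _read_record(fh, byteorder: str, what: str) -> bytes:
    head = fh.read(4)
    if len(head) < 4:
        raise TrajectoryError(f"unexpected end of file reading {what}")
    (length,) = struct.unpack(byteorder + "i", head)
    payload = fh.read(length)
    tail = fh.read(4)
    if len(payload) < length or len(tail) < 4:
        raise TrajectoryError(f"truncated record while reading {what}")
    (length2,) = struct.unpack(byteorder + "i", tail)
    if length2 != length:
        raise TrajectoryError(f"corrupt record markers while reading {what}")
    return payload


def _write_record(fh, payload: bytes, byteorder: str = "<") -> None:
    marker = struct.pack(byteorder + "i", len(payload))
    fh.write(marker + payload + marker)


def read_dcd(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a CHARMM/NAMD DCD file.

    Returns (coordinates (n_frames, n_atoms, 3) float32-derived, natom).
    Endianness is auto-detected from the leading record marker (84).
    Fixed-atom trajectories are rejected.
    """
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise TrajectoryError(f"{path}: not a DCD file (too short)")
        byteorder = None
        for bo in ("<", ">"):
            if struct.unpack(bo + "i", head)[0] == 84:
                byteorder = bo
                break
        if byteorder is None:
            raise TrajectoryError(
                f"{path}: not a CHARMM/NAMD DCD (header record marker != 84)"
            )
        fh.seek(0)
        header = _read_record(fh, byteorder, "header")
        if header[:4] != _DCD_MAGIC:
            raise TrajectoryError(f"{path}: missing CORD magic")
        icntrl = struct.unpack(byteorder + "20i", header[4:84])
        nframes_declared = icntrl[0]
        has_unitcell = icntrl[10] != 0
        n_fixed = icntrl[8]
        if n_fixed != 0:
            raise TrajectoryError(
                f"{path}: fixed-atom DCDs (NFIXED={n_fixed}) are not supported"
            )
        _read_record(fh, byteorder, "title block")
        natom_rec = _read_record(fh, byteorder, "atom count")
        (natom,) = struct.unpack(byteorder + "i", natom_rec[:4])

        frames: list[np.ndarray] = []
        while True:
            pos = fh.tell()
            probe = fh.read(4)
            if not probe:
                break
            fh.seek(pos)
            try:
                if has_unitcell:
                    _read_record(fh, byteorder, f"unit cell of frame {len(frames)}")
                xs = _read_record(fh, byteorder, f"frame {len(frames)} X block")
                ys = _read_record(fh, byteorder, f"frame {len(frames)} Y block")
                zs = _read_record(fh, byteorder, f"frame {len(frames)} Z block")
            except TrajectoryError as exc:
                raise TrajectoryError(
                    f"{path}: truncated frame after last complete frame "
                    f"{len(frames) - 1} ({exc})"
                ) from None
            fx = np.frombuffer(xs, dtype=byteorder + "f4")
            fy = np.frombuffer(ys, dtype=byteorder + "f4")
            fz = np.frombuffer(zs, dtype=byteorder + "f4")
            if not (len(fx) == len(fy) == len(fz) == natom):
                raise TrajectoryError(
                    f"{path}: frame {len(frames)} coordinate block length "
                    f"mismatch with NATOM={natom}"
                )
            frames.append(np.stack([fx, fy, fz], axis=1).astype(float))
            if nframes_declared and len(frames) == nframes_declared:
                # NAMD appends nothing after the declared frames; stop here so
                # stray trailing bytes do not masquerade as an extra frame.
                if not fh.read(4):
                    break
                fh.seek(-4, 1)
    if not frames:
        raise TrajectoryError(f"{path}: DCD contains no frames")
    return np.stack(frames), natom


def write_dcd(coords: np.ndarray, path: str | Path, title: str = "scaffoldkit") -> None:
    """Write coordinates (n_frames, n_atoms, 3) as a native-endian CHARMM DCD."""
    coords = np.asarray(coords, dtype=np.float32)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise TrajectoryError(f"expected (n_frames, n_atoms, 3), got {coords.shape}")
    n_frames, n_atoms = coords.shape[:2]
    if n_frames == 0:
        raise TrajectoryError("refusing to write a 0-frame trajectory")
    icntrl = [0] * 20
    icntrl[0] = n_frames        # NSET
    icntrl[1] = 1               # ISTART
    icntrl[2] = 1               # NSAVC
    icntrl[3] = n_frames        # NSTEP
    icntrl[9] = struct.unpack("i", struct.pack("f", 1.0))[0]  # DELTA as float bits
    icntrl[10] = 0              # no unit cell
    icntrl[19] = 24             # CHARMM version stamp
    with open(path, "wb") as fh:
        _write_record(fh, _DCD_MAGIC + struct.pack("<20i", *icntrl))
        title_line = title.encode()[:80].ljust(80)
        _write_record(fh, struct.pack("<i", 1) + title_line)
        _write_record(fh, struct.pack("<i", n_atoms))
        for frame in coords:
            for axis in range(3):
                _write_record(fh, frame[:, axis].astype("<f4").tobytes())


def _is_dcd(path: str | Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(4)
    if len(head) < 4:
        return False
    return 84 in (
        struct.unpack("<i", head)[0],
        struct.unpack(">i", head)[0],
    )


def read_trajectory(paths: Sequence[str | Path], topology: Structure) -> Trajectory:
    """Concatenate multi-model PDB and/or DCD files in argument order."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[np.ndarray] = []
    sources: list[str] = []
    n_topo = topology.n_atoms
    for path in paths:
        if _is_dcd(path):
            coords, natom = read_dcd(path)
            if natom != n_topo:
                raise TrajectoryError(
                    f"{path}: atom count mismatch {natom} vs {n_topo}"
                )
            file_frames = list(coords)
        else:
            models, _ = _read_pdb_models(path)
            file_frames = []
            for m in models:
                if len(m) != n_topo:
                    raise TrajectoryError(
                        f"{path}: atom count mismatch {len(m)} vs {n_topo}"
                    )
                file_frames.append(np.array([a.coords for a in m]))
        frames.extend(file_frames)
        sources.extend([str(path)] * len(file_frames))
    return Trajectory(topology=topology, frames=frames, source_files=sources)


def write_trajectory(t: Trajectory, path: str | Path, format: str = "dcd") -> None:
    """Write a trajectory as DCD (float32) or multi-model PDB (3 decimals)."""
    if t.n_frames == 0:
        raise TrajectoryError("refusing to write a 0-frame trajectory")
    if format == "dcd":
        write_dcd(t.coordinates(), path, title=t.topology.title or "scaffoldkit")
    elif format == "pdb":
        lines = []
        for i, frame in enumerate(t.frames, start=1):
            lines.append(f"MODEL     {i:>4d}")
            for j, a in enumerate(t.topology.atoms):
                lines.append(_format_atom_line(replace(a, coords=frame[j]), j + 1))
            lines.append("ENDMDL")
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Selections

def resolve_selection(sel: AtomSelection, s: Structure) -> list[int]:
    """Deterministic ordered atom indices matching the selection.

    Pure function of its inputs; raises SelectionError on empty resolution,
    naming the residues that matched nothing.
    """
    indices: list[int] = []
    seen_resids: set[int] = set()
    for i, a in enumerate(s.atoms):
        if a.record != "ATOM":
            continue
        if sel.chain is not None and a.chain != sel.chain:
            continue
        if sel.resids and a.resid not in sel.resids:
            continue
        seen_resids.add(a.resid)
        if sel.atom_names and a.name not in sel.atom_names:
            continue
        indices.append(i)
    if not indices:
        if sel.resids:
            missing = sorted(sel.resids - seen_resids)
            raise SelectionError(
                f"selection matched no atoms; residues not found: {missing}"
            )
        raise SelectionError("selection matched no atoms")
    if sel.resids:
        missing = sorted(sel.resids - seen_resids)
        if missing:
            raise SelectionError(
                f"selection residues not present in structure: {missing}"
            )
    return indices
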
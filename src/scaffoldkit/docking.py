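"""Docking preparation and resistance analysis.

Prepares the rigid-receptor docking stage (scaffold-to-reference alignment,
search-box config emission) and turns per-ligand pose energies into
wildtype-normalized resistance scores.  The docking engine itself is out of
scope: results enter through pose files carrying per-mode affinity remarks
("REMARK VINA RESULT: <affinity> <rmsd_lb> <rmsd_ub>") or the engine's
tabular log.

Resistance is reported as a difference of best-pose binding energies,
delta = E_variant - E_wildtype (kcal/mol): binding energies are free-energy
estimates, so their difference is the physically meaningful ddG.  Positive
delta means the variant binds more weakly — predicted resistance.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structio import AtomSelection, Structure, resolve_selection

__all__ = [
    "SearchBox",
    "DockingPose",
    "ResistanceTable",
    "align_scaffold_to_reference",
    "write_docking_config",
    "parse_docking_results",
    "best_affinity",
    "resistance_table",
    "plot_resistance",
]


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned docking search volume plus flexible-side-chain residues."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    flexible_resids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.size) != 3:
            raise ValueError("center and size must each have 3 components")
        if any(s <= 0 for s in self.size):
            raise ValueError(f"all box dimensions must be positive, got {self.size}")


@dataclass(frozen=True)
class DockingPose:
    ligand_id: str
    mode_rank: int
    affinity: float  # kcal/mol; more negative = stronger
    rmsd_lb: float = 0.0
    rmsd_ub: float = 0.0


@dataclass
class ResistanceTable:
    """Per ligand x variant-scaffold binding energies and ddG vs wildtype."""

    table: pd.DataFrame
    wt_scaffold_rank: int
    skipped_ligands: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


def align_scaffold_to_reference(
    scaffold: Structure,
    reference: Structure,
    align_sel: AtomSelection | None = None,
) -> Structure:
    """Rigidly fit the scaffold onto the reference over ``align_sel`` atoms,
    so one fixed search box defined on the reference is valid for every
    scaffold."""
    if align_sel is None:
        align_sel = AtomSelection()
    idx_s = resolve_selection(align_sel, scaffold)
    idx_r = resolve_selection(align_sel, reference)
    if len(idx_s) != len(idx_r):
        raise ValueError(
            f"selection resolves to {len(idx_s)} scaffold atoms vs "
            f"{len(idx_r)} reference atoms"
        )
    coords = scaffold.coords
    sup = kabsch_superpose(coords[idx_s], reference.coords[idx_r])
    return scaffold.with_coords(sup.apply(coords))


def write_docking_config(
    box: SearchBox,
    receptor_path: str | Path,
    out: str | Path,
    num_modes: int = 9,
) -> Path:
    """Emit the engine configuration (key = value dialect); deterministic bytes."""
    if num_modes < 1:
        raise ValueError(f"num_modes must be >= 1, got {num_modes}")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    lines = [
        f"receptor = {receptor_path}",
        f"center_x = {box.center[0]:.3f}",
        f"center_y = {box.center[1]:.3f}",
        f"center_z = {box.center[2]:.3f}",
        f"size_x = {box.size[0]:.3f}",
        f"size_y = {box.size[1]:.3f}",
        f"size_z = {box.size[2]:.3f}",
        f"num_modes = {num_modes}",
    ]
    if box.flexible_resids:
        flex = ",".join(str(r) for r in sorted(box.flexible_resids))
        lines.append(f"flex_resids = {flex}")
    path = out / "dock.conf"
    path.write_text("\n".join(lines) + "\n")
    return path


_RESULT_REMARK = re.compile(
    r"REMARK VINA RESULT:\s+(-?\d+\.?\d*)\s+(-?\d+\.?\d*)\s+(-?\d+\.?\d*)"
)
_LOG_ROW = re.compile(r"^\s*(\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$")


def parse_docking_results(path: str | Path) -> list[DockingPose]:
    """Parse per-mode affinities from a pose file or engine log.

    One pose per mode, ranked by file order; ligand id is the filename stem
    (a trailing ``_out`` suffix is dropped).  Non-monotone affinities get a
    warning, not an error.
    """
    path = Path(path)
    ligand_id = re.sub(r"_out$", "", path.stem)
    poses: list[DockingPose] = []
    text = path.read_text()
    for m in _RESULT_REMARK.finditer(text):
        poses.append(
            DockingPose(
                ligand_id=ligand_id,
                mode_rank=len(poses) + 1,
                affinity=float(m.group(1)),
                rmsd_lb=float(m.group(2)),
                rmsd_ub=float(m.group(3)),
            )
        )
    if not poses:
        for line in text.splitlines():
            m = _LOG_ROW.match(line)
            if m:
                poses.append(
                    DockingPose(
                        ligand_id=ligand_id,
                        mode_rank=len(poses) + 1,
                        affinity=float(m.group(2)),
                        rmsd_lb=float(m.group(3)),
                        rmsd_ub=float(m.group(4)),
                    )
                )
    if not poses:
        raise ValueError(f"{path}: no docking results found")
    affs = [p.affinity for p in poses]
    if any(b < a for a, b in zip(affs, affs[1:])):
        warnings.warn(
            f"{path}: affinities are not non-decreasing with mode rank",
            stacklevel=2,
        )
    return poses


def best_affinity(poses: Sequence[DockingPose]) -> dict[str, float]:
    """Per ligand, the most negative (best) affinity in kcal/mol."""
    if not poses:
        raise ValueError("no poses given")
    best: dict[str, float] = {}
    for p in poses:
        if p.ligand_id not in best or p.affinity < best[p.ligand_id]:
            best[p.ligand_id] = p.affinity
    return best


def resistance_table(
    variant_results: Mapping[tuple[str, int], Sequence[DockingPose]],
    wildtype_results: Sequence[DockingPose],
    wt_scaffold_rank: int = 1,
) -> ResistanceTable:
    """ddG table: for each shared ligand and variant scaffold,
    delta = bestE_variant - bestE_wildtype.

    Normalization uses one wildtype scaffold (by convention the most
    populated; rank recorded in the output).  Ligands present on only one
    side are listed as skipped, not scored.
    """
    wt_best = best_affinity(wildtype_results)
    rows = []
    skipped: set[str] = set()
    for (variant_label, scaffold_rank), poses in sorted(variant_results.items()):
        var_best = best_affinity(poses)
        shared = sorted(set(var_best) & set(wt_best))
        skipped.update(set(var_best) ^ set(wt_best))
        for lig in shared:
            delta = var_best[lig] - wt_best[lig]
            rows.append(
                {
                    "ligand_id": lig,
                    "variant_label": variant_label,
                    "scaffold_rank": scaffold_rank,
                    "E_variant": var_best[lig],
                    "E_wildtype": wt_best[lig],
                    "delta": delta,
                    "resistant": delta > 0,
                }
            )
    if not rows:
        raise ValueError("no ligands shared between variant and wildtype results")
    return ResistanceTable(
        table=pd.DataFrame(rows),
        wt_scaffold_rank=wt_scaffold_rank,
        skipped_ligands=sorted(skipped),
    )


def occupancy_weighted_summary(
    rt: ResistanceTable, occupancies: Mapping[tuple[str, int], float]
) -> pd.DataFrame:
    """Optional per-variant summary: delta averaged over a variant's
    scaffolds, weighted by scaffold occupancy.  Per-scaffold rows remain the
    primary output because clusters of one variant can behave divergently."""
    df = rt.table.copy()
    df["weight"] = [
        occupancies.get((r.variant_label, r.scaffold_rank), np.nan)
        for r in df.itertuples()
    ]
    if df["weight"].isna().any():
        raise ValueError("missing occupancy for some (variant, scaffold) pairs")

    def _agg(g: pd.DataFrame) -> float:
        return float(np.average(g["delta"], weights=g["weight"]))

    out = (
        df.groupby(["variant_label", "ligand_id"])
        .apply(_agg, include_groups=False)
        .rename("weighted_delta")
        .reset_index()
    )
    return out


def plot_resistance(rt: ResistanceTable, path: str | Path) -> None:
    """Bar plot of ddG per ligand, grouped by variant scaffold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = rt.table.copy()
    df["scaffold"] = (
        df["variant_label"] + "-" + df["scaffold_rank"].astype(str)
    )
    pivot = df.pivot_table(index="ligand_id", columns="scaffold", values="delta")
    ax = pivot.plot.bar(figsize=(max(6, 1.2 * len(pivot)), 4))
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel(r"$\Delta\Delta G$ vs wildtype (kcal/mol)")
    ax.set_xlabel("ligand")
    ax.set_title("positive = predicted resistance (weaker variant binding)")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
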
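"""Run orchestration: configuration, standardized output layout, logging.

The on-disk contract is stable so parallel runs on separate machines can be
aggregated: every run writes under ``<output_root>/<variant_label>/`` with
deterministic file names, and the resolved configuration is serialized
beside the outputs.  Primary outputs (CSV, PDB) are byte-reproducible for
identical configs and inputs.

Layout per variant::

    <root>/<variant>/
        config.yaml               resolved run configuration
        varscaffold.log           parameters + per-stage summary
        clusters.csv              cluster populations report
        <variant>_scaf<rank>.pdb  occupancy-ranked scaffolds
        resistance.csv            ddG table (dockanalyze)
        resistance.png            per-ligand ddG bar plot (dockanalyze)
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .docking import parse_docking_results, plot_resistance, resistance_table
from .geometry import align_trajectory
from .scaffold import (
    ScaffoldSet,
    cluster_report,
    pairwise_rmsd_matrix,
    qt_cluster,
    select_scaffolds,
)
from .structio import (
    AtomSelection,
    read_pdb,
    read_trajectory,
    write_pdb,
)

__all__ = ["RunConfig", "StageError", "run_varscaffold", "run_dockanalyze"]


class StageError(RuntimeError):
    """An orchestration stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one variant run."""

    variant_label: str = "WT"
    topology: str = ""
    reference: str = ""
    trajectories: list[str] = field(default_factory=list)
    output_root: str = "results"
    cutoff: float = 0.7
    max_clusters: int = 5
    min_occupancy: float = 0.10
    align_resids: list[int] = field(default_factory=list)  # empty = all residues
    bind_resids: list[int] = field(default_factory=list)
    chain: str | None = None
    num_modes: int = 9
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        )

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**data)

    @property
    def align_selection(self) -> AtomSelection:
        return AtomSelection(resids=frozenset(self.align_resids), chain=self.chain)

    @property
    def bind_selection(self) -> AtomSelection:
        return AtomSelection(resids=frozenset(self.bind_resids), chain=self.chain)

    def variant_dir(self) -> Path:
        return Path(self.output_root) / self.variant_label


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def run_varscaffold(cfg: RunConfig) -> ScaffoldSet:
    """Trajectory in, scaffolds out: read, align, cluster, select, report."""
    out_dir = cfg.variant_dir()
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"scaffoldkit {__version__} varscaffold",
        f"variant: {cfg.variant_label}",
        f"seed: {cfg.seed}",
        f"cutoff: {cfg.cutoff} A, max_clusters: {cfg.max_clusters}, "
        f"min_occupancy: {cfg.min_occupancy}",
        f"align resids: {sorted(cfg.align_resids) or 'all'}",
        f"bind resids: {sorted(cfg.bind_resids) or 'all'}",
    ]

    topology = _stage("read-topology")(read_pdb)(cfg.topology)
    reference = _stage("read-reference")(read_pdb)(cfg.reference)
    traj = _stage("read-trajectory")(read_trajectory)(cfg.trajectories, topology)
    log.append(f"frames read: {traj.n_frames} from {len(cfg.trajectories)} file(s)")

    aligned = _stage("align")(align_trajectory)(traj, reference, cfg.align_selection)
    matrix = _stage("rmsd-matrix")(pairwise_rmsd_matrix)(aligned, cfg.bind_selection)
    assignment = _stage("cluster")(qt_cluster)(
        matrix, cutoff=cfg.cutoff, max_clusters=cfg.max_clusters
    )
    scaffolds = _stage("select-scaffolds")(select_scaffolds)(
        assignment, aligned, min_occupancy=cfg.min_occupancy,
        variant_label=cfg.variant_label,
    )

    report = cluster_report(assignment, cfg.variant_label)
    report.to_csv(out_dir / "clusters.csv", index=False, float_format="%.6f")
    for s in scaffolds.scaffolds:
        write_pdb(s.structure, out_dir / f"{cfg.variant_label}_scaf{s.rank}.pdb")
    cfg.to_yaml(out_dir / "config.yaml")

    log.append(
        "clusters: "
        + ", ".join(
            f"#{r + 1}={p}" for r, p in enumerate(assignment.populations)
        )
        + f", unclustered={assignment.n_unclustered}"
    )
    log.append(f"scaffolds written: {len(scaffolds)} ({', '.join(scaffolds.labels()) or 'none'})")
    (out_dir / "varscaffold.log").write_text("\n".join(log) + "\n")
    return scaffolds


def run_dockanalyze(
    variant_dirs: dict[tuple[str, int], str | Path],
    wildtype_dir: str | Path,
    out_dir: str | Path,
    wt_scaffold_rank: int = 1,
    make_plot: bool = True,
):
    """Pose files in, resistance table out.

    ``variant_dirs`` maps (variant_label, scaffold_rank) to a directory of
    pose files; ``wildtype_dir`` holds the poses of the normalizing
    wildtype scaffold (by convention the most populated; ties go to the
    lowest rank).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _read_dir(d: str | Path):
        d = Path(d)
        files = sorted(d.glob("*.pdbqt")) + sorted(d.glob("*.txt")) + sorted(d.glob("*.log"))
        if not files:
            raise StageError(f"[read-poses] no pose files in {d}")
        poses = []
        for f in files:
            poses.extend(parse_docking_results(f))
        return poses

    wt_poses = _read_dir(wildtype_dir)
    variant_results = {key: _read_dir(d) for key, d in sorted(variant_dirs.items())}
    table = _stage("resistance")(resistance_table)(
        variant_results, wt_poses, wt_scaffold_rank=wt_scaffold_rank
    )
    table.to_csv(out_dir / "resistance.csv")
    if make_plot:
        plot_resistance(table, out_dir / "resistance.png")
    return table
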
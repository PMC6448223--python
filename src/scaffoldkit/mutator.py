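"""In-silico point mutation by template side-chain grafting.

The backbone of the target residue is kept bit-identical; the old side
chain is removed and the new one is placed by a rigid transform of an
idealized template into the residue's local N/CA/C frame.  No rotamer
search or clash relief is attempted: downstream molecular dynamics is
expected to relax the grafted geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .structio import AA_1_TO_3, AA_3_TO_1, Atom, Structure
from .templates import backbone_frame, get_template

__all__ = ["VariantSpec", "MutationError", "mutate_residue", "write_md_config"]

_VARIANT_RE = re.compile(
    r"^(?:(?P<chain>[A-Za-z0-9]):)?(?P<resid>\d+):(?P<wt>[A-Z])>(?P<mut>[A-Z])$"
)


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class VariantSpec:
    """A missense substitution: wildtype residue ``wt_aa`` at (chain, resid)
    replaced by ``mut_aa`` (1-letter codes)."""

    chain: str
    resid: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA_1_TO_3:
                raise MutationError(f"not a standard amino acid code: {aa!r}")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.resid}{self.mut_aa}"

    @staticmethod
    def parse(text: str) -> "VariantSpec":
        """Parse 'A:53:L>P' (or '53:L>P', any chain)."""
        m = _VARIANT_RE.match(text.strip())
        if not m:
            raise MutationError(
                f"cannot parse variant {text!r}; expected CHAIN:RESID:WT>MUT"
            )
        return VariantSpec(
            chain=m.group("chain") or "A",
            resid=int(m.group("resid")),
            wt_aa=m.group("wt"),
            mut_aa=m.group("mut"),
        )


_BACKBONE_KEEP = ("N", "CA", "C", "O", "OXT")


def mutate_residue(s: Structure, v: VariantSpec) -> Structure:
    """Return a copy of ``s`` with the target residue substituted.

    All atoms outside the target residue are untouched; within it, backbone
    coordinates are preserved exactly and the new side chain comes from the
    template library.  Serials are renumbered consecutively.
    """
    target_atoms = [
        a for a in s.atoms if a.chain == v.chain and a.resid == v.resid
    ]
    if not target_atoms:
        raise MutationError(f"residue {v.chain}:{v.resid} not found in structure")
    found_resname = target_atoms[0].resname
    if found_resname not in AA_3_TO_1:
        raise MutationError(
            f"residue {v.chain}:{v.resid} is {found_resname}, not a standard "
            "amino acid; refusing to mutate"
        )
    if AA_3_TO_1[found_resname] != v.wt_aa:
        raise MutationError(
            f"wildtype mismatch at {v.chain}:{v.resid}: structure has "
            f"{found_resname} ({AA_3_TO_1[found_resname]}), variant expects {v.wt_aa}"
        )
    bb = {a.name: a for a in target_atoms if a.name in _BACKBONE_KEEP}
    for required in ("N", "CA", "C"):
        if required not in bb:
            raise MutationError(
                f"residue {v.chain}:{v.resid} lacks backbone atom {required}"
            )

    template = get_template(v.mut_aa)
    mut_resname = AA_1_TO_3[v.mut_aa]
    rot, origin = backbone_frame(
        bb["N"].coords, bb["CA"].coords, bb["C"].coords
    )
    grafted = template.local_coords @ rot.T + origin

    new_atoms: list[Atom] = []
    for a in s.atoms:
        if a.chain == v.chain and a.resid == v.resid:
            if a.name in _BACKBONE_KEEP:
                new_atoms.append(replace(a, resname=mut_resname))
        else:
            new_atoms.append(a)
    # Insert side-chain atoms after the last kept backbone atom of the residue.
    insert_at = max(
        i for i, a in enumerate(new_atoms)
        if a.chain == v.chain and a.resid == v.resid
    ) + 1
    template_atoms = [
        Atom(
            serial=0,
            name=name,
            resname=mut_resname,
            chain=v.chain,
            resid=v.resid,
            coords=grafted[i],
            element=name.lstrip("0123456789")[:1],
            occupancy=1.0,
            bfactor=0.0,
        )
        for i, name in enumerate(template.atom_names)
    ]
    new_atoms[insert_at:insert_at] = template_atoms
    for serial, a in enumerate(new_atoms, start=1):
        a.serial = serial
    return Structure(atoms=new_atoms, title=f"{s.title} {v.label}".strip())


# ---------------------------------------------------------------------------
# MD configuration plumbing

#: Standardized simulation parameters written into every generated config.
#: These are toolkit defaults chosen as conventional values for solvated
#: all-atom protein runs; they are not tuned per system.
MD_TEMPLATE_DEFAULTS = {
    "timestep_fs": 2.0,
    "temperature_K": 310.0,
    "langevin_damping_per_ps": 1.0,
    "cutoff_A": 12.0,
    "switch_dist_A": 10.0,
    "pairlist_dist_A": 14.0,
    "output_freq_steps": 5000,
}

_MD_CONFIG_TEMPLATE = """\
# scaffoldkit standardized MD configuration
# structure/topology paths are filled in by the execution wrapper
structure          {structure}
coordinates        {coordinates}
paraTypeCharmm     on
temperature        {temperature_K}
timestep           {timestep_fs}
rigidBonds         all
nonbondedFreq      1
fullElectFrequency 2
cutoff             {cutoff_A}
switching          on
switchdist         {switch_dist_A}
pairlistdist       {pairlist_dist_A}
PME                yes
langevin           on
langevinDamping    {langevin_damping_per_ps}
langevinTemp       {temperature_K}
wrapAll            on
outputEnergies     {output_freq_steps}
dcdfreq            {output_freq_steps}
outputName         {output_name}
run                {n_steps}
"""


def write_md_config(template_params: dict, out_dir: str | Path) -> Path:
    """Emit a deterministic NAMD-style config for a run of
    ``template_params['time_ns']`` nanoseconds.

    The parameter block is standardized (see MD_TEMPLATE_DEFAULTS); only
    the run length, output name, and input paths vary.
    """
    params = dict(MD_TEMPLATE_DEFAULTS)
    params.update(template_params)
    time_ns = float(params.get("time_ns", 1.0))
    if time_ns <= 0:
        raise ValueError(f"simulation time must be positive, got {time_ns} ns")
    n_steps = int(round(time_ns * 1e6 / params["timestep_fs"]))
    text = _MD_CONFIG_TEMPLATE.format(
        structure=params.get("structure", "input.psf"),
        coordinates=params.get("coordinates", "input.pdb"),
        output_name=params.get("output_name", "run"),
        n_steps=n_steps,
        **{k: params[k] for k in MD_TEMPLATE_DEFAULTS},
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / f"{params.get('output_name', 'run')}.namd"
    out_path.write_text(text)
    return out_path
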
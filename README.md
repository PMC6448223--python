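# scaffoldkit

Missense variants of a drug target can reshape the geometry of its ligand
binding interface even when the mutated residue never touches the ligand.
Molecular-dynamics (MD) ensembles capture that effect, but using them for
docking requires a reduction step: pick a small set of *scaffolds* —
representative receptor conformations — that cover the variant's
conformational repertoire, dock a compound library against each scaffold,
and compare binding energies against the wildtype.

`scaffoldkit` is a self-contained toolkit for that reduction and scoring
pipeline, aimed at computational structural biologists who run MD and
docking elsewhere (NAMD, AutoDock Vina, clusters, clouds) and need the
analysis layer to be reproducible, scriptable, and testable without the
physics engines:

1. **mutate** — build a variant structure from the wildtype by grafting an
   idealized side-chain template onto a fixed backbone, and emit
   standardized MD configuration files.
2. **varscaffold** — read multi-file PDB/DCD trajectories, superpose every
   frame onto a common reference (Kabsch), cluster frames by the backbone
   RMSD of user-chosen binding residues (greedy quality-threshold
   clustering), and write occupancy-ranked medoid scaffolds.
3. **dockprep / dockanalyze** — align scaffolds to the reference so one
   docking search box fits all, emit engine configs, parse per-mode pose
   energies, and score resistance.

## The statistic at the core

For frames $x_i$ aligned once to the reference over the whole backbone,
frames are compared by

$$\mathrm{RMSD}(i,j) \;=\; \sqrt{\tfrac{1}{m}\textstyle\sum_{a\in \mathrm{bind}} \lVert x_{i,a}-x_{j,a}\rVert^2}$$

over the $m$ backbone atoms (N, CA, C, O) of the binding residues, with no
re-fitting on the subset. Greedy QT clustering with threshold $\delta$
(default 0.7 Å) repeatedly promotes the frame with the most neighbours
within $\delta$ to cluster founder (ties → lowest frame index), up to
$K=5$ clusters; clusters holding at least 10 % of *all* frames emit their
medoid as a scaffold. Resistance of a variant scaffold against ligand $L$
is the wildtype-normalized best-pose energy difference

$$\Delta\Delta G_L \;=\; E^{\mathrm{best}}_{\mathrm{variant},L} - E^{\mathrm{best}}_{\mathrm{wildtype},L}\quad(\mathrm{kcal/mol}),$$

positive values meaning weaker variant binding — predicted resistance.

A synthetic-data module generates toy proteins, trajectories with planted
conformational clusters (known labels), and docking pose files, so the
whole pipeline is exercised end-to-end with ground truth and no MD or
docking engine.

## Worked example

Generate a 200-frame trajectory with two planted conformers (65 % / 35 %,
1.5 Å apart over residues 5–10, 0.12 Å atomic noise), extract scaffolds at
the 0.7 Å threshold, and score a variant against the wildtype with
synthetic docking results:

```
$ scaffoldkit synth-traj --n-residues 14 --k 2 --weights 0.65,0.35 \
    --displace-resids 5,6,7,8,9,10 --separation 1.5 --sigma 0.12 \
    --n-frames 200 --seed 11 --out synth
wrote 200 frames / 70 atoms under synth

$ scaffoldkit varscaffold --traj synth/traj.dcd --topology synth/topology.pdb \
    --ref synth/topology.pdb --variant-label 95R \
    --bind-resids 5,6,7,8,9,10 --cutoff 0.7 --out results
2 scaffold(s): 95R-1, 95R-2
outputs under results/95R

$ cat results/95R/clusters.csv
variant,cluster,population,fraction,medoid_frame
95R,1,134,0.670000,84
95R,2,66,0.330000,46
95R,Unclustered,0,0.000000,
```

Both planted conformers are recovered (134/66 ≈ the planted 0.65/0.35
split) and written as `95R_scaf1.pdb` and `95R_scaf2.pdb`. Docking
analysis against wildtype pose files:

```
$ scaffoldkit dockanalyze --variant-dir 95R:1:poses/95R-1 \
    --wildtype-dir poses/WT-1 --out resistance
ligand_id variant_label  scaffold_rank  E_variant  E_wildtype  delta  resistant
  BMS1166           95R              1       -8.9        -9.1    0.2       True
   BMS202           95R              1       -7.6        -8.4    0.8       True
     LP23           95R              1       -7.3        -7.2   -0.1      False
```

`delta` is ΔΔG in kcal/mol: the 95R scaffold is predicted to weaken
BMS202 binding by 0.8 kcal/mol (resistant) and to leave LP23 essentially
unchanged.

A documented real-world configuration (PD-L1 Ig-like V-type domain,
PDB 4Z18; binding residues 19, 20, 54, 56, 66, 68, 115–117, 121–125;
0.7 Å threshold) is provided in `docs/methods.md` as the canonical example
of production parameters.

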
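# Methods

## Scope and model

`scaffoldkit` implements the analysis layer of a variant-scaffold docking
pipeline: structure mutation, trajectory alignment, binding-interface
clustering, scaffold extraction, and wildtype-normalized resistance
scoring. The physics stages that surround it — solvation, force-field
parameterization, MD integration, and the docking search itself — are
external by design; the toolkit writes their configuration files and
parses their outputs, nothing more. Trajectories are assumed to be
protein-only (solvent stripped before analysis); HETATM records are read
but never selected.

## Alignment and RMSD

Superposition uses the Kabsch closed form: the covariance of centered
point sets is decomposed by SVD and a possible reflection is corrected so
the rotation is proper (det = +1). Weights are uniform — clustering acts
on backbone atoms only (N, CA, C, O; the carbonyl oxygen is included to
match the common "backbone" selection convention), and mass differences
among those atoms are ignored for reproducibility. Degenerate inputs
(fewer than 3 points, collinear configurations: covariance rank < 2) are
rejected rather than silently resolved.

The alignment contract is deliberately two-stage:

1. every frame is fitted once onto the **user-supplied reference
   structure** (not frame 0) over the alignment selection — by default all
   backbone atoms;
2. subset RMSDs over the binding residues are then computed **without
   re-fitting** on the subset.

Re-fitting per subset would change the cluster geometry; using the
experimental reference as the common frame means the same frame later
serves docking preparation, where scaffolds must all sit in the
coordinate system the search box was defined in.

## Clustering and scaffold selection

Frames are clustered by greedy quality-threshold (QT) clustering on the
pairwise binding-site RMSD matrix: the unassigned frame with the most
unassigned neighbours within the cutoff δ founds the next cluster,
consisting of itself and those neighbours; the process repeats up to
`max_clusters` (default 5), and leftovers are labelled Unclustered. The
cutoff bounds the *distance to the founder*, not the cluster diameter —
the greedy-QT convention. Ties on neighbour count break to the lowest
frame index, which makes the procedure fully deterministic; an
independent brute-force transliteration of the rule pins these semantics
in the test suite and the acceptance script.

A cluster yields a scaffold when its population is at least
`min_occupancy` (default 0.10) of **all** frames — the denominator
includes unclustered frames. The representative is the **medoid** on the
binding-site RMSD (the member minimizing summed distance to co-members);
a coordinate-averaged centroid is not a physically valid structure.
Zero qualifying clusters is a legal outcome (empty scaffold set plus a
warning). Because cluster counts are sensitive to δ when few residues
define the interface, a sweep mode tabulates cluster counts over a cutoff
grid; the choice of δ is left to the user's judgment rather than an
automatic stopping rule.

Key parameters:

| parameter | default | units | meaning |
|---|---|---|---|
| `cutoff` (δ) | 0.7 | Å | QT neighbour threshold on binding-site backbone RMSD |
| `max_clusters` (K) | 5 | — | greedy clusters extracted before the Unclustered pool |
| `min_occupancy` (f) | 0.10 | fraction | population share (of all frames) required to emit a scaffold |
| `num_modes` | 9 | — | docking modes requested/parsed per ligand |

The canonical production example is the PD-L1 Ig-like V-type domain
(PDB 4Z18): alignment over the whole domain backbone, binding residues
19, 20, 54, 56, 66, 68, 115, 116, 117, 121, 122, 123, 124, 125, δ =
0.7 Å, with the same residues modelled flexible during docking. This
configuration is shipped as documentation only; it requires externally
generated MD trajectories.

## Mutation

A missense variant is built by keeping the target residue's backbone
(N, CA, C, O, and OXT when present) bit-identical, deleting the old side
chain, and rigidly placing an idealized side-chain template. The template
library is computed at first use from force-field-relaxed single-residue
conformers (RDKit ETKDG embedding with a fixed seed followed by MMFF
relaxation), expressed in a local frame anchored on the backbone: origin
at CA, x-axis toward N, the N–CA–C plane fixing y. Grafting maps that
frame onto the target residue's own N/CA/C. No rotamer search or clash
relief is attempted — downstream MD is expected to relax the geometry, so
grafted side chains are idealized and may clash. Proline substitutions
keep the backbone fixed even though proline constrains φ; this is a
documented limitation of backbone-preserving grafting. Template CA–CB
bond lengths fall in 1.4–1.6 Å for all 19 side-chain-bearing residues
(checked by tests).

The MD-config writer emits a standardized NAMD-style parameter block
(2 fs timestep, 310 K Langevin thermostat, PME, 12 Å cutoff) with only
the run length and I/O names substituted. These are conventional toolkit
defaults for solvated all-atom protein runs, not values tuned to any
particular system.

## File formats

PDB reading follows the v3.3 fixed columns (coordinates in columns
31–54); alternate locations other than blank or 'A' are dropped. Writing
uses the 8.3 fixed format, so round trips are exact in metadata and
within 5×10⁻⁴ Å in coordinates. DCD I/O implements the CHARMM/NAMD
dialect — Fortran record markers, "CORD" magic, 20-integer control block,
per-frame float32 X/Y/Z records, optional unit-cell record on read —
with native-endian writing and endianness auto-detection on read
(validating the leading marker value 84). Fixed-atom DCDs are rejected
with a clear error: the MD configurations this toolkit writes never
produce them. Cross-compatibility with MDAnalysis (both directions) is
covered by tests.

## Resistance scoring

"Normalizing to the wildtype prediction" is implemented as a
**difference** of best-pose binding energies, not a ratio: docking
energies are free-energy estimates, so ΔΔG = E_variant − E_wildtype
(kcal/mol) is the physically meaningful comparison, and positive values
flag predicted resistance (weaker variant binding). One wildtype scaffold
normalizes the table — by convention the most populated; if wildtype
scaffolds tie in occupancy the lowest rank wins. Scaffolds of one variant
are reported **per scaffold**, never averaged, because clusters of the
same variant can behave divergently against the same ligand; an optional
occupancy-weighted summary is available separately. Ligands present on
only one side of the comparison are listed as skipped rather than scored.

## Synthetic data

The generator emulates exactly the statistical structure the clustering
stage consumes, and nothing more. A toy protein is an extended
poly-alanine chain (5 heavy atoms per residue, CA–CA ≈ 3.8 Å). A
trajectory plants k conformer centers that differ by rigid translations
of a chosen residue set, arranged on a simplex so every pairwise
binding-site RMSD between centers equals the requested separation
(k ≤ 4 exactly; larger k approximately); each frame picks a center with
the given weights and adds isotropic per-atom Gaussian noise σ, so two
frames of one conformer have E[RMSD²] = 6σ² — the relation used to place
cutoffs between 3σ and half the separation in tests. Docking fixtures
write the result-remark dialect with mode-1 affinity = mean + jitter·z
and monotonically weaker later modes; with jitter 0 and means given to
three decimals, parsed best affinities reproduce the means exactly. All
generators are pure functions of their seed.

What this does **not** emulate: anisotropic or correlated fluctuations,
gradual conformational drift, transition paths between states, solvent
artifacts, or any real energetics. Passing the planted-recovery tests
therefore demonstrates the correctness of the alignment–clustering–
selection machinery under the stated noise model, not the adequacy of
any MD sampling protocol.

## Numerical and determinism choices

Default problem sizes in tests and the acceptance script (200-frame
trajectories, 14-residue toy proteins, 20 seeds per planted condition,
1000 random superposition cases) were chosen to make the planted-model
statistics decisive — separations of ≥ 5σ with n = 200 give
misclassification probabilities far below the 1 % tolerance — while the
whole suite remains comfortably interactive. The pairwise RMSD matrix is
computed via the Gram-matrix identity with a symmetrization and clamp at
zero to absorb floating-point negatives. Primary outputs (CSV, scaffold
PDBs, configs) contain no timestamps and use fixed float formats, so
identical configurations reproduce byte-identical files; this is asserted
end-to-end. Report frames are 1-indexed with source-file provenance;
internal indexing is 0-based.

## Known limitations

- Grafted side chains are single idealized conformers; severe clashes are
  possible in dense cores and are left to downstream relaxation.
- Only translation-generated planted conformers are produced by the
  generator; planted rotational differences are not currently modelled.
- No mmCIF, PSF, compressed-trajectory (XTC/TRR), or velocity-DCD
  support.
- The docking engine adapter is configuration/parsing only; it does not
  manage engine processes.
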
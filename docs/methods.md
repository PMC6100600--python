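# Methods

## Scope and model

`aptamd` analyzes snapshot series of a receptor–ligand(–water/ion) complex.
Each frame is an ordered atom list partitioned by residue name into
receptor, ligand, water and ion sets; residue numbering is taken from the
file (1-based) and never changed. All coordinates are Angstrom, all angles
degrees; the energy module alone works in GROMACS units (nm, kJ·mol⁻¹, e)
and converts at its boundary to avoid the classic 10× unit error.

Chemical roles are derived from geometry, not from a force field:

* covalent bonds are inferred by distance — ≤ 1.9 Å for heavy–heavy pairs,
  ≤ 1.25 Å for X–H. This is parameter-free and adequate for idealized
  fixtures and all-atom MD snapshots, where bond lengths sit far from these
  cutoffs; it will mis-bond only in badly clashed structures.
* hydrogen-bond **donors** are N/O atoms with at least one bonded hydrogen;
  **acceptors** are all N/O. In the default *strict* mode explicit hydrogens
  are required (an all-atom trajectory has them); the *lenient* heavy-atom
  mode treats every N/O as a potential donor, skips all angle tests rather
  than inventing hydrogen positions, and tags every downstream record
  `lenient`.
* **hydrophobic carbons** bond only to carbon or hydrogen.
* **aromatic rings** come from residue templates for the standard
  nucleobases (purine 5- and 6-rings, pyrimidine ring), from user templates
  for ligands, and otherwise from a generic search for 5/6-membered bonded
  cycles with RMS plane deviation ≤ 0.2 Å.

Roles are computed once from frame-0 topology and copied to every frame, so
thermal noise in a single snapshot cannot flip a flag mid-trajectory.

## Detection criteria

Defaults are the published PLIP geometric criteria; every number lives in
`InteractionConfig` and is serializable to JSON. A `strict` preset
(D–A ≤ 3.5 Å, angle ≥ 120°) ships for sensitivity checks, and a
`gromacs-like` preset (D–A ≤ 3.5 Å, D–H⋯A ≥ 150°) approximates the
GROMACS `hbond` convention (H–D–A ≤ 30°) for intramolecular counting.

| parameter | default | meaning |
|---|---|---|
| `hbond_da_max` | 4.1 Å | donor–acceptor distance |
| `hbond_angle_min` | 100° | D–H⋯A angle at the hydrogen |
| `hydrophobic_max` | 4.0 Å | C⋯C contact distance |
| `pistack_center_max` | 5.5 Å | ring centroid separation |
| `pistack_offset_max` | 2.0 Å | lateral centroid offset |
| `pistack_parallel_angle_max` | 30° | interplanar angle, parallel type |
| `pistack_tshape_angle_window` | 60–90° | interplanar angle, T-shaped type |
| `waterbridge_dist_min/max` | 2.5–4.1 Å | each bridge leg |
| `waterbridge_omega_window` | 71–140° | ∠(H, O_w, A) at the water oxygen |
| `waterbridge_theta_min` | 100° | D–H⋯O_w angle at the donor |

Design choices within these rules:

* each donor hydrogen is paired with at most its **nearest** qualifying
  acceptor (ties broken by lower atom serial). Without this reduction a
  single well-placed hydroxyl would count several simultaneous partners and
  inflate frequency tables.
* a water bridge is a (donor, water oxygen, acceptor) triple with donor and
  acceptor on opposite sides. The water's own hydrogens are not tested
  directly; the ω window at the water oxygen constrains the water's
  donating geometry implicitly, which keeps detection robust to water
  hydrogen placement. θ is taken at the non-water donor.
* π-stacking offset is the minimum of each centroid's in-plane projection
  distance onto the other ring; the interplanar angle is folded to [0°, 90°].
* interaction classes are detected independently — the same residue may
  appear simultaneously as hydrogen-bond and hydrophobic partner, which is
  chemically real for bases lining a binding pocket.

## Trajectory statistics

Radius of gyration is mass-weighted by default (GROMACS `gyrate`
convention) with an unweighted flag. RMSD uses Kabsch superposition via SVD
with reflection correction (proper rotations only); a paired mode compares
frame *i* of two topology-identical trajectories. RMSF superposes every
frame onto frame 0 in one fitting pass, then measures fluctuation about the
trajectory-mean structure — the standard definition, stated explicitly
because conventions differ. Per-region RMSF means are reported both over
member atoms and per residue, since published tables rarely say which
average they use. Intramolecular hydrogen-bond counting uses the
`gromacs-like` preset and excludes same-residue pairs.

## Distance maps and secondary structure

The distance map stores the minimum inter-atomic distance per residue pair
under a heavy-atom (default) or all-atom metric — published base-pair maps
with minima near 1.5 Å evidently include hydrogens, so both metrics are
selectable and no pixel-level reproduction of any particular figure is
claimed. The ligand can be appended as the final map entry.

Secondary structure is annotation, not prediction: the pairing is supplied
as dot-bracket or an explicit 1-based pair list. Crossing pairs raise a
`PseudoknotError` rather than being silently flattened — the target
molecules are short aptamers where nesting holds, and guessing a
pseudoknot layout would mislabel every enclosed residue. Fine labels are
tails, stem, interior loop, hairpin stem and hairpin loop (a helix whose
innermost pair encloses no further pairs closes a hairpin); unpaired
residues between two top-level helices fall back to `unpaired-other`.
Coarse labels merge the hairpin-closing stem into the hairpin loop, the
convention used when regions are reported as contiguous base ranges.

## Aggregation semantics

Two counting conventions coexist and are named explicitly, because both
appear in published tables:

* **frame presence** (per-base tables): a base scores a frame if at least
  one record of the class involves it in that frame; the `total` column is
  the union of frames over classes, never the column sum.
* **raw record counts** (per-anchor tables): absolute counts attributed to
  ligand anchor groups (e.g. the 3- and 17β-hydroxyls of an estradiol-like
  diol; π-stacks are anchored by ligand ring name, not an oxygen), with
  relative shares within each class column.

Combination shares label each frame by the subset of *specific* classes
present (hydrogen bond, water bridge, π-stack); hydrophobic contacts are
non-specific and excluded from combination and bound-fraction accounting,
though they do appear in per-base tables. Percentages are exact count
ratios internally and rounded half-up to two decimals only at presentation.

## Energy decomposition

The gas-phase molecular-mechanics terms of an MM/PBSA-style analysis:
E_ele = f·q₁q₂/(ε_r·r) with f = 138.935485 kJ·mol⁻¹·nm·e⁻², and
E_vdw = 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination. Pair
energies are summed over all (ligand atom, receptor atom) pairs, each pair
assigned wholly to its receptor residue (per-residue decomposition tools
differ on half-splitting; whole assignment is the simpler convention and is
stated here). Parameters arrive as a user TSV — missing parameters raise,
never default to zero charge. The Poisson–Boltzmann polar term and SASA
non-polar term of a full binding free energy are **not computed**; the
report carries explicit markers so the gas-phase numbers cannot be mistaken
for ΔG_binding. An optional hard cutoff exists for experimentation; the
default is no cutoff, which for small systems is both exact and cheap.

## Synthetic fixtures

The generator builds geometric test articles, not physical DNA: bare
nucleobase residues on idealized planar templates (hexagon side 1.39 Å,
fused regular pentagon for purines), an estradiol-mimic ligand (aromatic
A-ring, 3-hydroxyl, aliphatic chain to a 17-hydroxyl, methyl branch), and
3-site waters. Planted interactions are placed on separated approach axes
with margins of at least 10 % to every relevant threshold, on both sides:
present interactions satisfy their criteria with slack (so 3-decimal PDB
truncation cannot break them), absent ones violate them with slack. One
deliberate consequence: the planted parallel π-stack sits at 4.6 Å centroid
separation rather than the van-der-Waals 3.4–3.8 Å, because at true
stacking distance the rings' carbons legitimately form hydrophobic contacts
and exact planted recovery would be impossible; close-distance stacking
geometry is exercised directly in unit tests instead. Decoy waters keep
≥ 6 Å clearance. Each fixture is deterministic given its seed (logged in a
PDB REMARK), and `make_complex` verifies by construction that profiling
recovers exactly the planted (class, frame) multiset.

What passing fixture tests shows: the detectors implement their geometric
definitions exactly, with no false positives or negatives under controlled
geometry. What it does not show: agreement with any specific published
trajectory analysis, which depends on simulation details, hydrogen
treatment and tool versions that geometric fixtures do not emulate.

## Problem sizes and numerical notes

Test fixtures use systems of 3–10 residues, up to ~50 waters and 1–5
frames; the acceptance script uses 100 random fixtures for oracle
agreement, 100 seeded complexes for planted recovery and a 200-frame demo
trajectory — sizes chosen so the full suite runs in seconds while every
code path is exercised. Plane fitting uses SVD with the normal
sign-canonicalized toward +z (ties toward +x, then +y). Kabsch rejects
collinear selections (rank-deficient cross-covariance). Degenerate inputs —
empty selections, zero-atom partitions, zero pair distances, unparameterized
atoms — raise rather than return defaults.

## Known limitations

* No salt bridges, halogen bonds, cation–π or metal coordination; only the
  four classes above.
* No trajectory formats beyond multi-model PDB (XTC/DCD/GRO are a
  documented extension point); no topology-file parsing; no hydrogen
  placement — trajectories are analyzed as given.
* No secondary-structure prediction and no 3D structure building; pairing
  is input.
* No solvation or entropy terms: the energy module is a gas-phase MM
  decomposition, not a binding free energy.
* No equilibration detection; deciding which frames constitute equilibrium
  remains the analyst's call.
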
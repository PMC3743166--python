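# Methods

`groovebind` analyses the surface-bound state of a binuclear dumbbell
ligand (two octahedral Ru(II) centres joined by a planar, fused-ring
bridging system with one pivot torsion) in the minor groove of a B-DNA
duplex.  Because no coordinates or trajectories are available for such
complexes as machine-readable input, every input is produced by the
package's own synthetic builder; all statistics in the analysis layer are
then exact functions of that generated data.

## Synthetic structures

**Duplex.**  `build_bdna` stacks rigid, planar base-pair templates with a
fixed twist of 36.0 deg and rise of 3.38 A per step (canonical fiber-model
values; both configurable, validated to 0 < twist < 60 deg and
2 < rise < 5 A).  Base rings are idealized regular polygons (aromatic bond
1.39 A); within a pair the two glycosidic C1' anchors sit at a radius of
5.9 A and azimuths of +/-118.5 deg from the minor-groove direction, and
both glycosidic rays aim at a common point on the pair dyad axis solved
once (by bisection at import) so the central purine-N1...pyrimidine-N3
separation equals the 2.82 A template value.  The Watson-Crick
donor-acceptor distances of the resulting templates (2.4-3.5 A) are the
reference values for the builder's geometry checks; pairs are rigid, so
built duplexes reproduce them exactly.  The minimal backbone
(phosphate + five-membered sugar ring + H1') places phosphorus at a radius
of 9.6 A, 10 deg azimuthally beyond its C1'; these two constants set the
minor/major groove widths.  H1' blends the tetrahedral completion of the
C1' substituents with an equal-weight bias towards the minor-groove gap,
mimicking how H1' protons line the minor-groove walls.  Residues are
numbered 1..L on the first strand and L+1..2L on the second, so base pair
i pairs residues (i, 2L+1-i).

**Ligand.**  `build_ligand` builds one monomer as three linearly fused
hexagons: a terminal benzo ring carrying the pivot carbon and the two
NOE-candidate CH protons (HC1/HC2, flanking the phenazine nitrogens at
2.64 A, on the bridge moiety that buries in the groove), a pyrazine ring
whose two nitrogens are the hydrogen-bond acceptors, and a chelating ring
whose two nitrogens bind the metal (Ru-N 2.06 A).  Four idealized
pyridines per metal complete the octahedron; their directions are canted
16 deg (axial pair) and pulled to +/-38 deg in-plane (equatorial pair)
towards the dumbbell end, reproducing the propeller-like wrap of real
bipyridine caps and keeping the groove-facing bridge edge sterically
clean.  The second monomer is the two-fold image of the first about the
pivot-bond midpoint, rotated about the pivot bond by the torsion (default
33 deg); the measured dihedral CRFA-CPVA-CPVB-CRFB equals the requested
torsion by construction, and at torsion 0 the dimer is exactly two-fold
symmetric under the monomer-swap relabelling.

**Placement.**  `place_in_minor_groove` seats the bridging-ring centroid
near the wall of the chosen groove at base-pair step `register`, with the
metal-metal axis tilted from the helix axis by `tilt` (default 66.17 deg,
close to the ~65 deg reported by linear dichroism for this binding mode)
and the ring plane rolled about that axis by a fixed convention angle.
The numerical seating constants (axial offset 0.06 A, azimuthal offset
73.356 deg, roll -85.911 deg, seat radius 11.25 A minus `depth`) were
fixed once, by a constrained fit, so that the default pose (i) places the
two groove-facing candidate protons within the weak-NOE limit (5.0 A) of
the H1' protons of second-strand residues 16/17 while every competing
proton violates those limits by several Angstrom, (ii) keeps all
intermolecular heavy-atom distances above 2.4 A, and (iii) yields a
negative total interaction enthalpy under the energy model below.  This is
a surface-perched pose: the narrow bridge moiety leans over the
minor-groove mouth while the bulky metal ends ride on the backbone ridge
at ~11.5 A radius — the reason the builder's "metal near an AT pair"
behaviour is expressed through the bridge edge rather than the metals
themselves.  Placement never alters DNA coordinates; heavy-atom contact
below 1.5 A raises a clash error.

**Ensembles.**  `generate_ensemble` emulates thermal snapshots: isotropic
per-atom Gaussian noise (default 0.3 A, a typical heavy-atom RMSF scale on
the nanosecond timescale) plus a rigid-body ligand jitter (0.3 A
translation, 2 deg rotation about the ligand centroid).  One seeded
generator per call, noise drawn in fixed atom order, so equal seeds give
bit-identical ensembles.  What the generator does **not** emulate:
correlated backbone motions, groove breathing, base-pair fraying, solvent
or counterions, and any force-field energetics — a pose that drifts is
outside its vocabulary.  Passing tests therefore demonstrate the
correctness of the estimators on data with known ground truth, not the
stability of any real complex.

## NOE restraints and assignment selection

Observed NOEs are upper distance limits: 3.5 A (strong) or 5.0 A (weak).
Against an ensemble the tested quantity is the r^-6 average
`d_NOE = [(1/N) sum_i d_i^-6]^(-1/6)` with uniform snapshot weights; the
per-run table averages each run separately (pooling across runs is
available but not the default, matching how per-trajectory tables are
reported).  A distance exactly at its limit is satisfied; the violation is
`max(0, d_NOE - limit)`.

When two ligand resonances have four candidate protons, all P^R = 16
mappings are enumerated; the 4 with one proton serving both resonances are
excluded, and the remaining 12 collapse into 6 classes under the
monomer-swap involution applied jointly to all mapped protons (the two
members of a class describe the same physics under relabelling of the two
identical monomers, so a class scores as its better member).  Each class
receives a target function: the sum of squared restraint violations plus
a weighted (default weight 1) sum of squared van der Waals overlaps over
intermolecular heavy-atom pairs.  The steric radii are deliberately
*lower-limit* contact radii (C 1.15, N 1.05, O 1.0, P/S 1.2, Ru 1.2,
H 0.8 A) in the spirit of NMR structure-calculation van der Waals limits:
they flag interpenetration, not sub-equilibrium contact, which is the
appropriate reading for rigid idealized bodies that cannot relax.  For an
ensemble the steric term is evaluated on the ensemble-average structure,
as one would score a trajectory-averaged model.  The lowest-total class is
accepted only if its worst violation is at most 0.1 A and it beats the
runner-up by more than a configurable margin (default 1e-6); otherwise the
selection is reported ambiguous with the full ranking.

The default demo restraint set uses three weak (5.0 A) NOEs: resonance r1
to the H1' protons of residues 16 and 17, r2 to the H1' of residue 16
(one DNA proton with cross peaks to both resonances).  All-weak NOEs are
the physically expected signature of a surface-bound complex, and they are
what the rigid proxies can satisfy while simultaneously keeping the
Lennard-Jones term out of its repulsive core; the strong/weak machinery is
exercised against published per-run distance tables elsewhere in the test
suite.

## Interaction enthalpy

Three intermolecular terms, each with a per-pair ledger that sums exactly
to its total:

* **Coulomb** — point charges +2 e on each metal and -1 e on each backbone
  phosphorus, screened by a relative permittivity of 20:
  `E = 332.0636 q_M q_P / (eps_r r)` kcal/mol over all metal-phosphorus
  pairs.  No distance cutoff by default: most metal-phosphate separations
  exceed the Lennard-Jones cutoff, and truncating there would delete the
  dominant attractive term.  A `coulomb_cutoff` option exposes the
  truncated variant for sensitivity checks.
* **Lennard-Jones** — 12-6 form `eps_ij[(R_ij/r)^12 - 2(R_ij/r)^6]` over
  all ligand-DNA pairs within a hard 6 A cutoff.  Per-element well depths
  and like-pair optima follow the AutoDock-3-style docking set (bundled as
  `data/lj_params.csv`, user-replaceable), with phosphorus aliased to
  sulfur; ruthenium, absent from that set, ships with a soft default well
  (eps 0.056 kcal/mol, R 2.96 A).  Pair parameters combine as geometric
  mean (eps) and arithmetic mean (R).
* **Hydrogen bonds** — a fixed -2.0 kcal/mol per intermolecular
  donor-H...acceptor contact strictly closer than 3 A, each donor hydrogen
  counted once with its nearest acceptor.  The generous length limit
  reflects scoring of averaged structures; the per-bond energy is a
  configurable order-of-magnitude default ("a few kcal/mol" per bond).

**End-surface attribution.**  A vdW or Coulomb ledger term from a ligand
atom to a *base* atom of the terminal pair is attributed to the artificial
surface created by cutting the duplex out of longer DNA when the angle
between the interatomic direction and the least-squares plane of that base
exceeds 45 deg strictly (such an interaction could not exist if the helix
continued).  The end-surface fraction is
`100 x |sum of flagged terms| / |sum of all vdW+Coulomb terms|`; hydrogen
bonds enter neither sum.  Base atoms are the ring systems plus exocyclic
substituents; sugars and phosphates are excluded.

On the default pose the Lennard-Jones total is mildly positive
(a few tens of kcal/mol): rigid idealized rings pressed to NOE-contact
distance cannot relax the handful of sub-optimum contacts a force-field
structure would.  The electrostatic term dominates and the total enthalpy
is robustly negative, which is the property the pipeline asserts.

## Descriptors

* **Superposition** — Kabsch (SVD with determinant correction, proper
  rotations only), RMSD from the post-fit residuals; selections of fewer
  than 3 atoms or collinear selections raise a degenerate-selection error.
* **Displacement** — every structure is superposed onto the first over a
  stable base-pair block (default pairs 7-10, the binding half of the
  default scenario), and per-atom distances of the ligand heavy atoms to
  the mean structure are pooled into mean +/- sd.  The pipeline applies
  this to per-run average structures (cross-run comparison); applying it
  to raw snapshots gives the per-snapshot variant.
* **Hydrogen-bond geometry** — strict criteria: H...acceptor below 2.6 A
  and deviation from donor-H...acceptor linearity below 25 deg.  The
  deviation-from-linearity convention (vertex at the hydrogen) was chosen
  because it is the common strict convention; the criteria object makes
  the thresholds explicit and adjustable.
* **Ring geometry** — distance of a proton from an aromatic ring centroid
  and its elevation above the least-squares ring plane (0 deg in-plane,
  90 deg on the normal); collinear ring atoms raise a plane-fit error.
* **Helix-ligand angle** — acute angle between the metal-metal axis and
  the least-squares line through the base-pair centroids.  The centroid
  fit, not a helicoidal decomposition, is used because it is robust on
  idealized and perturbed duplexes; on a 12-mer it deviates from the exact
  construction axis by under a degree.

## Problem sizes and numerical conventions

The default scenario is a 12-mer duplex plus ligand (738 atoms), ten runs
of 25 snapshots each for the pipeline tables, and 100 independent
20-snapshot replicates for the assignment-recovery experiment — sizes
chosen so the entire workflow, including the recovery experiment, runs in
about a minute on one CPU while the recovery statistics remain sharp
(competing assignments violate by >2 A, far beyond the noise scale).
Floating-point conventions: distances and energies in double precision;
ledgers reproduce totals to 1e-6 kcal/mol; superposition residuals to
1e-9 A on rigid copies; JSON reports are written with sorted keys so equal
seeds give byte-identical bundles.

## Known limitations

* The duplex is sequence-independent in its helical parameters and has
  planar, propeller-free pairs; groove widths are set by two constants
  rather than emerging from backbone chemistry.
* The ligand is a topological proxy: ring counts, exact bond graphs and
  charges of a real bis(dipyridophenazine) dimer are not reproduced, only
  planarity, rigidity, two-fold symmetry, the pivot torsion and the
  placement of the NOE protons, H-bond acceptors and metals.
* The enthalpy model is a screened-point-charge/docking-LJ estimate on a
  single structure; it contains no solvent, no polarization and no
  hydrophobic or entropic contribution, so only signs, decompositions and
  attributions — not absolute magnitudes — are meaningful.
* The strict hydrogen-bond detector typically finds no bonds on the
  default surface pose (its acceptor-to-amino contacts sit near 3.6 A);
  the detector's correctness is established on constructed geometries and
  by brute-force comparison.
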
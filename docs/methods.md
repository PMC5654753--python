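# Methods

This note documents the models, conventions and design choices behind
`iscarod`: what each analysis computes, what the synthetic fixtures do and
do not emulate, and where the design was genuinely open.

## Units and conventions

Lengths are Angstrom, energies kcal/mol, charges elementary-charge units,
times nanoseconds. Angles are degrees at every I/O boundary and radians
internally. Residue ids follow the 1-based PDB convention; insertion
codes are not supported and the first alternate location wins. Torsion
angles use the standard right-handed convention about the central bond
(cis = 0°, trans = 180°, range (−180°, 180°]), verified in tests against
two independent libraries.

## Rod assembly

The rod is rebuilt the way extended assemblies are recovered from crystal
packing: the asymmetric unit is replicated over symmetry operators and
lattice translations (`expand_supercell`), and the contiguous polymer is
the largest connected component of a monomer-contact graph
(`extract_rod`). Two monomers are adjacent when any of their
cysteine-114/116 SG atoms lie within the adjacency cutoff; the same
residues define the Fe₂S₂ coordination sites, where a complete
four-sulfur quartet (two SG per monomer, all mutually within the site
cutoff) is required. Both cutoffs default to **6.0 Å** — a generous bound
on S–S separations in a cysteine-coordinated cluster environment, chosen
here since no value is prescribed by the construction being emulated —
and are configurable. Partial quartets (e.g. three sulfurs in range)
raise an ambiguous-site warning and are skipped rather than guessed.

Cluster placement puts an idealised Fe₂S₂ rhombus (Fe–Fe 2.7 Å, Fe–S
2.2 Å) at each site: bridging-sulfur midpoint on the SG-quartet centroid,
Fe–Fe axis along the bisector of the two monomers' SG-pair directions.
Any placed atom closer than 1.0 Å to an existing atom aborts with a
placement error; 1.0 Å is comfortably below any bonded contact, so only
genuinely impossible placements are rejected.

Monomer replacement (`superpose_replace`) and all alignment use
least-squares rigid superposition (Kabsch), delegated to
`scipy.spatial.transform.Rotation.align_vectors` behind the
`kabsch_align` surface. Degenerate (collinear or <3-point) subsets raise
rather than return an ill-conditioned fit; the degeneracy test is a rank
check on the centered subset at tolerance 1e-8.

## Docking

Partners dock via two alpha helices: the helix axis is the least-squares
line through the range's CA atoms (stable for short helices), each CA is
mapped to its arc-length position on the target anchor axis, and one
rigid transform is fitted over both helices jointly. A site is accepted
only if no transformed partner atom lies within the clash threshold
(default **2.0 Å**, below the closest plausible nonbonded contact) of any
already-placed atom. Fresh chain identifiers come from a deterministic
stream (A–Z, a–z, 0–9, then two-character codes with a warning; PDB
output requires the single-character range).

## Energetics

The conformational-stability estimator is the proper-dihedral energy
U = Σᵢ kᵢ[1 + cos(nᵢθᵢ − δᵢ)] (kᵢ in kcal/mol, multiplicity nᵢ, phase δᵢ).
Improper dihedrals and cross-term corrections are deliberately out of
scope: the estimator is exactly the printed periodic form.

Group–group interaction energy is a direct-space sum of Coulomb
(constant 332.0636 kcal·Å/(mol·e²)) and 12-6 Lennard-Jones terms
(geometric-mean ε, additive r_min/2), with a **12 Å** cutoff and a
CHARMM-style switching polynomial from **10 Å**, applied to both
components (configurable off); the switched energy is continuous through
both boundaries (verified by numeric scan at 1e-4 Å). Pairs closer than
0.1 Å raise an overlap error. 1-2/1-3 exclusions exist as explicit pair
sets but are irrelevant for inter-protein group pairs. Lattice-sum
electrostatics are out of scope: per-partner interaction energies are
defined here as cutoff sums, which is how such decompositions are
conventionally extracted and keeps the package engine-free. Which terms
constitute "interaction energy" (and whether solvent screening enters) is
an open modelling choice; the declared definition is electrostatics +
van der Waals between the partner's atoms and the whole polymer.

## Trajectory analyses

* **RMSD**: per frame, least-squares fit on a fit subset (CA by
  convention), RMSD over a measure subset; superposition can be disabled.
* **Edge-to-edge distance**: minimum pairwise distance between two atom
  sets, heavy atoms only by default (the standard electron-transfer
  distance convention; overridable). The nearest Fe₂S₂ cluster is
  re-evaluated every frame, not fixed at frame 0.
* **Marcus screening**: |H_DA|² = V₀²·exp(−βR) is reported relative to
  V₀² only — absolute coupling coefficients are system-specific and none
  is prescribed. The default β = 1.4 Å⁻¹ is the textbook protein-medium
  decay constant.
* **Contact maps**: a residue pair is in contact when any heavy-atom pair
  is within the cutoff (default **3 Å**); occupancy is the fraction of
  window frames, with presence (occupancy > 0) the default retention
  criterion since the maps mark contacts, not persistences (a 0.5
  threshold is one flag away). The default window is the final **6 ns**.
* **Hydrogen bonds**: geometric criteria, donor–acceptor heavy distance
  ≤ **3.5 Å** and D–H···A angle ≥ **150°** — the common convention; none
  is prescribed by the analysis being emulated. Donor hydrogens are
  identified by covalent proximity (≤ 1.25 Å, same residue) in the
  topology frame.
* **Rod shape**: monomer centroids form a polyline; reported are the
  end-to-end/contour ratio (1 for a straight rod) and the number of sign
  changes of the discrete curvature (binormal component against the
  dominant bending-plane normal) — 0 for an arc, exactly 1 for an
  S-shape. Segment pairs whose turn is below sin θ = 1e-6 count as
  straight, so a numerically straight rod reports zero sign changes.

## Binding modes

Per-partner energies are summarised by a Gaussian fit (sample mean,
n−1 standard deviation) and classified by the mean: strong at
E ≤ −700 kcal/mol, weak at E ≥ −200 kcal/mol, intermediate between, with
boundaries inclusive toward the extremes as printed. The quoted
±100 kcal/mol is reported and drives a `borderline` flag but does not
blur the hard assignment — every partner gets a unique mode, matching how
the three-mode split is presented. The printed interval notation for the
intermediate band orders the bounds by magnitude; it is read as
−700 < E < −200 on the energy axis.

## Synthetic fixtures: what they emulate and what they do not

The generators in `iscarod.synthetic` define the study conditions; their
defaults are fixed, not tuning knobs.

* **Unit cell / rod**: 3 monomers per cell, expanded 2×2×2 into a
  24-monomer rod with a complete SG quartet between every adjacent pair
  (23 sites). Monomers are coarse *annular* pseudo-proteins — a
  20-residue backbone ring ~5 Å thick at ~12 Å radius, cysteines 114/116
  reaching toward the axis, an arginine-like donor at residue 110.
  The thin-ring design is deliberate: under translation-only expansion,
  adjacent-monomer SG quartets within a 6 Å cutoff require monomers
  thinner along the rod axis than any helix bundle can be, and the ring
  achieves the required counts exactly. The lattice vectors are
  deliberately collinear (12d/6d/3d along the axis, d = 5 Å) so the eight
  lattice images interleave into one contiguous rod.
* **Docked complex**: 10 partners docked at anchors spaced evenly along
  the rod with a 144° azimuthal twist (no two partners can clash).
  Partners are ~42-residue two-helix pseudo-proteins. FAD- and
  TRP_C-tagged pseudo-cofactor arms are planted at edge-to-edge distances
  drawn uniformly from **[30, 50] Å** to the nearest cluster — achieved
  *exactly* by a bisection along the arm direction, so measured distances
  equal the drawn ones to 1e-6 Å. A donor–acceptor hydrogen bond
  (D539 on the partner to R110 on the nearest monomer) is planted for
  every partner except Cry6, mirroring the one weak binder that lacks the
  recurring interface bond.
* **Bending trajectory**: a transverse sinusoidal displacement field (one
  full period along the rod → S-shape) ramping linearly from 0 to the
  bend amplitude (default **14 Å**, which puts the RMSD excursion on the
  ~10 Å scale of the observed rod flexing) plus i.i.d. Gaussian
  coordinate noise (default sd **0.5 Å**); times span 0–150 ns over
  `n_frames` (default 50).
* **Complex trajectory**: per-frame random global rigid motions. These
  preserve every planted distance exactly while exercising the analyses'
  rigid-motion invariance; genuinely thermal motion would smear the
  planted distances out of their verified interval.
* **Energy samples**: Gaussian modes (−800, −450, −150 kcal/mol, σ = 100)
  with the 1/6/3 partner layout (strong = Cry1, weak = Cry4–6, mirroring
  the observed arrangement along the rod).

Randomness is partitioned per generator via
`SeedSequence(seed, spawn_key=(stream,))`, so adding a generator never
perturbs existing fixtures and every fixture is bit-reproducible.

What passing tests on these fixtures show: that the *algorithms* —
assembly counts, site detection, docking acceptance, energy kernels,
distance/contact/H-bond/shape analyses, classification — are correct
against independent oracles and planted ground truth. What they do not
show: anything about real ISCA1 or cryptochrome structures, force-field
accuracy, solvent effects, or the actual MD observables of the
multi-million-atom system, which are outside desk scale by design.

## Bundled parameters

Two partial-charge sets for the Fe₂S₂/cysteine moiety are bundled (a
literature set and an ESP-fitted set; cysteine hydrogens +0.09 e in
both). The Lennard-Jones entries for cluster iron/sulfur are synthetic
stand-ins of plausible magnitude — published cluster LJ parameter sets
are not redistributable here — and are labelled as such; fixture
energetics need only be well-behaved, not calibrated. The toy backbone
torsion (k = 0.6 kcal/mol, n = 3, δ = 0 over consecutive CA quadruples)
exists to exercise the dihedral-energy pathway on coarse fixtures.

## Pipeline problem sizes

The default pipeline run operates on the 24-monomer rod (~2,000 atoms),
10 partners (~50 atoms each plus planted arms) and 50-frame trajectories;
a full run completes in well under a minute. Stages hand over through
files, so any stage can be disabled and rerun against prior outputs; the
manifest records the complete effective configuration and a SHA-256 per
output, and two runs with the same configuration and seed are
bit-identical apart from the manifest timestamp.

## Known limitations

* No mmCIF/PSF/DCD support; PDB fixed-column format only, so structures
  with more than 62 chains cannot be written (internally they are fine).
* The selection grammar is deliberately small (chain / resid / resname /
  name / moiety / heavy with boolean combinations).
* Hydrogen-bond detection infers donor hydrogens from geometry, not from
  an explicit bond table.
* The docking-site layout on the rod reproduces the partner *count*; how
  the original ten sites were enumerated on the real rod is not
  specified anywhere, so the fixture geometry is the package's own.
* Whether cluster placement in the original model was energy-minimised
  before simulation is unknown; placed clusters here are purely
  geometric.
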
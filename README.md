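# iscarod

Reconstruction and trajectory analysis of a rod-shaped iron–sulfur
(ISCA1-like) protein polymer complexed with cryptochrome-like partner
proteins.

## The scientific problem

A proposed model of animal magnetoreception places the photoreceptor
cryptochrome — host of the FAD/tryptophan radical pair — on the surface of
an elongated polymer of ISCA1 monomers cross-linked by Fe₂S₂ clusters.
Whether that assembly could work as a "biocompass needle" hinges on
questions a structural pipeline can quantify:

* Can the rod be rebuilt from crystal packing, and is its geometry stable
  (RMSD, dihedral energy, large-scale bending modes)?
* Are the electron-transfer distances between each cryptochrome's FAD /
  terminal tryptophan W_C and the nearest Fe₂S₂ cluster short enough for
  Marcus-theory electron transfer, where the squared electronic coupling
  decays as |H_DA|² ∝ V₀²·exp(−βR) with R the edge-to-edge distance?
* How strongly does each partner bind, as classified from its
  interaction-energy distribution E (strong: E ≤ −700 kcal/mol, weak:
  E ≥ −200 kcal/mol, intermediate between), and which hydrogen bonds and
  residue contacts carry the interface?

The package implements the full computational pathway — rod assembly from
a unit cell (supercell expansion, monomer superpose–replace, four-cysteine
Fe₂S₂ site detection and cluster placement, paired-helix docking with
clash rejection), CHARMM-style proper-dihedral energies
U = Σᵢ kᵢ[1 + cos(nᵢθᵢ − δᵢ)], group–group nonbonded energies (Coulomb +
12-6 Lennard-Jones, 12 Å cutoff with switching), aligned RMSD, contact
maps, hydrogen bonds, rod-shape profiling and binding-mode classification
— and exercises it end to end on synthetic fixtures with planted,
exactly-known answers. Real MD trajectories of the ~2-million-atom system
are out of desk-scale reach; the fixtures stand in for them with
controlled geometry (see `docs/methods.md`).

It is aimed at structural-bioinformatics practitioners who want a tested,
engine-free reference implementation of these analyses.

## Worked example

```python
from iscarod import (
    FixtureSpec, make_docked_complex_fixture, make_complex_trajectory,
    nearest_cluster_series, MarcusModel, marcus_coupling,
    sample_interaction_energies, classify_all, InteractionEnergySeries,
)
from iscarod.modes import mode_counts

spec = FixtureSpec(seed=1)
fixture = make_docked_complex_fixture(spec)          # rod + clusters + partners
traj = make_complex_trajectory(fixture.structure, n_frames=5, seed=spec.seed)
series = nearest_cluster_series(traj, fixture.cofactor_sets(),
                                fixture.cluster_sets())
for s in series[:4]:
    rel = marcus_coupling(MarcusModel(beta=1.4, r=s.mean))
    print(f"{s.partner_id} {s.kind}: {s.mean:5.1f} +/- {s.std:.1f} A  "
          f"relative coupling {rel:.1e}")

energies = sample_interaction_energies(FixtureSpec(seed=1, n_frames=1000))
reports = classify_all([InteractionEnergySeries(partner_id=p, per_frame_energy=e)
                        for p, e in energies.items()])
print("mode counts:", mode_counts(reports))
```

prints

```
Cry0 d_FAD:  39.5 +/- 0.0 A  relative coupling 9.4e-25
Cry0 d_Trp:  42.0 +/- 0.0 A  relative coupling 2.9e-26
Cry1 d_FAD:  34.9 +/- 0.0 A  relative coupling 6.0e-22
Cry1 d_Trp:  34.5 +/- 0.0 A  relative coupling 1.0e-21
mode counts: {'strong': 1, 'intermediate': 6, 'weak': 3}
```

Every cofactor–cluster distance sits in the 30–50 Å band planted by the
fixture generator — distances at which the relative Marcus coupling
(β = 1.4 Å⁻¹) is ~10⁻²¹–10⁻²⁶ of its contact value, i.e. electron transfer
is effectively switched off — and the planted one-strong /
six-intermediate / three-weak binding cohort is recovered exactly.

The same pathway is available from the shell:

```sh
iscarod run --seed 1 --outdir scratch/demo        # all stages
iscarod build --reps 2,2,2 --outdir scratch/demo  # one stage, prior outputs reused
```

Each run writes TSV/PDB outputs per stage plus `manifest.json` recording
the complete effective configuration and SHA-256 of every output.

## Layout

| module | contents |
| --- | --- |
| `iscarod.structure` | atom/structure/trajectory model, PDB I/O, selection grammar, charge assignment |
| `iscarod.forcefield` | parameter-file dialect, bundled Fe₂S₂/cysteine charge sets, stand-in LJ parameters |
| `iscarod.builder` | supercell expansion, rod extraction, superpose–replace, Fe₂S₂ sites, docking |
| `iscarod.energetics` | dihedral and nonbonded interaction energies |
| `iscarod.analysis` | Kabsch/RMSD, edge-to-edge distances, Marcus coupling, contacts, H-bonds, rod shape |
| `iscarod.modes` | binding-mode classification |
| `iscarod.synthetic` | fixture generators (the study conditions) |
| `iscarod.pipeline`, `iscarod.cli` | orchestration, manifest, `iscarod` command |
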
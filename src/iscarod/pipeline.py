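"""Reproducible build -> energy -> analyze -> classify pipeline.

Stages hand data over through files in the output directory, so any stage
can be toggled off and rerun later against prior outputs. A manifest
(``manifest.json``) records the complete effective configuration, the
seed, and every output file with its SHA-256 hash; two runs with the same
configuration and seed produce bit-identical outputs (the manifest differs
only in its timestamp).

Defaults follow the reference analysis conditions: 12 A nonbonded cutoff
with switching from 10 A, 3 A contact cutoff evaluated over the last 6 ns,
3.5 A / 150 degree hydrogen-bond criteria, and binding-mode thresholds at
-700 / -200 kcal/mol (tolerance +-100).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, builder, energetics, forcefield, modes, synthetic
from .errors import ConfigurationError
from .structure import Structure, Trajectory, read_pdb, select, write_pdb

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("iscarod.pipeline")


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run.

    Every value with a printed reference default keeps it: nonbonded
    cutoff 12 A (switching on from 10 A), contact cutoff 3 A over the last
    6 ns, binding-mode thresholds -700/-200 kcal/mol.
    """

    seed: int = 0
    outdir: str = "scratch/pipeline-run"
    # stage toggles
    simulate: bool = True
    build: bool = True
    energy: bool = True
    analyze: bool = True
    classify: bool = True
    # fixture conditions
    n_monomers_per_cell: int = 3
    reps: tuple[int, int, int] = (2, 2, 2)
    monomer_size: int = 20
    docking_sites: int = 10
    planted_distance_range: tuple[float, float] = (30.0, 50.0)
    bend_amplitude: float = 14.0
    noise_sigma: float = 0.5
    n_frames: int = 50
    energy_modes: tuple[tuple[float, float, int], ...] = synthetic.DEFAULT_ENERGY_MODES
    # geometry parameters
    adjacency_cutoff: float = 6.0
    site_cutoff: float = 6.0
    clash_threshold: float = 2.0
    # nonbonded parameters
    nonbonded_cutoff: float = 12.0
    switch_on: float = 10.0
    # analysis parameters
    contact_cutoff: float = 3.0
    contact_window_ns: float = 6.0
    hbond_dist_cutoff: float = 3.5
    hbond_angle_cutoff: float = 150.0
    marcus_beta: float = 1.4
    # classification thresholds
    strong_max: float = -700.0
    weak_min: float = -200.0
    tolerance: float = 100.0
    charge_set: str = "esp"

    def fixture_spec(self) -> synthetic.FixtureSpec:
        return synthetic.FixtureSpec(
            seed=self.seed,
            n_monomers_per_cell=self.n_monomers_per_cell,
            reps=tuple(self.reps),
            monomer_size=self.monomer_size,
            docking_sites=self.docking_sites,
            planted_distance_range=tuple(self.planted_distance_range),
            bend_amplitude=self.bend_amplitude,
            noise_sigma=self.noise_sigma,
            n_frames=self.n_frames,
            energy_modes=tuple(tuple(m) for m in self.energy_modes),
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["reps"] = list(self.reps)
        out["planted_distance_range"] = list(self.planted_distance_range)
        out["energy_modes"] = [list(m) for m in self.energy_modes]
        return out

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        """Load a YAML config; explicit ``overrides`` take precedence."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_charge_set(name: str):
    if name == "esp":
        return forcefield.esp_charges()
    if name == "mouesca":
        return forcefield.mouesca_charges()
    raise ConfigurationError(f"unknown charge set {name!r}")


def _toy_parameters() -> forcefield.ForceFieldParameters:
    with resources.as_file(
        resources.files("iscarod.data") / "toy_backbone.prm"
    ) as prm:
        return forcefield.load_parameters(prm)


def _backbone_dihedral_terms(structure: Structure, ff) -> list[energetics.DihedralTerm]:
    """Torsion terms over consecutive CA quadruples of every chain."""
    params = ff.dihedral_terms_for(("CA", "CA", "CA", "CA"))
    terms: list[energetics.DihedralTerm] = []
    ca = select(structure, "name CA")
    by_chain: dict[str, list[int]] = {}
    for i in ca:
        by_chain.setdefault(structure.atoms[i].chain_id, []).append(int(i))
    for chain_atoms in by_chain.values():
        for k in range(len(chain_atoms) - 3):
            quad = tuple(chain_atoms[k : k + 4])
            for p in params:
                terms.append(
                    energetics.DihedralTerm(atoms=quad, k=p.k, n=p.n, delta=p.delta)
                )
    return terms


def _complex_groups(complex_structure: Structure):
    """Partner / cluster / polymer chain partition, from moiety tags."""
    partner_chains: list[str] = []
    cluster_chain = None
    for chain in complex_structure.chains:
        tags = {
            complex_structure.atoms[i].moiety_tag
            for i in complex_structure.chain_atom_indices(chain)
        }
        if "FAD" in tags:
            partner_chains.append(chain)
        elif "FE2S2" in tags:
            cluster_chain = chain
    polymer_chains = [
        c for c in complex_structure.chains
        if c not in partner_chains and c != cluster_chain
    ]
    return partner_chains, cluster_chain, polymer_chains


def _prepare_energetic_structure(structure: Structure, config: PipelineConfig) -> Structure:
    charged = forcefield.assign_default_charges(structure)
    charged = forcefield.assign_lj_parameters(charged)
    charge_set = _load_charge_set(config.charge_set)
    role_map: dict[int, str] = {}
    for i, atom in enumerate(charged.atoms):
        if atom.moiety_tag == "FE2S2":
            role_map[i] = "Fe" if atom.element.upper() == "FE" else "S*"
        elif atom.res_name == "CYS" and atom.name == "SG":
            role_map[i] = "S"
    from .structure import assign_charges

    return assign_charges(charged, charge_set, role_map)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, outdir: Path, outputs: list[Path]) -> None:
    spec = config.fixture_spec()
    fixtures = outdir / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    asym, operators, cell = synthetic.make_unit_cell_fixture(spec)
    write_pdb(asym, fixtures / "unit_cell.pdb")
    builder.write_operator_file(operators, cell, fixtures / "operators.txt")
    fixture = synthetic.make_docked_complex_fixture(spec)
    write_pdb(fixture.structure, fixtures / "docked_complex.pdb")
    rod = builder.extract_rod(
        builder.expand_supercell(asym, operators, spec.reps, cell),
        adjacency_cutoff=config.adjacency_cutoff,
    )
    bending = synthetic.make_bending_trajectory(rod, spec)
    write_pdb(bending, fixtures / "bending.pdb")
    complex_traj = synthetic.make_complex_trajectory(
        fixture.structure, n_frames=spec.n_frames, seed=spec.seed
    )
    write_pdb(complex_traj, fixtures / "complex_traj.pdb")
    energies = synthetic.sample_interaction_energies(spec)
    rows = [
        {"partner": pid, "sample": k, "energy_kcal_mol": e}
        for pid in sorted(energies)
        for k, e in enumerate(energies[pid])
    ]
    pd.DataFrame(rows).to_csv(fixtures / "energies.tsv", sep="\t", index=False)
    planted_rows = [
        {"partner": pid, "kind": kind, "planted_distance_A": d}
        for pid, kinds in sorted(fixture.planted.items())
        for kind, d in sorted(kinds.items())
    ]
    pd.DataFrame(planted_rows).to_csv(fixtures / "planted_distances.tsv", sep="\t", index=False)
    outputs.extend(sorted(fixtures.iterdir()))
    logger.info("simulate: wrote fixtures for %d partners", len(fixture.partner_chains))


def _stage_build(config: PipelineConfig, outdir: Path, outputs: list[Path]) -> None:
    spec = config.fixture_spec()
    fixtures = outdir / "fixtures"
    build_dir = outdir / "build"
    build_dir.mkdir(parents=True, exist_ok=True)
    asym = read_pdb(fixtures / "unit_cell.pdb")
    operators, cell = builder.read_operator_file(fixtures / "operators.txt")
    supercell = builder.expand_supercell(asym, operators, spec.reps, cell)
    rod = builder.extract_rod(supercell, adjacency_cutoff=config.adjacency_cutoff)
    sites = builder.detect_cluster_sites(rod, site_cutoff=config.site_cutoff)
    complexed = builder.place_clusters(rod, sites, synthetic.make_cluster_template())
    template = dataclasses.replace(
        synthetic.build_docking_template(rod, spec),
        clash_threshold=config.clash_threshold,
    )
    partner = synthetic.make_partner_template()
    docked, reports = builder.dock_partner(complexed, partner, template)
    write_pdb(rod, build_dir / "rod.pdb")
    write_pdb(docked, build_dir / "complex.pdb")
    pd.DataFrame(
        [
            {
                "site": r.site_index,
                "accepted": r.accepted,
                "reason": r.reason,
                "chains": ",".join(r.chain_ids),
                "fit_rmsd_A": r.fit_rmsd,
            }
            for r in reports
        ]
    ).to_csv(build_dir / "docking_report.tsv", sep="\t", index=False)
    logger.info(
        "build: rod of %d monomers, %d sites, %d/%d partners docked",
        len(rod.chains), len(sites), sum(r.accepted for r in reports), len(reports),
    )
    outputs.extend(sorted(build_dir.iterdir()))


def _stage_energy(config: PipelineConfig, outdir: Path, outputs: list[Path]) -> None:
    energy_dir = outdir / "energy"
    energy_dir.mkdir(parents=True, exist_ok=True)
    traj = read_pdb(outdir / "fixtures" / "complex_traj.pdb")
    charged = _prepare_energetic_structure(traj.topology, config)
    traj = Trajectory(charged, traj.frames, frame_times=traj.frame_times)
    partner_chains, cluster_chain, polymer_chains = _complex_groups(charged)
    polymer_group = np.concatenate(
        [charged.chain_atom_indices(c) for c in polymer_chains + [cluster_chain]]
    )
    partner_groups = {
        f"Cry{k}": charged.chain_atom_indices(c)
        for k, c in enumerate(partner_chains)
    }
    nb = energetics.NonbondedConfig(
        cutoff=config.nonbonded_cutoff, switch_on=config.switch_on
    )
    rows = []
    for partner_id in sorted(partner_groups):
        group = partner_groups[partner_id]
        for m in range(traj.n_frames):
            e_elec, e_vdw, e_total = energetics.pair_interaction_energy(
                charged, group, polymer_group, config=nb, frame=traj.frames[m]
            )
            rows.append(
                {
                    "frame": m,
                    "time_ns": traj.frame_times[m],
                    "partner": partner_id,
                    "E_elec": e_elec,
                    "E_vdw": e_vdw,
                    "E_total": e_total,
                }
            )
    pd.DataFrame(rows).to_csv(energy_dir / "interaction_energies.tsv", sep="\t", index=False)
    logger.info("energy: %d partner-frame energies", len(rows))
    outputs.extend(sorted(energy_dir.iterdir()))


def _stage_analyze(config: PipelineConfig, outdir: Path, outputs: list[Path]) -> None:
    analysis_dir = outdir / "analysis"
    analysis_dir.mkdir(parents=True, exist_ok=True)
    bending = read_pdb(outdir / "fixtures" / "bending.pdb")

    ca = select(bending.topology, "name CA")
    rmsd = analysis.rmsd_series(bending, fit_subset=ca, measure_subset=ca)
    pd.DataFrame(
        {"frame": np.arange(bending.n_frames), "time_ns": bending.frame_times,
         "rmsd_A": rmsd}
    ).to_csv(analysis_dir / "rmsd.tsv", sep="\t", index=False)

    ff = _toy_parameters()
    terms = _backbone_dihedral_terms(bending.topology, ff)
    dihedral = [
        energetics.dihedral_energy(bending.frames[m], terms)
        for m in range(bending.n_frames)
    ]
    pd.DataFrame(
        {"frame": np.arange(bending.n_frames), "time_ns": bending.frame_times,
         "U_dihedral_kcal_mol": dihedral}
    ).to_csv(analysis_dir / "dihedral_energy.tsv", sep="\t", index=False)

    partition = [
        bending.topology.chain_atom_indices(c) for c in bending.topology.chains
    ]
    shapes = analysis.rod_shape_profile(bending, partition)
    pd.DataFrame(
        {
            "frame": np.arange(bending.n_frames),
            "time_ns": bending.frame_times,
            "end_to_end_over_contour": [s.ratio for s in shapes],
            "curvature_sign_changes": [s.sign_changes for s in shapes],
        }
    ).to_csv(analysis_dir / "rod_shape.tsv", sep="\t", index=False)

    traj = read_pdb(outdir / "fixtures" / "complex_traj.pdb")
    topo = traj.topology
    partner_chains, cluster_chain, polymer_chains = _complex_groups(topo)
    cluster_sets = []
    by_site: dict[int, list[int]] = {}
    for i in topo.chain_atom_indices(cluster_chain):
        by_site.setdefault(topo.atoms[i].res_id, []).append(int(i))
    cluster_sets = [np.array(v, dtype=int) for _, v in sorted(by_site.items())]
    cofactors = {
        f"Cry{k}": {
            "d_FAD": select(topo, f"chain {chain} and moiety FAD"),
            "d_Trp": select(topo, f"chain {chain} and moiety TRP_C"),
        }
        for k, chain in enumerate(partner_chains)
    }
    series = analysis.nearest_cluster_series(traj, cofactors, cluster_sets)
    frame_rows = []
    summary_rows = []
    for s in series:
        for m, d in enumerate(s.per_frame):
            frame_rows.append(
                {"partner": s.partner_id, "kind": s.kind, "frame": m,
                 "time_ns": traj.frame_times[m], "distance_A": d}
            )
        coupling = analysis.marcus_coupling(
            analysis.MarcusModel(beta=config.marcus_beta, r=s.mean)
        )
        summary_rows.append(
            {"partner": s.partner_id, "kind": s.kind, "mean_A": s.mean,
             "std_A": s.std, "relative_coupling": coupling}
        )
    pd.DataFrame(frame_rows).to_csv(analysis_dir / "distance_series.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(analysis_dir / "distances.tsv", sep="\t", index=False)

    window = (
        float(traj.frame_times[-1]) - config.contact_window_ns,
        float(traj.frame_times[-1]),
    )
    polymer_group = np.concatenate(
        [topo.chain_atom_indices(c) for c in polymer_chains]
    )
    for k, chain in enumerate(partner_chains):
        cmap = analysis.contact_map(
            traj, topo.chain_atom_indices(chain), polymer_group,
            cutoff=config.contact_cutoff, window=window, partner_id=f"Cry{k}",
        )
        rows_idx = cmap.rows
        cols_idx = cmap.cols
        matrix = pd.DataFrame(0.0, index=rows_idx, columns=cols_idx)
        for (ri, ci), occ in cmap.occupancy.items():
            matrix.loc[ri, ci] = occ
        matrix.index.name = "partner_resid"
        matrix.to_csv(analysis_dir / f"contacts_Cry{k}.tsv", sep="\t")

    donors = select(topo, f"resid {synthetic.DONOR_RESID} and name NH1")
    acceptors = select(topo, "name OD1")
    labels = {c: "ISCA1" for c in polymer_chains}
    labels.update({c: f"Cry{k}" for k, c in enumerate(partner_chains)})
    records = (
        analysis.hydrogen_bonds(
            traj, donors, acceptors,
            dist_cutoff=config.hbond_dist_cutoff,
            angle_cutoff=config.hbond_angle_cutoff,
            group_labels=labels,
        )
        if donors.size and acceptors.size
        else []
    )
    pd.DataFrame(
        [
            {"label": r.label, "occupancy": r.occupancy, "donor": r.donor,
             "hydrogen": r.hydrogen, "acceptor": r.acceptor}
            for r in records
        ],
        columns=["label", "occupancy", "donor", "hydrogen", "acceptor"],
    ).to_csv(analysis_dir / "hydrogen_bonds.tsv", sep="\t", index=False)
    logger.info("analyze: %d distance series, %d hydrogen bonds", len(series), len(records))
    outputs.extend(sorted(analysis_dir.iterdir()))


def _stage_classify(config: PipelineConfig, outdir: Path, outputs: list[Path]) -> None:
    classify_dir = outdir / "classify"
    classify_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(outdir / "fixtures" / "energies.tsv", sep="\t")
    series = [
        energetics.InteractionEnergySeries(
            partner_id=pid, per_frame_energy=group["energy_kcal_mol"].to_numpy()
        )
        for pid, group in table.groupby("partner")
    ]
    thresholds = modes.BindingModeThresholds(
        strong_max=config.strong_max, weak_min=config.weak_min,
        tolerance=config.tolerance,
    )
    reports = modes.classify_all(series, thresholds)
    pd.DataFrame(
        [
            {"partner": r.partner_id, "mean_E": r.mean_E, "std_E": r.std_E,
             "mode": r.mode, "borderline": r.borderline}
            for r in reports
        ]
    ).to_csv(classify_dir / "binding_modes.tsv", sep="\t", index=False)
    counts = modes.mode_counts(reports)
    pd.DataFrame([counts]).to_csv(classify_dir / "mode_counts.tsv", sep="\t", index=False)
    logger.info("classify: modes %s", counts)
    outputs.extend(sorted(classify_dir.iterdir()))


_STAGES = (
    ("simulate", _stage_simulate),
    ("build", _stage_build),
    ("energy", _stage_energy),
    ("analyze", _stage_analyze),
    ("classify", _stage_classify),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and write the run manifest.

    Returns the manifest dictionary (also written to
    ``<outdir>/manifest.json``). Any stage failure propagates with the
    stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for stage_name, stage in _STAGES:
        if not getattr(config, stage_name):
            logger.info("stage %s disabled; skipping", stage_name)
            continue
        logger.info("stage %s starting", stage_name)
        try:
            stage(config, outdir, outputs)
        except Exception as exc:
            raise type(exc)(f"stage {stage_name!r} failed: {exc}") from exc
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in outputs
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
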
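"""Synthetic fixture generators for the full pipeline.

Every fixture the pipeline consumes is generated here, emulating the
study conditions of the reconstructed rod-polymer/partner system:

* a translation-only "unit cell" of 3 coarse monomers whose 2 x 2 x 2
  expansion tiles into one contiguous 24-monomer rod with a four-sulfur
  Fe2S2 coordination site between every adjacent monomer pair;
* a docked complex with 10 pseudo-partner proteins, each carrying
  FAD-tagged and TRP_C-tagged pseudo-cofactor groups planted at
  edge-to-edge distances to the nearest Fe2S2 cluster drawn uniformly
  from 30-50 A (achieved exactly, by construction);
* a bending trajectory that ramps a sinusoidal transverse displacement
  (one full period along the rod, i.e. an S-shape) onto the straight rod
  with optional thermal coordinate noise;
* Gaussian per-partner interaction-energy samples planted as one strong
  (-800 kcal/mol), six intermediate (-450) and three weak (-150) binders
  with sigma 100 kcal/mol, mirroring the observed binding-mode split.

Monomers are deliberately coarse *annular* pseudo-proteins (a 20-residue
backbone ring about 5 A thick, cysteine SG atoms reaching toward the rod
axis): a thin monomer is what lets pure lattice translations tile adjacent
monomers closely enough that every neighbouring pair presents a complete
SG quartet within the 6 A site cutoff. They are synthetic stand-ins, not
homology models; nothing about their internal geometry is physical.

Random streams are partitioned per generator via ``SeedSequence(seed,
spawn_key=(stream,))`` (streams: 1 docked complex, 2 bending trajectory,
3 energy samples, 4 rigid-motion trajectory), so adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .builder import (
    AxisAnchor,
    DockingTemplate,
    DockReport,
    detect_cluster_sites,
    dock_partner,
    expand_supercell,
    extract_rod,
    fit_helix_axis,
    place_clusters,
    SymmetryOperator,
)
from .errors import InputError
from .structure import AtomRecord, Structure, Trajectory, select

__all__ = [
    "FixtureSpec",
    "DockedComplexFixture",
    "MONOMER_SPACING",
    "RESID_START",
    "make_unit_cell_fixture",
    "make_cluster_template",
    "make_partner_template",
    "build_docking_template",
    "make_docked_complex_fixture",
    "make_bending_trajectory",
    "make_complex_trajectory",
    "sample_interaction_energies",
    "DEFAULT_ENERGY_MODES",
]

#: Axial spacing between adjacent monomers, A. Chosen below the 6 A site
#: cutoff so adjacent monomers' SG quartets are mutually in range.
MONOMER_SPACING = 5.0

#: First residue id of a monomer; covers the coordinating cysteines 114/116
#: and the arginine donor residue 110.
RESID_START = 105

#: Arginine-like donor residue planted in every monomer.
DONOR_RESID = 110

#: Radial distance of docking-site anchor axes from the rod axis, A.
DOCK_RADIUS = 23.0

#: Planted Gaussian interaction-energy modes: (mean, sigma, count) in
#: kcal/mol — one strong, six intermediate, three weak binders.
DEFAULT_ENERGY_MODES: tuple[tuple[float, float, int], ...] = (
    (-800.0, 100.0, 1),
    (-450.0, 100.0, 6),
    (-150.0, 100.0, 3),
)

#: Partner labels per mode for the canonical 1/6/3 cohort, mirroring the
#: observed layout: the strong binder is Cry1, the weak ones sit at the
#: rod centre (Cry4-6), the intermediates at the ends.
CANONICAL_MODE_LAYOUT = (
    ("Cry1",),
    ("Cry0", "Cry2", "Cry3", "Cry7", "Cry8", "Cry9"),
    ("Cry4", "Cry5", "Cry6"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study system.

    Distances in A, energies in kcal/mol. Defaults encode the reference
    conditions: a 3-monomer cell expanded 2x2x2 into a 24-monomer rod,
    10 docking sites, planted cofactor-cluster distances in [30, 50] A, a
    bending amplitude of 14 A (giving an RMSD excursion of order 10 A),
    0.5 A thermal coordinate noise and the 1/6/3 energy-mode cohort.
    """

    seed: int = 0
    n_monomers_per_cell: int = 3
    reps: tuple[int, int, int] = (2, 2, 2)
    monomer_size: int = 20
    docking_sites: int = 10
    planted_distance_range: tuple[float, float] = (30.0, 50.0)
    bend_amplitude: float = 14.0
    noise_sigma: float = 0.5
    n_frames: int = 50
    energy_modes: tuple[tuple[float, float, int], ...] = DEFAULT_ENERGY_MODES

    def __post_init__(self) -> None:
        if self.n_monomers_per_cell < 1 or self.monomer_size < 12:
            raise InputError("need >= 1 monomer of >= 12 residues per cell")
        if any(r < 1 for r in self.reps):
            raise InputError("reps must be positive")
        if self.docking_sites < 1 or self.n_frames < 1:
            raise InputError("counts must be positive")
        lo, hi = self.planted_distance_range
        if not lo <= hi or lo < 0:
            raise InputError("planted distance interval is empty or negative")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be nonnegative")
        for mean, sigma, count in self.energy_modes:
            if sigma < 0 or count < 1:
                raise InputError("energy modes need sigma >= 0 and count >= 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Unit-cell fixture
# ---------------------------------------------------------------------------

def _make_monomer(chain_id: str, center_z: float, n_res: int) -> list[AtomRecord]:
    """One coarse annular monomer centred on the rod axis at ``center_z``."""
    ring_radius = 3.8 / (2.0 * math.sin(math.pi / n_res))
    atoms: list[AtomRecord] = []
    serial = 0

    def add(name, element, res_name, res_id, pos):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(serial=serial, name=name, element=element, res_name=res_name,
                       res_id=res_id, chain_id=chain_id, position=np.asarray(pos))
        )

    z = np.array([0.0, 0.0, 1.0])
    for j in range(n_res):
        res_id = RESID_START + j
        phi = 2.0 * math.pi * j / n_res
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
        ca = ring_radius * radial + center_z * z
        if res_id in (114, 116):
            res_name = "CYS"
        elif res_id == DONOR_RESID:
            res_name = "ARG"
        else:
            res_name = "ALA"
        add("N", "N", res_name, res_id, ca - 1.2 * tangent + 0.4 * z)
        add("CA", "C", res_name, res_id, ca)
        add("C", "C", res_name, res_id, ca + 1.2 * tangent - 0.2 * z)
        add("O", "O", res_name, res_id, ca + 1.4 * tangent - 1.4 * z)
        if res_name == "ARG":
            add("NH1", "N", res_name, res_id, (ring_radius + 1.3) * radial + center_z * z)
            add("HH1", "H", res_name, res_id, (ring_radius + 2.3) * radial + center_z * z)
        if res_name == "CYS":
            # SG arms reach toward the rod axis; together with the next
            # monomer's arms they form the four-sulfur coordination quartet.
            x_side = 1.2 if res_id == 114 else -1.2
            add("SG", "S", res_name, res_id, np.array([x_side, 0.0, center_z + 2.0]))
    return atoms


def make_unit_cell_fixture(
    spec: FixtureSpec | None = None,
) -> tuple[Structure, list[SymmetryOperator], np.ndarray]:
    """Unit-cell fixture: asymmetric unit, symmetry operators, lattice.

    The asymmetric unit stacks ``n_monomers_per_cell`` monomers along z at
    :data:`MONOMER_SPACING`; the (deliberately collinear) lattice vectors
    are chosen so the ``reps`` lattice images interleave into one
    contiguous rod of ``n_monomers_per_cell * prod(reps)`` monomers.
    Deterministic — the geometry carries no randomness.
    """
    if spec is None:
        spec = FixtureSpec()
    atoms: list[AtomRecord] = []
    for m in range(spec.n_monomers_per_cell):
        chain_id = chr(ord("A") + m) if m < 26 else f"c{m}"
        atoms.extend(_make_monomer(chain_id, m * MONOMER_SPACING, spec.monomer_size))
    period = spec.n_monomers_per_cell * MONOMER_SPACING
    cell = np.array(
        [
            [0.0, 0.0, period * spec.reps[2] * spec.reps[1]],
            [0.0, 0.0, period * spec.reps[2]],
            [0.0, 0.0, period],
        ]
    )
    return Structure(atoms), [SymmetryOperator.identity()], cell


def make_cluster_template() -> Structure:
    """Idealised Fe2S2 rhombus: Fe-Fe 2.7 A, bridging S on the normal axis."""
    specs = [
        ("FE1", "FE", np.array([-1.35, 0.0, 0.0])),
        ("FE2", "FE", np.array([1.35, 0.0, 0.0])),
        ("S1", "S", np.array([0.0, -1.73, 0.0])),
        ("S2", "S", np.array([0.0, 1.73, 0.0])),
    ]
    atoms = [
        AtomRecord(serial=i + 1, name=name, element=element, res_name="FES",
                   res_id=1, chain_id="X", position=pos, moiety_tag="FE2S2")
        for i, (name, element, pos) in enumerate(specs)
    ]
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Partner template and docking geometry
# ---------------------------------------------------------------------------

PARTNER_HELIX_A = (501, 512)
PARTNER_HELIX_B = (521, 532)
PARTNER_ASP_RESID = 539


def make_partner_template() -> Structure:
    """Coarse pseudo-partner: two parallel 12-residue helices plus a body.

    Helix CA atoms spiral (100 degrees/residue, 1.5 A rise) about axes at
    local x = +-5; the body is an 18-residue ring between them. Residue
    539 is an aspartate-like acceptor residue (its OD1 acceptor atom is
    planted per docked copy). A synthetic stand-in, not a real partner.
    """
    atoms: list[AtomRecord] = []
    serial = 0

    def add(name, element, res_name, res_id, pos):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(serial=serial, name=name, element=element, res_name=res_name,
                       res_id=res_id, chain_id="p", position=np.asarray(pos))
        )

    for j in range(12):
        phase = math.radians(100.0 * j)
        add("CA", "C", "ALA", PARTNER_HELIX_A[0] + j,
            (5.0 + 2.3 * math.cos(phase), 2.3 * math.sin(phase), 1.5 * j))
        phase_b = math.radians(100.0 * j + 40.0)
        add("CA", "C", "ALA", PARTNER_HELIX_B[0] + j,
            (-5.0 + 2.3 * math.cos(phase_b), 2.3 * math.sin(phase_b), 1.5 * j))
    for j in range(18):
        res_id = 533 + j
        alpha = 2.0 * math.pi * j / 18.0
        res_name = "ASP" if res_id == PARTNER_ASP_RESID else "ALA"
        add("CA", "C", res_name, res_id,
            (3.5 * math.cos(alpha), 2.0, 8.0 + 3.5 * math.sin(alpha)))
    return Structure(atoms)


def build_docking_template(rod: Structure, spec: FixtureSpec) -> DockingTemplate:
    """Docking template with evenly spaced anchor sites along the rod.

    Sites advance along the rod axis with a 144-degree azimuthal twist so
    neighbouring partners cannot clash; both anchor axes run parallel to
    the rod at :data:`DOCK_RADIUS`.
    """
    partner = make_partner_template()
    ca_a = select(partner, f"resid {PARTNER_HELIX_A[0]}-{PARTNER_HELIX_A[1]} and name CA")
    _, _, helix_length = fit_helix_axis(partner.coords[ca_a])
    coords = rod.coords
    z_lo, z_hi = coords[:, 2].min(), coords[:, 2].max()
    span = z_hi - z_lo
    anchors = []
    for k in range(spec.docking_sites):
        z_k = z_lo + (k + 0.5) * span / spec.docking_sites
        theta = math.radians(144.0 * k)
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        center = DOCK_RADIUS * radial + np.array([0.0, 0.0, z_k])
        axis_z = np.array([0.0, 0.0, 1.0])
        half = (helix_length / 2.0) * axis_z
        anchors.append(
            (
                AxisAnchor(origin=center + 5.0 * tangent - half, direction=axis_z,
                           length=helix_length),
                AxisAnchor(origin=center - 5.0 * tangent - half, direction=axis_z,
                           length=helix_length),
            )
        )
    return DockingTemplate(
        helix_a=PARTNER_HELIX_A, helix_b=PARTNER_HELIX_B,
        site_anchors=tuple(anchors), clash_threshold=2.0,
    )


# ---------------------------------------------------------------------------
# Docked complex with planted moieties
# ---------------------------------------------------------------------------

@dataclass
class DockedComplexFixture:
    """Docked-complex fixture plus its construction bookkeeping."""

    structure: Structure
    partner_chains: dict[str, str]  # partner id -> chain id
    planted: dict[str, dict[str, float]]  # partner id -> {kind: distance A}
    cluster_chain: str
    reports: list[DockReport]

    def partner_ids(self) -> list[str]:
        return sorted(self.partner_chains)

    def moiety_indices(self, partner_id: str, tag: str) -> np.ndarray:
        chain = self.partner_chains[partner_id]
        return select(self.structure, f"chain {chain} and moiety {tag}")

    def partner_indices(self, partner_id: str) -> np.ndarray:
        return self.structure.chain_atom_indices(self.partner_chains[partner_id])

    def cluster_sets(self) -> list[np.ndarray]:
        """Atom-index sets of the placed Fe2S2 clusters, one per site."""
        indices = select(self.structure, f"chain {self.cluster_chain}")
        by_site: dict[int, list[int]] = {}
        for i in indices:
            by_site.setdefault(self.structure.atoms[i].res_id, []).append(int(i))
        return [np.array(by_site[r], dtype=int) for r in sorted(by_site)]

    def cofactor_sets(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            pid: {
                "d_FAD": self.moiety_indices(pid, "FAD"),
                "d_Trp": self.moiety_indices(pid, "TRP_C"),
            }
            for pid in self.partner_ids()
        }


def _solve_planted_tip(
    cluster_coords: np.ndarray, base: np.ndarray, direction: np.ndarray,
    distance: float,
) -> np.ndarray:
    """Point along ``base + t*direction`` whose minimum distance to the
    cluster atoms equals ``distance`` exactly (bisection; monotone for
    rays leaving the cluster region)."""

    def min_dist(t: float) -> float:
        p = base + t * direction
        return float(np.min(np.linalg.norm(cluster_coords - p, axis=1)))

    lo, hi = distance, distance + 80.0
    if min_dist(hi) < distance:
        raise InputError("planted distance unreachable along ray")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < distance:
            lo = mid
        else:
            hi = mid
    return base + hi * direction


def _rotate_about_z(v: np.ndarray, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def make_docked_complex_fixture(spec: FixtureSpec | None = None) -> DockedComplexFixture:
    """Build the full docked-complex fixture.

    Pipeline: unit cell -> supercell -> rod -> Fe2S2 site detection and
    placement -> paired-helix docking of ``docking_sites`` partners ->
    planted FAD/TRP_C pseudo-cofactor arms at exact distances drawn from
    ``planted_distance_range`` -> planted donor-acceptor hydrogen bond
    D539(partner)-R110(monomer) for every partner except Cry6 (mirroring
    the one weak binder that loses the recurring bond). Deterministic for
    a fixed seed.
    """
    if spec is None:
        spec = FixtureSpec()
    rng = _rng(spec.seed, stream=1)
    asym, operators, cell = make_unit_cell_fixture(spec)
    supercell = expand_supercell(asym, operators, spec.reps, cell)
    rod = extract_rod(supercell)
    sites = detect_cluster_sites(rod)
    complexed = place_clusters(rod, sites, make_cluster_template())
    cluster_chain = complexed.chains[-1]
    template = build_docking_template(rod, spec)
    partner = make_partner_template()
    docked, reports = dock_partner(complexed, partner, template)

    accepted = [r for r in reports if r.accepted]
    partner_chains = {f"Cry{k}": r.chain_ids[0] for k, r in enumerate(accepted)}

    cluster_indices = select(docked, f"chain {cluster_chain}")
    cluster_coords = docked.coords[cluster_indices]
    tree = cKDTree(docked.coords)

    by_chain: dict[str, list[AtomRecord]] = {c: [] for c in docked.chains}
    for atom in docked.atoms:
        by_chain[atom.chain_id].append(atom)

    planted: dict[str, dict[str, float]] = {}
    extra_points: list[np.ndarray] = []

    arm_specs = {
        "d_FAD": ("FAD", "FAD", 601, ("FD1", "FD2", "FD3"), ("C", "N", "C"), 0.0),
        "d_Trp": ("TRP_C", "TRC", 602, ("TP1", "TP2", "TP3"), ("C", "C", "N"), 25.0),
    }

    lo, hi = spec.planted_distance_range
    donor_sel = select(docked, f"resid {DONOR_RESID} and name NH1")
    donor_h_sel = select(docked, f"resid {DONOR_RESID} and name HH1")
    rod_chain_of = {docked.atoms[i].chain_id: (i, h) for i, h in zip(donor_sel, donor_h_sel)}
    rod_chain_z = {
        c: docked.coords[docked.chain_atom_indices(c)].mean(axis=0)[2]
        for c in rod.chains
    }

    for pid in sorted(partner_chains):
        chain = partner_chains[pid]
        body = np.array([a.position for a in by_chain[chain]])
        center = body.mean(axis=0)
        radial = center.copy()
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)
        planted[pid] = {}
        for kind, (tag, res_name, res_id, names, elements, twist) in arm_specs.items():
            distance = float(rng.uniform(lo, hi))
            nearest = int(np.argmin(np.linalg.norm(cluster_coords - center, axis=1)))
            base = cluster_coords[nearest]
            aim = center + 10.0 * radial - base
            direction = _rotate_about_z(aim / np.linalg.norm(aim), twist)
            placed = None
            for attempt in range(12):
                cand_dir = _rotate_about_z(direction, 10.0 * attempt)
                tip = _solve_planted_tip(cluster_coords, base, cand_dir, distance)
                pts = [tip + k * 1.4 * cand_dir for k in range(3)]
                clearances = [tree.query(p)[0] for p in pts]
                near_extra = (
                    min(
                        (np.linalg.norm(q - p) for q in extra_points for p in pts),
                        default=np.inf,
                    )
                )
                if min(clearances) >= 1.5 and near_extra >= 1.5:
                    placed = pts
                    break
            if placed is None:  # pragma: no cover - geometry guard
                raise InputError(f"could not place {tag} arm for {pid}")
            extra_points.extend(placed)
            for name, element, pos in zip(names, elements, placed):
                by_chain[chain].append(
                    AtomRecord(serial=0, name=name, element=element, res_name=res_name,
                               res_id=res_id, chain_id=chain, position=pos,
                               moiety_tag=tag)
                )
            planted[pid][kind] = distance

        if pid != "Cry6":
            # Planted recurring hydrogen bond D539(partner)-R110(monomer).
            z_c = center[2]
            nearest_monomer = min(rod_chain_z, key=lambda c: abs(rod_chain_z[c] - z_c))
            n_idx, h_idx = rod_chain_of[nearest_monomer]
            n_pos = docked.coords[n_idx]
            h_pos = docked.coords[h_idx]
            u = (h_pos - n_pos) / np.linalg.norm(h_pos - n_pos)
            by_chain[chain].append(
                AtomRecord(serial=0, name="OD1", element="O", res_name="ASP",
                           res_id=PARTNER_ASP_RESID, chain_id=chain,
                           position=n_pos + 2.9 * u)
            )

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in docked.chains:
        for atom in by_chain[chain]:
            serial += 1
            atom.serial = serial
            atoms.append(atom)
    return DockedComplexFixture(
        structure=Structure(atoms),
        partner_chains=partner_chains,
        planted=planted,
        cluster_chain=cluster_chain,
        reports=reports,
    )


# ---------------------------------------------------------------------------
# Trajectories and energy samples
# ---------------------------------------------------------------------------

def make_bending_trajectory(
    polymer: Structure, spec: FixtureSpec | None = None
) -> Trajectory:
    """Bending-mode trajectory: straight rod ramping into an S-shape.

    Frames interpolate a transverse sinusoidal displacement field (one
    full period along the rod axis) from zero to ``bend_amplitude``, plus
    i.i.d. Gaussian coordinate noise of sd ``noise_sigma``. Times span
    0-150 ns. Bit-reproducible for a fixed seed.
    """
    if spec is None:
        spec = FixtureSpec()
    rng = _rng(spec.seed, stream=2)
    coords0 = polymer.coords
    centered = coords0 - coords0.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    s = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    transverse = helper - np.dot(helper, axis) * axis
    transverse /= np.linalg.norm(transverse)
    mode = np.sin(2.0 * math.pi * s)[:, None] * transverse
    n = spec.n_frames
    frames = np.empty((n, coords0.shape[0], 3))
    for m in range(n):
        ramp = m / (n - 1) if n > 1 else 1.0
        frames[m] = coords0 + spec.bend_amplitude * ramp * mode
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    times = np.linspace(0.0, 150.0, n)
    return Trajectory(polymer.copy(), frames, frame_times=times)


def make_complex_trajectory(
    structure: Structure,
    n_frames: int = 5,
    seed: int = 0,
    rotation_scale: float = 0.15,
    translation_scale: float = 2.0,
) -> Trajectory:
    """Rigid-motion trajectory of a structure (frame 0 is the original).

    Each later frame applies a random global rotation (rotation-vector sd
    ``rotation_scale`` rad) and translation (sd ``translation_scale`` A):
    internal geometry — planted distances included — is preserved exactly,
    so the frames exercise rigid-motion invariance of the analyses.
    """
    from scipy.spatial.transform import Rotation

    rng = _rng(seed, stream=4)
    coords0 = structure.coords
    center = coords0.mean(axis=0)
    frames = np.empty((n_frames, coords0.shape[0], 3))
    frames[0] = coords0
    for m in range(1, n_frames):
        rotation = Rotation.from_rotvec(rng.normal(0.0, rotation_scale, 3)).as_matrix()
        shift = rng.normal(0.0, translation_scale, 3)
        frames[m] = (coords0 - center) @ rotation.T + center + shift
    times = np.linspace(0.0, 150.0, n_frames)
    return Trajectory(structure.copy(), frames, frame_times=times)


def sample_interaction_energies(
    spec: FixtureSpec | None = None,
) -> dict[str, np.ndarray]:
    """Planted per-partner Gaussian interaction-energy samples (kcal/mol).

    Partners are labelled Cry0..Cry{n-1}; for the canonical 1/6/3 cohort
    the strong binder is Cry1 and the weak ones Cry4-6 (the observed
    layout); otherwise modes are assigned sequentially. Each partner gets
    ``n_frames`` draws from its mode; fixed seed, reproducible.
    """
    if spec is None:
        spec = FixtureSpec()
    rng = _rng(spec.seed, stream=3)
    counts = tuple(c for _, _, c in spec.energy_modes)
    n_partners = sum(counts)
    if counts == tuple(len(g) for g in CANONICAL_MODE_LAYOUT) and n_partners == 10:
        assignment: dict[str, tuple[float, float]] = {}
        for (mean, sigma, _), group in zip(spec.energy_modes, CANONICAL_MODE_LAYOUT):
            for pid in group:
                assignment[pid] = (mean, sigma)
    else:
        assignment = {}
        k = 0
        for mean, sigma, count in spec.energy_modes:
            for _ in range(count):
                assignment[f"Cry{k}"] = (mean, sigma)
                k += 1
    return {
        pid: rng.normal(assignment[pid][0], assignment[pid][1], size=spec.n_frames)
        for pid in sorted(assignment)
    }
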
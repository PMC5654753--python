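"""Assembly of the rod polymer and the docked partner complex.

The rod is built the way extended assemblies are recovered from crystal
packing: the asymmetric unit is replicated by symmetry operators and
lattice translations into a supercell, the contiguous polymer is extracted
as the largest connected component of the monomer-contact graph (contacts
between the cysteine-114/116 SG atoms that coordinate the bridging Fe2S2
clusters), monomers can be swapped for a homology model by least-squares
superposition on shared atoms, Fe2S2 clusters are placed at each detected
four-sulfur coordination site, and partner proteins are docked by
superposing two of their alpha helices onto per-site helix-axis anchors
with steric clash rejection.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .analysis import kabsch_align
from .errors import (
    GeometryError,
    InputError,
    PlacementError,
    SiteDetectionError,
    TemplateError,
)
from .structure import AtomRecord, Structure, select

__all__ = [
    "SymmetryOperator",
    "ClusterSite",
    "AxisAnchor",
    "DockingTemplate",
    "DockReport",
    "chain_name_sequence",
    "expand_supercell",
    "extract_rod",
    "superpose_replace",
    "detect_cluster_sites",
    "place_clusters",
    "dock_partner",
]

#: Cysteine residues coordinating the Fe2S2 cross-links.
COORDINATING_CYSTEINES = (114, 116)


@dataclass(frozen=True)
class SymmetryOperator:
    """Rigid crystal-symmetry operator: proper rotation plus translation (A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise InputError("operator needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise InputError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise InputError("rotation matrix must be proper (det +1)")

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ClusterSite:
    """A Fe2S2 cross-link site: four cysteine SG atoms of two monomers."""

    monomer_pair: tuple[str, str]
    sg_atoms: tuple[int, int, int, int]
    centroid: np.ndarray


@dataclass(frozen=True)
class AxisAnchor:
    """Target helix axis at a docking site: origin, unit direction, length (A)."""

    origin: np.ndarray
    direction: np.ndarray
    length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(direction)
        if norm < 1e-10:
            raise InputError("anchor direction must be nonzero")
        object.__setattr__(self, "direction", direction / norm)
        if self.length <= 0:
            raise InputError("anchor length must be positive")


@dataclass(frozen=True)
class DockingTemplate:
    """Paired-helix docking recipe.

    ``helix_a``/``helix_b`` are non-overlapping residue-id ranges on the
    partner protein; ``site_anchors`` lists, per docking site, the two
    target axes the partner helices are superposed onto;
    ``clash_threshold`` is the heavy-atom rejection distance in A.
    """

    helix_a: tuple[int, int]
    helix_b: tuple[int, int]
    site_anchors: tuple[tuple[AxisAnchor, AxisAnchor], ...]
    clash_threshold: float = 2.0

    def __post_init__(self) -> None:
        a0, a1 = self.helix_a
        b0, b1 = self.helix_b
        if max(a0, b0) <= min(a1, b1):
            raise InputError("helix ranges must not overlap")


@dataclass
class DockReport:
    """Outcome of one docking-site attempt."""

    site_index: int
    accepted: bool
    reason: str
    chain_ids: tuple[str, ...] = ()
    fit_rmsd: float = float("nan")


# ---------------------------------------------------------------------------
# Chain naming
# ---------------------------------------------------------------------------

_SINGLE_CHARS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_name_sequence():
    """Deterministic chain-id stream: A-Z, a-z, 0-9, then two-char codes."""
    yield from _SINGLE_CHARS
    for first in _SINGLE_CHARS:
        for second in _SINGLE_CHARS:
            yield first + second


def _fresh_chain_ids(used: set[str], count: int) -> list[str]:
    out: list[str] = []
    warned = False
    for name in chain_name_sequence():
        if name in used:
            continue
        if len(name) > 1 and not warned:
            warnings.warn(
                "single-character chain namespace exhausted (>62 chains); "
                "falling back to two-character chain codes",
                stacklevel=3,
            )
            warned = True
        out.append(name)
        used.add(name)
        if len(out) == count:
            return out
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Supercell expansion and rod extraction
# ---------------------------------------------------------------------------

def expand_supercell(
    asym_unit: Structure,
    operators: Sequence[SymmetryOperator],
    reps: tuple[int, int, int],
    cell: np.ndarray,
) -> Structure:
    """Replicate the asymmetric unit over operators and lattice translations.

    ``cell`` holds the three lattice vectors as rows (A). Each of the
    ``len(operators) * n_a * n_b * n_c`` copies of each input chain gets a
    fresh deterministic chain identifier; copy coordinates are
    ``R @ x + t + i*a + j*b + k*c``. Per-copy atom count and intra-chain
    geometry are conserved exactly.
    """
    if not operators:
        raise InputError("at least one symmetry operator is required")
    if any(n < 1 for n in reps):
        raise InputError("supercell repetitions must be positive integers")
    cell = np.asarray(cell, dtype=float)
    if cell.shape != (3, 3):
        raise InputError("cell must be three lattice row-vectors")
    used: set[str] = set()
    n_copies = len(operators) * reps[0] * reps[1] * reps[2] * len(asym_unit.chains)
    names = iter(_fresh_chain_ids(used, n_copies))
    atoms: list[AtomRecord] = []
    serial = 0
    for op in operators:
        for i, j, k in product(range(reps[0]), range(reps[1]), range(reps[2])):
            shift = i * cell[0] + j * cell[1] + k * cell[2]
            for chain_id in asym_unit.chains:
                new_chain = next(names)
                for index in asym_unit.chain_atom_indices(chain_id):
                    atom = asym_unit.atoms[index].copy()
                    atom.position = op.rotation @ atom.position + op.translation + shift
                    atom.chain_id = new_chain
                    serial += 1
                    atom.serial = serial
                    atoms.append(atom)
    return Structure(atoms)


def _sg_indices_by_chain(structure: Structure) -> dict[str, np.ndarray]:
    resids = " ".join(str(r) for r in COORDINATING_CYSTEINES)
    sg = select(structure, f"resid {resids} and name SG")
    out: dict[str, np.ndarray] = {c: [] for c in structure.chains}
    for i in sg:
        out[structure.atoms[i].chain_id].append(i)
    return {c: np.asarray(v, dtype=int) for c, v in out.items()}


def _principal_order(centroids: np.ndarray) -> np.ndarray:
    centered = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # Fix the axis sign deterministically: first-to-last centroid direction.
    if centroids.shape[0] > 1 and np.dot(centroids[-1] - centroids[0], axis) < 0:
        axis = -axis
    return np.argsort(centered @ axis, kind="stable")


def extract_rod(supercell: Structure, adjacency_cutoff: float = 6.0) -> Structure:
    """Largest connected rod of monomers, ordered along its principal axis.

    Two monomers (chains) are adjacent when any of their cysteine-114/116
    SG atoms lie within ``adjacency_cutoff`` of each other. The largest
    connected component of that contact graph is returned with its chains
    reordered by centroid projection onto the component's principal axis.
    """
    chains = supercell.chains
    if not chains:
        raise InputError("supercell has no chains")
    sg_by_chain = _sg_indices_by_chain(supercell)
    if all(v.size == 0 for v in sg_by_chain.values()):
        raise SiteDetectionError(
            "no cysteine-114/116 SG atoms found; cannot build the contact graph"
        )
    coords = supercell.coords
    n = len(chains)
    rows, cols = [], []
    for i in range(n):
        sgi = sg_by_chain[chains[i]]
        if sgi.size == 0:
            continue
        for j in range(i + 1, n):
            sgj = sg_by_chain[chains[j]]
            if sgj.size == 0:
                continue
            if cdist(coords[sgi], coords[sgj]).min() <= adjacency_cutoff:
                rows.extend((i, j))
                cols.extend((j, i))
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = int(np.argmax(sizes))  # ties: lowest label = earliest chain
    members = [chains[i] for i in range(n) if labels[i] == best]
    centroids = np.array(
        [coords[supercell.chain_atom_indices(c)].mean(axis=0) for c in members]
    )
    order = _principal_order(centroids) if len(members) > 1 else np.array([0])
    atoms: list[AtomRecord] = []
    for rank in order:
        for index in supercell.chain_atom_indices(members[rank]):
            atoms.append(supercell.atoms[index].copy())
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Monomer replacement
# ---------------------------------------------------------------------------

def superpose_replace(
    template_monomer: Structure,
    model_monomer: Structure,
    shared_atoms: str = "name CA",
) -> Structure:
    """Rigidly place a model monomer into a template monomer's frame.

    ``shared_atoms`` is a selection expression evaluated on both monomers;
    atoms are paired by ``(res_id, name)``. The model is transformed by
    the least-squares superposition of its shared atoms onto the
    template's, leaving its internal geometry untouched.
    """
    t_sel = select(template_monomer, shared_atoms)
    m_sel = select(model_monomer, shared_atoms)
    t_keyed = {(template_monomer.atoms[i].res_id, template_monomer.atoms[i].name): i
               for i in t_sel}
    m_keyed = {(model_monomer.atoms[i].res_id, model_monomer.atoms[i].name): i
               for i in m_sel}
    common = sorted(set(t_keyed) & set(m_keyed))
    if len(common) < 3:
        raise GeometryError(
            f"shared-atom selection pairs only {len(common)} atoms; need >= 3"
        )
    t_idx = [t_keyed[k] for k in common]
    m_idx = [m_keyed[k] for k in common]
    model_coords = model_monomer.coords
    rotation, translation, _ = kabsch_align(
        model_coords[m_idx], template_monomer.coords[t_idx]
    )
    out = model_monomer.copy()
    out.set_coords(model_coords @ rotation.T + translation)
    return out


# ---------------------------------------------------------------------------
# Fe2S2 site detection and placement
# ---------------------------------------------------------------------------

def detect_cluster_sites(
    polymer: Structure, site_cutoff: float = 6.0
) -> list[ClusterSite]:
    """Detect four-sulfur Fe2S2 coordination sites between monomer pairs.

    A site is recorded for a monomer pair whose four cysteine-114/116 SG
    atoms (two per monomer) are mutually within ``site_cutoff``; pairs
    with a partial quartet in range raise an ambiguous-site warning and
    are skipped. Sites are returned sorted along the rod axis.
    """
    chains = polymer.chains
    sg_by_chain = {c: v for c, v in _sg_indices_by_chain(polymer).items() if v.size}
    if not sg_by_chain:
        raise SiteDetectionError("polymer carries no cysteine-114/116 SG atoms")
    coords = polymer.coords
    sites: list[ClusterSite] = []
    chain_list = [c for c in chains if c in sg_by_chain]
    for a_pos, chain_a in enumerate(chain_list):
        for chain_b in chain_list[a_pos + 1:]:
            sga, sgb = sg_by_chain[chain_a], sg_by_chain[chain_b]
            cross = cdist(coords[sga], coords[sgb])
            if cross.min() > site_cutoff:
                continue
            if sga.size != 2 or sgb.size != 2:
                warnings.warn(
                    f"monomer pair ({chain_a}, {chain_b}) has "
                    f"{sga.size}+{sgb.size} SG atoms; site skipped",
                    stacklevel=2,
                )
                continue
            quartet = np.concatenate([sga, sgb])
            pairwise = cdist(coords[quartet], coords[quartet])
            if pairwise.max() <= site_cutoff:
                sites.append(
                    ClusterSite(
                        monomer_pair=(chain_a, chain_b),
                        sg_atoms=tuple(int(i) for i in quartet),
                        centroid=coords[quartet].mean(axis=0),
                    )
                )
            else:
                in_range = sum(
                    1 for k in range(4)
                    if np.all(np.delete(pairwise[k], k) <= site_cutoff)
                )
                warnings.warn(
                    f"monomer pair ({chain_a}, {chain_b}) has only {in_range} "
                    f"SG atoms mutually in range; ambiguous site skipped",
                    stacklevel=2,
                )
    if len(sites) > 1:
        centroids = np.array([s.centroid for s in sites])
        order = _principal_order(centroids)
        sites = [sites[i] for i in order]
    return sites


def place_clusters(
    polymer: Structure,
    sites: Sequence[ClusterSite],
    cluster_geometry: Structure,
) -> Structure:
    """Add one Fe2S2 copy per site, oriented by the SG quartet geometry.

    The template's bridging-sulfur midpoint is moved onto the SG-quartet
    centroid and its Fe-Fe axis aligned with the bisector of the two
    monomers' SG-pair directions. Added atoms carry the ``FE2S2`` moiety
    tag and live in one fresh chain (one residue per site). Any added atom
    closer than 1.0 A to an existing atom raises a placement error.
    """
    if not sites:
        raise InputError("no cluster sites given")
    fe = [a for a in cluster_geometry.atoms if a.element.upper() == "FE"]
    sstar = [a for a in cluster_geometry.atoms if a.element.upper() == "S"]
    if len(fe) != 2 or len(sstar) != 2:
        raise InputError("cluster geometry must contain 2 Fe and 2 S* atoms")
    smid = (sstar[0].position + sstar[1].position) / 2.0
    ex = fe[1].position - fe[0].position
    ex = ex / np.linalg.norm(ex)
    ey = sstar[1].position - sstar[0].position
    ey = ey - np.dot(ey, ex) * ex
    ey = ey / np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    local_frame = np.column_stack([ex, ey, ez])  # local -> template coords

    out = polymer.copy()
    coords = out.coords
    tree = cKDTree(coords)
    used = set(out.chains)
    (cluster_chain,) = _fresh_chain_ids(used, 1)
    polymer_coords = polymer.coords
    serial = max((a.serial for a in out.atoms), default=0)
    new_atoms: list[AtomRecord] = []
    for site_index, site in enumerate(sites):
        sg = np.array([polymer_coords[i] for i in site.sg_atoms])
        # SG pairs per monomer: detect_cluster_sites stores monomer A then B.
        pair_dir_a = sg[1] - sg[0]
        pair_dir_b = sg[3] - sg[2]
        if np.dot(pair_dir_b, pair_dir_a) < 0:
            pair_dir_b = -pair_dir_b
        e1 = pair_dir_a / np.linalg.norm(pair_dir_a) + pair_dir_b / np.linalg.norm(pair_dir_b)
        e1 = e1 / np.linalg.norm(e1)
        inter = (sg[2] + sg[3]) / 2.0 - (sg[0] + sg[1]) / 2.0
        e2 = inter - np.dot(inter, e1) * e1
        norm2 = np.linalg.norm(e2)
        if norm2 < 1e-8:
            # Inter-monomer axis parallel to the bisector; pick any normal.
            helper = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(helper, e1)) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            e2 = helper - np.dot(helper, e1) * e1
            norm2 = np.linalg.norm(e2)
        e2 = e2 / norm2
        e3 = np.cross(e1, e2)
        target_frame = np.column_stack([e1, e2, e3])
        centroid = site.centroid
        for template_atom in cluster_geometry.atoms:
            local = local_frame.T @ (template_atom.position - smid)
            world = centroid + target_frame @ local
            distance, _ = tree.query(world)
            if distance < 1.0:
                raise PlacementError(
                    f"cluster atom at site {site_index} ({site.monomer_pair}) "
                    f"clashes with an existing atom ({distance:.2f} A)"
                )
            serial += 1
            new_atoms.append(
                AtomRecord(
                    serial=serial,
                    name=template_atom.name,
                    element=template_atom.element,
                    res_name="FES",
                    res_id=site_index + 1,
                    chain_id=cluster_chain,
                    position=world,
                    moiety_tag="FE2S2",
                )
            )
    return Structure(out.atoms + new_atoms)


# ---------------------------------------------------------------------------
# Partner docking
# ---------------------------------------------------------------------------

def write_operator_file(
    operators: Sequence[SymmetryOperator], cell: np.ndarray, path
) -> None:
    """Write symmetry operators and lattice vectors in the plain-text
    operator dialect: CELL rows, then per operator three ROT rows and one
    TRANS row."""
    lines = ["# symmetry operators: CELL rows (A), then ROT x3 + TRANS per operator"]
    for row in np.asarray(cell, dtype=float):
        lines.append("CELL  " + " ".join(f"{v:.6f}" for v in row))
    for op in operators:
        for row in op.rotation:
            lines.append("ROT   " + " ".join(f"{v:.6f}" for v in row))
        lines.append("TRANS " + " ".join(f"{v:.6f}" for v in op.translation))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def read_operator_file(path) -> tuple[list[SymmetryOperator], np.ndarray]:
    """Read an operator file written by :func:`write_operator_file`."""
    from pathlib import Path

    cell_rows: list[list[float]] = []
    rot_rows: list[list[float]] = []
    operators: list[SymmetryOperator] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        keyword, *values = line.split()
        values = [float(v) for v in values]
        if keyword == "CELL":
            cell_rows.append(values)
        elif keyword == "ROT":
            rot_rows.append(values)
        elif keyword == "TRANS":
            operators.append(
                SymmetryOperator(rotation=np.array(rot_rows[-3:]), translation=np.array(values))
            )
        else:
            raise InputError(f"unknown operator-file keyword {keyword!r}")
    if len(cell_rows) != 3:
        raise InputError("operator file must contain exactly 3 CELL rows")
    if not operators:
        raise InputError("operator file contains no operators")
    return operators, np.array(cell_rows)


def fit_helix_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares line through helix backbone points.

    Returns ``(origin, direction, length)`` with the origin at the
    lowest-parameter end and the direction pointing from the first toward
    the last point.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise GeometryError("helix axis fit needs at least 3 points")
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    direction = vt[0]
    if np.dot(points[-1] - points[0], direction) < 0:
        direction = -direction
    t = (points - centroid) @ direction
    origin = centroid + t.min() * direction
    return origin, direction, float(t.max() - t.min())


def _helix_ca(partner: Structure, resid_range: tuple[int, int]) -> np.ndarray:
    lo, hi = resid_range
    indices = select(partner, f"resid {lo}-{hi} and name CA")
    if indices.size == 0:
        raise TemplateError(
            f"partner has no CA atoms in helix residue range {lo}-{hi}"
        )
    return indices


def dock_partner(
    polymer: Structure,
    partner: Structure,
    template: DockingTemplate,
) -> tuple[Structure, list[DockReport]]:
    """Dock partner copies onto every template site with clash rejection.

    For each site, the partner is rigidly superposed so its two helix axes
    match the site's axis anchors (least-squares over the helices' CA
    atoms mapped onto the anchor axes). A site is accepted only when no
    transformed partner atom lies within ``template.clash_threshold`` of
    any already-placed atom; accepted copies are appended with fresh chain
    identifiers. Returns the grown structure and a per-site report.
    """
    ca_a = _helix_ca(partner, template.helix_a)
    ca_b = _helix_ca(partner, template.helix_b)
    partner_coords = partner.coords

    def axis_points(ca_idx: np.ndarray, anchor: AxisAnchor) -> np.ndarray:
        pts = partner_coords[ca_idx]
        origin, direction, length = fit_helix_axis(pts)
        t = (pts - origin) @ direction
        if length < 1e-8:
            raise GeometryError("degenerate helix (zero length)")
        return anchor.origin + np.outer(t * (anchor.length / length), anchor.direction)

    out = polymer.copy()
    used = set(out.chains)
    all_coords = [out.coords]
    tree = cKDTree(np.concatenate(all_coords))
    serial = max((a.serial for a in out.atoms), default=0)
    reports: list[DockReport] = []
    appended: list[AtomRecord] = []
    for site_index, (anchor_a, anchor_b) in enumerate(template.site_anchors):
        source = np.concatenate([partner_coords[ca_a], partner_coords[ca_b]])
        target = np.concatenate(
            [axis_points(ca_a, anchor_a), axis_points(ca_b, anchor_b)]
        )
        rotation, translation, _ = kabsch_align(source, target)
        moved = partner_coords @ rotation.T + translation
        fit_rmsd = float(
            np.sqrt(np.mean(np.sum((source @ rotation.T + translation - target) ** 2, axis=1)))
        )
        min_dist, _ = tree.query(moved, k=1)
        closest = float(np.min(min_dist))
        if closest < template.clash_threshold:
            reports.append(
                DockReport(
                    site_index=site_index, accepted=False,
                    reason=f"clash: nearest placed atom at {closest:.2f} A",
                    fit_rmsd=fit_rmsd,
                )
            )
            continue
        chain_map = dict(zip(partner.chains, _fresh_chain_ids(used, len(partner.chains))))
        site_atoms: list[AtomRecord] = []
        for atom, xyz in zip(partner.atoms, moved):
            new = atom.copy()
            new.position = xyz
            new.chain_id = chain_map[atom.chain_id]
            serial += 1
            new.serial = serial
            site_atoms.append(new)
        appended.extend(site_atoms)
        all_coords.append(moved)
        tree = cKDTree(np.concatenate(all_coords))
        reports.append(
            DockReport(
                site_index=site_index, accepted=True, reason="ok",
                chain_ids=tuple(chain_map.values()), fit_rmsd=fit_rmsd,
            )
        )
    return Structure(out.atoms + appended), reports
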
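"""Trajectory analysis: superposition, RMSD, electron-transfer distance
screening, contact maps, hydrogen bonds and rod-bending profiling.

The electron-transfer screen follows Marcus theory: the squared electronic
coupling between donor and acceptor decays exponentially with their
edge-to-edge separation R,

    |H_DA|^2 ~ V0^2 * exp(-beta * R),

with V0 the coupling coefficient and beta the characteristic decay-length
parameter (1/A). Edge-to-edge means the minimum heavy-atom pair distance
between the two moieties, the standard convention for electron-transfer
distances; couplings are reported relative to V0^2 since absolute
coefficients are system-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import (
    GeometryError,
    InputError,
    SelectionError,
    WindowError,
)
from .structure import Structure, Trajectory

__all__ = [
    "MarcusModel",
    "DistanceSeries",
    "ContactMap",
    "HBondRecord",
    "RodShape",
    "kabsch_align",
    "rmsd_series",
    "edge_to_edge_distance",
    "nearest_cluster_series",
    "marcus_coupling",
    "contact_map",
    "hydrogen_bonds",
    "rod_shape_profile",
]


@dataclass(frozen=True)
class MarcusModel:
    """Exponential distance decay of the squared electronic coupling.

    ``v0`` is the coupling coefficient (arbitrary energy units), ``beta``
    the decay-length parameter in 1/A and ``r`` the donor-acceptor
    edge-to-edge distance in A.
    """

    v0: float = 1.0
    beta: float = 1.4
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise InputError(f"beta={self.beta} must be positive")
        if self.r < 0:
            raise InputError(f"distance r={self.r} must be nonnegative")


@dataclass
class DistanceSeries:
    """Per-frame nearest-cluster edge-to-edge distance for one partner."""

    partner_id: str
    kind: str  # "d_FAD" or "d_Trp"
    per_frame: np.ndarray  # Angstrom
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        if np.any(self.per_frame < 0):
            raise ValueError("distances must be nonnegative")
        self.mean = float(np.mean(self.per_frame))
        self.std = (
            float(np.std(self.per_frame, ddof=1)) if self.per_frame.size > 1 else 0.0
        )


@dataclass
class ContactMap:
    """Residue-pair contact occupancies over an analysis window.

    ``occupancy`` maps ``(partner_res_id, polymer_res_id)`` to the fraction
    of window frames in which any heavy-atom pair of the two residues lies
    within ``cutoff``; only pairs with occupancy above the detection
    threshold are present.
    """

    partner_id: str
    occupancy: dict[tuple[int, int], float]
    cutoff: float
    window: tuple[float, float]

    @property
    def rows(self) -> list[int]:
        return sorted({k[0] for k in self.occupancy})

    @property
    def cols(self) -> list[int]:
        return sorted({k[1] for k in self.occupancy})

    def cells(self) -> set[tuple[int, int]]:
        return set(self.occupancy)


@dataclass
class HBondRecord:
    """One donor-hydrogen-acceptor bond with its frame occupancy."""

    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float
    label: str


@dataclass
class RodShape:
    """Per-frame rod geometry: end-to-end/contour ratio and curvature
    sign-change count along the monomer-centroid polyline."""

    ratio: float
    sign_changes: int


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _check_non_degenerate(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise GeometryError("superposition subset needs at least 3 atoms")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("superposition subset is collinear/degenerate")


def kabsch_align(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal rotation/translation is fitted on ``subset`` (all atoms
    when omitted) and applied to every mobile atom. Returns
    ``(rotation, translation, aligned)`` with ``aligned = mobile @ R.T + t``;
    the rotation is proper (det +1) and the subset RMSD after the
    transform is the global least-squares minimum.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subset is None:
        subset = np.arange(mobile.shape[0])
    subset = np.asarray(subset, dtype=int)
    mob = mobile[subset]
    ref = reference[subset]
    if mob.shape != ref.shape:
        raise GeometryError("subset shapes of mobile and reference differ")
    _check_non_degenerate(mob)
    _check_non_degenerate(ref)
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    rotation = rot.as_matrix()
    translation = ref_c - rotation @ mob_c
    aligned = mobile @ rotation.T + translation
    return rotation, translation, aligned


def rmsd_series(
    traj: Trajectory,
    reference_frame_index: int = 0,
    fit_subset: np.ndarray | None = None,
    measure_subset: np.ndarray | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (A) to a reference frame.

    Each frame is first least-squares fitted on ``fit_subset`` (skipped
    when ``superpose`` is False), then the RMSD is measured over
    ``measure_subset``. Defaults use all atoms for both. The reference
    frame maps to exactly 0.
    """
    if not 0 <= reference_frame_index < traj.n_frames:
        raise InputError(f"reference frame {reference_frame_index} out of range")
    n_atoms = len(traj.topology)
    if fit_subset is None:
        fit_subset = np.arange(n_atoms)
    if measure_subset is None:
        measure_subset = np.arange(n_atoms)
    fit_subset = np.asarray(fit_subset, dtype=int)
    measure_subset = np.asarray(measure_subset, dtype=int)
    if fit_subset.size == 0 or measure_subset.size == 0:
        raise SelectionError("fit and measure subsets must be non-empty")
    reference = traj.frames[reference_frame_index]
    out = np.empty(traj.n_frames)
    for m in range(traj.n_frames):
        frame = traj.frames[m]
        if superpose:
            _, _, frame = kabsch_align(frame, reference, subset=fit_subset)
        delta = frame[measure_subset] - reference[measure_subset]
        out[m] = np.sqrt(np.mean(np.sum(delta**2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# Distances and Marcus screening
# ---------------------------------------------------------------------------

def edge_to_edge_distance(
    structure: Structure,
    moiety_a: np.ndarray,
    moiety_b: np.ndarray,
    frame: np.ndarray | None = None,
    heavy_only: bool = True,
) -> float:
    """Minimum pairwise distance (A) between two atom sets.

    With ``heavy_only`` (the default) hydrogens are excluded from both
    sets, the standard electron-transfer distance convention. Symmetric in
    its arguments.
    """
    moiety_a = np.asarray(moiety_a, dtype=int)
    moiety_b = np.asarray(moiety_b, dtype=int)
    if heavy_only:
        moiety_a = np.array(
            [i for i in moiety_a if structure.atoms[i].is_heavy], dtype=int
        )
        moiety_b = np.array(
            [i for i in moiety_b if structure.atoms[i].is_heavy], dtype=int
        )
    if moiety_a.size == 0 or moiety_b.size == 0:
        raise SelectionError("edge-to-edge moiety sets must be non-empty")
    coords = np.asarray(frame, dtype=float) if frame is not None else structure.coords
    shared = np.intersect1d(moiety_a, moiety_b)
    d = cdist(coords[moiety_a], coords[moiety_b])
    if shared.size:
        # A shared atom pairs with itself at distance 0; exclude those cells.
        pos_a = {i: k for k, i in enumerate(moiety_a)}
        pos_b = {i: k for k, i in enumerate(moiety_b)}
        for i in shared:
            d[pos_a[i], pos_b[i]] = np.inf
    return float(d.min())


def nearest_cluster_series(
    traj: Trajectory,
    cofactor_sets: Mapping[str, Mapping[str, np.ndarray]],
    cluster_sets: Sequence[np.ndarray],
    heavy_only: bool = True,
) -> list[DistanceSeries]:
    """Per-frame distance from each cofactor to its nearest Fe2S2 cluster.

    ``cofactor_sets`` maps partner id to ``{"d_FAD": indices,
    "d_Trp": indices}`` (any kind labels are accepted); the nearest cluster
    is re-evaluated every frame. Returns one series per (partner, kind),
    ordered by partner id then kind.
    """
    if not cluster_sets:
        raise InputError("at least one cluster atom set is required")
    out = []
    for partner_id in sorted(cofactor_sets):
        for kind in sorted(cofactor_sets[partner_id]):
            indices = np.asarray(cofactor_sets[partner_id][kind], dtype=int)
            per_frame = np.empty(traj.n_frames)
            for m in range(traj.n_frames):
                per_frame[m] = min(
                    edge_to_edge_distance(
                        traj.topology, indices, np.asarray(cluster, dtype=int),
                        frame=traj.frames[m], heavy_only=heavy_only,
                    )
                    for cluster in cluster_sets
                )
            out.append(DistanceSeries(partner_id=partner_id, kind=kind, per_frame=per_frame))
    return out


def marcus_coupling(model: MarcusModel) -> float:
    """Squared electronic coupling V0^2 * exp(-beta * r) (relative units)."""
    return model.v0**2 * float(np.exp(-model.beta * model.r))


# ---------------------------------------------------------------------------
# Contacts and hydrogen bonds
# ---------------------------------------------------------------------------

def _window_frames(traj: Trajectory, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.arange(traj.n_frames)
    lo, hi = window
    if lo > hi:
        raise WindowError(f"empty window ({lo}, {hi})")
    mask = (traj.frame_times >= lo) & (traj.frame_times <= hi)
    frames = np.nonzero(mask)[0]
    if frames.size == 0:
        raise WindowError(
            f"window ({lo}, {hi}) ns selects no frames of a trajectory spanning "
            f"{traj.frame_times[0]:g}..{traj.frame_times[-1]:g} ns"
        )
    return frames


def contact_map(
    traj: Trajectory,
    partner_group: np.ndarray,
    polymer_group: np.ndarray,
    cutoff: float = 3.0,
    window: tuple[float, float] | None = None,
    occupancy_threshold: float = 0.0,
    partner_id: str = "partner",
) -> ContactMap:
    """Residue-pair contact map over a trajectory time window.

    A partner/polymer residue pair is in contact in a frame when any
    heavy-atom pair is within ``cutoff`` (3 A default). Cells are retained
    when their occupancy exceeds ``occupancy_threshold`` (any frame, by
    default, since presence marks are wanted).
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    partner_group = np.asarray(partner_group, dtype=int)
    polymer_group = np.asarray(polymer_group, dtype=int)
    if partner_group.size == 0 or polymer_group.size == 0:
        raise SelectionError("contact-map groups must be non-empty")
    pa = np.array([i for i in partner_group if traj.topology.atoms[i].is_heavy])
    pb = np.array([i for i in polymer_group if traj.topology.atoms[i].is_heavy])
    res_a = np.array([traj.topology.atoms[i].res_id for i in pa])
    res_b = np.array([traj.topology.atoms[i].res_id for i in pb])
    frames = _window_frames(traj, window)
    counts: dict[tuple[int, int], int] = {}
    for m in frames:
        d = cdist(traj.frames[m][pa], traj.frames[m][pb])
        ii, jj = np.nonzero(d <= cutoff)
        for pair in {(int(res_a[i]), int(res_b[j])) for i, j in zip(ii, jj)}:
            counts[pair] = counts.get(pair, 0) + 1
    n = frames.size
    occupancy = {
        pair: c / n for pair, c in counts.items() if c / n > occupancy_threshold
    }
    lo, hi = (
        (float(traj.frame_times[frames[0]]), float(traj.frame_times[frames[-1]]))
    )
    return ContactMap(
        partner_id=partner_id, occupancy=occupancy, cutoff=cutoff, window=(lo, hi)
    )


def _find_bonded_hydrogens(
    structure: Structure, donor: int, bond_cutoff: float = 1.25
) -> list[int]:
    """Hydrogens covalently bonded to a donor heavy atom, by proximity in
    the topology coordinates (same residue, within ``bond_cutoff`` A)."""
    d_atom = structure.atoms[donor]
    out = []
    for i, atom in enumerate(structure.atoms):
        if atom.is_heavy:
            continue
        if atom.chain_id != d_atom.chain_id or atom.res_id != d_atom.res_id:
            continue
        if np.linalg.norm(atom.position - d_atom.position) <= bond_cutoff:
            out.append(i)
    return out


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _residue_label(structure: Structure, index: int, group_labels) -> str:
    atom = structure.atoms[index]
    code = _THREE_TO_ONE.get(atom.res_name, atom.res_name)
    group = group_labels.get(atom.chain_id, atom.chain_id) if group_labels else atom.chain_id
    return f"{code}{atom.res_id}({group})"


def hydrogen_bonds(
    traj: Trajectory,
    donors: np.ndarray,
    acceptors: np.ndarray,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
    window: tuple[float, float] | None = None,
    group_labels: Mapping[str, str] | None = None,
) -> list[HBondRecord]:
    """Geometric hydrogen-bond detection over a trajectory window.

    A (donor, acceptor) pair qualifies in a frame when the donor-acceptor
    heavy distance is <= ``dist_cutoff`` (3.5 A default) and the
    D-H...A angle is >= ``angle_cutoff`` (150 degrees default). A record
    is emitted for each pair qualifying in at least one window frame, with
    occupancy the qualifying-frame fraction and a label in
    ``D539(Cry)-R29(ISCA1)`` style (group names from ``group_labels`` by
    chain, chain ids otherwise).
    """
    from .errors import IscarodError

    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise SelectionError("donor and acceptor sets must be non-empty")
    topo = traj.topology
    donor_h: dict[int, list[int]] = {}
    for d in donors:
        hyds = _find_bonded_hydrogens(topo, d)
        if not hyds:
            atom = topo.atoms[d]
            raise IscarodError(
                f"donor {atom.chain_id}/{atom.res_id}/{atom.name} carries no bonded hydrogen"
            )
        donor_h[int(d)] = hyds
    frames = _window_frames(traj, window)
    cos_cut = np.cos(np.radians(angle_cutoff))
    counts: dict[tuple[int, int, int], int] = {}
    for m in frames:
        coords = traj.frames[m]
        for d, hyds in donor_h.items():
            for a in acceptors:
                if a == d:
                    continue
                if np.linalg.norm(coords[d] - coords[a]) > dist_cutoff:
                    continue
                for h in hyds:
                    hd = coords[d] - coords[h]
                    ha = coords[a] - coords[h]
                    denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                    if denom < 1e-10:
                        continue
                    # angle >= cutoff <=> cos(angle) <= cos(cutoff)
                    if np.dot(hd, ha) / denom <= cos_cut:
                        counts[(d, h, int(a))] = counts.get((d, h, int(a)), 0) + 1
                        break
    records = []
    for (d, h, a), c in sorted(counts.items()):
        label = (
            f"{_residue_label(topo, d, group_labels)}-"
            f"{_residue_label(topo, a, group_labels)}"
        )
        records.append(
            HBondRecord(donor=d, hydrogen=h, acceptor=a,
                        occupancy=c / frames.size, label=label)
        )
    return records


# ---------------------------------------------------------------------------
# Rod bending profile
# ---------------------------------------------------------------------------

def rod_shape_profile(
    traj: Trajectory,
    monomer_partition: Sequence[np.ndarray],
) -> list[RodShape]:
    """Per-frame bending profile of the rod polymer.

    Monomer centroids form a polyline. The end-to-end/contour ratio is 1
    for a straight rod and drops as it bends; curvature sign changes are
    counted on the binormal component of consecutive segment pairs
    projected onto the dominant bending plane normal. A single-arc bend
    gives 0 sign changes, an S-shape exactly 1.
    """
    if len(monomer_partition) < 4:
        raise GeometryError("rod shape profiling needs at least 4 monomers")
    partition = [np.asarray(p, dtype=int) for p in monomer_partition]
    out = []
    for m in range(traj.n_frames):
        coords = traj.frames[m]
        centroids = np.array([coords[p].mean(axis=0) for p in partition])
        segments = np.diff(centroids, axis=0)
        seg_lengths = np.linalg.norm(segments, axis=1)
        contour = float(seg_lengths.sum())
        end_to_end = float(np.linalg.norm(centroids[-1] - centroids[0]))
        ratio = end_to_end / contour if contour > 0 else 1.0
        binormals = np.cross(segments[:-1], segments[1:])
        norms = np.linalg.norm(binormals, axis=1)
        # A pair of segments is treated as locally straight when the sine of
        # the turn angle is below 1e-6.
        scale = seg_lengths[:-1] * seg_lengths[1:]
        significant = norms > 1e-6 * scale
        sign_changes = 0
        if np.any(significant):
            ref = binormals[np.argmax(norms)]
            ref = ref / np.linalg.norm(ref)
            signed = binormals[significant] @ ref
            signs = np.sign(signed)
            signs = signs[signs != 0]
            sign_changes = int(np.sum(signs[1:] != signs[:-1]))
        out.append(RodShape(ratio=ratio, sign_changes=sign_changes))
    return out
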
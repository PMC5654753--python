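"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, alternative formulas, exhaustive grids) and shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Torsion angle via atan2 of cross products (alternative formula)."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_hat = b2 / np.linalg.norm(b2)
    y = np.dot(np.cross(n1, n2), b2_hat)
    x = np.dot(n1, n2)
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


def dihedral_energy_oracle(frame: np.ndarray, terms) -> float:
    """Term-by-term summation of k*(1 + cos(n*theta - delta))."""
    total = 0.0
    for term in terms:
        theta = math.radians(dihedral_oracle(*(frame[i] for i in term.atoms)))
        total += term.k * (1.0 + math.cos(term.n * theta - math.radians(term.delta)))
    return total


def switching_oracle(r: float, switch_on: float, cutoff: float) -> float:
    if r >= cutoff:
        return 0.0
    if r <= switch_on:
        return 1.0
    rc2, ron2, r2 = cutoff**2, switch_on**2, r**2
    return ((rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ron2)) / (rc2 - ron2) ** 3


def pair_energy_oracle(structure, group_a, group_b, config, frame=None):
    """Double-loop nonbonded sum without any vectorisation or neighbour
    lists; returns (E_elec, E_vdw, E_total)."""
    coords = frame if frame is not None else structure.coords
    e_elec = e_vdw = 0.0
    for i in group_a:
        for j in group_b:
            ai, aj = structure.atoms[i], structure.atoms[j]
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r >= config.cutoff:
                continue
            s = (
                switching_oracle(r, config.switch_on, config.cutoff)
                if config.switching
                else 1.0
            )
            e_elec += config.coulomb_constant * ai.charge * aj.charge / r * s
            eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            e_vdw += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6) * s
    return e_elec, e_vdw, e_elec + e_vdw


_GRID_CACHE: dict[float, np.ndarray] = {}


def _rotation_grid(step_deg: float) -> np.ndarray:
    """All zyz-Euler rotations on a step_deg grid, as (M, 3, 3) matrices."""
    if step_deg not in _GRID_CACHE:
        alphas = np.arange(0.0, 360.0, step_deg)
        betas = np.arange(0.0, 180.0 + step_deg / 2, step_deg)
        gammas = np.arange(0.0, 360.0, step_deg)
        grid = np.array(np.meshgrid(alphas, betas, gammas, indexing="ij"))
        euler = grid.reshape(3, -1).T
        _GRID_CACHE[step_deg] = Rotation.from_euler(
            "zyz", euler, degrees=True
        ).as_matrix()
    return _GRID_CACHE[step_deg]


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray,
                     step_deg: float = 5.0) -> float:
    """Exhaustive rotation-grid superposition RMSD (centroid-matched)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    mats = _rotation_grid(step_deg)
    rotated = np.einsum("mij,nj->mni", mats, mob)
    rmsds = np.sqrt(np.mean(np.sum((rotated - ref) ** 2, axis=2), axis=1))
    return float(rmsds.min())


def min_distance_oracle(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """All-pairs minimum distance via explicit loops."""
    best = math.inf
    for a in coords_a:
        for b in coords_b:
            best = min(best, float(np.linalg.norm(a - b)))
    return best


def hydrogen_bond_oracle(coords, donors_h, acceptors, dist_cutoff, angle_cutoff):
    """Exhaustive triple loop over (donor, hydrogen, acceptor) in one frame.

    ``donors_h`` is a list of (donor_index, [hydrogen indices]). Returns
    the set of (donor, acceptor) pairs satisfying the geometric criteria.
    """
    found = set()
    for d, hyds in donors_h:
        for a in acceptors:
            if a == d:
                continue
            if np.linalg.norm(coords[d] - coords[a]) > dist_cutoff:
                continue
            for h in hyds:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_cutoff:
                    found.add((int(d), int(a)))
    return found


def contact_pairs_oracle(structure, coords, group_a, group_b, cutoff):
    """Exhaustive residue-pair contact scan of one frame (heavy atoms)."""
    pairs = set()
    for i in group_a:
        ai = structure.atoms[i]
        if not ai.is_heavy:
            continue
        for j in group_b:
            aj = structure.atoms[j]
            if not aj.is_heavy:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                pairs.add((ai.res_id, aj.res_id))
    return pairs
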
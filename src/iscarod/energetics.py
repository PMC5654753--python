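"""Dihedral and nonbonded interaction energies.

The conformational-stability estimator is the proper-dihedral energy

    U_dihedral = sum_i k_i * [1 + cos(n_i * theta_i - delta_i)],

with stiffness k_i (kcal/mol), multiplicity n_i and phase delta_i per
torsion i. The partner-binding observable is the group-group nonbonded
interaction energy: direct-space Coulomb plus 12-6 Lennard-Jones with a
CHARMM-style switching function between ``switch_on`` and ``cutoff``
(12 A by default), Lorentz-Berthelot-style combination (geometric-mean
epsilon, additive rmin halves) and Coulomb constant 332.0636
kcal*A/(mol*e^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, InputError, OverlapError, ParameterError, SelectionError
from .structure import Structure, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "DihedralTerm",
    "NonbondedConfig",
    "InteractionEnergySeries",
    "dihedral_angle",
    "dihedral_energy",
    "pair_interaction_energy",
    "interaction_energy_series",
]

#: CHARMM-convention Coulomb constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636


@dataclass(frozen=True)
class DihedralTerm:
    """One torsion term: atom-index quadruple and (k, n, delta) parameters.

    ``k`` in kcal/mol, ``n`` a positive integer multiplicity, ``delta`` the
    phase in degrees.
    """

    atoms: tuple[int, int, int, int]
    k: float
    n: int
    delta: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ParameterError(f"k={self.k} must be >= 0 for term {self.atoms}")
        if self.n < 1:
            raise ParameterError(f"n={self.n} must be >= 1 for term {self.atoms}")
        a, b, c, d = self.atoms
        if a == b or b == c or c == d:
            raise ParameterError(
                f"consecutive atoms of dihedral quadruple {self.atoms} must differ"
            )


@dataclass(frozen=True)
class NonbondedConfig:
    """Nonbonded summation settings.

    ``cutoff``/``switch_on`` in Angstrom; interactions are scaled by the
    CHARMM switching polynomial between ``switch_on`` and ``cutoff`` and
    are zero beyond the cutoff. ``switching=False`` applies a hard cutoff
    instead. Bonded exclusions (1-2, 1-3) are accepted as explicit pair
    sets; 1-4 pairs are included at full strength.
    """

    cutoff: float = 12.0
    switch_on: float = 10.0
    coulomb_constant: float = COULOMB_CONSTANT
    switching: bool = True
    excluded_pairs: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.switch_on < self.cutoff:
            raise ParameterError(
                f"require 0 < switch_on ({self.switch_on}) < cutoff ({self.cutoff})"
            )


@dataclass
class InteractionEnergySeries:
    """Per-frame group-group interaction energy for one docked partner."""

    partner_id: str
    per_frame_energy: np.ndarray  # kcal/mol
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_frame_energy = np.asarray(self.per_frame_energy, dtype=float)
        self.mean = float(np.mean(self.per_frame_energy))
        self.std = (
            float(np.std(self.per_frame_energy, ddof=1))
            if self.per_frame_energy.size > 1
            else 0.0
        )


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, in degrees in (-180, 180].

    The angle is measured between the (p1,p2,p3) and (p2,p3,p4) planes,
    right-handed about the p2->p3 axis; a planar cis arrangement gives 0
    and trans gives 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b2 = p3 - p2
    b3 = p4 - p3
    b2_norm = np.linalg.norm(b2)
    if b2_norm < 1e-10:
        raise GeometryError("central bond p2->p3 has zero length")
    axis = b2 / b2_norm
    # Components of the outer bonds perpendicular to the central bond.
    v = b0 - np.dot(b0, axis) * axis
    w = b3 - np.dot(b3, axis) * axis
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("collinear atoms give an undefined dihedral")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(axis, v), w))
    angle = np.degrees(np.arctan2(y, x))
    # Map the branch point -180 onto +180 so the range is (-180, 180].
    if angle <= -180.0 + 1e-12:
        angle = 180.0
    return float(angle)


def dihedral_energy(frame: np.ndarray, terms: Sequence[DihedralTerm]) -> float:
    """Proper-dihedral energy of one frame, kcal/mol.

    ``frame`` is an (N, 3) coordinate array; each term's atom indices must
    resolve within it. Nonnegative whenever all k >= 0 and bounded above
    by 2*sum(k).
    """
    frame = np.asarray(frame, dtype=float)
    total = 0.0
    for term in terms:
        for index in term.atoms:
            if not 0 <= index < frame.shape[0]:
                raise ParameterError(
                    f"dihedral term {term.atoms} references atom {index} "
                    f"outside the frame of {frame.shape[0]} atoms"
                )
        theta = np.radians(
            dihedral_angle(*(frame[i] for i in term.atoms))
        )
        total += term.k * (1.0 + np.cos(term.n * theta - np.radians(term.delta)))
    return float(total)


def _switching_factor(r: np.ndarray, config: NonbondedConfig) -> np.ndarray:
    """CHARMM switching polynomial S(r): 1 below switch_on, 0 beyond cutoff."""
    ron2 = config.switch_on**2
    rc2 = config.cutoff**2
    r2 = r**2
    s = np.ones_like(r)
    beyond = r >= config.cutoff
    s[beyond] = 0.0
    mid = (~beyond) & (r > config.switch_on)
    r2m = r2[mid]
    s[mid] = ((rc2 - r2m) ** 2 * (rc2 + 2.0 * r2m - 3.0 * ron2)) / (rc2 - ron2) ** 3
    return s


def _gather_params(structure: Structure, indices: np.ndarray):
    q = np.empty(len(indices))
    eps = np.empty(len(indices))
    rmh = np.empty(len(indices))
    for k, i in enumerate(indices):
        atom = structure.atoms[i]
        if atom.charge is None:
            raise ParameterError(
                f"atom {atom.chain_id}/{atom.res_id}/{atom.name} has no charge"
            )
        if atom.lj_epsilon is None or atom.lj_rmin_half is None:
            raise ParameterError(
                f"atom {atom.chain_id}/{atom.res_id}/{atom.name} has no LJ parameters"
            )
        q[k] = atom.charge
        eps[k] = atom.lj_epsilon
        rmh[k] = atom.lj_rmin_half
    return q, eps, rmh


def pair_interaction_energy(
    structure: Structure,
    group_a: np.ndarray,
    group_b: np.ndarray,
    config: NonbondedConfig | None = None,
    frame: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Group-group nonbonded energy: (E_elec, E_vdw, E_total) in kcal/mol.

    ``structure`` provides charges and LJ parameters; coordinates are taken
    from ``frame`` (an (N, 3) array) when given, else from the structure.
    Groups must be disjoint index sets. Both components are scaled by the
    switching function and vanish beyond the cutoff; the energy is
    symmetric under swapping the groups.
    """
    if config is None:
        config = NonbondedConfig()
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise SelectionError("interaction groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise SelectionError("interaction groups must be disjoint")
    coords = np.asarray(frame, dtype=float) if frame is not None else structure.coords
    qa, epsa, rmha = _gather_params(structure, group_a)
    qb, epsb, rmhb = _gather_params(structure, group_b)
    xa = coords[group_a]
    xb = coords[group_b]
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    if config.excluded_pairs:
        mask = np.ones_like(r, dtype=bool)
        for i, ia in enumerate(group_a):
            for j, ib in enumerate(group_b):
                if (ia, ib) in config.excluded_pairs or (ib, ia) in config.excluded_pairs:
                    mask[i, j] = False
    else:
        mask = np.ones_like(r, dtype=bool)
    active = mask & (r < config.cutoff)
    if np.any(active & (r < 0.1)):
        raise OverlapError("atom pair closer than 0.1 A")
    if not np.any(active):
        return 0.0, 0.0, 0.0
    rr = r[active]
    scale = _switching_factor(rr, config) if config.switching else np.ones_like(rr)
    qq = (qa[:, None] * qb[None, :])[active]
    e_elec = float(np.sum(config.coulomb_constant * qq / rr * scale))
    eps_ij = np.sqrt(epsa[:, None] * epsb[None, :])[active]
    rmin_ij = (rmha[:, None] + rmhb[None, :])[active]
    ratio6 = (rmin_ij / rr) ** 6
    e_vdw = float(np.sum(eps_ij * (ratio6**2 - 2.0 * ratio6) * scale))
    return e_elec, e_vdw, e_elec + e_vdw


def interaction_energy_series(
    traj: Trajectory,
    partner_groups: Mapping[str, np.ndarray],
    polymer_group: np.ndarray,
    config: NonbondedConfig | None = None,
) -> list[InteractionEnergySeries]:
    """Per-frame partner-polymer interaction energies for each partner.

    Returns one :class:`InteractionEnergySeries` per partner id, ordered by
    partner id, with mean and standard deviation populated.
    """
    if not partner_groups:
        raise InputError("no partner groups given")
    polymer_group = np.asarray(polymer_group, dtype=int)
    if polymer_group.size == 0:
        raise SelectionError("polymer group is empty")
    out = []
    for partner_id in sorted(partner_groups):
        group = np.asarray(partner_groups[partner_id], dtype=int)
        if group.size == 0:
            raise SelectionError(f"partner group {partner_id!r} is empty")
        energies = np.empty(traj.n_frames)
        for m in range(traj.n_frames):
            _, _, energies[m] = pair_interaction_energy(
                traj.topology, group, polymer_group, config=config,
                frame=traj.frames[m],
            )
        out.append(InteractionEnergySeries(partner_id=partner_id, per_frame_energy=energies))
    return out
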
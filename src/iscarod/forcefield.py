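"""Minimal force-field parameter dialect and bundled parameter sets.

The package defines its own small keyword parameter format so it stays
simulation-engine independent::

    # comment
    DIHEDRAL  CA CA CA CA   0.6  3  0.0      # k (kcal/mol), n, delta (deg)
    NONBONDED CA            0.055 2.0        # epsilon (kcal/mol), rmin/2 (A)
    CHARGE    S*           -0.69             # elementary charges, by role

Two partial-charge sets for the Fe2S2 cluster and its coordinating
cysteines are bundled: the literature (Mouesca) set and an ESP-fitted set.
Cysteine hydrogens carry +0.09 e in both, following CHARMM nomenclature.

The bundled Lennard-Jones parameters for cluster iron and sulfur are
synthetic stand-ins of plausible magnitude — published cluster parameter
sets are not redistributable here — and are labelled as such; they only
need to give well-behaved repulsion/dispersion on the synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ParameterError
from .structure import ChargeSet, Structure

__all__ = [
    "DihedralParameter",
    "ForceFieldParameters",
    "load_parameters",
    "mouesca_charges",
    "esp_charges",
    "STANDIN_LJ_BY_ELEMENT",
    "DEFAULT_BACKBONE_CHARGES",
    "assign_lj_parameters",
    "assign_default_charges",
]


@dataclass(frozen=True)
class DihedralParameter:
    """One proper-dihedral Fourier term keyed by an atom-type quadruple."""

    types: tuple[str, str, str, str]
    k: float  # kcal/mol
    n: int  # multiplicity
    delta: float  # phase, degrees

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ParameterError(f"dihedral stiffness k={self.k} must be >= 0")
        if self.n < 1:
            raise ParameterError(f"dihedral multiplicity n={self.n} must be >= 1")


@dataclass
class ForceFieldParameters:
    """Parsed parameter file: dihedral terms, LJ parameters and charges."""

    dihedrals: dict[tuple[str, str, str, str], list[DihedralParameter]]
    nonbonded: dict[str, tuple[float, float]]  # type -> (epsilon, rmin/2)
    charges: dict[str, float]  # role -> elementary charge

    def dihedral_terms_for(self, types: tuple[str, str, str, str]):
        """Terms for a type quadruple, matching either atom order."""
        if types in self.dihedrals:
            return self.dihedrals[types]
        return self.dihedrals.get(types[::-1], [])


def load_parameters(path: str | Path) -> ForceFieldParameters:
    """Parse a parameter dialect file.

    Blank lines, trailing whitespace and ``#`` comments are tolerated.
    """
    dihedrals: dict[tuple[str, str, str, str], list[DihedralParameter]] = {}
    nonbonded: dict[str, tuple[float, float]] = {}
    charges: dict[str, float] = {}
    for line_number, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        keyword = fields[0].upper()
        try:
            if keyword == "DIHEDRAL":
                if len(fields) != 8:
                    raise ValueError("expected: DIHEDRAL t1 t2 t3 t4 k n delta")
                types = tuple(fields[1:5])
                term = DihedralParameter(
                    types=types, k=float(fields[5]), n=int(fields[6]),
                    delta=float(fields[7]),
                )
                dihedrals.setdefault(types, []).append(term)
            elif keyword == "NONBONDED":
                if len(fields) != 4:
                    raise ValueError("expected: NONBONDED type epsilon rmin_half")
                nonbonded[fields[1]] = (float(fields[2]), float(fields[3]))
            elif keyword == "CHARGE":
                if len(fields) != 3:
                    raise ValueError("expected: CHARGE role value")
                charges[fields[1]] = float(fields[2])
            else:
                raise ValueError(f"unknown keyword {fields[0]!r}")
        except ValueError as exc:
            raise ParameterError(f"parameter file line {line_number}: {exc}") from None
    return ForceFieldParameters(dihedrals=dihedrals, nonbonded=nonbonded, charges=charges)


# ---------------------------------------------------------------------------
# Bundled charge sets (Fe2S2 cluster + coordinating cysteines)
# ---------------------------------------------------------------------------

def mouesca_charges() -> ChargeSet:
    """Literature partial-charge set for the Fe2S2/cysteine moiety."""
    return ChargeSet(
        name="mouesca",
        charges={"S*": -0.61, "Fe": 0.76, "S": -0.59, "C_B": -0.16, "H": 0.09},
    )


def esp_charges() -> ChargeSet:
    """ESP-fitted partial-charge set for the Fe2S2/cysteine moiety."""
    return ChargeSet(
        name="esp",
        charges={"S*": -0.69, "Fe": 0.78, "S": -0.68, "C_B": -0.04, "H": 0.09},
    )


#: Synthetic stand-in Lennard-Jones parameters by element:
#: (epsilon kcal/mol, rmin/2 A). Magnitudes follow common protein
#: force-field conventions; the FE entry in particular is a stand-in.
STANDIN_LJ_BY_ELEMENT: dict[str, tuple[float, float]] = {
    "C": (0.055, 2.000),
    "N": (0.200, 1.850),
    "O": (0.120, 1.700),
    "S": (0.450, 2.000),
    "H": (0.046, 0.2245),
    "FE": (0.010, 0.650),
}

#: Generic small partial charges by atom name used to give the synthetic
#: fixtures a nonzero electrostatic signal; not a calibrated charge model.
DEFAULT_BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.47,
    "CA": 0.07,
    "C": 0.51,
    "O": -0.51,
    "CB": -0.18,
    "SG": -0.23,
    "NH1": -0.80,
    "HH1": 0.46,
    "OD1": -0.76,
    "CG": -0.28,
}


def assign_lj_parameters(structure: Structure, by_element=None) -> Structure:
    """Copy of ``structure`` with LJ parameters filled in by element."""
    table = STANDIN_LJ_BY_ELEMENT if by_element is None else by_element
    out = structure.copy()
    for atom in out.atoms:
        key = atom.element.upper()
        if key not in table:
            raise ParameterError(f"no LJ parameters for element {atom.element!r}")
        atom.lj_epsilon, atom.lj_rmin_half = table[key]
    return out


def assign_default_charges(structure: Structure) -> Structure:
    """Copy with generic per-atom-name charges (zero where unknown)."""
    out = structure.copy()
    for atom in out.atoms:
        atom.charge = DEFAULT_BACKBONE_CHARGES.get(atom.name, 0.0)
    return out
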
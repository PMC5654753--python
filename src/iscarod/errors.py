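"""Exception hierarchy for the iscarod package."""


class IscarodError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(IscarodError):
    """Malformed PDB record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class PDBFormatError(IscarodError):
    """A structure cannot be expressed in fixed-column PDB format."""


class TopologyMismatchError(IscarodError):
    """MODEL blocks of a multi-model file disagree on their atom set."""


class SelectionSyntaxError(IscarodError):
    """Selection expression violates the mini-grammar."""


class SelectionError(IscarodError):
    """A selection is empty or inconsistent where a non-empty one is required."""


class ConfigurationError(IscarodError):
    """Missing or inconsistent configuration (charge roles, pipeline options)."""


class ParameterError(IscarodError):
    """A force-field parameter (charge, LJ, dihedral term) is missing or invalid."""


class GeometryError(IscarodError):
    """Degenerate geometry: collinear dihedral atoms, degenerate superposition."""


class OverlapError(IscarodError):
    """Two interacting atoms are unphysically close (r < 0.1 A)."""


class PlacementError(IscarodError):
    """Placing a moiety would clash with existing atoms."""


class SiteDetectionError(IscarodError):
    """Cross-link site detection failed (e.g. no cysteines present)."""


class NamingError(IscarodError):
    """Chain-identifier namespace exhausted."""


class TemplateError(IscarodError):
    """A docking template does not match the partner structure."""


class WindowError(IscarodError):
    """Requested analysis time window lies outside the trajectory."""


class InputError(IscarodError):
    """Invalid top-level input (empty series list, bad sample sizes, ...)."""
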
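"""Exception hierarchy shared across the package."""


class HydronetError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(HydronetError):
    """A coordinate file contained no ATOM/HETATM records."""


class EnsembleConsistencyError(HydronetError):
    """Frames of an ensemble disagree on the non-water atom table."""


class SelectionSyntaxError(HydronetError):
    """A selection expression could not be parsed."""


class AtomNotFoundError(HydronetError):
    """A referenced atom key is absent from the model."""


class DegenerateFitError(HydronetError):
    """Superposition input is too small or rank-deficient."""


class AlignmentSelectionError(HydronetError):
    """Fit selection is empty or missing from some frame."""


class DegenerateTorsionError(HydronetError):
    """Three consecutive torsion atoms are collinear."""


class DegenerateRingError(HydronetError):
    """Ring atoms are collinear; no plane can be fit."""


class PlacementError(HydronetError):
    """Synthetic scaffold geometry could not be realized without clashes."""


class GraphConsistencyError(HydronetError):
    """Interaction events reference atoms absent from the ensemble."""
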
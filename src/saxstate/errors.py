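"""Exception hierarchy for saxstate."""


class SaxstateError(Exception):
    """Base class for all saxstate errors."""


class FormatError(SaxstateError):
    """A coordinate or profile file could not be parsed."""


class EmptyModelError(SaxstateError):
    """A model contains no Calpha atoms."""


class SelectionError(SaxstateError):
    """A residue selection is empty, overlapping, or unresolvable."""


class DegeneracyError(SaxstateError):
    """A point set is too small or too degenerate for superposition."""


class GridError(SaxstateError):
    """A q-grid is invalid or two grids do not overlap."""


class DataError(SaxstateError):
    """Experimental data violate a precondition (e.g. non-positive sigma)."""


class FitError(SaxstateError):
    """A fit failed or is degenerate."""


class InversionError(SaxstateError):
    """The indirect transform could not be solved acceptably."""


class SamplingError(SaxstateError):
    """Conformer sampling could not satisfy its constraints."""


class ConstructionError(SaxstateError):
    """A synthetic-model specification is geometrically impossible."""


class ConfigError(SaxstateError):
    """A protocol or pipeline configuration is invalid."""
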
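"""Exception hierarchy for the envim package."""


class EnvimError(Exception):
    """Base class for all envim-specific errors."""


class FormatError(EnvimError):
    """Malformed input file (wrong columns, duplicate identifiers, ...)."""


class ValidationError(EnvimError):
    """Input violates a domain invariant (negative abundance, stray NA, ...)."""


class ParameterError(EnvimError):
    """A configuration parameter is outside its admissible range."""


class MatchingError(EnvimError):
    """Sample matching across tables produced an empty intersection."""


class EmptyResultError(EnvimError):
    """A filter removed every feature (or nothing was left to analyse)."""


class DegenerateSampleError(EnvimError):
    """A sample cannot be normalised (e.g. zero total abundance)."""


class DegenerateTargetError(EnvimError):
    """A response vector is constant and cannot be modelled."""


class ImputationError(EnvimError):
    """A metabolite has too few observed values to impute."""
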
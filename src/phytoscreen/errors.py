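"""Exception hierarchy shared across the pipeline stages."""


class PhytoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhytoscreenError):
    """A column mapping, config file or threshold is invalid."""


class ValidationError(PhytoscreenError):
    """Input data violates a documented precondition."""


class StructureError(PhytoscreenError):
    """A SMILES string does not parse to a valid molecule."""


class ComparabilityError(PhytoscreenError):
    """Two fingerprints with different parameters were compared."""


class ParseError(PhytoscreenError):
    """A structured text file (GMT, table) is malformed."""


class GenerationError(PhytoscreenError):
    """The synthetic generator could not satisfy its planted-truth design."""
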
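"""Exception hierarchy for the neutromet pipeline."""


class NeutrometError(Exception):
    """Base class for all neutromet errors."""


class FormatError(NeutrometError):
    """A file could not be parsed in the expected format."""


class InvariantError(NeutrometError):
    """Input data violates a structural invariant (axis, boundaries, shapes)."""


class ReferencingError(NeutrometError):
    """No usable reference peak found for chemical-shift referencing."""


class EstimationError(NeutrometError):
    """A spectral estimate (line width, baseline anchors) could not be computed."""


class ConfigError(NeutrometError):
    """Pipeline configuration is invalid or incomplete."""
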
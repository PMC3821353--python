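"""Exception and warning types shared across veinmap."""


class VeinMapError(Exception):
    """Base class for all veinmap errors."""


class InvalidInputError(VeinMapError, ValueError):
    """An input violates a precondition (wrong shape, empty, out of range)."""


class IncompatibleCodesError(VeinMapError, ValueError):
    """Two binary codes (or a code and a weight map) cannot be compared:
    their lengths or operator tags differ."""


class InsufficientTrainingError(VeinMapError, ValueError):
    """Fewer than two training codes were supplied; a single sample carries
    no stability information."""


class DegenerateWeightsError(VeinMapError, ValueError):
    """A weight map sums to zero, so the weighted similarity is undefined."""


class DegenerateTemplateError(VeinMapError, ValueError):
    """A best-bit mask has no set bits, so masked matching is undefined."""


class ProtocolViolationError(VeinMapError, ValueError):
    """A gallery does not satisfy the sample-count requirements of the
    requested evaluation protocol."""


class DegenerateTemplateWarning(UserWarning):
    """Emitted when best-bit training produces an empty mask; the mask is
    still returned but cannot be used for matching."""
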
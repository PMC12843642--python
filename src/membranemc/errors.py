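"""Exception hierarchy for membranemc."""


class MembraneMCError(Exception):
    """Base class for all membranemc errors."""


class ConfigurationError(MembraneMCError):
    """Invalid simulation parameters or configuration file."""


class PlacementError(MembraneMCError):
    """Dopant placement could not satisfy the exclusion constraints."""


class ParseError(MembraneMCError):
    """Malformed checkpoint, config, or spectrum record."""


class DivergenceError(MembraneMCError):
    """Coincident charges produced a divergent pair energy."""


class DetectionError(MembraneMCError):
    """A spectral line could not be located in its search window."""


class DegenerateBaselineError(MembraneMCError):
    """A normalization baseline is zero or otherwise unusable."""


class InsufficientDataError(MembraneMCError):
    """Too few points to compute the requested statistic."""
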
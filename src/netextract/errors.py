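"""Exception hierarchy for netextract."""


class NetExtractError(Exception):
    """Base class for all netextract errors."""


class ConfigurationError(NetExtractError):
    """Invalid pipeline configuration (unknown step, stage order, bad file)."""


class ParameterError(NetExtractError, ValueError):
    """A step parameter is out of its valid range."""


class DegenerateMarkerError(NetExtractError):
    """A marker strategy produced an empty seed class."""


class PathIntegrityError(NetExtractError):
    """Consecutive pixels of an edge path are not 8-adjacent."""


class WidthLookupError(NetExtractError):
    """An edge path pixel lies on segmentation background."""


class GraphIntegrityError(NetExtractError):
    """Graph construction received inconsistent vertices/edges."""
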
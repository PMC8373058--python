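"""Exception hierarchy.

Every error raised by this package derives from :class:`MtscError`, so
callers (and the CLI) can distinguish package failures from bugs.
"""


class MtscError(Exception):
    """Base class for all errors raised by mtsc."""


class ParseError(MtscError):
    """A file could not be parsed; the message names the offending line."""


class DimensionError(MtscError):
    """Matrix / sidecar / label dimensions are inconsistent."""


class EmptyDatasetError(MtscError):
    """A filtering step removed every cell (or every cell type)."""


class DegenerateCellError(MtscError):
    """A cell with zero total counts reached normalization."""


class BatchConstructionError(MtscError):
    """An N-pair batch cannot be built (a cell type has < 2 cells)."""


class UntrainableTaskError(MtscError):
    """A reference dataset cannot serve as a training task."""


class ModelLoadError(MtscError):
    """A saved model archive is missing, truncated, or of a wrong version."""


class ConfigurationError(MtscError):
    """Invalid run configuration (unknown key, bad decision set, ...)."""
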
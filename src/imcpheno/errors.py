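"""Exception hierarchy shared across the package."""


class ImcPhenoError(Exception):
    """Base class for all package errors."""


class ParameterError(ImcPhenoError, ValueError):
    """An operator parameter violates its contract (e.g. non-positive cap)."""


class DimensionError(ImcPhenoError, ValueError):
    """Two grids that must share a shape do not."""


class ConfigurationError(ImcPhenoError, ValueError):
    """A configuration object (rule set, pipeline config) is invalid."""


class IntegrityError(ImcPhenoError, ValueError):
    """A cross-table consistency requirement is violated (e.g. overlapping
    subcluster results)."""


class PlacementError(ImcPhenoError, RuntimeError):
    """The synthetic renderer could not place objects under its constraints."""
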
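"""Exception hierarchy.

Every rejection named in a module contract maps onto one of these types so
callers can discriminate failure modes without parsing messages.
"""


class TractstatsError(Exception):
    """Base class for all package errors."""


class ConfigError(TractstatsError, ValueError):
    """Invalid configuration value."""


class UnknownTractError(TractstatsError, KeyError):
    """Tract name outside the supported vocabulary."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"unknown tract name: {name!r}")


class MeshError(TractstatsError, ValueError):
    """Mesh violates a structural invariant (manifoldness, normals, ...)."""


class DesignError(TractstatsError, ValueError):
    """GLM design is rank-deficient or groups are too small."""


class ProjectionError(TractstatsError, ValueError):
    """Projection failed; carries the offending vertex indices."""

    def __init__(self, message: str, vertices=None):
        self.vertices = [] if vertices is None else list(vertices)
        super().__init__(message)


class UnderdeterminedError(TractstatsError, ValueError):
    """Fewer than six independent gradient directions."""


class NotPositiveSemidefiniteError(TractstatsError, ValueError):
    """Tensor input has a clearly negative eigenvalue."""


class ConstantInputError(TractstatsError, ValueError):
    """A correlation input has zero variance."""


class SchemaError(TractstatsError, ValueError):
    """Tabular file is missing required columns; lists them."""

    def __init__(self, message: str, missing=None):
        self.missing = [] if missing is None else list(missing)
        super().__init__(message)


class FormatError(TractstatsError, ValueError):
    """Malformed file; carries position information where available."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
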
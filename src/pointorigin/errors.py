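"""Exception types shared across the package."""


class PointOriginError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PointOriginError, ValueError):
    """A kinematic or model parameter violates its stated domain."""


class DegenerateGeometryError(PointOriginError, ValueError):
    """A bearing or quadrant is undefined (zero-length vector, boundary hit)."""


class EmptyCohortError(PointOriginError, ValueError):
    """No participants remain after filtering, or none were requested."""


class InvalidCoefficientError(PointOriginError, ValueError):
    """A coefficient matrix contains non-finite or ill-shaped entries."""


class InvalidContrastError(PointOriginError, ValueError):
    """A requested factor level or outcome is absent from the design."""


class RankDeficiencyError(PointOriginError, ValueError):
    """The design matrix or outcome coding cannot support the requested fit."""


class DegenerateOutcomeError(PointOriginError, ValueError):
    """The outcome variable has too few observed levels to fit."""
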
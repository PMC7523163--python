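"""Exception types shared across the audit pipeline."""


class CxrAuditError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CxrAuditError, ValueError):
    """An argument is outside its documented domain (e.g. rho not in [0, 1])."""


class GeometryError(CxrAuditError, ValueError):
    """A region, glyph or patch does not fit the image geometry."""


class ConfigError(CxrAuditError, ValueError):
    """A configuration value or scheme identifier is unknown or malformed."""


class SchemaError(CxrAuditError, ValueError):
    """Two manifests disagree on label scheme or required columns."""


class IntegrityError(CxrAuditError, ValueError):
    """A fold assignment would violate patient grouping."""


class ModelSelectionError(CxrAuditError, ValueError):
    """Validation fold unusable for epoch selection (e.g. single class)."""


class UndefinedMetricError(CxrAuditError, ValueError):
    """A metric is undefined for the given inputs (e.g. one-class AUROC)."""


class AuditError(CxrAuditError, ValueError):
    """A confound-transfer audit cannot run (e.g. constant attribute)."""


class NumericError(CxrAuditError, ArithmeticError):
    """Non-finite values encountered where finite ones are required."""
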
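"""Typed exceptions used across the pipeline."""


class RadhetError(Exception):
    """Base class for all package errors."""


class DegenerateLesionError(RadhetError):
    """A lesion mask is empty or too small for the requested operation."""


class ConfigurationError(RadhetError):
    """An invalid configuration value was supplied."""


class UnsupportedFeatureError(RadhetError):
    """A feature was requested that is not in the native set and not ingested."""


class GeometryError(RadhetError):
    """Image and mask geometry (spacing/affine) disagree."""


class NonBinaryMaskError(RadhetError):
    """A segmentation mask contains values other than 0 and 1."""


class SchemaError(RadhetError):
    """A feature table or manifest is missing mandatory columns or types."""


class InsufficientDataError(RadhetError):
    """Too few lesions or groups to compute the requested statistic."""
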
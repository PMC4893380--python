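"""Exception hierarchy for the stereodeform pipeline."""


class StereoDeformError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(StereoDeformError):
    """Camera rig geometry is degenerate (e.g. zero baseline, singular K)."""


class BehindCameraError(StereoDeformError):
    """A 3D point or disparity implies non-positive depth."""


class InvalidFeatureError(StereoDeformError):
    """A feature region violates its invariants (e.g. non-positive saliency)."""


class DegenerateConfigurationError(StereoDeformError):
    """Control-point configuration is rank deficient (e.g. coplanar TPS sources)."""


class UnderdeterminedFitError(StereoDeformError):
    """Not enough distinct samples to fit the requested model."""


class FittingError(StereoDeformError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


class ConfigError(StereoDeformError):
    """Pipeline configuration file is invalid (unknown key or out-of-range value)."""
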
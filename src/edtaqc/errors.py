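"""Exception hierarchy for the edtaqc pipeline."""


class EdtaqcError(Exception):
    """Base class for all package errors."""


class SpectrumDomainError(EdtaqcError, ValueError):
    """An operation was asked to act outside a spectrum's valid domain
    (region off the axis, too few points, inconsistent fields, ...)."""


class ConfigurationError(EdtaqcError, ValueError):
    """Required acquisition metadata or configuration is missing/invalid."""


class AnchorNotFoundError(EdtaqcError, RuntimeError):
    """The glucose anomeric doublet anchor could not be located; the
    assignment pipeline aborts for the affected sample."""


class DegenerateFitError(EdtaqcError, ValueError):
    """A regression or deconvolution problem is degenerate (constant
    predictor, fewer points than parameters, zero concentration span)."""
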
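"""Exception hierarchy for gxescan.

Every anticipated failure mode raises a subclass of :class:`GxeError` so
callers (the scan runner, the CLI) can distinguish flagged analyses from
programming errors.
"""


class GxeError(Exception):
    """Base class for all gxescan errors."""


class ConfigError(GxeError):
    """Invalid configuration value (allele frequency, study size, OR, ...)."""


class InvalidCallError(GxeError):
    """A genotype call contains an allele not defined for the SNP."""


class EmptyAnalysisError(GxeError):
    """An analysis subset contains no usable rows."""


class DegeneratePredictorError(GxeError):
    """A predictor is constant in the analysis subset (e.g. monomorphic SNP)."""


class SeparationError(GxeError):
    """The logistic likelihood has no finite maximiser (perfect separation)."""


class CollinearityError(GxeError):
    """The design matrix is rank deficient."""


class NestingError(GxeError):
    """Likelihood-ratio test requested for non-nested or mismatched fits."""


class DegenerateVarianceError(GxeError):
    """A Wald interval was requested for a term with non-positive variance."""


class GenerationError(GxeError):
    """The cohort simulator could not meet its sampling targets."""
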
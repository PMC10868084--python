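"""Exception hierarchy.

Configuration problems raise before any simulation work starts; invariant
violations signal a bug trap (a probability composed outside [0, 1], accrual
after death) and are never silently clamped.
"""


class FrailsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrailsimError):
    """A config file or config object failed validation; message names the field."""


class MissingDataError(FrailsimError):
    """A deficit profile is too incomplete to score."""


class CovariateResolutionError(FrailsimError):
    """A regression term could not find its covariate; no silent zero-fill."""


class RegistryError(FrailsimError):
    """An equation name is not registered."""


class InvariantViolation(FrailsimError):
    """A model invariant was broken at run time (bug trap, not user error)."""
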
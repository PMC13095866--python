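"""Exception types shared across the bearhr pipeline."""


class BearHRError(Exception):
    """Base class for all bearhr errors."""


class ParameterError(BearHRError):
    """An argument violates its documented constraints."""


class FormatError(BearHRError):
    """An input file does not match the documented schema."""


class InsufficientDataError(BearHRError):
    """Too few observations to carry out the requested estimate."""


class DegenerateInputError(BearHRError):
    """Input is formally valid but geometrically degenerate (e.g. zero spread)."""


class SingularDesignError(BearHRError):
    """A model design matrix is rank deficient."""


class InferenceError(BearHRError):
    """A statistical routine cannot be run on the given table."""
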
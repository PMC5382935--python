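"""Exception hierarchy for the cfnips pipeline."""


class CfnipsError(Exception):
    """Base class for all pipeline errors."""


class ParseError(CfnipsError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CfnipsError, ValueError):
    """An in-memory object violates a declared invariant."""


class FitError(CfnipsError, RuntimeError):
    """A reference / model fit is ill-conditioned or under-sampled."""


class QCFailure(CfnipsError, RuntimeError):
    """A sample cannot enter the pipeline (e.g. zero autosomal reads)."""
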
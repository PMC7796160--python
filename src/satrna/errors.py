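"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all satrna errors."""


class InvalidParameterError(PipelineError, ValueError):
    """A parameter violates its documented domain (raised before any work is done)."""


class InvalidAlphabetError(InvalidParameterError):
    """A sequence contains symbols outside the accepted nucleotide alphabet."""


class NotComputableError(PipelineError):
    """A quantity is undefined for this input (e.g. a ratio with a zero denominator).

    Deliberately distinct from returning infinity or NaN: callers must decide
    how to report a non-computable statistic.
    """
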
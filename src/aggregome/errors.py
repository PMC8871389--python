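"""Exception types shared across the pipeline."""


class AggregomeError(Exception):
    """Base class for pipeline errors."""


class FormatError(AggregomeError, ValueError):
    """An input file does not conform to its declared dialect."""


class DesignError(AggregomeError, ValueError):
    """The sample design is inconsistent with the data it describes."""


class InternalError(AggregomeError, RuntimeError):
    """An invariant that upstream stages should have guaranteed was violated."""
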
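"""Package-wide exception types."""


class TuglabError(Exception):
    """Base class for all package errors."""


class SegmentationError(TuglabError):
    """A recording could not be segmented into the expected subtasks."""


class DegenerateDataError(TuglabError):
    """Input data carry no usable variance for the requested statistic."""
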
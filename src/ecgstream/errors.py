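"""Exception hierarchy for the ecgstream toolkit."""


class EcgStreamError(Exception):
    """Base class for all ecgstream errors."""


class SpecificationError(EcgStreamError, ValueError):
    """An operation was configured with invalid parameters."""


class StreamIntegrityError(EcgStreamError):
    """The packet stream is inconsistent (gap, duplicate, bad offset)."""


class SinkError(EcgStreamError):
    """The output sink could not commit a batch."""


class ModelLoadError(EcgStreamError):
    """A model artifact is corrupt or has an incompatible version."""


class DegenerateTrainingError(EcgStreamError):
    """Training data cannot support a multiclass model (e.g. one class)."""


class PipelineError(EcgStreamError):
    """An end-to-end workflow failed (empty beat set, join failure, ...)."""


class FsMismatchError(EcgStreamError):
    """A record's sampling rate differs from the 360 Hz the pipeline assumes."""
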
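"""Exception hierarchy for the screen-analysis pipeline.

All package errors derive from :class:`ScreenError` so callers (and the CLI)
can distinguish validation problems, degenerate inputs, and runtime failures.
"""


class ScreenError(Exception):
    """Base class for all pooledscreen errors."""


class InvalidConfigError(ScreenError, ValueError):
    """A configuration value is out of its allowed range."""


class InvalidManifestError(ScreenError, ValueError):
    """A library manifest violates a structural invariant."""


class InvalidInputError(ScreenError, ValueError):
    """An input object is structurally unusable (e.g. missing control genes)."""


class UnknownGeneError(ScreenError, KeyError):
    """A gene symbol was referenced that the manifest does not contain."""


class DegenerateSampleError(ScreenError, ValueError):
    """A sample is unusable, e.g. a count column with zero total reads."""


class IncompletePairError(ScreenError, ValueError):
    """A patient is missing one of the two required timepoints (D0/D20)."""


class InsufficientInputError(ScreenError, ValueError):
    """Too few inputs for the requested operation (e.g. pooling < 2 screens)."""


class FastqParseError(ScreenError, ValueError):
    """A FASTQ stream is malformed; carries the index of the offending record."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index
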
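"""Exception hierarchy shared across the pipeline.

Extractors raise these; the dataset pipeline catches the recoverable ones
(:class:`InsufficientVoicingError`, :class:`InsufficientCyclesError`,
:class:`SignalTooShortError`, :class:`SilentInputError`) and records the
affected features as missing instead of aborting the record.
"""


class VocalmarkersError(Exception):
    """Base class for all package errors."""


class ParameterError(VocalmarkersError, ValueError):
    """A parameter violates its documented range or type."""


class SignalTooShortError(VocalmarkersError):
    """The signal is shorter than the analysis requires."""


class UnsupportedFormatError(VocalmarkersError):
    """The audio file is not RIFF PCM or is otherwise unreadable."""


class InsufficientVoicingError(VocalmarkersError):
    """Too little voiced content to estimate glottal cycles."""


class InsufficientCyclesError(VocalmarkersError):
    """A perturbation metric needs more glottal cycles than were found."""


class SilentInputError(VocalmarkersError):
    """All analysis frames are silent."""


class StratificationError(VocalmarkersError):
    """A class is too small for the requested stratified split."""


class DegenerateTrainingError(VocalmarkersError):
    """The training set does not contain at least two classes."""


class DegenerateColumnError(VocalmarkersError):
    """A feature column has no usable fitting values."""


class EmptyDatasetError(VocalmarkersError):
    """No records were discovered under the dataset root."""
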
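"""Exception hierarchy for tremorkit.

All exceptions derive from :class:`TremorkitError` so callers can catch the
package's failures with one handler; each subclass also derives from the
built-in exception a naive caller would expect (``ValueError``).
"""


class TremorkitError(Exception):
    """Base class for all tremorkit errors."""


class DegenerateInputError(TremorkitError, ValueError):
    """Input that cannot be processed at all (e.g. all-zero accelerometer)."""


class InconsistentInputError(TremorkitError, ValueError):
    """Arrays or series that should be aligned are not (length mismatch)."""


class RecordingTooShortError(TremorkitError, ValueError):
    """Recording shorter than one analysis window."""


class NoTremorEvidenceError(TremorkitError, ValueError):
    """No spectral peak qualifies for subject-band estimation."""


class StageOrderError(TremorkitError, RuntimeError):
    """A pipeline stage was invoked before its prerequisites."""
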
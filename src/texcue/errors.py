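"""Exception hierarchy shared across the package.

All errors derive from :class:`TexcueError` so callers can catch the package's
failures with one clause; most also derive from :class:`ValueError` because
they signal invalid inputs rather than internal faults.
"""


class TexcueError(Exception):
    """Base class for every error raised by texcue."""


class InvalidCueError(TexcueError, ValueError):
    """An unknown cue kind, or a cue used where it does not apply."""


class InconsistentCueError(TexcueError, ValueError):
    """A cone-contrast vector does not match the requested cue's structure."""


class GamutError(TexcueError, ValueError):
    """A requested colour falls outside the [0, 1] primary gamut.

    Carries the name of the offending primary channel in ``channel``.
    """

    def __init__(self, message: str, channel: str):
        super().__init__(message)
        self.channel = channel


class DegenerateTransformError(TexcueError, ValueError):
    """The cone/mechanism transform is numerically singular for this k."""


class EmptyLatticeError(TexcueError, ValueError):
    """The requested geometry admits no circles inside the grid."""


class NonIdentifiableError(TexcueError, ValueError):
    """A psychometric dataset carries no information about (alpha, beta).

    Raised for all-zero or all-n response counts and for constant response
    proportions, where no finite maximum-likelihood slope exists.
    """


class DegenerateSampleError(TexcueError, ValueError):
    """A paired sample with zero variance; the t statistic is undefined."""


class TrialTableError(TexcueError, ValueError):
    """A trial table failed schema validation; names the offending rows."""
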
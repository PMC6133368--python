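"""Exception hierarchy shared by all sliceflex modules.

Every error raised by the package derives from :class:`SliceflexError`,
so callers (and the CLI) can map any failure to a one-line reason.
"""


class SliceflexError(Exception):
    """Base class for all errors raised by sliceflex."""


class FormatError(SliceflexError):
    """A file exists but is not in the expected format."""


class TagMissingError(SliceflexError, KeyError):
    """A requested DICOM tag is absent from the record."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return SliceflexError.__str__(self)


class ConfigValidationError(SliceflexError):
    """A configuration document violates an invariant."""


class ConfigParseError(SliceflexError):
    """A configuration document is not parseable."""


class RegistrationError(SliceflexError):
    """A compute plugin cannot be registered (missing hooks, duplicate id)."""


class EmptyDatasetError(SliceflexError):
    """No files matched the configured discovery patterns."""


class ConsistencyError(SliceflexError):
    """Loaded images are mutually inconsistent (slices, echoes, shapes)."""


class DispatchError(SliceflexError):
    """An event with an unknown name was dispatched."""


class TableError(SliceflexError):
    """A table entry call named an absent property or method."""


class ForwardVersionError(SliceflexError):
    """A stored session is newer than the running code."""


class MigrationError(SliceflexError):
    """A stored session is older than the code but no migration exists."""


class EmptyRoiError(SliceflexError):
    """A region of interest contains no pixels."""


class FitDataError(SliceflexError):
    """Fit input data are insufficient or invalid."""


class PasteError(SliceflexError):
    """ROI paste failed (empty clipboard or shape mismatch)."""


class NothingToExportError(SliceflexError):
    """Export requested but no ROI in the session has been fitted."""


class PhantomSpecError(SliceflexError):
    """A phantom specification is invalid."""
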
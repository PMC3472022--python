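"""Error taxonomy shared by every module.

Each error class carries a CLI exit code so the command-line front end can
map library failures 1:1 onto distinct process exit statuses.
"""

from __future__ import annotations


class MsReaderError(Exception):
    """Base class for all library errors."""

    exit_code = 1


class UnsupportedFormatError(MsReaderError):
    """The input is not one of the seven supported formats."""

    exit_code = 2


class VersionedFormatError(UnsupportedFormatError):
    """A persisted artifact (e.g. an index file) declares an unknown schema version."""


class MalformedRecordError(MsReaderError):
    """A single record violates its format grammar."""

    exit_code = 3


class CodecError(MalformedRecordError):
    """Base64 / binary / compression payload could not be decoded."""


class FormatDialectError(MalformedRecordError):
    """A lexical value (duration, charge string, ...) does not match the dialect."""

    def __init__(self, message: str, raw: str | None = None):
        super().__init__(message)
        self.raw = raw


class IntegrityError(MsReaderError):
    """Declared counts or lengths disagree with the decoded content."""

    exit_code = 4


class StaleIndexError(MsReaderError):
    """A persisted index no longer matches the file it was built from."""

    exit_code = 5


class ReferenceNotFoundError(MsReaderError):
    """A spectrum reference resolved to nothing under the reader's scheme."""

    exit_code = 6


class ReferenceFormatError(ReferenceNotFoundError):
    """A spectrum reference is syntactically invalid for the reader's scheme."""


class DialectWarning(UserWarning):
    """Recoverable deviation from the expected file dialect."""


class VersionWarning(DialectWarning):
    """The file declares a schema version outside the supported range."""
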
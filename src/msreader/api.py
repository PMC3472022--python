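"""The common reader interface over all seven formats.

One Reader abstraction exposes count, iteration, positional access and
the three-scheme ``get_spectrum_by_id`` dispatcher that mirrors how
mzIdentML references external spectra: by native id (mzData, mzXML,
mzML), by 0-based position (DTA, PKL, MS2, MGF), or by filename for
directories of single-spectrum DTA/PKL files.

Readers are immutable after opening and may be shared for concurrent
reads.
"""

from __future__ import annotations

import enum
import json
import os
import re
import warnings
from dataclasses import replace
from typing import Iterator

from . import formats_text, formats_xml
from .core import Spectrum
from .errors import (
    DialectWarning,
    MalformedRecordError,
    ReferenceFormatError,
    ReferenceNotFoundError,
    UnsupportedFormatError,
    VersionedFormatError,
)
from .index import (
    FileIndex,
    build_text_index,
    build_xml_index,
    load_index,
    read_span,
    save_index,
    verify_fingerprint,
)

__all__ = ["FormatId", "ReferenceScheme", "Reader", "DirectoryReader", "open_reader"]


class FormatId(str, enum.Enum):
    """The seven supported MS data formats."""

    DTA = "dta"
    PKL = "pkl"
    MGF = "mgf"
    MS2 = "ms2"
    MZXML = "mzxml"
    MZDATA = "mzdata"
    MZML = "mzml"


TEXT_FORMATS = frozenset({FormatId.DTA, FormatId.PKL, FormatId.MGF, FormatId.MS2})
XML_FORMATS = frozenset({FormatId.MZXML, FormatId.MZDATA, FormatId.MZML})
DIRECTORY_FORMATS = frozenset({FormatId.DTA, FormatId.PKL})


class ReferenceScheme(enum.Enum):
    """The three mzIdentML spectrum-referencing methods."""

    BY_ID = "id"
    BY_POSITION = "position"
    BY_FILENAME = "filename"


_SCHEME_FOR_FORMAT = {
    FormatId.MZXML: ReferenceScheme.BY_ID,
    FormatId.MZDATA: ReferenceScheme.BY_ID,
    FormatId.MZML: ReferenceScheme.BY_ID,
    FormatId.DTA: ReferenceScheme.BY_POSITION,
    FormatId.PKL: ReferenceScheme.BY_POSITION,
    FormatId.MGF: ReferenceScheme.BY_POSITION,
    FormatId.MS2: ReferenceScheme.BY_POSITION,
}

_EXTENSION_MAP = {
    ".dta": FormatId.DTA,
    ".pkl": FormatId.PKL,
    ".mgf": FormatId.MGF,
    ".ms2": FormatId.MS2,
    ".mzxml": FormatId.MZXML,
    ".mzdata": FormatId.MZDATA,
    ".mzml": FormatId.MZML,
}

DIR_INDEX_SCHEMA = "msreader-index-dir/1"


def _sniff_content(path) -> FormatId | None:
    with open(path, "rb") as fh:
        head = fh.read(4096)
    text = head.decode("utf-8", errors="replace")
    if re.search(r"<(?:\w+:)?mzXML\b", text):
        return FormatId.MZXML
    if re.search(r"<(?:\w+:)?mzData\b", text):
        return FormatId.MZDATA
    if re.search(r"<(?:\w+:)?(?:indexed)?mzML\b", text):
        return FormatId.MZML
    if "BEGIN IONS" in text.upper():
        return FormatId.MGF
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if lines:
        first = lines[0].split()
        if first[0] in ("H", "S"):
            return FormatId.MS2
        numeric = []
        for tok in first:
            try:
                float(tok)
                numeric.append(tok)
            except ValueError:
                return None
        if len(numeric) == 2:
            return FormatId.DTA
        if len(numeric) == 3:
            return FormatId.PKL
    return None


def sniff_format(path) -> FormatId:
    """Guess the format: extension map first, content probe second.

    When extension and content disagree, content wins with a warning.
    """
    ext = os.path.splitext(str(path))[1].lower()
    by_ext = _EXTENSION_MAP.get(ext)
    by_content = _sniff_content(path)
    if by_content is not None and by_ext is not None and by_content != by_ext:
        # DTA and PKL content probes are arity heuristics; trust the extension there
        if by_content in (FormatId.DTA, FormatId.PKL) and by_ext in (FormatId.DTA, FormatId.PKL):
            return by_ext
        warnings.warn(
            f"extension suggests {by_ext.value} but content looks like "
            f"{by_content.value}; using content",
            DialectWarning,
            stacklevel=2,
        )
        return by_content
    if by_content is not None:
        return by_content
    if by_ext is not None:
        return by_ext
    raise UnsupportedFormatError(f"cannot determine the format of {path}")


class Reader:
    """Open handle on one MS data file, backed by a byte-range index."""

    def __init__(
        self,
        path: str,
        format: FormatId,
        index: FileIndex,
        mode: str = "lenient",
        dialect: formats_xml.XmlDialect | None = None,
    ):
        self.path = str(path)
        self.format = format
        self.index = index
        self.mode = mode
        self.dialect = dialect
        self.scheme = _SCHEME_FOR_FORMAT[format]
        self._lenient = mode != "strict"
        self._by_native: dict[str, int] = {}
        for rec in index.records:
            if rec.native_id is not None:
                self._by_native[rec.native_id] = rec.position
                if format is FormatId.MZXML and rec.native_id.isdigit():
                    # scan numbers match as canonical integer text too
                    self._by_native.setdefault(str(int(rec.native_id)), rec.position)
        self._mgf_globals = None
        self._ms2_header = None
        if format is FormatId.MGF:
            header = b""
            if index.header_span is not None:
                header = read_span(self.path, index.header_span)
            self._mgf_globals = formats_text.parse_mgf_header(header)
        elif format is FormatId.MS2:
            header = b""
            if index.header_span is not None:
                header = read_span(self.path, index.header_span)
            self._ms2_header = formats_text.parse_ms2_header(header)

    # -- counts and ids ----------------------------------------------------

    @property
    def count(self) -> int:
        return len(self.index.records)

    def get_spectra_count(self) -> int:
        return self.count

    def get_spectra_ids(self) -> list[str]:
        """Spectrum references valid under this reader's scheme."""
        if self.scheme is ReferenceScheme.BY_ID:
            return [rec.native_id or str(rec.position) for rec in self.index.records]
        return [str(rec.position) for rec in self.index.records]

    # -- record access -----------------------------------------------------

    def _parse_record(self, data: bytes, position: int) -> Spectrum:
        fmt = self.format
        if fmt is FormatId.DTA:
            s = formats_text.parse_dta_block(data, self.path, position, self._lenient)
        elif fmt is FormatId.PKL:
            s = formats_text.parse_pkl_block(data, self.path, position, self._lenient)
        elif fmt is FormatId.MGF:
            s = formats_text.parse_mgf_block(
                data, self._mgf_globals, self.path, position, self._lenient
            )
        elif fmt is FormatId.MS2:
            s = formats_text.parse_ms2_record(
                data, self._ms2_header, self.path, position, self._lenient
            )
        elif fmt is FormatId.MZXML:
            s = formats_xml.parse_mzxml_scan(data, self.dialect, position)
        elif fmt is FormatId.MZDATA:
            s = formats_xml.parse_mzdata_spectrum(data, self.dialect, position)
        else:
            s = formats_xml.parse_mzml_spectrum(data, self.dialect, position)
        if s.source != self.path:
            s = replace(s, source=self.path)
        return s

    def get_spectrum_by_index(self, position: int) -> Spectrum:
        """The ``position``-th (0-based) spectrum, via its byte span only."""
        if not 0 <= position < self.count:
            raise ReferenceNotFoundError(
                f"position {position} out of range: {self.path} holds {self.count} spectra"
            )
        span = self.index.records[position]
        return self._parse_record(read_span(self.path, span), position)

    def get_spectrum_by_id(self, spectrum_id: str) -> Spectrum:
        """Resolve a reference under this reader's scheme and fetch it."""
        if not spectrum_id:
            raise ReferenceFormatError("empty spectrum reference")
        if self.scheme is ReferenceScheme.BY_ID:
            position = self._by_native.get(spectrum_id)
            if position is None and self.format is FormatId.MZXML and spectrum_id.isdigit():
                position = self._by_native.get(str(int(spectrum_id)))
            if position is None:
                raise ReferenceNotFoundError(
                    f"no spectrum with native id {spectrum_id!r} in {self.path} (scheme: id)"
                )
            return self.get_spectrum_by_index(position)
        try:
            position = int(spectrum_id, 10)
        except ValueError:
            raise ReferenceFormatError(
                f"reference {spectrum_id!r} is not a 0-based position "
                f"(scheme: position for {self.format.value})"
            ) from None
        try:
            return self.get_spectrum_by_index(position)
        except ReferenceNotFoundError:
            raise ReferenceNotFoundError(
                f"no spectrum at position {spectrum_id} in {self.path} (scheme: position)"
            ) from None

    def iterate(self) -> Iterator[Spectrum]:
        """Lazily yield all spectra; lenient mode skips malformed records."""
        for position in range(self.count):
            try:
                yield self.get_spectrum_by_index(position)
            except MalformedRecordError:
                if not self._lenient:
                    raise
                warnings.warn(
                    f"skipping malformed record {position} of {self.path}",
                    DialectWarning,
                    stacklevel=2,
                )

    def __iter__(self) -> Iterator[Spectrum]:
        return self.iterate()

    def __len__(self) -> int:
        return self.count

    def export_index(self) -> str:
        """JSON document that lets a later open skip the indexing scan."""
        return save_index(self.index)


class DirectoryReader:
    """Reader over a directory of single-spectrum DTA or PKL files.

    Files are ordered lexicographically; references resolve by filename
    (with or without extension) or by 0-based position.
    """

    def __init__(self, directory: str, format: FormatId, mode: str = "lenient"):
        if format not in DIRECTORY_FORMATS:
            raise UnsupportedFormatError(
                f"directories are only supported for DTA/PKL, not {format.value}"
            )
        self.path = str(directory)
        self.format = format
        self.mode = mode
        self.scheme = ReferenceScheme.BY_FILENAME
        self._lenient = mode != "strict"
        ext = f".{format.value}"
        self.files = sorted(
            name
            for name in os.listdir(directory)
            if name.lower().endswith(ext)
            and os.path.isfile(os.path.join(directory, name))
        )
        self._by_name: dict[str, int] = {}
        for i, name in enumerate(self.files):
            self._by_name[name] = i
            self._by_name.setdefault(os.path.splitext(name)[0], i)

    @property
    def count(self) -> int:
        return len(self.files)

    def get_spectra_count(self) -> int:
        return self.count

    def get_spectra_ids(self) -> list[str]:
        return list(self.files)

    def _parse_file(self, name: str, position: int) -> Spectrum:
        filepath = os.path.join(self.path, name)
        with open(filepath, "r", encoding="utf-8", errors="replace") as fh:
            text = fh.read()
        if self.format is FormatId.DTA:
            s = formats_text.parse_dta_block(text, filepath, 0, self._lenient)
        else:
            s = formats_text.parse_pkl_block(text, filepath, 0, self._lenient)
        return replace(s, position=position)

    def get_spectrum_by_index(self, position: int) -> Spectrum:
        if not 0 <= position < self.count:
            raise ReferenceNotFoundError(
                f"position {position} out of range: {self.path} holds {self.count} files"
            )
        return self._parse_file(self.files[position], position)

    def get_spectrum_by_id(self, spectrum_id: str) -> Spectrum:
        position = self._by_name.get(spectrum_id)
        if position is None:
            raise ReferenceNotFoundError(
                f"no file named {spectrum_id!r} in {self.path} (scheme: filename)"
            )
        return self.get_spectrum_by_index(position)

    def iterate(self) -> Iterator[Spectrum]:
        for position in range(self.count):
            try:
                yield self.get_spectrum_by_index(position)
            except MalformedRecordError:
                if not self._lenient:
                    raise
                warnings.warn(
                    f"skipping malformed file {self.files[position]!r}",
                    DialectWarning,
                    stacklevel=2,
                )

    def __iter__(self) -> Iterator[Spectrum]:
        return self.iterate()

    def __len__(self) -> int:
        return self.count

    def export_index(self) -> str:
        """Per-file index map: every member file indexed individually."""
        files = {}
        for name in self.files:
            ix = build_text_index(os.path.join(self.path, name), self.format.value)
            files[name] = json.loads(save_index(ix))
        return json.dumps(
            {"version": DIR_INDEX_SCHEMA, "format": self.format.value, "files": files},
            indent=1,
        )


def _warn_on_declared_count(path: str, format: FormatId, found: int) -> None:
    # files lie about their counts; mismatch is a warning, not an error
    with open(path, "rb") as fh:
        head = fh.read(4096).decode("utf-8", errors="replace")
    m = None
    if format is FormatId.MZXML:
        m = re.search(r'scanCount\s*=\s*["\'](\d+)["\']', head)
    else:
        m = re.search(r'<(?:\w+:)?spectrumList[^>]*\bcount\s*=\s*["\'](\d+)["\']', head)
    if m and int(m.group(1)) != found:
        warnings.warn(
            f"{path} declares {m.group(1)} spectra but {found} were indexed",
            DialectWarning,
            stacklevel=3,
        )


def open_reader(
    path,
    format: FormatId | str | None = None,
    saved_index: FileIndex | str | None = None,
    mode: str = "lenient",
) -> Reader | DirectoryReader:
    """Open a file (or a DTA/PKL directory) behind the common interface.

    ``saved_index`` (a FileIndex or its JSON text) skips the indexing
    scan; its fingerprint is verified against the file first and a
    mismatch raises StaleIndexError.
    """
    path = os.fspath(path)
    if isinstance(format, str):
        format = FormatId(format.lower())

    if os.path.isdir(path):
        if format is None:
            exts = {os.path.splitext(n)[1].lower() for n in os.listdir(path)}
            if ".dta" in exts and ".pkl" not in exts:
                format = FormatId.DTA
            elif ".pkl" in exts and ".dta" not in exts:
                format = FormatId.PKL
            else:
                raise UnsupportedFormatError(
                    f"cannot infer a unique DTA/PKL format for directory {path}"
                )
        return DirectoryReader(path, format, mode)

    if not os.path.isfile(path):
        raise FileNotFoundError(path)
    if format is None:
        format = sniff_format(path)

    dialect = None
    if format in XML_FORMATS:
        dialect = formats_xml.detect_dialect(path)
        if FormatId(dialect.format) is not format:
            warnings.warn(
                f"requested format {format.value} but content is {dialect.format}; "
                "using content",
                DialectWarning,
                stacklevel=2,
            )
            format = FormatId(dialect.format)

    index = None
    if saved_index is not None:
        ix = load_index(saved_index) if isinstance(saved_index, str) else saved_index
        if ix.format != format.value:
            raise VersionedFormatError(
                f"saved index is for format {ix.format!r}, file is {format.value!r}"
            )
        verify_fingerprint(path, ix)
        index = ix
    if index is None:
        if format in TEXT_FORMATS:
            index = build_text_index(path, format.value)
        else:
            index = build_xml_index(path, format.value)
            _warn_on_declared_count(path, format, len(index.records))

    return Reader(path, format, index, mode, dialect)
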
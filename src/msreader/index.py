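"""Random-access machinery: build byte-range indexes over text and XML MS
data files by buffered streaming, fetch single records by span, and
persist/restore indexes as versioned JSON.

The scan never loads the whole file: it reads fixed-size chunks (1 MiB)
and keeps only bounded state. XML indexing is byte-pattern based (tag
scanning with quote awareness), not a DOM parse. For mzXML, nested
``<scan>`` elements are indexed individually in document order, so spans
of a parent and its children may nest; spans of text formats never
overlap.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import warnings
from dataclasses import dataclass, field
from typing import BinaryIO, Iterator

from .errors import (
    IntegrityError,
    MalformedRecordError,
    StaleIndexError,
    VersionedFormatError,
)

__all__ = [
    "INDEX_SCHEMA",
    "CHUNK_SIZE",
    "RecordSpan",
    "FileIndex",
    "fingerprint_file",
    "build_text_index",
    "build_xml_index",
    "read_span",
    "save_index",
    "load_index",
]

INDEX_SCHEMA = "msreader-index/1"
CHUNK_SIZE = 1 << 20  # 1 MiB buffered reads
_FP_PROBE = 8 * 1024  # fingerprint hashes the first and last 8 KiB


@dataclass(frozen=True)
class RecordSpan:
    """Byte range of one spectrum record: [start, start+length)."""

    start: int
    length: int
    position: int
    native_id: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"span start must be >= 0, got {self.start}")
        if self.length <= 0:
            raise ValueError(f"span length must be > 0, got {self.length}")
        if self.position < 0:
            raise ValueError(f"span position must be >= 0, got {self.position}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class FileIndex:
    """Byte-range index of all spectrum records in one source file."""

    path: str
    format: str
    file_size: int
    fingerprint: str
    records: list[RecordSpan] = field(default_factory=list)
    header_span: RecordSpan | None = None

    def __len__(self) -> int:
        return len(self.records)


def fingerprint_file(path: str | os.PathLike) -> tuple[int, str]:
    """Best-effort identity of a file: (size, size:sha1(head):sha1(tail)).

    Only the first and last 8 KiB are hashed so that fingerprinting stays
    O(1) for arbitrarily large files.
    """
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(_FP_PROBE)
        if size > _FP_PROBE:
            fh.seek(max(size - _FP_PROBE, 0))
            tail = fh.read(_FP_PROBE)
        else:
            tail = head
    fp = f"{size}:{hashlib.sha1(head).hexdigest()}:{hashlib.sha1(tail).hexdigest()}"
    return size, fp


def verify_fingerprint(path: str | os.PathLike, ix: FileIndex) -> None:
    """Raise StaleIndexError if ``path`` no longer matches the index."""
    size, fp = fingerprint_file(path)
    if size != ix.file_size or fp != ix.fingerprint:
        raise StaleIndexError(
            f"index is stale for {path}: file changed since indexing (re-index required)"
        )


def _iter_raw_lines(fh: BinaryIO) -> Iterator[tuple[int, bytes]]:
    """Yield (byte offset, raw line incl. terminator) reading in 1 MiB chunks."""
    offset = 0
    pending = b""
    while True:
        chunk = fh.read(CHUNK_SIZE)
        if not chunk:
            break
        pending += chunk
        lines = pending.splitlines(keepends=True)
        # the final piece may be an incomplete line, or end in a bare \r
        # whose \n could arrive with the next chunk
        if lines and (not lines[-1].endswith((b"\n", b"\r")) or lines[-1].endswith(b"\r")):
            pending = lines.pop()
        else:
            pending = b""
        for ln in lines:
            yield offset, ln
            offset += len(ln)
    if pending:
        yield offset, pending


def _line_end(offset: int, raw: bytes) -> int:
    return offset + len(raw)


def build_text_index(path: str | os.PathLike, format: str) -> FileIndex:
    """Index the spectrum records of a DTA/PKL/MGF/MS2 file.

    MGF records span BEGIN IONS..END IONS inclusive; MS2 records run from
    an S-line to the line before the next S-line; DTA/PKL records are
    contiguous non-blank blocks. Pre-record content (MGF global params,
    MS2 H-lines) becomes the header span, trimmed to non-blank lines.
    """
    fmt = format.lower()
    if fmt not in ("dta", "pkl", "mgf", "ms2"):
        raise ValueError(f"build_text_index does not handle format {format!r}")
    path = os.fspath(path)
    size, fp = fingerprint_file(path)

    raw_spans: list[tuple[int, int]] = []
    header: tuple[int, int] | None = None

    with open(path, "rb") as fh:
        if fmt == "mgf":
            raw_spans, header = _scan_mgf(fh)
        elif fmt == "ms2":
            raw_spans, header = _scan_ms2(fh)
        else:
            raw_spans = _scan_blocks(fh)

    records = [
        RecordSpan(start=s, length=e - s, position=i)
        for i, (s, e) in enumerate(raw_spans)
    ]
    header_span = None
    if header is not None:
        hs, he = header
        if he > hs:
            header_span = RecordSpan(start=hs, length=he - hs, position=0)
    if not records and size > 0:
        warnings.warn(f"no spectrum records found in non-empty file {path}", stacklevel=2)
    return FileIndex(
        path=path, format=fmt, file_size=size, fingerprint=fp,
        records=records, header_span=header_span,
    )


def _scan_mgf(fh: BinaryIO) -> tuple[list[tuple[int, int]], tuple[int, int] | None]:
    spans: list[tuple[int, int]] = []
    in_block = False
    block_start = 0
    first_block_start: int | None = None
    header_start: int | None = None
    header_end = 0
    end = 0
    for offset, raw in _iter_raw_lines(fh):
        end = _line_end(offset, raw)
        stripped = raw.strip().upper()
        if not in_block:
            if stripped.startswith(b"BEGIN IONS"):
                in_block = True
                block_start = offset
                if first_block_start is None:
                    first_block_start = offset
            elif first_block_start is None and raw.strip():
                if header_start is None:
                    header_start = offset
                header_end = end
        else:
            if stripped.startswith(b"END IONS"):
                spans.append((block_start, end))
                in_block = False
            elif stripped.startswith(b"BEGIN IONS"):
                # missing END IONS: close the broken block at this boundary
                spans.append((block_start, offset))
                block_start = offset
    if in_block:
        spans.append((block_start, end))
    header = (header_start, header_end) if header_start is not None else None
    return spans, header


def _scan_ms2(fh: BinaryIO) -> tuple[list[tuple[int, int]], tuple[int, int] | None]:
    spans: list[tuple[int, int]] = []
    record_start: int | None = None
    last_nonblank_end = 0
    header_start: int | None = None
    header_end = 0
    for offset, raw in _iter_raw_lines(fh):
        end = _line_end(offset, raw)
        stripped = raw.strip()
        is_s_line = stripped[:1] == b"S" and (len(stripped) == 1 or stripped[1:2] in (b" ", b"\t"))
        if is_s_line:
            if record_start is not None:
                spans.append((record_start, last_nonblank_end))
            record_start = offset
            last_nonblank_end = end
        elif record_start is None:
            if stripped:
                if header_start is None:
                    header_start = offset
                header_end = end
        elif stripped:
            last_nonblank_end = end
    if record_start is not None:
        spans.append((record_start, last_nonblank_end))
    header = (header_start, header_end) if header_start is not None else None
    return spans, header


def _scan_blocks(fh: BinaryIO) -> list[tuple[int, int]]:
    """Contiguous non-blank blocks (DTA / PKL); blank runs collapse to one separator."""
    spans: list[tuple[int, int]] = []
    block_start: int | None = None
    last_nonblank_end = 0
    for offset, raw in _iter_raw_lines(fh):
        if raw.strip():
            if block_start is None:
                block_start = offset
            last_nonblank_end = _line_end(offset, raw)
        else:
            if block_start is not None:
                spans.append((block_start, last_nonblank_end))
                block_start = None
    if block_start is not None:
        spans.append((block_start, last_nonblank_end))
    return spans


# --- XML element scanning -------------------------------------------------

_XML_ID_ATTRS = {"mzxml": "num", "mzdata": "id", "mzml": "id"}
_XML_RECORD_TAGS = {"mzxml": "scan", "mzdata": "spectrum", "mzml": "spectrum"}

_ATTR_RE = re.compile(rb'([A-Za-z_][\w.:-]*)\s*=\s*(?:"([^"]*)"|\'([^\']*)\')')


def _find_tag_close(buf: bytes, pos: int) -> int:
    """Index of the '>' ending the tag opened before ``pos``; -1 if absent.

    Quote-aware: '>' inside single- or double-quoted attribute values is
    skipped.
    """
    quote = 0
    n = len(buf)
    while pos < n:
        c = buf[pos]
        if quote:
            if c == quote:
                quote = 0
        elif c in (34, 39):  # " '
            quote = c
        elif c == 62:  # >
            return pos
        pos += 1
    return -1


def scan_xml_element_spans(
    path: str | os.PathLike, localname: str
) -> list[tuple[int, int, bytes]]:
    """Byte spans of every ``<localname>`` element, in document order.

    Returns (start, end_exclusive, opening_tag_bytes) triples sorted by
    start offset. Same-name nesting (mzXML scans) is handled by depth
    counting; self-closing elements are accepted. The file is streamed in
    1 MiB chunks with a bounded carry-over buffer.
    """
    pattern = re.compile(
        rb"<(/?)(?:[A-Za-z_][\w.-]*:)?" + re.escape(localname.encode()) + rb"(?=[\s/>])"
    )
    spans: list[tuple[int, int, bytes]] = []
    stack: list[tuple[int, bytes]] = []
    buf = b""
    base = 0  # absolute offset of buf[0]
    processed = 0  # absolute offset below which every tag start is consumed
    overlap = len(localname) + 64
    with open(path, "rb") as fh:
        eof = False
        while True:
            if not eof:
                chunk = fh.read(CHUNK_SIZE)
                if chunk:
                    buf += chunk
                else:
                    eof = True
            incomplete_at: int | None = None
            for m in pattern.finditer(buf):
                abs_start = base + m.start()
                if abs_start < processed:
                    continue
                close = _find_tag_close(buf, m.end())
                if close < 0:
                    if eof:
                        raise MalformedRecordError(
                            f"unterminated tag at byte {abs_start} in {path}"
                        )
                    incomplete_at = m.start()
                    break
                tag = buf[m.start() : close + 1]
                if m.group(1):  # closing tag
                    if stack:
                        start, open_tag = stack.pop()
                        spans.append((start, base + close + 1, open_tag))
                elif tag.rstrip().endswith(b"/>"):
                    spans.append((abs_start, base + close + 1, tag))
                else:
                    stack.append((abs_start, tag))
                processed = base + close + 1
            if incomplete_at is not None:
                cut = incomplete_at
            else:
                cut = max(len(buf) - overlap, 0)
            base += cut
            buf = buf[cut:]
            if eof and incomplete_at is None:
                break
    if stack:
        raise IntegrityError(
            f"truncated <{localname}> element starting at byte {stack[0][0]} in {path}"
        )
    spans.sort(key=lambda t: t[0])
    return spans


def parse_tag_attributes(tag: bytes) -> dict[str, str]:
    """Attribute name->value mapping of one opening tag's raw bytes."""
    out: dict[str, str] = {}
    for m in _ATTR_RE.finditer(tag):
        value = m.group(2) if m.group(2) is not None else m.group(3)
        out[m.group(1).decode("ascii", "replace")] = value.decode("utf-8", "replace")
    return out


def build_xml_index(path: str | os.PathLike, format: str) -> FileIndex:
    """Index ``<scan>`` (mzXML) or ``<spectrum>`` (mzData/mzML) elements.

    native_id is taken from the scan ``num`` (mzXML) or spectrum ``id``
    attribute of each opening tag. Nested mzXML scans are flattened in
    document order.
    """
    fmt = format.lower()
    if fmt not in _XML_RECORD_TAGS:
        raise ValueError(f"build_xml_index does not handle format {format!r}")
    path = os.fspath(path)
    size, fp = fingerprint_file(path)
    tag = _XML_RECORD_TAGS[fmt]
    id_attr = _XML_ID_ATTRS[fmt]
    records = []
    seen_ids: set[str] = set()
    for i, (start, end, open_tag) in enumerate(scan_xml_element_spans(path, tag)):
        attrs = parse_tag_attributes(open_tag)
        native_id = attrs.get(id_attr)
        if native_id is not None:
            if native_id in seen_ids:
                raise IntegrityError(f"duplicate native id {native_id!r} in {path}")
            seen_ids.add(native_id)
        records.append(
            RecordSpan(start=start, length=end - start, position=i, native_id=native_id)
        )
    return FileIndex(path=path, format=fmt, file_size=size, fingerprint=fp, records=records)


def read_span(path: str | os.PathLike, span: RecordSpan) -> bytes:
    """Read exactly the bytes of one record span."""
    size = os.path.getsize(path)
    if span.end > size:
        raise StaleIndexError(
            f"span [{span.start}, {span.end}) lies beyond EOF ({size} bytes) of {path}; "
            "re-index the file"
        )
    with open(path, "rb") as fh:
        fh.seek(span.start)
        data = fh.read(span.length)
    if len(data) != span.length:
        raise StaleIndexError(f"short read for span at {span.start} in {path}; re-index")
    return data


def _span_to_dict(span: RecordSpan) -> dict:
    d = {"start": span.start, "length": span.length, "position": span.position}
    if span.native_id is not None:
        d["native_id"] = span.native_id
    return d


def _span_from_dict(d: dict) -> RecordSpan:
    return RecordSpan(
        start=d["start"], length=d["length"], position=d["position"],
        native_id=d.get("native_id"),
    )


def save_index(ix: FileIndex) -> str:
    """Serialize a FileIndex to its versioned JSON document."""
    doc = {
        "version": INDEX_SCHEMA,
        "path": ix.path,
        "format": ix.format,
        "file_size": ix.file_size,
        "fingerprint": ix.fingerprint,
        "records": [_span_to_dict(r) for r in ix.records],
    }
    if ix.header_span is not None:
        doc["header_span"] = _span_to_dict(ix.header_span)
    return json.dumps(doc, indent=1)


def load_index(text: str) -> FileIndex:
    """Parse the JSON produced by :func:`save_index`; bit-exact round trip."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise VersionedFormatError(f"index document is not valid JSON: {exc}") from exc
    version = doc.get("version")
    if version != INDEX_SCHEMA:
        raise VersionedFormatError(
            f"unsupported index schema {version!r}; expected {INDEX_SCHEMA!r}"
        )
    header = doc.get("header_span")
    return FileIndex(
        path=doc["path"],
        format=doc["format"],
        file_size=doc["file_size"],
        fingerprint=doc["fingerprint"],
        records=[_span_from_dict(d) for d in doc["records"]],
        header_span=_span_from_dict(header) if header is not None else None,
    )
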
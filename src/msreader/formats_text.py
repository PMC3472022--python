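"""Parsers and writers for the four text peak-list formats: DTA, PKL,
MGF and MS2.

Each record parser consumes the text of one record (as cut out by the
index module) and is usable standalone; sequential whole-file readers
are provided as an independent access route. Both ``\\n`` and ``\\r\\n``
line endings are accepted; output is always ``\\n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .codec import mh_to_mz, parse_charge
from .core import ParamEntry, Peak, PrecursorInfo, Spectrum, normalize_spectrum
from .errors import DialectWarning, MalformedRecordError

__all__ = [
    "MgfGlobalParams",
    "parse_dta_block",
    "parse_pkl_block",
    "parse_mgf_block",
    "parse_mgf_header",
    "parse_ms2_record",
    "parse_ms2_header",
    "read_dta",
    "read_pkl",
    "read_mgf",
    "read_ms2",
    "write_mgf",
]

_MGF_COMMENT_PREFIXES = ("#", ";", "!", "/")


@dataclass
class MgfGlobalParams:
    """KEY=VALUE entries appearing before the first BEGIN IONS block."""

    entries: list[ParamEntry] = field(default_factory=list)

    def get(self, key: str) -> str | None:
        key = key.upper()
        for e in self.entries:
            if e.name == key:
                return e.value
        return None


def _to_text(data: str | bytes) -> str:
    if isinstance(data, bytes):
        return data.decode("utf-8", errors="replace")
    return data


def _float(token: str, source: str, position: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise MalformedRecordError(
            f"non-numeric {what} {token!r} in {source} position {position}"
        ) from None


def _int(token: str, source: str, position: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise MalformedRecordError(
            f"non-integer {what} {token!r} in {source} position {position}"
        ) from None


def _parse_peak_lines(
    lines: Iterable[str],
    source: str,
    position: int,
    lenient: bool,
    allow_charge: bool = False,
) -> list[Peak]:
    peaks: list[Peak] = []
    for line in lines:
        tokens = line.split()
        if not tokens:
            continue
        ok = len(tokens) == 2 or (allow_charge and len(tokens) == 3)
        if ok:
            try:
                mz = float(tokens[0])
                intensity = float(tokens[1])
                charge = None
                if len(tokens) == 3:
                    charge = parse_charge(tokens[2])[0]
                peaks.append(Peak(mz=mz, intensity=intensity, charge=charge))
                continue
            except (ValueError, MalformedRecordError):
                pass
        if lenient:
            warnings.warn(
                f"skipping malformed peak line {line!r} in {source} position {position}",
                DialectWarning,
                stacklevel=3,
            )
        else:
            raise MalformedRecordError(
                f"malformed peak line {line!r} in {source} position {position}"
            )
    return peaks


def parse_dta_block(
    data: str | bytes, source: str, position: int, lenient: bool = True
) -> Spectrum:
    """Parse one DTA block: an ``MH+ charge`` header line then peak pairs.

    The header's (M+H)+ value is kept verbatim in extras; the common
    interface exposes the computed precursor m/z.
    """
    lines = [ln for ln in _to_text(data).splitlines() if ln.strip()]
    if not lines:
        raise MalformedRecordError(f"empty DTA block in {source} position {position}")
    head = lines[0].split()
    if len(head) != 2:
        raise MalformedRecordError(
            f"DTA header needs exactly 2 tokens, got {len(head)} in {source} position {position}"
        )
    mh = _float(head[0], source, position, "MH+")
    z = _int(head[1], source, position, "charge")
    precursor = PrecursorInfo(mz=mh_to_mz(mh, z), mh_plus=mh, charges=[z])
    peaks = _parse_peak_lines(lines[1:], source, position, lenient)
    spectrum = Spectrum(
        source=source,
        position=position,
        precursor=precursor,
        peaks=peaks,
        extras=[ParamEntry("MH+", head[0]), ParamEntry("CHARGE", head[1])],
    )
    return normalize_spectrum(spectrum)


def parse_pkl_block(
    data: str | bytes, source: str, position: int, lenient: bool = True
) -> Spectrum:
    """Parse one PKL block: ``m/z intensity charge`` header then peak pairs."""
    lines = [ln for ln in _to_text(data).splitlines() if ln.strip()]
    if not lines:
        raise MalformedRecordError(f"empty PKL block in {source} position {position}")
    head = lines[0].split()
    if len(head) != 3:
        raise MalformedRecordError(
            f"PKL header needs exactly 3 tokens, got {len(head)} in {source} position {position}"
        )
    precursor = PrecursorInfo(
        mz=_float(head[0], source, position, "precursor m/z"),
        intensity=_float(head[1], source, position, "precursor intensity"),
        charges=[_int(head[2], source, position, "charge")],
    )
    peaks = _parse_peak_lines(lines[1:], source, position, lenient)
    spectrum = Spectrum(source=source, position=position, precursor=precursor, peaks=peaks)
    return normalize_spectrum(spectrum)


def parse_mgf_header(data: str | bytes) -> MgfGlobalParams:
    """Parse the KEY=VALUE lines preceding the first BEGIN IONS block."""
    entries: list[ParamEntry] = []
    for line in _to_text(data).splitlines():
        line = line.strip()
        if not line or line.startswith(_MGF_COMMENT_PREFIXES):
            continue
        if "=" in line:
            key, _, value = line.partition("=")
            entries.append(ParamEntry(key.strip().upper(), value.strip()))
    return MgfGlobalParams(entries=entries)


def parse_mgf_block(
    data: str | bytes,
    global_params: MgfGlobalParams | None,
    source: str,
    position: int,
    lenient: bool = True,
) -> Spectrum:
    """Parse one BEGIN IONS..END IONS block.

    Local KEY=VALUE params precede the peak lines; a local CHARGE
    overrides the file-level default. Comment lines (#, ;, !, /) are
    ignored. A missing PEPMASS yields a valid spectrum with no precursor.
    """
    lines = _to_text(data).splitlines()
    stripped = [ln.strip() for ln in lines]
    try:
        begin = next(i for i, ln in enumerate(stripped) if ln.upper().startswith("BEGIN IONS"))
    except StopIteration:
        raise MalformedRecordError(
            f"no BEGIN IONS in block at {source} position {position}"
        ) from None
    end = None
    for i in range(len(stripped) - 1, begin, -1):
        if stripped[i].upper().startswith("END IONS"):
            end = i
            break
    if end is None:
        raise MalformedRecordError(f"missing END IONS in {source} position {position}")

    pepmass_mz: float | None = None
    pepmass_intensity: float | None = None
    charges: list[int] | None = None
    retention: float | None = None
    extras: list[ParamEntry] = []
    peak_lines: list[str] = []

    for line in stripped[begin + 1 : end]:
        if not line or line.startswith(_MGF_COMMENT_PREFIXES):
            continue
        key, sep, value = line.partition("=")
        if sep and not key[0].isdigit():
            key = key.strip().upper()
            value = value.strip()
            if key == "PEPMASS":
                tokens = value.split()
                if tokens:
                    pepmass_mz = _float(tokens[0], source, position, "PEPMASS m/z")
                if len(tokens) > 1:
                    pepmass_intensity = _float(
                        tokens[1], source, position, "PEPMASS intensity"
                    )
            elif key == "CHARGE":
                charges = parse_charge(value)
            elif key == "RTINSECONDS":
                retention = _float(value, source, position, "RTINSECONDS")
            extras.append(ParamEntry(key, value))
        else:
            peak_lines.append(line)

    if charges is None and global_params is not None:
        default = global_params.get("CHARGE")
        if default:
            charges = parse_charge(default)

    precursor = None
    if pepmass_mz is not None:
        precursor = PrecursorInfo(
            mz=pepmass_mz, intensity=pepmass_intensity, charges=list(charges or [])
        )
    peaks = _parse_peak_lines(peak_lines, source, position, lenient, allow_charge=True)
    spectrum = Spectrum(
        source=source,
        position=position,
        ms_level=2,
        retention_seconds=retention,
        precursor=precursor,
        peaks=peaks,
        extras=extras,
    )
    return normalize_spectrum(spectrum)


def parse_ms2_header(data: str | bytes) -> list[ParamEntry]:
    """Parse MS2 H-lines into file-level params attached to every spectrum."""
    entries: list[ParamEntry] = []
    for line in _to_text(data).splitlines():
        tokens = line.strip().split(None, 2)
        if tokens and tokens[0] == "H":
            name = tokens[1] if len(tokens) > 1 else ""
            value = tokens[2] if len(tokens) > 2 else None
            if name:
                entries.append(ParamEntry(name, value))
    return entries


def parse_ms2_record(
    data: str | bytes | Iterable[str],
    header: list[ParamEntry] | None,
    source: str,
    position: int,
    lenient: bool = True,
) -> Spectrum:
    """Parse one MS2 record: S-line, optional I/Z/D lines, then peaks.

    Every Z-line contributes one precursor charge; Z-line (M+H)+ masses,
    I- and D-lines and the scan numbers are preserved in extras. A D-line
    before any Z-line is a dialect deviation: warned about, kept.
    """
    if isinstance(data, (str, bytes)):
        lines = _to_text(data).splitlines()
    else:
        lines = list(data)
    extras: list[ParamEntry] = list(header or [])
    s_line = None
    charges: list[int] = []
    peak_lines: list[str] = []
    seen_z = False
    for line in lines:
        tokens = line.strip().split()
        if not tokens:
            continue
        tag = tokens[0]
        if tag == "S" and s_line is None:
            if len(tokens) < 4:
                raise MalformedRecordError(
                    f"S-line needs 4 fields in {source} position {position}: {line!r}"
                )
            s_line = tokens
        elif tag == "Z":
            if len(tokens) < 3:
                raise MalformedRecordError(
                    f"Z-line needs charge and mass in {source} position {position}: {line!r}"
                )
            charges.append(_int(tokens[1], source, position, "Z-line charge"))
            extras.append(ParamEntry("Z", f"{tokens[1]} {tokens[2]}"))
            seen_z = True
        elif tag == "I":
            name = tokens[1] if len(tokens) > 1 else ""
            extras.append(ParamEntry(name, " ".join(tokens[2:]) or None))
        elif tag == "D":
            if not seen_z and lenient:
                warnings.warn(
                    f"D-line before any Z-line in {source} position {position}",
                    DialectWarning,
                    stacklevel=2,
                )
            extras.append(ParamEntry("D", " ".join(tokens[1:]) or None))
        else:
            peak_lines.append(line)
    if s_line is None:
        raise MalformedRecordError(f"MS2 record without S-line in {source} position {position}")
    first_scan, last_scan = s_line[1], s_line[2]
    prec_mz = _float(s_line[3], source, position, "precursor m/z")
    extras.insert(0, ParamEntry("lastScan", last_scan))
    extras.insert(0, ParamEntry("firstScan", first_scan))
    precursor = PrecursorInfo(mz=prec_mz, charges=charges)
    peaks = _parse_peak_lines(peak_lines, source, position, lenient)
    spectrum = Spectrum(
        source=source,
        position=position,
        native_id=first_scan,
        ms_level=2,
        precursor=precursor,
        peaks=peaks,
        extras=extras,
    )
    return normalize_spectrum(spectrum)


# --- sequential whole-file readers ---------------------------------------


def _iter_blocks(text: str) -> Iterator[str]:
    block: list[str] = []
    for line in text.splitlines():
        if line.strip():
            block.append(line)
        elif block:
            yield "\n".join(block)
            block = []
    if block:
        yield "\n".join(block)


def read_dta(path, lenient: bool = True) -> list[Spectrum]:
    """Sequentially parse a (possibly blank-line concatenated) DTA file."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    return [
        parse_dta_block(block, str(path), i, lenient)
        for i, block in enumerate(_iter_blocks(text))
    ]


def read_pkl(path, lenient: bool = True) -> list[Spectrum]:
    """Sequentially parse a (possibly multi-block) PKL file."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    return [
        parse_pkl_block(block, str(path), i, lenient)
        for i, block in enumerate(_iter_blocks(text))
    ]


def read_mgf(path, lenient: bool = True) -> list[Spectrum]:
    """Sequentially parse an MGF file, honouring the global param header."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    lines = text.splitlines()
    header_lines: list[str] = []
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in lines:
        upper = line.strip().upper()
        if upper.startswith("BEGIN IONS"):
            if current is not None:
                blocks.append(current)
            current = [line]
        elif current is not None:
            current.append(line)
            if upper.startswith("END IONS"):
                blocks.append(current)
                current = None
        else:
            header_lines.append(line)
    if current is not None:
        blocks.append(current)
    global_params = parse_mgf_header("\n".join(header_lines))
    return [
        parse_mgf_block("\n".join(block), global_params, str(path), i, lenient)
        for i, block in enumerate(blocks)
    ]


def read_ms2(path, lenient: bool = True) -> list[Spectrum]:
    """Sequentially parse an MS2 file, attaching H-line params to each record."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    header_lines: list[str] = []
    records: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        tokens = line.strip().split()
        if tokens and tokens[0] == "S":
            if current is not None:
                records.append(current)
            current = [line]
        elif current is not None:
            current.append(line)
        else:
            header_lines.append(line)
    if current is not None:
        records.append(current)
    header = parse_ms2_header("\n".join(header_lines))
    return [
        parse_ms2_record(rec, header, str(path), i, lenient)
        for i, rec in enumerate(records)
    ]


# --- MGF export -----------------------------------------------------------


def _format_charge_list(charges: list[int]) -> str:
    def one(c: int) -> str:
        return f"{abs(c)}{'-' if c < 0 else '+'}"

    return " and ".join(one(c) for c in charges)


def write_mgf(spectra: Iterable[Spectrum], destination: str | IO[str]) -> int:
    """Write spectra as Mascot generic format; returns the record count.

    TITLE is preserved from extras when present, otherwise synthesized as
    ``source:position``. Peak values are written with repr-faithful
    decimals so that a re-parse recovers them exactly.
    """
    own = isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__")
    fh = open(destination, "w", encoding="utf-8", newline="\n") if own else destination
    count = 0
    try:
        for s in spectra:
            title = None
            for e in s.extras:
                if e.name == "TITLE":
                    title = e.value
                    break
            if title is None:
                title = f"{s.source}:{s.position}"
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={title}\n")
            if s.precursor is not None and s.precursor.mz is not None:
                line = f"PEPMASS={s.precursor.mz!r}"
                if s.precursor.intensity is not None:
                    line += f" {s.precursor.intensity!r}"
                fh.write(line + "\n")
                if s.precursor.charges:
                    fh.write(f"CHARGE={_format_charge_list(s.precursor.charges)}\n")
            if s.retention_seconds is not None:
                fh.write(f"RTINSECONDS={s.retention_seconds!r}\n")
            for p in s.peaks:
                if p.charge is not None:
                    fh.write(f"{p.mz!r} {p.intensity!r} {_format_charge_list([p.charge])}\n")
                else:
                    fh.write(f"{p.mz!r} {p.intensity!r}\n")
            fh.write("END IONS\n")
            count += 1
    finally:
        if own:
            fh.close()
    return count
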
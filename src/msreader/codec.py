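"""Binary and lexical codecs shared by the XML parsers.

Covers base64 + IEEE-754 peak arrays (32/64-bit, either byte order,
optional zlib), xs:duration retention times, charge strings and the
MH+ <-> m/z precursor arithmetic.
"""

from __future__ import annotations

import base64
import binascii
import re
import struct
import zlib
from dataclasses import dataclass
from math import isfinite
from typing import Iterable, Sequence

from .errors import CodecError, FormatDialectError, IntegrityError

__all__ = [
    "PROTON_MASS",
    "ArrayEncoding",
    "decode_array",
    "encode_array",
    "parse_duration",
    "parse_charge",
    "mh_to_mz",
    "mz_to_mh",
]

#: Mass of a proton in Da, used for (M+H)+ <-> m/z conversions.
PROTON_MASS = 1.00727646688

_PRECISIONS = (32, 64)
_BYTE_ORDERS = ("big", "little")
_COMPRESSIONS = ("none", "zlib")
_LAYOUTS = ("single_array", "interleaved_pairs")


@dataclass(frozen=True)
class ArrayEncoding:
    """How a binary peak array is laid out on the wire.

    mzXML uses 64/32-bit big-endian interleaved (m/z, intensity) pairs;
    mzData declares its endianness explicitly and stores two single
    arrays; mzML stores little-endian single arrays.
    """

    precision: int = 64
    byte_order: str = "big"
    compression: str = "none"
    layout: str = "single_array"

    def __post_init__(self):
        if self.precision not in _PRECISIONS:
            raise ValueError(f"precision must be one of {_PRECISIONS}, got {self.precision}")
        if self.byte_order not in _BYTE_ORDERS:
            raise ValueError(f"byte_order must be one of {_BYTE_ORDERS}, got {self.byte_order}")
        if self.compression not in _COMPRESSIONS:
            raise ValueError(f"compression must be one of {_COMPRESSIONS}, got {self.compression}")
        if self.layout not in _LAYOUTS:
            raise ValueError(f"layout must be one of {_LAYOUTS}, got {self.layout}")

    @property
    def struct_char(self) -> str:
        return "d" if self.precision == 64 else "f"

    @property
    def order_char(self) -> str:
        return ">" if self.byte_order == "big" else "<"


def decode_array(
    b64: str | bytes,
    enc: ArrayEncoding,
    expected_count: int | None = None,
) -> list[float]:
    """Decode a base64 binary array into floats.

    ``expected_count`` is the declared number of values (of peaks for the
    interleaved layout); a mismatch raises IntegrityError naming both
    numbers. Whitespace inside the payload is tolerated.
    """
    if isinstance(b64, bytes):
        b64 = b64.decode("ascii", errors="replace")
    cleaned = re.sub(r"\s+", "", b64)
    try:
        raw = base64.b64decode(cleaned, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise CodecError(f"invalid base64 payload: {exc}") from exc
    if enc.compression == "zlib":
        if raw:
            try:
                raw = zlib.decompress(raw)
            except zlib.error as exc:
                raise CodecError(f"zlib decompression failed: {exc}") from exc
    width = enc.precision // 8
    if len(raw) % width:
        raise CodecError(
            f"byte length {len(raw)} is not a multiple of {width} ({enc.precision}-bit values)"
        )
    n = len(raw) // width
    values = list(struct.unpack(f"{enc.order_char}{n}{enc.struct_char}", raw))
    if enc.layout == "interleaved_pairs":
        if n % 2:
            raise CodecError(f"interleaved payload holds an odd number of values ({n})")
        count = n // 2
    else:
        count = n
    if expected_count is not None and count != expected_count:
        raise IntegrityError(
            f"declared count {expected_count} but decoded {count} values"
        )
    return values


def encode_array(values: Iterable[float], enc: ArrayEncoding) -> str:
    """Encode floats as a base64 binary array (inverse of :func:`decode_array`)."""
    vals = list(values)
    for v in vals:
        if not isfinite(v):
            raise CodecError(f"non-finite value {v!r} cannot be encoded")
    raw = struct.pack(f"{enc.order_char}{len(vals)}{enc.struct_char}", *vals)
    if enc.compression == "zlib" and raw:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


_DURATION_RE = re.compile(
    r"^P(?:(?P<days>\d+(?:\.\d+)?)D)?"
    r"(?:T(?:(?P<hours>\d+(?:\.\d+)?)H)?"
    r"(?:(?P<minutes>\d+(?:\.\d+)?)M)?"
    r"(?:(?P<seconds>\d+(?:\.\d+)?)S)?)?$"
)


def parse_duration(text: str, lenient: bool = True) -> float:
    """Parse an xs:duration subset (``PT60.5S`` style) to seconds.

    In lenient mode (the default) a bare decimal number is accepted and
    interpreted as seconds, because real-world mzXML writers emit those.
    """
    raw = text.strip()
    m = _DURATION_RE.match(raw)
    if m and any(v is not None for v in m.groupdict().values()):
        parts = {k: float(v) if v is not None else 0.0 for k, v in m.groupdict().items()}
        return (
            parts["days"] * 86400.0
            + parts["hours"] * 3600.0
            + parts["minutes"] * 60.0
            + parts["seconds"]
        )
    if lenient:
        try:
            value = float(raw)
        except ValueError:
            pass
        else:
            if value >= 0:
                return value
    raise FormatDialectError(f"unparseable duration {text!r}", raw=text)


_CHARGE_TOKEN_RE = re.compile(r"^(?:(?P<pre>[+-])?(?P<num>\d+)(?P<post>[+-])?)$")


def parse_charge(text: str) -> list[int]:
    """Parse an MGF-style charge string into signed integers.

    Accepts ``2+``, ``+2``, ``2``, ``3-`` and comma- or ``and``-separated
    lists of those.
    """
    tokens = [t for t in re.split(r",|\band\b", text) if t.strip()]
    if not tokens:
        raise FormatDialectError(f"empty charge string {text!r}", raw=text)
    charges: list[int] = []
    for token in tokens:
        m = _CHARGE_TOKEN_RE.match(token.strip())
        if not m or (m.group("pre") and m.group("post")):
            raise FormatDialectError(f"unparseable charge token {token.strip()!r}", raw=text)
        sign = -1 if "-" in (m.group("pre"), m.group("post")) else 1
        value = sign * int(m.group("num"))
        if value == 0:
            raise FormatDialectError(f"zero charge in {text!r}", raw=text)
        charges.append(value)
    return charges


def mh_to_mz(mh_plus: float, z: int) -> float:
    """Convert a singly protonated mass (M+H)+ to m/z at charge ``z``."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mh_plus + (z - 1) * PROTON_MASS) / z


def mz_to_mh(mz: float, z: int) -> float:
    """Inverse of :func:`mh_to_mz`: m/z at charge ``z`` back to (M+H)+."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return mz * z - (z - 1) * PROTON_MASS


def interleave(mz: Sequence[float], intensity: Sequence[float]) -> list[float]:
    """Zip two aligned arrays into the mzXML interleaved pair layout."""
    if len(mz) != len(intensity):
        raise IntegrityError(f"array lengths differ: {len(mz)} vs {len(intensity)}")
    out: list[float] = []
    for a, b in zip(mz, intensity):
        out.append(a)
        out.append(b)
    return out
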
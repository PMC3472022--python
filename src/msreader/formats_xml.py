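"""Record-level parsers for mzXML (2.1-3.2), mzData (1.05) and a minimal
mzML 1.1 subset.

Each parser consumes the bytes of one indexed element and returns a
Spectrum; sequential whole-document readers (an independent access
route built on iterparse) are provided for oracle comparisons and
low-level use. Tag matching is namespace-agnostic (local names only).
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterator

from .codec import ArrayEncoding, decode_array, parse_duration
from .core import ParamEntry, Peak, PrecursorInfo, Spectrum, normalize_spectrum
from .errors import (
    CodecError,
    FormatDialectError,
    IntegrityError,
    MalformedRecordError,
    UnsupportedFormatError,
    VersionWarning,
)

__all__ = [
    "XmlDialect",
    "detect_dialect",
    "parse_mzxml_scan",
    "parse_mzdata_spectrum",
    "parse_mzml_spectrum",
    "read_xml_file",
    "MZXML_MIN_VERSION",
    "MZXML_MAX_VERSION",
    "MZDATA_SUPPORTED_VERSION",
]

MZXML_MIN_VERSION = "2.1"
MZXML_MAX_VERSION = "3.2"
MZDATA_SUPPORTED_VERSION = "1.05"

_PROBE_BYTES = 4096


@dataclass(frozen=True)
class XmlDialect:
    format: str  # "mzxml" | "mzdata" | "mzml"
    version: str
    namespace: str = ""


def _version_tuple(v: str) -> tuple[int, ...]:
    return tuple(int(p) for p in re.findall(r"\d+", v)[:2] or (0,))


def detect_dialect(path) -> XmlDialect:
    """Sniff format and schema version from the first 4 KiB of ``path``.

    mzXML versions outside [2.1, 3.2] and mzData versions other than
    1.05 raise a VersionWarning; parsing then proceeds best effort.
    """
    with open(path, "rb") as fh:
        head = fh.read(_PROBE_BYTES).decode("utf-8", errors="replace")
    m = re.search(r"<(?:\w+:)?mzXML\b([^>]*)>", head)
    if m:
        attrs = m.group(1)
        vm = re.search(r"mzXML[_/]([0-9]+\.[0-9]+)", attrs) or re.search(
            r'\bversion\s*=\s*["\']([^"\']+)["\']', attrs
        )
        version = vm.group(1) if vm else "unknown"
        nm = re.search(r'xmlns\s*=\s*["\']([^"\']+)["\']', attrs)
        if vm and not (
            _version_tuple(MZXML_MIN_VERSION)
            <= _version_tuple(version)
            <= _version_tuple(MZXML_MAX_VERSION)
        ):
            warnings.warn(
                f"mzXML version {version} is outside the supported range "
                f"{MZXML_MIN_VERSION}-{MZXML_MAX_VERSION}; parsing best effort",
                VersionWarning,
                stacklevel=2,
            )
        return XmlDialect("mzxml", version, nm.group(1) if nm else "")
    m = re.search(r"<(?:\w+:)?mzData\b([^>]*)>", head)
    if m:
        vm = re.search(r'\bversion\s*=\s*["\']([^"\']+)["\']', m.group(1))
        version = vm.group(1) if vm else "unknown"
        if version != MZDATA_SUPPORTED_VERSION:
            warnings.warn(
                f"mzData version {version} differs from the supported version "
                f"{MZDATA_SUPPORTED_VERSION}; parsing best effort",
                VersionWarning,
                stacklevel=2,
            )
        return XmlDialect("mzdata", version)
    m = re.search(r"<(?:\w+:)?(?:indexed)?mzML\b([^>]*)>", head)
    if m:
        attrs = m.group(1)
        vm = re.search(r'\bversion\s*=\s*["\']([^"\']+)["\']', attrs)
        nm = re.search(r'xmlns\s*=\s*["\']([^"\']+)["\']', attrs)
        return XmlDialect("mzml", vm.group(1) if vm else "1.1.0", nm.group(1) if nm else "")
    raise UnsupportedFormatError(f"no known XML root element found in {path}")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(el: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in el if _local(c.tag) == name]

def _find_deep(el: ET.Element, name: str, skip: str | None = None) -> ET.Element | None:
    for c in el:
        lname = _local(c.tag)
        if lname == skip:
            continue
        if lname == name:
            return c
        found = _find_deep(c, name, skip)
        if found is not None:
            return found
    return None


def _fromstring(data: bytes) -> ET.Element:
    try:
        return ET.fromstring(data)
    except ET.ParseError as exc:
        # tolerate namespace prefixes left unbound by span extraction
        if "unbound prefix" in str(exc):
            stripped = re.sub(rb"<(/?)\w+:", rb"<\1", data)
            stripped = re.sub(rb"\sxmlns:\w+=", b" xmlns-ignored=", stripped)
            try:
                return ET.fromstring(stripped)
            except ET.ParseError:
                pass
        raise MalformedRecordError(f"record is not well-formed XML: {exc}") from exc


def _cv_lookup(el: ET.Element) -> list[tuple[str, str, str]]:
    """(accession, name, value) for every cvParam child (recursive)."""
    out = []
    for c in el.iter():
        if _local(c.tag) == "cvParam":
            out.append(
                (
                    c.get("accession", ""),
                    c.get("name", ""),
                    c.get("value", ""),
                )
            )
    return out


def _match_cv(params, accessions: tuple[str, ...], names: tuple[str, ...]) -> str | None:
    # accession match wins; name match (case-insensitive) is the fallback
    for acc, _name, value in params:
        if acc in accessions:
            return value
    lowered = tuple(n.lower() for n in names)
    for _acc, name, value in params:
        if name.lower() in lowered:
            return value
    return None


# --- mzXML ----------------------------------------------------------------

_POLARITY_MAP = {"+": "positive", "-": "negative"}
_KNOWN_SCAN_ATTRS = {"num", "msLevel", "peaksCount", "retentionTime", "polarity"}


def _mzxml_scan_to_spectrum(el: ET.Element, dialect: XmlDialect, position: int) -> Spectrum:
    attrs = dict(el.attrib)
    native_id = attrs.get("num")
    ms_level = int(attrs["msLevel"]) if "msLevel" in attrs else None
    retention = None
    extras: list[ParamEntry] = []
    if "retentionTime" in attrs:
        retention = parse_duration(attrs["retentionTime"])
        extras.append(ParamEntry("retentionTime", attrs["retentionTime"]))
    polarity = _POLARITY_MAP.get(attrs.get("polarity", ""))
    for k, v in attrs.items():
        if k not in _KNOWN_SCAN_ATTRS:
            extras.append(ParamEntry(k, v))

    precursor = None
    peaks: list[Peak] = []
    declared = int(attrs["peaksCount"]) if "peaksCount" in attrs else None
    # nested child <scan> elements have their own index spans: skip them
    for child in el:
        name = _local(child.tag)
        if name == "scan":
            continue
        if name == "precursorMz":
            text = (child.text or "").strip()
            mz = float(text) if text else None
            intensity = child.get("precursorIntensity")
            charge = child.get("precursorCharge")
            precursor = PrecursorInfo(
                mz=mz,
                intensity=float(intensity) if intensity is not None else None,
                charges=[int(charge)] if charge is not None else [],
            )
        elif name == "peaks":
            precision = int(child.get("precision", "32"))
            compression = child.get("compressionType", "none")
            if compression not in ("none", "zlib"):
                raise CodecError(
                    f"unknown mzXML compressionType {compression!r} in scan {native_id}"
                )
            byte_order = child.get("byteOrder", "network")
            enc = ArrayEncoding(
                precision=precision,
                byte_order="big" if byte_order in ("network", "big") else "little",
                compression=compression,
                layout="interleaved_pairs",
            )
            flat = decode_array(child.text or "", enc, expected_count=declared)
            peaks = [
                Peak(mz=flat[i], intensity=flat[i + 1]) for i in range(0, len(flat), 2)
            ]
            for k in ("contentType", "pairOrder"):
                if child.get(k):
                    extras.append(ParamEntry(k, child.get(k)))
        else:
            extras.append(ParamEntry(name, (child.text or "").strip() or None))
    if declared is not None and len(peaks) != declared:
        raise IntegrityError(
            f"peaksCount={declared} but decoded {len(peaks)} peaks in scan {native_id}"
        )
    spectrum = Spectrum(
        source="",
        position=position,
        native_id=native_id,
        ms_level=ms_level,
        retention_seconds=retention,
        polarity=polarity,
        precursor=precursor,
        peaks=peaks,
        extras=extras,
    )
    return normalize_spectrum(spectrum)


def parse_mzxml_scan(element_bytes: bytes, dialect: XmlDialect, position: int) -> Spectrum:
    """Parse one ``<scan>`` element's bytes (nested child scans ignored)."""
    return _mzxml_scan_to_spectrum(_fromstring(element_bytes), dialect, position)


# --- mzData ---------------------------------------------------------------

_MZDATA_MZ_ACC = ("PSI:1000040", "MS:1000744")
_MZDATA_MZ_NAMES = ("MassToChargeRatio", "mass to charge ratio", "m/z")
_MZDATA_CHARGE_ACC = ("PSI:1000041", "MS:1000041")
_MZDATA_CHARGE_NAMES = ("ChargeState", "charge state")
_MZDATA_INTENSITY_ACC = ("PSI:1000042", "MS:1000042")
_MZDATA_INTENSITY_NAMES = ("Intensity", "intensity")


def _decode_mzdata_array(el: ET.Element, what: str, native_id: str | None) -> list[float]:
    data = _children(el, "data")
    if not data:
        raise IntegrityError(f"missing <data> in {what} of spectrum {native_id}")
    d = data[0]
    declared = d.get("length")
    enc = ArrayEncoding(
        precision=int(d.get("precision", "32")),
        byte_order=d.get("endian", "big"),
        compression="none",
        layout="single_array",
    )
    return decode_array(
        d.text or "", enc, expected_count=int(declared) if declared is not None else None
    )


def parse_mzdata_spectrum(element_bytes: bytes, dialect: XmlDialect, position: int) -> Spectrum:
    """Parse one mzData ``<spectrum id=...>`` element's bytes."""
    el = _fromstring(element_bytes)
    native_id = el.get("id")
    instrument = _find_deep(el, "spectrumInstrument")
    ms_level = None
    extras: list[ParamEntry] = []
    if instrument is not None and instrument.get("msLevel") is not None:
        ms_level = int(instrument.get("msLevel"))

    precursor = None
    ion_selection = _find_deep(el, "ionSelection")
    if ion_selection is not None:
        params = _cv_lookup(ion_selection)
        mz = _match_cv(params, _MZDATA_MZ_ACC, _MZDATA_MZ_NAMES)
        charge = _match_cv(params, _MZDATA_CHARGE_ACC, _MZDATA_CHARGE_NAMES)
        intensity = _match_cv(params, _MZDATA_INTENSITY_ACC, _MZDATA_INTENSITY_NAMES)
        if mz is not None or charge is not None:
            precursor = PrecursorInfo(
                mz=float(mz) if mz is not None else None,
                intensity=float(intensity) if intensity is not None else None,
                charges=[int(charge)] if charge is not None else [],
            )

    mz_el = _find_deep(el, "mzArrayBinary")
    inten_el = _find_deep(el, "intenArrayBinary")
    mz_values: list[float] = []
    inten_values: list[float] = []
    if mz_el is not None:
        mz_values = _decode_mzdata_array(mz_el, "mzArrayBinary", native_id)
    if inten_el is not None:
        inten_values = _decode_mzdata_array(inten_el, "intenArrayBinary", native_id)
    if len(mz_values) != len(inten_values):
        raise IntegrityError(
            f"m/z and intensity array lengths differ ({len(mz_values)} vs "
            f"{len(inten_values)}) in spectrum {native_id}"
        )
    peaks = [Peak(mz=m, intensity=i) for m, i in zip(mz_values, inten_values)]
    spectrum = Spectrum(
        source="",
        position=position,
        native_id=native_id,
        ms_level=ms_level,
        precursor=precursor,
        peaks=peaks,
        extras=extras,
    )
    return normalize_spectrum(spectrum)


# --- mzML -----------------------------------------------------------------

_MZML_ACC_MZ_ARRAY = "MS:1000514"
_MZML_ACC_INTENSITY_ARRAY = "MS:1000515"
_MZML_ACC_64BIT = "MS:1000523"
_MZML_ACC_32BIT = "MS:1000521"
_MZML_ACC_ZLIB = "MS:1000574"
_MZML_ACC_NONE = "MS:1000576"
_MZML_ACC_MS_LEVEL = "MS:1000511"
_MZML_ACC_SELECTED_MZ = "MS:1000744"
_MZML_ACC_CHARGE = "MS:1000041"
_MZML_ACC_PEAK_INTENSITY = "MS:1000042"


def _classify_mzml_array(bda: ET.Element, native_id: str | None):
    kind = None
    precision = 64
    compression = "none"
    for acc, name, _value in _cv_lookup(bda):
        if acc == _MZML_ACC_MZ_ARRAY or name == "m/z array":
            kind = "mz"
        elif acc == _MZML_ACC_INTENSITY_ARRAY or name == "intensity array":
            kind = "intensity"
        elif acc == _MZML_ACC_64BIT or name == "64-bit float":
            precision = 64
        elif acc == _MZML_ACC_32BIT or name == "32-bit float":
            precision = 32
        elif acc == _MZML_ACC_ZLIB or name == "zlib compression":
            compression = "zlib"
        elif acc == _MZML_ACC_NONE or name == "no compression":
            compression = "none"
    if kind is None:
        raise FormatDialectError(
            f"binaryDataArray without a type cvParam in spectrum {native_id}"
        )
    return kind, ArrayEncoding(
        precision=precision, byte_order="little", compression=compression,
        layout="single_array",
    )


def parse_mzml_spectrum(element_bytes: bytes, dialect: XmlDialect, position: int) -> Spectrum:
    """Parse one mzML ``<spectrum>`` element's bytes (minimal subset)."""
    el = _fromstring(element_bytes)
    native_id = el.get("id")
    declared = el.get("defaultArrayLength")
    declared_n = int(declared) if declared is not None else None
    ms_level = None
    extras: list[ParamEntry] = []
    for c in _children(el, "cvParam"):
        acc, name, value = c.get("accession", ""), c.get("name", ""), c.get("value", "")
        if acc == _MZML_ACC_MS_LEVEL or name == "ms level":
            ms_level = int(value)
        else:
            extras.append(ParamEntry(name or acc, value or None, acc or None))

    precursor = None
    selected_ion = _find_deep(el, "selectedIon")
    if selected_ion is not None:
        params = _cv_lookup(selected_ion)
        mz = _match_cv(params, (_MZML_ACC_SELECTED_MZ,), ("selected ion m/z",))
        charge = _match_cv(params, (_MZML_ACC_CHARGE,), ("charge state",))
        intensity = _match_cv(params, (_MZML_ACC_PEAK_INTENSITY,), ("peak intensity",))
        precursor = PrecursorInfo(
            mz=float(mz) if mz else None,
            intensity=float(intensity) if intensity else None,
            charges=[int(charge)] if charge else [],
        )

    mz_values: list[float] = []
    inten_values: list[float] = []
    bda_list = _find_deep(el, "binaryDataArrayList")
    if bda_list is not None:
        for bda in _children(bda_list, "binaryDataArray"):
            kind, enc = _classify_mzml_array(bda, native_id)
            binary = _children(bda, "binary")
            text = binary[0].text or "" if binary else ""
            values = decode_array(text, enc, expected_count=declared_n)
            if kind == "mz":
                mz_values = values
            else:
                inten_values = values
    if len(mz_values) != len(inten_values):
        raise IntegrityError(
            f"m/z and intensity array lengths differ ({len(mz_values)} vs "
            f"{len(inten_values)}) in spectrum {native_id}"
        )
    peaks = [Peak(mz=m, intensity=i) for m, i in zip(mz_values, inten_values)]
    spectrum = Spectrum(
        source="",
        position=position,
        native_id=native_id,
        ms_level=ms_level,
        precursor=precursor,
        peaks=peaks,
        extras=extras,
    )
    return normalize_spectrum(spectrum)


# --- sequential whole-document readers ------------------------------------

_RECORD_PARSE = {
    "mzxml": _mzxml_scan_to_spectrum,
}


def read_xml_file(path, dialect: XmlDialect | None = None) -> list[Spectrum]:
    """Parse all spectra of an XML file via a full-document streaming parse.

    This is an independent access route from the byte-span index: it uses
    iterparse over the whole document. mzXML nested scans are flattened
    in document order (order of their start tags).
    """
    from dataclasses import replace

    if dialect is None:
        dialect = detect_dialect(path)
    src = str(path)
    if dialect.format == "mzxml":
        spectra: list[tuple[int, Spectrum]] = []
        order: dict[int, int] = {}
        counter = 0
        for event, el in ET.iterparse(path, events=("start", "end")):
            if _local(el.tag) != "scan":
                continue
            if event == "start":
                order[id(el)] = counter
                counter += 1
            else:
                pos = order.pop(id(el))
                spectra.append((pos, _mzxml_scan_to_spectrum(el, dialect, pos)))
        spectra.sort(key=lambda t: t[0])
        return [replace(s, source=src) for _, s in spectra]
    converter = _mzdata_el_to_spectrum if dialect.format == "mzdata" else _mzml_el_to_spectrum
    out: list[Spectrum] = []
    pos = 0
    for _event, el in ET.iterparse(path, events=("end",)):
        if _local(el.tag) == "spectrum":
            out.append(replace(converter(el, dialect, pos), source=src))
            pos += 1
            el.clear()
    return out


def _mzdata_el_to_spectrum(el: ET.Element, dialect: XmlDialect, position: int) -> Spectrum:
    return parse_mzdata_spectrum(ET.tostring(el), dialect, position)


def _mzml_el_to_spectrum(el: ET.Element, dialect: XmlDialect, position: int) -> Spectrum:
    return parse_mzml_spectrum(ET.tostring(el), dialect, position)
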
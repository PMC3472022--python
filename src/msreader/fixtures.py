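"""Deterministic synthetic spectra and test-grade writers for all seven
formats, plus targeted corruption helpers that drive the error taxonomy.

Text writers print m/z with 6 decimals and intensity with 4; the
generator rounds values to exactly that precision so text round trips
are lossless. XML writers emit minimal but well-formed documents.
"""

from __future__ import annotations

import os
import random
import re
from dataclasses import dataclass

from .codec import ArrayEncoding, encode_array, interleave, mz_to_mh
from .core import ParamEntry, Peak, PrecursorInfo, Spectrum

__all__ = ["FixtureSpec", "generate_spectra", "write_fixture", "corrupt_fixture"]

_MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_{version}"
_MZML_NS = "http://psi.hupo.org/ms/mzml"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic synthetic dataset."""

    n_spectra: int = 3
    peaks_min: int = 3
    peaks_max: int = 8
    mz_range: tuple[float, float] = (100.0, 2000.0)
    seed: int = 0
    ms_level_pattern: tuple[int, ...] = (2,)
    charge_set: tuple[int, ...] = (2, 3)


def generate_spectra(spec: FixtureSpec) -> list[Spectrum]:
    """Deterministic spectra: same spec, same list, every time.

    Peak m/z are uniform in ``mz_range`` (rounded to 6 decimals, sorted
    ascending); intensities are log-uniform in [1, 1e6] (rounded to 4).
    MS2-level spectra get a precursor whose (mz, mh_plus, z) satisfy the
    proton-mass consistency relation exactly.
    """
    low, high = spec.mz_range
    if not (high > low > 0):
        raise ValueError(f"invalid mz_range {spec.mz_range}")
    if spec.n_spectra < 0:
        raise ValueError("n_spectra must be >= 0")
    rng = random.Random(spec.seed)
    out: list[Spectrum] = []
    for i in range(spec.n_spectra):
        ms_level = spec.ms_level_pattern[i % len(spec.ms_level_pattern)]
        n_peaks = rng.randint(spec.peaks_min, spec.peaks_max)
        mzs = sorted(round(rng.uniform(low, high), 6) for _ in range(n_peaks))
        intensities = [round(10 ** rng.uniform(0, 6), 4) for _ in range(n_peaks)]
        peaks = [Peak(mz=m, intensity=j) for m, j in zip(mzs, intensities)]
        precursor = None
        if ms_level >= 2:
            pmz = round(rng.uniform(low, high), 6)
            z = rng.choice(spec.charge_set)
            precursor = PrecursorInfo(
                mz=pmz,
                mh_plus=mz_to_mh(pmz, z),
                intensity=round(10 ** rng.uniform(2, 6), 4),
                charges=[z],
            )
        out.append(
            Spectrum(
                source="",
                position=i,
                native_id=str(i + 1),
                ms_level=ms_level,
                retention_seconds=round(0.5 + 1.5 * i, 3),
                precursor=precursor,
                peaks=peaks,
                extras=[ParamEntry("TITLE", f"fixture spectrum {i}")],
            )
        )
    return out


# --- writers --------------------------------------------------------------


def _write_text(path, text: str) -> str:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(text)
    return str(path)


def _peak_lines(s: Spectrum) -> str:
    return "".join(f"{p.mz:.6f} {p.intensity:.4f}\n" for p in s.peaks)


def _require_precursor(s: Spectrum, fmt: str):
    if s.precursor is None or not s.precursor.charges:
        raise ValueError(f"{fmt} cannot represent a spectrum without precursor and charge")
    return s.precursor


def _dta_block(s: Spectrum) -> str:
    pre = _require_precursor(s, "DTA")
    mh = pre.mh_plus if pre.mh_plus is not None else mz_to_mh(pre.mz, pre.charges[0])
    return f"{mh:.6f} {pre.charges[0]}\n" + _peak_lines(s)


def _pkl_block(s: Spectrum) -> str:
    pre = _require_precursor(s, "PKL")
    intensity = pre.intensity if pre.intensity is not None else 0.0
    return f"{pre.mz:.6f} {intensity:.4f} {pre.charges[0]}\n" + _peak_lines(s)


def _mgf_text(spectra: list[Spectrum], header: bool = True) -> str:
    parts = []
    if header:
        parts.append("COM=msreader synthetic fixture\n\n")
    for s in spectra:
        block = ["BEGIN IONS\n", f"TITLE=fixture spectrum {s.position}\n"]
        if s.precursor is not None and s.precursor.mz is not None:
            line = f"PEPMASS={s.precursor.mz:.6f}"
            if s.precursor.intensity is not None:
                line += f" {s.precursor.intensity:.4f}"
            block.append(line + "\n")
            if s.precursor.charges:
                block.append(
                    "CHARGE="
                    + ", ".join(f"{abs(c)}{'-' if c < 0 else '+'}" for c in s.precursor.charges)
                    + "\n"
                )
        if s.retention_seconds is not None:
            block.append(f"RTINSECONDS={s.retention_seconds}\n")
        block.append(_peak_lines(s))
        block.append("END IONS\n")
        parts.append("".join(block) + "\n")
    return "".join(parts)


def _ms2_text(spectra: list[Spectrum]) -> str:
    parts = ["H\tCreationDate\t2012-01-01\nH\tExtractor\tmsreader-fixtures\n"]
    for i, s in enumerate(spectra):
        pre = _require_precursor(s, "MS2")
        scan = i + 1
        parts.append(f"S\t{scan}\t{scan}\t{pre.mz:.6f}\n")
        for z in pre.charges:
            mh = pre.mh_plus if pre.mh_plus is not None else mz_to_mh(pre.mz, z)
            parts.append(f"Z\t{z}\t{mh:.6f}\n")
        parts.append(_peak_lines(s))
    return "".join(parts)


def _mzxml_text(
    spectra: list[Spectrum],
    version: str,
    precision: int,
    compression: str,
    nested: bool,
) -> str:
    if compression == "zlib" and tuple(int(p) for p in version.split(".")[:2]) < (3, 0):
        raise ValueError(f"zlib compression is not legal for mzXML {version}")
    enc = ArrayEncoding(
        precision=precision, byte_order="big", compression=compression,
        layout="interleaved_pairs",
    )

    def scan_xml(s: Spectrum, num: int, indent: str) -> str:
        payload = encode_array(interleave([p.mz for p in s.peaks],
                                          [p.intensity for p in s.peaks]), enc)
        attrs = (
            f'num="{num}" msLevel="{s.ms_level or 1}" peaksCount="{len(s.peaks)}"'
        )
        if s.retention_seconds is not None:
            attrs += f' retentionTime="PT{s.retention_seconds}S"'
        if s.polarity is not None:
            attrs += ' polarity="{}"'.format("+" if s.polarity == "positive" else "-")
        lines = [f"{indent}<scan {attrs}>"]
        if s.precursor is not None and s.precursor.mz is not None:
            pattrs = ""
            if s.precursor.intensity is not None:
                pattrs += f' precursorIntensity="{s.precursor.intensity}"'
            if s.precursor.charges:
                pattrs += f' precursorCharge="{s.precursor.charges[0]}"'
            lines.append(
                f"{indent}  <precursorMz{pattrs}>{s.precursor.mz!r}</precursorMz>"
            )
        comp = f' compressionType="{compression}"' if compression != "none" else ""
        lines.append(
            f'{indent}  <peaks precision="{precision}" byteOrder="network"'
            f' contentType="m/z-int"{comp}>{payload}</peaks>'
        )
        return "\n".join(lines)

    body: list[str] = []
    i = 0
    n = len(spectra)
    while i < n:
        s = spectra[i]
        if nested and (s.ms_level or 1) == 1:
            chunk = [scan_xml(s, i + 1, "    ")]
            j = i + 1
            while j < n and (spectra[j].ms_level or 1) >= 2:
                chunk.append(scan_xml(spectra[j], j + 1, "      ") + "\n      </scan>")
                j += 1
            chunk.append("    </scan>")
            body.append("\n".join(chunk))
            i = j
        else:
            body.append(scan_xml(s, i + 1, "    ") + "\n    </scan>")
            i += 1
    ns = _MZXML_NS.format(version=version)
    return (
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        f'<mzXML xmlns="{ns}">\n'
        f'  <msRun scanCount="{n}">\n'
        + "\n".join(body)
        + "\n  </msRun>\n</mzXML>\n"
    )


def _mzdata_text(
    spectra: list[Spectrum],
    version: str,
    precision: int,
    endian: str,
    id_start: int = 1,
) -> str:
    enc = ArrayEncoding(
        precision=precision, byte_order=endian, compression="none", layout="single_array"
    )
    body = []
    for i, s in enumerate(spectra):
        sid = id_start + i
        mz_payload = encode_array([p.mz for p in s.peaks], enc)
        in_payload = encode_array([p.intensity for p in s.peaks], enc)
        pre = ""
        if s.precursor is not None and s.precursor.mz is not None:
            cv = [
                f'              <cvParam cvLabel="psi" accession="PSI:1000040"'
                f' name="MassToChargeRatio" value="{s.precursor.mz!r}"/>'
            ]
            if s.precursor.charges:
                cv.append(
                    f'              <cvParam cvLabel="psi" accession="PSI:1000041"'
                    f' name="ChargeState" value="{s.precursor.charges[0]}"/>'
                )
            if s.precursor.intensity is not None:
                cv.append(
                    f'              <cvParam cvLabel="psi" accession="PSI:1000042"'
                    f' name="Intensity" value="{s.precursor.intensity!r}"/>'
                )
            pre = (
                '        <precursorList count="1">\n'
                '          <precursor msLevel="1" spectrumRef="0">\n'
                "            <ionSelection>\n" + "\n".join(cv) + "\n"
                "            </ionSelection>\n"
                "            <activation/>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
            )
        body.append(
            f'    <spectrum id="{sid}">\n'
            "      <spectrumDesc>\n"
            "        <spectrumSettings>\n"
            f'          <spectrumInstrument msLevel="{s.ms_level or 1}"/>\n'
            "        </spectrumSettings>\n"
            + pre
            + "      </spectrumDesc>\n"
            f'      <mzArrayBinary>\n'
            f'        <data precision="{precision}" endian="{endian}"'
            f' length="{len(s.peaks)}">{mz_payload}</data>\n'
            "      </mzArrayBinary>\n"
            f"      <intenArrayBinary>\n"
            f'        <data precision="{precision}" endian="{endian}"'
            f' length="{len(s.peaks)}">{in_payload}</data>\n'
            "      </intenArrayBinary>\n"
            "    </spectrum>"
        )
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<mzData version="{version}" accessionNumber="msreader:fixture">\n'
        f'  <spectrumList count="{len(spectra)}">\n'
        + "\n".join(body)
        + "\n  </spectrumList>\n</mzData>\n"
    )


def _mzml_text(spectra: list[Spectrum], precision: int, compression: str) -> str:
    enc = ArrayEncoding(
        precision=precision, byte_order="little", compression=compression,
        layout="single_array",
    )
    prec_cv = "MS:1000523" if precision == 64 else "MS:1000521"
    prec_name = "64-bit float" if precision == 64 else "32-bit float"
    comp_cv = "MS:1000574" if compression == "zlib" else "MS:1000576"
    comp_name = "zlib compression" if compression == "zlib" else "no compression"

    def array_xml(values, kind_cv, kind_name):
        payload = encode_array(values, enc)
        return (
            '          <binaryDataArray encodedLength="{n}">\n'
            '            <cvParam cvRef="MS" accession="{p}" name="{pn}"/>\n'
            '            <cvParam cvRef="MS" accession="{c}" name="{cn}"/>\n'
            '            <cvParam cvRef="MS" accession="{k}" name="{kn}"/>\n'
            "            <binary>{b}</binary>\n"
            "          </binaryDataArray>\n"
        ).format(
            n=len(payload), p=prec_cv, pn=prec_name, c=comp_cv, cn=comp_name,
            k=kind_cv, kn=kind_name, b=payload,
        )

    body = []
    for i, s in enumerate(spectra):
        pre = ""
        if s.precursor is not None and s.precursor.mz is not None:
            ion = [
                f'              <cvParam cvRef="MS" accession="MS:1000744"'
                f' name="selected ion m/z" value="{s.precursor.mz!r}"/>'
            ]
            if s.precursor.charges:
                ion.append(
                    f'              <cvParam cvRef="MS" accession="MS:1000041"'
                    f' name="charge state" value="{s.precursor.charges[0]}"/>'
                )
            if s.precursor.intensity is not None:
                ion.append(
                    f'              <cvParam cvRef="MS" accession="MS:1000042"'
                    f' name="peak intensity" value="{s.precursor.intensity!r}"/>'
                )
            pre = (
                '        <precursorList count="1">\n'
                "          <precursor>\n"
                '            <selectedIonList count="1">\n'
                "            <selectedIon>\n" + "\n".join(ion) + "\n"
                "            </selectedIon>\n"
                "            </selectedIonList>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
            )
        body.append(
            f'      <spectrum id="scan={i + 1}" index="{i}"'
            f' defaultArrayLength="{len(s.peaks)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level"'
            f' value="{s.ms_level or 1}"/>\n'
            + pre
            + '        <binaryDataArrayList count="2">\n'
            + array_xml([p.mz for p in s.peaks], "MS:1000514", "m/z array")
            + array_xml([p.intensity for p in s.peaks], "MS:1000515", "intensity array")
            + "        </binaryDataArrayList>\n"
            "      </spectrum>"
        )
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">\n'
        '  <run id="fixture">\n'
        f'    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">\n'
        + "\n".join(body)
        + "\n    </spectrumList>\n  </run>\n</mzML>\n"
    )


def write_fixture(
    spectra: list[Spectrum],
    format: str,
    destination,
    *,
    version: str | None = None,
    precision: int = 64,
    compression: str = "none",
    endian: str = "big",
    directory: bool = False,
    mgf_header: bool = True,
    nested: bool = False,
    id_start: int = 1,
):
    """Write spectra in any of the seven formats; returns the path(s).

    ``directory=True`` (DTA/PKL only) writes one file per spectrum into
    ``destination`` and returns the list of paths. Option combinations
    that a format cannot express raise ValueError.
    """
    fmt = str(format).lower()
    if directory:
        if fmt not in ("dta", "pkl"):
            raise ValueError(f"directory mode is only valid for DTA/PKL, not {fmt}")
        os.makedirs(destination, exist_ok=True)
        paths = []
        block = _dta_block if fmt == "dta" else _pkl_block
        for i, s in enumerate(spectra):
            p = os.path.join(destination, f"sample{i}.{fmt}")
            paths.append(_write_text(p, block(s)))
        return paths
    if fmt == "dta":
        return _write_text(destination, "\n".join(_dta_block(s) for s in spectra))
    if fmt == "pkl":
        return _write_text(destination, "\n".join(_pkl_block(s) for s in spectra))
    if fmt == "mgf":
        return _write_text(destination, _mgf_text(spectra, header=mgf_header))
    if fmt == "ms2":
        return _write_text(destination, _ms2_text(spectra))
    if fmt == "mzxml":
        return _write_text(
            destination,
            _mzxml_text(spectra, version or "3.2", precision, compression, nested),
        )
    if fmt == "mzdata":
        if compression != "none":
            raise ValueError("mzData has no compressed binary representation")
        return _write_text(
            destination,
            _mzdata_text(spectra, version or "1.05", precision, endian, id_start),
        )
    if fmt == "mzml":
        return _write_text(destination, _mzml_text(spectra, precision, compression))
    raise ValueError(f"unknown format {format!r}")


# --- corruption helpers ---------------------------------------------------


def corrupt_fixture(path, mutation: str):
    """Damage a fixture in a way that triggers one documented error class.

    truncate_tail  -> stale/integrity errors (bytes chopped off the end)
    garble_base64  -> codec error (invalid characters in a binary payload)
    drop_end_ions  -> malformed-record on the first MGF block
    bad_count_attr -> integrity error (declared count off by one)
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        data = fh.read()
    if mutation == "truncate_tail":
        data = data[: max(len(data) * 7 // 10, 1)]
    elif mutation == "garble_base64":
        m = re.search(rb">([A-Za-z0-9+/=]{16,})<", data)
        if not m:
            raise ValueError(f"no base64 payload found in {path}")
        start = m.start(1)
        data = data[:start] + b"!!!!" + data[start + 4 :]
    elif mutation == "drop_end_ions":
        new = re.sub(rb"END IONS[^\n]*\n?", b"", data, count=1)
        if new == data:
            raise ValueError(f"no END IONS line found in {path}")
        data = new
    elif mutation == "bad_count_attr":
        for attr in (b"peaksCount", b"defaultArrayLength", b"length"):
            m = re.search(attr + rb'="(\d+)"', data)
            if m:
                bumped = str(int(m.group(1)) + 1).encode()
                data = data[: m.start(1)] + bumped + data[m.end(1) :]
                break
        else:
            raise ValueError(f"no count attribute found in {path}")
    else:
        raise ValueError(f"unknown mutation {mutation!r}")
    with open(path, "wb") as fh:
        fh.write(data)
    return path
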
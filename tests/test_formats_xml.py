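from __future__ import annotations

import base64
import struct
import warnings

import pytest

from msreader.errors import (
    CodecError,
    FormatDialectError,
    IntegrityError,
    UnsupportedFormatError,
    VersionWarning,
)
from msreader.fixtures import FixtureSpec, generate_spectra, write_fixture
from msreader.formats_xml import (
    MZDATA_SUPPORTED_VERSION,
    MZXML_MAX_VERSION,
    MZXML_MIN_VERSION,
    XmlDialect,
    detect_dialect,
    parse_mzdata_spectrum,
    parse_mzml_spectrum,
    parse_mzxml_scan,
    read_xml_file,
)


def b64(values, fmt):
    """Independent binary payload oracle: struct + base64 only."""
    return base64.b64encode(struct.pack(fmt % len(values), *values)).decode()


MZXML_DIALECT = XmlDialect("mzxml", "3.2")
MZDATA_DIALECT = XmlDialect("mzdata", "1.05")
MZML_DIALECT = XmlDialect("mzml", "1.1.0")


class TestDetectDialect:
    def test_mzxml_version_from_namespace(self, tmp_path):
        p = write_fixture(generate_spectra(FixtureSpec(1, seed=1)), "mzxml",
                          tmp_path / "a.mzxml", version="3.2")
        d = detect_dialect(p)
        assert (d.format, d.version) == ("mzxml", "3.2")

    def test_mzdata_version_attribute(self, tmp_path):
        p = write_fixture(generate_spectra(FixtureSpec(1, seed=1)), "mzdata",
                          tmp_path / "a.mzdata")
        d = detect_dialect(p)
        assert (d.format, d.version) == ("mzdata", "1.05")

    def test_mzml_detected(self, tmp_path):
        p = write_fixture(generate_spectra(FixtureSpec(1, seed=1)), "mzml",
                          tmp_path / "a.mzml")
        assert detect_dialect(p).format == "mzml"

    def test_plain_mgf_rejected(self, tmp_path):
        p = write_fixture(generate_spectra(FixtureSpec(1, seed=1)), "mgf", tmp_path / "a.mgf")
        with pytest.raises(UnsupportedFormatError):
            detect_dialect(p)

    @pytest.mark.parametrize("version", ["2.1", "3.0", "3.2"])
    def test_supported_mzxml_versions_no_warning(self, tmp_path, version):
        p = write_fixture(generate_spectra(FixtureSpec(1, seed=1)), "mzxml",
                          tmp_path / "v.mzxml", version=version)
        with warnings.catch_warnings():
            warnings.simplefilter("error", VersionWarning)
            detect_dialect(p)

    @pytest.mark.parametrize("version", ["2.0", "4.0"])
    def test_out_of_range_mzxml_warns(self, tmp_path, version):
        p = write_fixture(generate_spectra(FixtureSpec(1, seed=1)), "mzxml",
                          tmp_path / "v.mzxml", version=version)
        with pytest.warns(VersionWarning):
            detect_dialect(p)

    def test_unsupported_mzdata_version_warns_best_effort(self, tmp_path):
        p = write_fixture(generate_spectra(FixtureSpec(2, seed=1)), "mzdata",
                          tmp_path / "v.mzdata", version="1.04")
        with pytest.warns(VersionWarning):
            d = detect_dialect(p)
        assert d.version == "1.04"
        assert len(read_xml_file(p, d)) == 2  # still parsed

    def test_supported_version_constants(self):
        assert (MZXML_MIN_VERSION, MZXML_MAX_VERSION) == ("2.1", "3.2")
        assert MZDATA_SUPPORTED_VERSION == "1.05"


class TestMzxmlScan:
    def test_scan_with_oracle_payload(self):
        payload = b64([100.0, 10.0, 200.0, 20.0], ">%dd")
        xml = (
            f'<scan num="7" msLevel="2" peaksCount="2" retentionTime="PT60.5S">'
            f'<precursorMz precursorIntensity="300.5" precursorCharge="2">450.25</precursorMz>'
            f'<peaks precision="64" byteOrder="network">{payload}</peaks></scan>'
        ).encode()
        s = parse_mzxml_scan(xml, MZXML_DIALECT, 0)
        assert s.native_id == "7"
        assert s.ms_level == 2
        assert s.retention_seconds == 60.5
        assert [(p.mz, p.intensity) for p in s.peaks] == [(100.0, 10.0), (200.0, 20.0)]
        assert s.precursor.mz == 450.25
        assert s.precursor.intensity == 300.5
        assert s.precursor.charges == [2]

    def test_peaks_count_mismatch_is_integrity_error(self):
        payload = b64([100.0, 10.0, 200.0, 20.0], ">%dd")
        xml = f'<scan num="1" peaksCount="3"><peaks precision="64">{payload}</peaks></scan>'
        with pytest.raises(IntegrityError):
            parse_mzxml_scan(xml.encode(), MZXML_DIALECT, 0)

    def test_missing_ms_level_is_optional(self):
        payload = b64([100.0, 10.0], ">%dd")
        xml = f'<scan num="1" peaksCount="1"><peaks precision="64">{payload}</peaks></scan>'
        s = parse_mzxml_scan(xml.encode(), MZXML_DIALECT, 0)
        assert s.ms_level is None and len(s.peaks) == 1

    def test_unknown_compression_is_codec_error(self):
        xml = '<scan num="1"><peaks precision="64" compressionType="lzma">AA==</peaks></scan>'
        with pytest.raises(CodecError):
            parse_mzxml_scan(xml.encode(), MZXML_DIALECT, 0)

    def test_32bit_payload(self):
        payload = b64([100.0, 10.0], ">%df")
        xml = f'<scan num="1" peaksCount="1"><peaks precision="32">{payload}</peaks></scan>'
        s = parse_mzxml_scan(xml.encode(), MZXML_DIALECT, 0)
        assert s.peaks[0].mz == pytest.approx(100.0, rel=1e-6)

    def test_nested_child_scan_ignored(self):
        inner = b64([300.0, 30.0], ">%dd")
        outer = b64([100.0, 10.0], ">%dd")
        xml = (
            f'<scan num="1" msLevel="1" peaksCount="1">'
            f'<peaks precision="64">{outer}</peaks>'
            f'<scan num="2" msLevel="2" peaksCount="1">'
            f'<peaks precision="64">{inner}</peaks></scan></scan>'
        )
        s = parse_mzxml_scan(xml.encode(), MZXML_DIALECT, 0)
        assert [(p.mz, p.intensity) for p in s.peaks] == [(100.0, 10.0)]


class TestMzdataSpectrum:
    def make(self, mz_payload, inten_payload, length, endian="big", precision=64):
        return (
            f'<spectrum id="10"><spectrumDesc><spectrumSettings>'
            f'<spectrumInstrument msLevel="2"/></spectrumSettings>'
            f'<precursorList count="1"><precursor msLevel="1" spectrumRef="0">'
            f"<ionSelection>"
            f'<cvParam cvLabel="psi" accession="PSI:1000040" name="MassToChargeRatio" value="450.25"/>'
            f'<cvParam cvLabel="psi" accession="PSI:1000041" name="ChargeState" value="2"/>'
            f"</ionSelection><activation/></precursor></precursorList></spectrumDesc>"
            f'<mzArrayBinary><data precision="{precision}" endian="{endian}" '
            f'length="{length}">{mz_payload}</data></mzArrayBinary>'
            f'<intenArrayBinary><data precision="{precision}" endian="{endian}" '
            f'length="{length}">{inten_payload}</data></intenArrayBinary></spectrum>'
        ).encode()

    def test_basic_spectrum(self):
        xml = self.make(b64([100.0, 200.0], ">%dd"), b64([10.0, 20.0], ">%dd"), 2)
        s = parse_mzdata_spectrum(xml, MZDATA_DIALECT, 0)
        assert s.native_id == "10"
        assert s.ms_level == 2
        assert s.precursor.mz == 450.25
        assert s.precursor.charges == [2]
        assert [(p.mz, p.intensity) for p in s.peaks] == [(100.0, 10.0), (200.0, 20.0)]

    def test_little_endian_equals_big_endian(self):
        big = self.make(b64([100.0], ">%dd"), b64([10.0], ">%dd"), 1, endian="big")
        little = self.make(b64([100.0], "<%dd"), b64([10.0], "<%dd"), 1, endian="little")
        a = parse_mzdata_spectrum(big, MZDATA_DIALECT, 0)
        b = parse_mzdata_spectrum(little, MZDATA_DIALECT, 0)
        assert a.peaks == b.peaks

    def test_zero_length_arrays(self):
        xml = self.make("", "", 0)
        assert parse_mzdata_spectrum(xml, MZDATA_DIALECT, 0).peaks == []

    def test_length_mismatch_between_arrays(self):
        xml = (
            '<spectrum id="1">'
            f'<mzArrayBinary><data precision="64" endian="big" length="2">'
            f'{b64([100.0, 200.0], ">%dd")}</data></mzArrayBinary>'
            f'<intenArrayBinary><data precision="64" endian="big" length="1">'
            f'{b64([10.0], ">%dd")}</data></intenArrayBinary></spectrum>'
        ).encode()
        with pytest.raises(IntegrityError):
            parse_mzdata_spectrum(xml, MZDATA_DIALECT, 0)

    def test_declared_length_mismatch(self):
        xml = self.make(b64([100.0], ">%dd"), b64([10.0], ">%dd"), 5)
        with pytest.raises(IntegrityError):
            parse_mzdata_spectrum(xml, MZDATA_DIALECT, 0)


def mzml_spectrum_xml(
    mz_values, inten_values, declared=None, compression="none", id="scan=1"
):
    import zlib as _zlib

    def arr(values, acc, name):
        raw = struct.pack(f"<{len(values)}d", *values)
        if compression == "zlib":
            raw = _zlib.compress(raw)
        payload = base64.b64encode(raw).decode()
        comp_acc, comp_name = (
            ("MS:1000574", "zlib compression")
            if compression == "zlib"
            else ("MS:1000576", "no compression")
        )
        return (
            f"<binaryDataArray>"
            f'<cvParam accession="MS:1000523" name="64-bit float"/>'
            f'<cvParam accession="{comp_acc}" name="{comp_name}"/>'
            f'<cvParam accession="{acc}" name="{name}"/>'
            f"<binary>{payload}</binary></binaryDataArray>"
        )

    n = declared if declared is not None else len(mz_values)
    return (
        f'<spectrum id="{id}" index="0" defaultArrayLength="{n}">'
        f'<cvParam accession="MS:1000511" name="ms level" value="2"/>'
        f'<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
        f'<cvParam accession="MS:1000744" name="selected ion m/z" value="450.25"/>'
        f'<cvParam accession="MS:1000041" name="charge state" value="2"/>'
        f"</selectedIon></selectedIonList></precursor></precursorList>"
        f'<binaryDataArrayList count="2">'
        + arr(mz_values, "MS:1000514", "m/z array")
        + arr(inten_values, "MS:1000515", "intensity array")
        + "</binaryDataArrayList></spectrum>"
    ).encode()


class TestMzmlSpectrum:
    def test_basic_spectrum(self):
        xml = mzml_spectrum_xml([100.0, 200.0], [10.0, 20.0])
        s = parse_mzml_spectrum(xml, MZML_DIALECT, 0)
        assert s.native_id == "scan=1"  # verbatim id string
        assert s.ms_level == 2
        assert s.precursor.mz == 450.25
        assert s.precursor.charges == [2]
        assert [(p.mz, p.intensity) for p in s.peaks] == [(100.0, 10.0), (200.0, 20.0)]

    def test_zlib_equals_uncompressed_twin(self):
        plain = parse_mzml_spectrum(
            mzml_spectrum_xml([100.0, 200.0], [1.0, 2.0]), MZML_DIALECT, 0
        )
        packed = parse_mzml_spectrum(
            mzml_spectrum_xml([100.0, 200.0], [1.0, 2.0], compression="zlib"),
            MZML_DIALECT, 0,
        )
        assert plain.peaks == packed.peaks

    def test_declared_length_mismatch(self):
        with pytest.raises(IntegrityError):
            parse_mzml_spectrum(
                mzml_spectrum_xml([100.0, 200.0], [1.0, 2.0], declared=5),
                MZML_DIALECT, 0,
            )

    def test_array_without_type_cvparam_is_dialect_error(self):
        payload = base64.b64encode(struct.pack("<1d", 1.0)).decode()
        xml = (
            '<spectrum id="scan=1" index="0" defaultArrayLength="1">'
            "<binaryDataArrayList count=\"1\"><binaryDataArray>"
            '<cvParam accession="MS:1000523" name="64-bit float"/>'
            f"<binary>{payload}</binary></binaryDataArray></binaryDataArrayList></spectrum>"
        ).encode()
        with pytest.raises(FormatDialectError):
            parse_mzml_spectrum(xml, MZML_DIALECT, 0)


class TestSpanVsStreamingEquivalence:
    @pytest.mark.parametrize("fmt", ["mzxml", "mzdata", "mzml"])
    def test_record_parsers_match_full_document_parse(self, fmt, tmp_path):
        from msreader.api import open_reader

        spectra = generate_spectra(FixtureSpec(n_spectra=5, seed=31))
        p = write_fixture(spectra, fmt, tmp_path / f"e.{fmt}")
        reader = open_reader(p)
        indexed = [reader.get_spectrum_by_index(i) for i in range(reader.count)]
        streamed = read_xml_file(p)
        assert indexed == streamed

    def test_64bit_values_survive_bit_exactly(self, tmp_path):
        spectra = generate_spectra(FixtureSpec(n_spectra=3, seed=37))
        for fmt in ("mzxml", "mzdata", "mzml"):
            p = write_fixture(spectra, fmt, tmp_path / f"x.{fmt}")
            got = read_xml_file(p)
            for orig, back in zip(spectra, got):
                assert [(p_.mz, p_.intensity) for p_ in back.peaks] == [
                    (p_.mz, p_.intensity) for p_ in orig.peaks
                ]
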
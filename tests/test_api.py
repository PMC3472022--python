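from __future__ import annotations

import json
import os

import pytest

from msreader.api import (
    DirectoryReader,
    FormatId,
    Reader,
    ReferenceScheme,
    open_reader,
    sniff_format,
)
from msreader.errors import (
    ReferenceFormatError,
    ReferenceNotFoundError,
    StaleIndexError,
    UnsupportedFormatError,
)
from msreader.fixtures import FixtureSpec, generate_spectra, write_fixture

from conftest import ALL_FORMATS


def open_any(tmp_path, spectra, kind):
    """Open one of the 9 access modes: 7 single files + 2 directory modes."""
    if kind.startswith("dir:"):
        fmt = kind.split(":", 1)[1]
        d = tmp_path / f"{fmt}_dir"
        write_fixture(spectra, fmt, d, directory=True)
        return open_reader(d)
    return open_reader(write_fixture(spectra, kind, tmp_path / f"u.{kind}"))


ALL_MODES = ALL_FORMATS + ["dir:dta", "dir:pkl"]


class TestFormatId:
    def test_exactly_seven_formats(self):
        assert len(FormatId) == 7
        assert {f.value for f in FormatId} == {
            "dta", "pkl", "mgf", "ms2", "mzxml", "mzdata", "mzml"
        }

    def test_exactly_three_reference_schemes(self):
        assert len(ReferenceScheme) == 3


class TestSniffing:
    @pytest.mark.parametrize("fmt", ALL_FORMATS)
    def test_extension_and_content_sniffing(self, fmt, tmp_path, base_spectra):
        p = write_fixture(base_spectra, fmt, tmp_path / f"s.{fmt}")
        assert sniff_format(p) is FormatId(fmt)
        # content probe alone (extension hidden)
        hidden = tmp_path / "noext.bin"
        hidden.write_bytes(open(p, "rb").read())
        if fmt not in ("dta", "pkl"):  # 2- vs 3-column probe is exact here too
            assert sniff_format(hidden) is FormatId(fmt)

    def test_unknown_content_rejected(self, tmp_path):
        p = tmp_path / "junk.xyz"
        p.write_text("complete nonsense\nnothing numeric\n")
        with pytest.raises(UnsupportedFormatError):
            open_reader(p)


class TestUniformInterface:
    """The same contract holds across all 7 formats and both directory modes."""

    @pytest.mark.parametrize("kind", ALL_MODES)
    def test_count_matches_ids_and_iteration(self, kind, tmp_path, base_spectra):
        r = open_any(tmp_path, base_spectra, kind)
        assert r.count == len(base_spectra)
        assert len(r.get_spectra_ids()) == r.count
        assert len(list(r.iterate())) == r.count

    @pytest.mark.parametrize("kind", ALL_MODES)
    def test_by_index_equals_iteration_order(self, kind, tmp_path, base_spectra):
        r = open_any(tmp_path, base_spectra, kind)
        iterated = list(r.iterate())
        for i in range(r.count):
            assert r.get_spectrum_by_index(i) == iterated[i]

    @pytest.mark.parametrize("kind", ALL_MODES)
    def test_every_listed_id_resolves(self, kind, tmp_path, base_spectra):
        r = open_any(tmp_path, base_spectra, kind)
        for i, spectrum_id in enumerate(r.get_spectra_ids()):
            assert r.get_spectrum_by_id(spectrum_id).position == i

    @pytest.mark.parametrize("kind", ALL_MODES)
    def test_out_of_range_position(self, kind, tmp_path, base_spectra):
        r = open_any(tmp_path, base_spectra, kind)
        with pytest.raises(ReferenceNotFoundError):
            r.get_spectrum_by_index(r.count)

    @pytest.mark.parametrize("fmt", ALL_FORMATS)
    def test_export_restore_equivalence(self, fmt, tmp_path, base_spectra):
        p = write_fixture(base_spectra, fmt, tmp_path / f"x.{fmt}")
        r1 = open_reader(p)
        saved = r1.export_index()
        r2 = open_reader(p, saved_index=saved)
        assert r2.count == r1.count
        for i in range(r1.count):
            assert r1.get_spectrum_by_index(i) == r2.get_spectrum_by_index(i)


class TestReferenceSchemes:
    def test_mzdata_by_native_id(self, tmp_path):
        spectra = generate_spectra(FixtureSpec(n_spectra=2, seed=8))
        p = write_fixture(spectra, "mzdata", tmp_path / "d.mzdata", id_start=10)
        r = open_reader(p)
        assert r.scheme is ReferenceScheme.BY_ID
        assert r.get_spectrum_by_id("10").position == 0
        assert r.get_spectrum_by_id("11").position == 1

    def test_mgf_positional_id_is_zero_based(self, tmp_path, base_spectra):
        r = open_reader(write_fixture(base_spectra, "mgf", tmp_path / "m.mgf"))
        assert r.scheme is ReferenceScheme.BY_POSITION
        assert r.get_spectrum_by_id("1") == r.get_spectrum_by_index(1)

    def test_positional_formats_reject_non_numeric_ids(self, tmp_path, base_spectra):
        r = open_reader(write_fixture(base_spectra, "ms2", tmp_path / "m.ms2"))
        with pytest.raises(ReferenceFormatError):
            r.get_spectrum_by_id("scan=1")

    def test_dta_directory_by_filename(self, tmp_path, base_spectra):
        d = tmp_path / "dtas"
        write_fixture(base_spectra, "dta", d, directory=True)
        r = open_reader(d)
        assert r.scheme is ReferenceScheme.BY_FILENAME
        assert r.get_spectrum_by_id("sample2.dta").position == 2
        assert r.get_spectrum_by_id("sample2").position == 2  # extensionless form

    def test_mzxml_scan_number_canonical_integer_match(self, tmp_path, base_spectra):
        r = open_reader(write_fixture(base_spectra, "mzxml", tmp_path / "x.mzxml"))
        assert r.get_spectrum_by_id("2") == r.get_spectrum_by_id("02")

    def test_mzml_verbatim_id(self, tmp_path, base_spectra):
        r = open_reader(write_fixture(base_spectra, "mzml", tmp_path / "m.mzml"))
        assert r.get_spectrum_by_id("scan=3").position == 2
        with pytest.raises(ReferenceNotFoundError):
            r.get_spectrum_by_id("3")  # only the verbatim string matches

    def test_by_id_formats_keep_positional_access(self, tmp_path, base_spectra):
        r = open_reader(write_fixture(base_spectra, "mzml", tmp_path / "m.mzml"))
        assert r.get_spectrum_by_index(0).native_id == "scan=1"

    @pytest.mark.parametrize("fmt", ["dta", "pkl", "ms2", "mgf"])
    def test_by_id_equals_by_index_for_positional_formats(self, fmt, tmp_path, base_spectra):
        r = open_reader(write_fixture(base_spectra, fmt, tmp_path / f"p.{fmt}"))
        for k in range(r.count):
            assert r.get_spectrum_by_id(str(k)) == r.get_spectrum_by_index(k)


class TestCrossFormatEquality:
    def test_same_spectra_through_all_seven_formats(self, fixture_files, base_spectra):
        readings = {}
        for fmt, path in fixture_files.items():
            readings[fmt] = list(open_reader(path).iterate())
        for fmt, spectra in readings.items():
            assert len(spectra) == len(base_spectra), fmt
            for orig, got in zip(base_spectra, spectra):
                assert [(p.mz, p.intensity) for p in got.peaks] == [
                    (p.mz, p.intensity) for p in orig.peaks
                ], fmt
                assert got.precursor.mz == pytest.approx(orig.precursor.mz, rel=1e-6), fmt
                assert got.precursor.charges == orig.precursor.charges, fmt


class TestSavedIndexBehaviour:
    def test_stale_after_truncation(self, tmp_path, base_spectra):
        p = write_fixture(base_spectra, "mzxml", tmp_path / "t.mzxml")
        saved = open_reader(p).export_index()
        data = open(p, "rb").read()
        with open(p, "wb") as fh:
            fh.write(data[: len(data) // 2])
        with pytest.raises(StaleIndexError):
            open_reader(p, saved_index=saved)

    def test_reopen_with_index_skips_the_scan(self, tmp_path, monkeypatch):
        import msreader.index as ix_mod

        spectra = generate_spectra(
            FixtureSpec(n_spectra=80, seed=17, peaks_min=20, peaks_max=40)
        )
        p = write_fixture(spectra, "mgf", tmp_path / "big.mgf")
        file_size = os.path.getsize(p)
        assert file_size > 40_000  # must dwarf the fingerprint probes
        saved = open_reader(p).export_index()

        counted = {"bytes": 0}
        real_open = open

        def counting_open(path, *args, **kwargs):
            fh = real_open(path, *args, **kwargs)
            if str(path) == str(p):
                real_read = fh.read

                def read(n=-1):
                    data = real_read(n)
                    counted["bytes"] += len(data)
                    return data

                fh.read = read
            return fh

        monkeypatch.setattr(ix_mod, "open", counting_open, raising=False)
        r = open_reader(p, saved_index=saved)
        # fingerprint (2 x 8 KiB) + header span only; never the whole file
        assert counted["bytes"] < file_size
        assert r.count == 80

    def test_directory_export_is_per_file_map(self, tmp_path, base_spectra):
        d = tmp_path / "pkls"
        write_fixture(base_spectra, "pkl", d, directory=True)
        r = open_reader(d)
        doc = json.loads(r.export_index())
        assert doc["version"] == "msreader-index-dir/1"
        assert set(doc["files"]) == set(r.get_spectra_ids())
        for sub in doc["files"].values():
            assert sub["version"] == "msreader-index/1"
            assert len(sub["records"]) == 1


class TestDirectoryReader:
    def test_lexicographic_order(self, tmp_path, base_spectra):
        d = tmp_path / "dd"
        write_fixture(base_spectra, "dta", d, directory=True)
        r = open_reader(d)
        assert r.get_spectra_ids() == sorted(r.get_spectra_ids())

    def test_directory_with_wrong_format_rejected(self, tmp_path):
        d = tmp_path / "mix"
        d.mkdir()
        (d / "a.mgf").write_text("BEGIN IONS\nEND IONS\n")
        with pytest.raises(UnsupportedFormatError):
            open_reader(d)

    def test_explicit_non_dta_pkl_format_rejected(self, tmp_path):
        d = tmp_path / "dir2"
        d.mkdir()
        with pytest.raises(UnsupportedFormatError):
            DirectoryReader(str(d), FormatId.MGF)


class TestLenientVsStrict:
    def test_lenient_iteration_skips_broken_record(self, tmp_path, base_spectra):
        from msreader.fixtures import corrupt_fixture

        p = write_fixture(base_spectra, "mgf", tmp_path / "broken.mgf")
        corrupt_fixture(p, "drop_end_ions")
        r = open_reader(p)
        with pytest.warns(UserWarning):
            survivors = list(r.iterate())
        assert len(survivors) == len(base_spectra) - 1

    def test_strict_iteration_raises(self, tmp_path, base_spectra):
        from msreader.errors import MalformedRecordError
        from msreader.fixtures import corrupt_fixture

        p = write_fixture(base_spectra, "mgf", tmp_path / "broken.mgf")
        corrupt_fixture(p, "drop_end_ions")
        r = open_reader(p, mode="strict")
        with pytest.raises(MalformedRecordError):
            list(r.iterate())
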
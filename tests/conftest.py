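from __future__ import annotations

import pytest

from msreader.fixtures import FixtureSpec, generate_spectra, write_fixture

ALL_FORMATS = ["dta", "pkl", "mgf", "ms2", "mzxml", "mzdata", "mzml"]
TEXT_FORMATS = ["dta", "pkl", "mgf", "ms2"]
XML_FORMATS = ["mzxml", "mzdata", "mzml"]


@pytest.fixture(scope="session")
def base_spectra():
    return generate_spectra(FixtureSpec(n_spectra=4, seed=42))


@pytest.fixture(scope="session")
def fixture_files(base_spectra, tmp_path_factory):
    """One file per format, all holding the same synthetic spectra."""
    root = tmp_path_factory.mktemp("fixtures")
    paths = {}
    for fmt in ALL_FORMATS:
        paths[fmt] = write_fixture(base_spectra, fmt, root / f"sample.{fmt}")
    return paths


@pytest.fixture()
def mutable_file(base_spectra, tmp_path):
    """Factory for a throw-away copy of a fixture in one format."""

    def make(fmt: str, **options):
        return write_fixture(base_spectra, fmt, tmp_path / f"mut.{fmt}", **options)

    return make
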
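# msreader

One Python interface over seven mass-spectrometry data formats: the text
peak lists **DTA**, **PKL**, **MGF**, **MS2** and the XML containers
**mzXML** (2.1–3.2), **mzData** (1.05) and a minimal **mzML** 1.1 subset.

Every format is parsed behind a common `Reader` that supports

* **indexed random access** — spectra are located by a byte-range index
  built in one buffered streaming scan; fetching one spectrum reads only
  its record bytes, never the whole file;
* **the three spectrum-referencing schemes** used by identification
  formats: native id (mzData/mzXML/mzML), 0-based position
  (DTA/PKL/MS2/MGF) and filename (directories of single-spectrum
  DTA/PKL files) — all behind one `get_spectrum_by_id`;
* **persistable indexes** — a versioned JSON document that lets a later
  open skip the indexing scan, with fingerprint-based stale detection;
* **MGF export** from any supported format.

Positions are **0-based** everywhere (API, CLI, index files).

## Library quick start

```python
from msreader import open_reader, write_mgf

reader = open_reader("run.mzxml")          # format is sniffed
print(reader.count, reader.scheme)         # e.g. 4  ReferenceScheme.BY_ID
s = reader.get_spectrum_by_id("7")         # mzXML scan number
s = reader.get_spectrum_by_index(0)        # positional access always works
for s in reader:                           # lazy, one record at a time
    print(s.native_id, len(s.peaks), s.precursor)

saved = reader.export_index()              # JSON text; store anywhere
reader = open_reader("run.mzxml", saved_index=saved)  # skips the scan

write_mgf(reader.iterate(), "run.mgf")     # convert anything to MGF
```

Per-format parsers (`msreader.formats_text`, `msreader.formats_xml`) are
usable standalone, and `msreader.fixtures` generates deterministic
synthetic files in all seven formats for testing.

## CLI

```sh
msreader info    run.mzml                  # format, version, count, scheme
msreader list    run.mzml                  # position, id, level, m/z, peaks
msreader get     run.mzml --id "scan=3"    # or --index 2; add --json
msreader convert run.mzxml --out run.mgf
msreader index   run.mgf --out idx.json    # persist the index
msreader index   run.mgf --use idx.json    # validate it against the file
msreader validate run.mgf                  # strict parse; exit 0 iff clean
```

Errors map to distinct exit codes: 2 unsupported format, 3 malformed
record, 4 integrity (declared counts disagree with content), 5 stale
index, 6 reference not found.

## Notes

* The proton mass used for (M+H)+ ↔ m/z conversion is 1.00727646688 Da.
* mzXML binary peak payloads are big-endian interleaved pairs; mzData
  honours its `endian` attribute; mzML arrays are little-endian.
  zlib compression is accepted for mzXML ≥ 3.0 and mzML.
* Peaks are kept as a list (duplicate m/z values survive round trips)
  and sorted ascending by m/z with ties broken by descending intensity;
  a reorder is flagged in the spectrum's extras.
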
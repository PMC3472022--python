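"""Format-neutral spectrum model: the smallest common denominator of all
seven supported formats plus an extras bag that preserves everything a
format knows beyond it.

Positions are 0-based everywhere in this library (API, CLI, index files).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import MalformedRecordError

__all__ = [
    "Peak",
    "PrecursorInfo",
    "ParamEntry",
    "Spectrum",
    "normalize_spectrum",
    "peaks_as_arrays",
]

REORDERED_FLAG = "peaks_reordered"


@dataclass(frozen=True)
class Peak:
    """One (m/z, intensity[, charge]) triple.

    mz is in Thomson and must be positive; intensity is in arbitrary units
    and must be non-negative. charge only ever comes from an MGF per-peak
    third column.
    """

    mz: float
    intensity: float
    charge: int | None = None


@dataclass
class PrecursorInfo:
    """Precursor ion description; at least one of mz / mh_plus is present.

    mh_plus is the singly protonated mass (M+H)+ in Da, as stored by DTA
    headers and MS2 Z-lines. charges may hold more than one entry for
    multi-Z MS2 records.
    """

    mz: float | None = None
    mh_plus: float | None = None
    intensity: float | None = None
    charges: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class ParamEntry:
    """One name/value[/accession] metadata entry preserved from the source file."""

    name: str
    value: str | None = None
    accession: str | None = None


@dataclass
class Spectrum:
    """One mass spectrum, format neutral.

    Attributes
    ----------
    source : str
        Path of the file (or directory member) the spectrum came from.
    position : int
        0-based ordinal of the record within its source.
    native_id : str or None
        The identifier the format itself assigns (mzData/mzML ``id``,
        mzXML scan ``num`` as text); None for purely positional formats.
    peaks : list of Peak
        Sorted ascending by m/z after :func:`normalize_spectrum`.
    extras : list of ParamEntry
        Format-specific metadata preserved verbatim.
    """

    source: str
    position: int
    native_id: str | None = None
    ms_level: int | None = None
    retention_seconds: float | None = None
    polarity: str | None = None
    precursor: PrecursorInfo | None = None
    peaks: list[Peak] = field(default_factory=list)
    extras: list[ParamEntry] = field(default_factory=list)


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Return ``s`` with peaks sorted ascending by m/z (ties: descending intensity).

    Validates the per-peak invariants (mz > 0, intensity >= 0). When the
    file order had to be changed, a ``peaks_reordered`` flag is appended to
    extras so the original ordering fact is not silently lost. Idempotent.
    """
    for p in s.peaks:
        if not (p.mz > 0):
            raise MalformedRecordError(
                f"non-positive m/z {p.mz!r} in {s.source} position {s.position}"
            )
        if p.intensity < 0:
            raise MalformedRecordError(
                f"negative intensity {p.intensity!r} in {s.source} position {s.position}"
            )
    ordered = sorted(s.peaks, key=lambda p: (p.mz, -p.intensity))
    if ordered == s.peaks:
        return replace(s, peaks=ordered)
    extras = list(s.extras)
    if not any(e.name == REORDERED_FLAG for e in extras):
        extras.append(ParamEntry(REORDERED_FLAG, "true"))
    return replace(s, peaks=ordered, extras=extras)


def peaks_as_arrays(s: Spectrum) -> tuple[list[float], list[float]]:
    """Project the peak list into two positionally aligned sequences (mz, intensity)."""
    return [p.mz for p in s.peaks], [p.intensity for p in s.peaks]
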
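"""Peak detection and wavenumber -> molecule assignment.

The shipped :class:`AssignmentTable` encodes the biomolecule assignments
used when interpreting 785 nm live-cell SERS spectra: DNA nucleotide
lines (720 adenine, 790 cytosine, ...), mitochondrial cytochrome hemes
(750 heme C vs 760 heme B), RNA, protein, lipid and carbohydrate lines,
plus the substrate lines seen from nanostructures outside a cell.  The
table is deliberately extensible — it carries the in-text subset of the
literature, each entry with a citation tag.

Ambiguity is preserved, never collapsed: 720 cm^-1 is listed under both
adenine (DNA) and phospholipids, and the contextual rule that separates
them (absence of the strong 1445 cm^-1 lipid line implies adenine) is
exposed as the explicit :func:`disambiguate_adenine_lipid` operation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.signal import find_peaks

from .spectral import Spectrum, SpectralError

__all__ = [
    "PeakAssignment",
    "AssignmentTable",
    "DetectedPeak",
    "detect_peaks",
    "assign",
    "disambiguate_adenine_lipid",
]


@dataclass(frozen=True)
class PeakAssignment:
    """One literature assignment: a center or window, molecule and note.

    ``molecule`` is the specific species ("cytosine", "heme C", ...);
    ``group`` is its molecule class (DNA, RNA, heme, protein, lipid,
    carbohydrate, substrate, other).
    """

    molecule: str
    note: str
    source: str
    group: str = "other"
    center: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.center is None and (self.lo is None or self.hi is None):
            raise SpectralError("assignment needs a center or a (lo, hi) window")
        if self.center is not None and self.center <= 0:
            raise SpectralError("center must be positive")
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise SpectralError("assignment window needs lo < hi")
        if not self.source:
            raise SpectralError("every assignment carries a source tag")

    def distance(self, position: float) -> float:
        """0 inside a window; otherwise distance to the center/nearest edge."""
        if self.center is not None:
            return abs(position - self.center)
        assert self.lo is not None and self.hi is not None
        if self.lo <= position <= self.hi:
            return 0.0
        return min(abs(position - self.lo), abs(position - self.hi))

    def matches(self, position: float, tolerance: float) -> bool:
        return self.distance(position) <= (
            tolerance if self.center is not None else 0.0
        )


@dataclass(frozen=True)
class AssignmentTable:
    entries: tuple[PeakAssignment, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise SpectralError("assignment table must be non-empty")

    @classmethod
    def default(cls) -> "AssignmentTable":
        data = resources.files("cellmap.data").joinpath("assignments.yaml")
        return cls.from_yaml_text(data.read_text())

    @classmethod
    def from_yaml_text(cls, text: str) -> "AssignmentTable":
        raw = yaml.safe_load(text)
        return cls(tuple(PeakAssignment(**e) for e in raw["entries"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssignmentTable":
        return cls.from_yaml_text(Path(path).read_text())

    def to_yaml(self, path: str | Path) -> None:
        entries = [
            {k: v for k, v in asdict(e).items() if v is not None}
            for e in self.entries
        ]
        Path(path).write_text(yaml.safe_dump({"entries": entries}, sort_keys=False))


@dataclass(frozen=True)
class DetectedPeak:
    position: float  # cm^-1
    height: float
    prominence: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.prominence <= 0:
            raise SpectralError("detected peak needs positive height and prominence")


def detect_peaks(
    spectrum: Spectrum, min_prominence: float, min_separation: float
) -> list[DetectedPeak]:
    """Local maxima of a baseline-subtracted spectrum, sorted by position.

    ``min_separation`` is in cm^-1 and is converted to a sample distance
    using the median axis step; of two peaks closer than that, only the
    taller survives (scipy's distance rule).
    """
    if min_prominence <= 0 or min_separation <= 0:
        raise SpectralError("detection thresholds must be positive")
    x = spectrum.axis.values
    step = float(np.median(np.diff(x)))
    distance = max(1, int(round(min_separation / step)))
    idx, props = find_peaks(
        spectrum.intensities, prominence=min_prominence, distance=distance
    )
    peaks = [
        DetectedPeak(float(x[i]), float(spectrum.intensities[i]), float(p))
        for i, p in zip(idx, props["prominences"])
        if spectrum.intensities[i] > 0
    ]
    return sorted(peaks, key=lambda p: p.position)


def assign(
    peak: DetectedPeak, table: AssignmentTable, tolerance: float = 5.0
) -> list[PeakAssignment]:
    """All table entries matching the peak position, nearest first.

    Center entries match within +/- tolerance; window entries match when
    the position lies inside the window.  Multiple hits are preserved
    (e.g. 720 cm^-1 -> adenine and phospholipid); ties keep table order.
    """
    if tolerance <= 0:
        raise SpectralError("tolerance must be positive")
    hits = [e for e in table.entries if e.matches(peak.position, tolerance)]
    return sorted(hits, key=lambda e: e.distance(peak.position))


def disambiguate_adenine_lipid(
    spectrum_or_peaks: Spectrum | Sequence[DetectedPeak],
    table: AssignmentTable,
    min_prominence: float = 1.0,
    min_separation: float = 5.0,
    tolerance: float = 5.0,
) -> str:
    """Resolve the 720 cm^-1 adenine-vs-phospholipid ambiguity.

    The 720 cm^-1 line belongs to adenine in DNA and to phospholipids at
    the same time; the strongest lipid line at 1445 cm^-1 arbitrates:

    * no detected peak in 1440-1450 cm^-1  -> ``"adenine"``
    * 1445 present and no other DNA line   -> ``"phospholipid"``
    * both lines of evidence present        -> ``"ambiguous"``

    Accepts either a baseline-subtracted spectrum (peaks are detected
    with the given thresholds) or a pre-detected peak list.
    """
    if isinstance(spectrum_or_peaks, Spectrum):
        peaks = detect_peaks(spectrum_or_peaks, min_prominence, min_separation)
    else:
        peaks = list(spectrum_or_peaks)
    if not any(abs(p.position - 720.0) <= tolerance for p in peaks):
        raise SpectralError("no detected peak near 720 cm^-1 to disambiguate")
    has_1445 = any(1440.0 <= p.position <= 1450.0 for p in peaks)
    if not has_1445:
        return "adenine"
    dna_elsewhere = False
    for p in peaks:
        if abs(p.position - 720.0) <= tolerance:
            continue
        if any(e.group == "DNA" for e in assign(p, table, tolerance)):
            dna_elsewhere = True
            break
    if not dna_elsewhere:
        return "phospholipid"
    return "ambiguous"
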
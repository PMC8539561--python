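"""Core domain types and I/O for SERS hyperspectral data.

The atomic object is a :class:`Spectrum` — one strictly increasing
wavenumber axis (Raman shift, cm^-1) plus an intensity vector in detector
counts.  A :class:`HyperspectralImage` is an H x W grid of spectra sharing
a single axis, acquired on a regular pixel grid (default pitch 1 um).

Band windows (the frequency ranges the per-pixel RMS statistic is taken
over) live in a :class:`BandRegistry`.  Two registries are kept distinct:

* *imaging bands* — the narrow mapping windows used to build molecular
  maps (DNA 655-680, heme 740-765, RNA 825-835, protein 995-1010), plus
  the 500-520 cm^-1 noise window used as the per-spectrum normalisation
  denominator;
* *assignment bands* — the broader interpretation windows used when
  reading peaks off a single spectrum (DNA 660-690, 790-805, 1300-1350;
  RNA 805-850, around 1510; hemes 730-765; lipids 700-730, 1300-1330,
  1430-1470; proteins 1000-1010, 1360-1370).

Conventions: the axis is stored ascending (readers reorder descending
input; everything else raises on a non-monotonic axis), band membership is
the closed interval lo <= nu <= hi evaluated on native axis samples, and
the pixel grid is row-major with the origin at the top-left.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "SpectralAxis",
    "Spectrum",
    "HyperspectralImage",
    "Band",
    "BandRegistry",
    "SpectralError",
    "ParseError",
    "EmptyBandError",
    "read_spectrum",
    "write_spectrum",
    "read_cube",
    "write_cube",
    "default_registry",
    "band_mask",
]

MOLECULE_CLASSES = frozenset(
    {"DNA", "RNA", "heme", "protein", "lipid", "carbohydrate", "noise", "other"}
)
CHANNELS = frozenset({"red", "green", "blue", "none"})


class SpectralError(ValueError):
    """Base error for domain invariant violations."""


class ParseError(SpectralError):
    """Raised when a text spectrum cannot be parsed."""


class EmptyBandError(SpectralError):
    """Raised when a band contains no samples of the axis it is evaluated on."""


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectralError("axis must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise SpectralError("axis values must be finite and positive")
        if not np.all(np.diff(v) > 0):
            raise SpectralError("axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: intensities (detector counts) on a shared axis.

    ``meta`` is free-form provenance (acquisition point, recipe used, ...).
    """

    axis: SpectralAxis
    intensities: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.axis),):
            raise SpectralError(
                f"intensities length {y.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise SpectralError("intensities must be finite")
        object.__setattr__(self, "intensities", y)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.axis, self.intensities * factor, dict(self.meta))


@dataclass(frozen=True)
class HyperspectralImage:
    """H x W grid of spectra on one shared axis.

    ``cube`` has shape (H, W, K) with K == len(axis); ``pixel_pitch_um``
    is the scan step in micrometres (1 um in the source acquisitions).
    """

    axis: SpectralAxis
    cube: np.ndarray
    pixel_pitch_um: float = 1.0
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.cube, dtype=float)
        if c.ndim != 3:
            raise SpectralError("cube must be H x W x K")
        if c.shape[2] != len(self.axis):
            raise SpectralError(
                f"cube spectral depth {c.shape[2]} != axis length {len(self.axis)}"
            )
        if self.pixel_pitch_um <= 0:
            raise SpectralError("pixel_pitch_um must be positive")
        object.__setattr__(self, "cube", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col], {"row": row, "col": col})


@dataclass(frozen=True)
class Band:
    """Named closed wavenumber window [lo, hi] with a molecule class."""

    name: str
    lo: float
    hi: float
    molecule_class: str = "other"
    channel: str = "none"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SpectralError(f"band {self.name!r}: lo must be < hi")
        if self.molecule_class not in MOLECULE_CLASSES:
            raise SpectralError(f"unknown molecule class {self.molecule_class!r}")
        if self.channel not in CHANNELS:
            raise SpectralError(f"unknown channel {self.channel!r}")

    def contains(self, wavenumber: float) -> bool:
        return self.lo <= wavenumber <= self.hi


def band_mask(axis: SpectralAxis, band: Band) -> np.ndarray:
    """Boolean mask of axis samples inside the closed band window.

    Raises :class:`EmptyBandError` when no axis sample falls in the band.
    """
    m = (axis.values >= band.lo) & (axis.values <= band.hi)
    if not m.any():
        raise EmptyBandError(
            f"band {band.name!r} [{band.lo}, {band.hi}] contains no samples of "
            f"axis spanning [{axis.values[0]}, {axis.values[-1]}] cm^-1"
        )
    return m


@dataclass(frozen=True)
class BandRegistry:
    """The imaging windows and the broader assignment windows, kept apart."""

    imaging_bands: tuple[Band, ...]
    assignment_bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        for group in (self.imaging_bands, self.assignment_bands):
            names = [b.name for b in group]
            if len(names) != len(set(names)):
                raise SpectralError("band names must be unique within a registry")
        n_noise = sum(b.molecule_class == "noise" for b in self.imaging_bands)
        if n_noise != 1:
            raise SpectralError(
                f"imaging bands must contain exactly one noise band, got {n_noise}"
            )

    def imaging(self, name: str) -> Band:
        for b in self.imaging_bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def noise_band(self) -> Band:
        return next(b for b in self.imaging_bands if b.molecule_class == "noise")

    def to_dict(self) -> dict:
        def enc(bands: Iterable[Band]) -> list[dict]:
            return [
                {
                    "name": b.name,
                    "lo": b.lo,
                    "hi": b.hi,
                    "molecule_class": b.molecule_class,
                    "channel": b.channel,
                }
                for b in bands
            ]

        return {
            "imaging_bands": enc(self.imaging_bands),
            "assignment_bands": enc(self.assignment_bands),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BandRegistry":
        def dec(items: Sequence[Mapping]) -> tuple[Band, ...]:
            return tuple(Band(**it) for it in items)

        return cls(dec(d["imaging_bands"]), dec(d["assignment_bands"]))


def default_registry() -> BandRegistry:
    """The standard band registry for 785 nm live-cell SERS maps.

    Imaging windows carry the RGB channel pairing used for the merged
    composites: DNA -> red, RNA -> green, mitochondrial hemes -> blue.
    The 500-520 cm^-1 window contains no cellular peaks and serves as the
    per-spectrum noise normaliser.
    """
    imaging = (
        Band("DNA", 655.0, 680.0, "DNA", "red"),
        Band("heme", 740.0, 765.0, "heme", "blue"),
        Band("RNA", 825.0, 835.0, "RNA", "green"),
        Band("protein", 995.0, 1010.0, "protein", "none"),
        Band("noise", 500.0, 520.0, "noise", "none"),
    )
    assignment = (
        Band("DNA_660_690", 660.0, 690.0, "DNA"),
        Band("DNA_790_805", 790.0, 805.0, "DNA"),
        Band("DNA_1300_1350", 1300.0, 1350.0, "DNA"),
        Band("RNA_805_850", 805.0, 850.0, "RNA"),
        Band("RNA_1505_1515", 1505.0, 1515.0, "RNA"),
        Band("heme_730_765", 730.0, 765.0, "heme"),
        Band("lipid_700_730", 700.0, 730.0, "lipid"),
        Band("lipid_1300_1330", 1300.0, 1330.0, "lipid"),
        Band("lipid_1430_1470", 1430.0, 1470.0, "lipid"),
        Band("protein_1000_1010", 1000.0, 1010.0, "protein"),
        Band("protein_1360_1370", 1360.0, 1370.0, "protein"),
    )
    return BandRegistry(imaging, assignment)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path, dialect: str = "two-column") -> Spectrum:
    """Read a spectrum from a plain-text file.

    ``dialect='two-column'``: whitespace- or comma-separated wavenumber and
    intensity columns; lines starting with ``#`` are comments.  A descending
    axis is reordered ascending (both columns together).

    ``dialect='long-table'``: CSV with columns ``wavenumber,intensity``
    (header optional).
    """
    path = Path(path)
    if dialect not in {"two-column", "long-table"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    wn: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if dialect == "long-table" and lineno == 1 and not _is_number(parts[0]):
                continue  # header row
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            try:
                wn.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if len(wn) < 2:
        raise ParseError(f"{path}: fewer than two data rows")
    w = np.array(wn)
    y = np.array(inten)
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    dup = np.flatnonzero(np.diff(w) == 0)
    if dup.size:
        raise ParseError(
            f"{path}: duplicate wavenumber(s) {sorted(set(w[dup].tolist()))}"
        )
    return Spectrum(SpectralAxis(w), y, {"source": str(path)})


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text (``# wavenumber intensity``)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1 intensity\n")
        for w, y in zip(spectrum.axis.values, spectrum.intensities):
            fh.write(f"{float(w)!r} {float(y)!r}\n")


def write_cube(img: HyperspectralImage, path: str | Path) -> None:
    """Write a cube container.

    ``.h5``/``.hdf5``: datasets ``/axis`` (float64, K) and ``/cube``
    (float64, H x W x K), root attribute ``pixel_pitch_um``.
    ``.csv``: long-table fallback with columns row,col,wavenumber,intensity.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("axis", data=img.axis.values, dtype="float64")
            f.create_dataset("cube", data=img.cube, dtype="float64")
            f.attrs["pixel_pitch_um"] = float(img.pixel_pitch_um)
    elif path.suffix.lower() == ".csv":
        H, W = img.shape
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["row", "col", "wavenumber", "intensity"])
            wr.writerow(["# pixel_pitch_um", img.pixel_pitch_um, "", ""])
            for r in range(H):
                for c in range(W):
                    for w, y in zip(img.axis.values, img.cube[r, c]):
                        wr.writerow([r, c, repr(float(w)), repr(float(y))])
    else:
        raise ValueError(f"unsupported cube format {path.suffix!r}")


def read_cube(path: str | Path) -> HyperspectralImage:
    """Read a cube written by :func:`write_cube` (HDF5 or long-table CSV)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            axis = np.asarray(f["axis"][...], dtype=float)
            cube = np.asarray(f["cube"][...], dtype=float)
            pitch = float(f.attrs.get("pixel_pitch_um", 1.0))
        if cube.ndim != 3 or cube.shape[2] != axis.size:
            raise SpectralError(
                f"{path}: cube shape {cube.shape} inconsistent with axis "
                f"length {axis.size}"
            )
        return HyperspectralImage(SpectralAxis(axis), cube, pitch)
    if path.suffix.lower() == ".csv":
        return _read_cube_csv(path)
    raise ValueError(f"unsupported cube format {path.suffix!r}")


def _read_cube_csv(path: Path) -> HyperspectralImage:
    rows: list[int] = []
    cols: list[int] = []
    wns: list[float] = []
    ys: list[float] = []
    pitch = 1.0
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        for rec in rd:
            if not rec:
                continue
            if rec[0] == "row":
                continue
            if rec[0].startswith("#"):
                if "pitch" in rec[0]:
                    pitch = float(rec[1])
                continue
            rows.append(int(rec[0]))
            cols.append(int(rec[1]))
            wns.append(float(rec[2]))
            ys.append(float(rec[3]))
    H = max(rows) + 1
    W = max(cols) + 1
    axis_vals = np.array(sorted(set(wns)))
    K = axis_vals.size
    if len(ys) != H * W * K:
        raise SpectralError(f"{path}: incomplete long-table cube")
    idx = {w: k for k, w in enumerate(axis_vals.tolist())}
    cube = np.empty((H, W, K))
    for r, c, w, y in zip(rows, cols, wns, ys):
        cube[r, c, idx[w]] = y
    return HyperspectralImage(SpectralAxis(axis_vals), cube, pitch)
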
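"""AFM film thickness from the height histogram of a scratched layer.

A soft film (e.g. the polymer adhesion layer anchoring nanostar
aggregates) is scratched down to the substrate, the topography image is
flattened by removing a low-order polynomial background, and the height
histogram of the scratch neighbourhood becomes bimodal: one mode at the
substrate floor, one at the film surface.  The film thickness is the
separation of the two mode centers, each refined by a parabolic fit
through the three bins around the mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .spectral import SpectralError

__all__ = [
    "HeightMap",
    "read_heightmap",
    "flatten",
    "thickness_from_histogram",
]


@dataclass(frozen=True)
class HeightMap:
    """AFM topography in nm on a square pixel grid.

    ``scratch_mask``, when given, marks the scratched region; only the
    mask plus a dilated border is histogrammed, localising the two height
    populations.
    """

    heights: np.ndarray
    pixel_pitch_nm: float = 1.0
    scratch_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise SpectralError("height map must be 2-D")
        if not np.all(np.isfinite(h)):
            raise SpectralError("heights must be finite")
        if self.pixel_pitch_nm <= 0:
            raise SpectralError("pixel pitch must be positive")
        object.__setattr__(self, "heights", h)
        if self.scratch_mask is not None:
            m = np.asarray(self.scratch_mask, dtype=bool)
            if m.shape != h.shape:
                raise SpectralError("scratch mask shape must match heights")
            object.__setattr__(self, "scratch_mask", m)


def read_heightmap(path: str | Path, pixel_pitch_nm: float = 1.0) -> HeightMap:
    """Read a plain ASCII matrix export (whitespace-separated rows).

    Lines starting with ``#`` (Gwyddion-style headers) are skipped.
    """
    h = np.loadtxt(Path(path), comments="#")
    return HeightMap(np.atleast_2d(h), pixel_pitch_nm)


def _poly2d_design(shape: tuple[int, int], degree: int) -> np.ndarray:
    H, W = shape
    # normalised coordinates for conditioning
    yy, xx = np.mgrid[0:H, 0:W]
    y = (yy.ravel() - (H - 1) / 2) / max(H - 1, 1)
    x = (xx.ravel() - (W - 1) / 2) / max(W - 1, 1)
    cols = [np.ones_like(x)]
    if degree >= 1:
        cols += [x, y]
    if degree >= 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


def flatten(hmap: HeightMap, degree: int = 1, iterations: int = 3) -> HeightMap:
    """Remove a 2-D polynomial background (degree 0, 1 or 2) robustly.

    A plain least-squares plane through a scratched image tilts across the
    step, because the scratch population drags the fit.  The background is
    therefore levelled on the dominant terrace: after each fit the
    residual histogram is split by an Otsu threshold and, when the two
    clusters are genuinely separated (gap > 4x the within-cluster
    spread), the surface is refitted on the larger cluster only.  The
    returned map has exactly zero mean.
    """
    if degree not in (0, 1, 2):
        raise SpectralError("flatten degree must be 0, 1 or 2")
    A = _poly2d_design(hmap.heights.shape, degree)
    if hmap.heights.size < A.shape[1]:
        raise SpectralError("fewer pixels than background coefficients")
    z = hmap.heights.ravel()
    # terrace detection starts from median-centred raw heights: a full
    # least-squares fit of a stepped surface is already tilted, which
    # smears the two populations into a continuum
    resid = z - np.median(z)
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    for _ in range(iterations):
        sel = _dominant_terrace(resid)
        if sel is None or sel.sum() < A.shape[1]:
            break
        coef, *_ = np.linalg.lstsq(A[sel], z[sel], rcond=None)
        resid = z - A @ coef
    resid = z - A @ coef
    resid -= resid.mean()
    return HeightMap(resid.reshape(hmap.heights.shape), hmap.pixel_pitch_nm, hmap.scratch_mask)


def _dominant_terrace(resid: np.ndarray) -> np.ndarray | None:
    """Mask of the larger height population when the residuals are bimodal."""
    thr = threshold_otsu(resid)
    low = resid <= thr
    high = ~low
    if low.sum() < 2 or high.sum() < 2:
        return None
    gap = float(resid[high].mean() - resid[low].mean())
    spread = max(float(resid[low].std()), float(resid[high].std()), 1e-30)
    if gap <= 4.0 * spread:
        return None  # effectively unimodal: keep the full-image fit
    return low if low.sum() >= high.sum() else high


def _default_bin_width(values: np.ndarray) -> float:
    """max(0.1 nm, Freedman-Diaconis estimate)."""
    q75, q25 = np.percentile(values, [75, 25])
    fd = 2.0 * (q75 - q25) / max(values.size, 1) ** (1.0 / 3.0)
    return max(0.1, float(fd))


def thickness_from_histogram(
    hmap: HeightMap,
    bin_width: float | None = None,
    prominence_fraction: float = 0.05,
    border_px: int = 3,
) -> tuple[float, tuple[float, float]]:
    """Thickness (nm) and the two refined histogram peak centers.

    Heights (all pixels, or the scratch mask dilated by ``border_px``
    when a mask is present) are histogrammed with the given bin width
    (default: max of 0.1 nm and the Freedman-Diaconis estimate).  The two
    most prominent modes above ``prominence_fraction`` of the tallest bin
    are taken as substrate floor and film surface; each center is refined
    by parabolic interpolation over the three bins at the mode, and the
    thickness is their absolute separation.

    Raises when the distribution is not bimodal (e.g. no scratch).
    """
    if hmap.scratch_mask is not None:
        region = binary_dilation(hmap.scratch_mask, iterations=border_px)
        values = hmap.heights[region]
    else:
        values = hmap.heights.ravel()
    if bin_width is None:
        bin_width = _default_bin_width(values)
    if bin_width <= 0:
        raise SpectralError("bin width must be positive")
    lo = float(values.min()) - bin_width / 2
    nbins = int(np.ceil((float(values.max()) - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    padded = np.concatenate([[0.0], counts.astype(float), [0.0]])
    idx, props = find_peaks(padded, prominence=prominence_fraction * counts.max())
    idx = idx - 1  # undo padding offset
    if idx.size < 2:
        raise SpectralError("no bimodal height distribution")
    order = np.argsort(props["prominences"])[::-1]
    top2 = np.sort(idx[order[:2]])

    def refined(i: int) -> float:
        c = float(counts[i])
        l = float(counts[i - 1]) if i > 0 else 0.0
        r = float(counts[i + 1]) if i < counts.size - 1 else 0.0
        denom = l - 2 * c + r
        delta = 0.0 if denom == 0 else 0.5 * (l - r) / denom
        return float(centers[i] + np.clip(delta, -0.5, 0.5) * bin_width)

    c1, c2 = refined(int(top2[0])), refined(int(top2[1]))
    return abs(c2 - c1), (c1, c2)
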
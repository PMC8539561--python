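"""Baseline subtraction with one fixed recipe per image.

Live-cell SERS spectra at 785 nm ride on a strong, slowly varying
fluorescence background.  Before any band statistic is computed the
background is removed, and — critically — the *same* recipe is applied to
every pixel of an image, chosen once after inspecting a small sample of
spectra.  Per-pixel adaptation would distort the relative band-RMS values
the molecular maps are built from.

Two recipe families are supported:

* ``asymmetric-least-squares`` (default): the Eilers–Boelens smoother that
  minimises ``||w .* (y - z)||^2 + lam * ||D2 z||^2`` with asymmetric
  weights (w = p above the baseline, 1 - p below), iterated to
  convergence.  This is the standard fluorescence-background remover for
  cell Raman/SERS work.
* ``polynomial-through-anchors``: least-squares polynomial through
  user-chosen anchor wavenumbers, the anchor-based "recipe" style of
  interactive Raman tools.

Negative residuals are kept after subtraction (clipping at zero would bias
the downstream RMS statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solveh_banded

from .spectral import Band, HyperspectralImage, Spectrum, SpectralError

__all__ = [
    "BaselineRecipe",
    "fit_baseline",
    "subtract_baseline",
    "subtract_baseline_image",
    "suggest_recipe",
]

_METHODS = ("asymmetric-least-squares", "polynomial-through-anchors")


@dataclass(frozen=True)
class BaselineRecipe:
    """Parameters of one baseline-removal recipe.

    For ALS: ``smoothness`` is the lambda penalty on the second difference
    of the baseline (larger -> stiffer), ``asymmetry`` the weight p given
    to points above the baseline (small p lets peaks float above), and
    ``iterations`` the number of reweighting passes.

    For the polynomial mode: ``anchors`` are wavenumbers the polynomial is
    fitted through (None means the full axis) and ``degree`` its order.
    """

    method: str = "asymmetric-least-squares"
    smoothness: float = 1e5
    asymmetry: float = 0.01
    iterations: int = 10
    anchors: tuple[float, ...] | None = None
    degree: int = 3

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise SpectralError(f"unknown baseline method {self.method!r}")
        if self.method == "asymmetric-least-squares":
            if self.smoothness <= 0:
                raise SpectralError("smoothness must be positive")
            if not 0 < self.asymmetry < 1:
                raise SpectralError("asymmetry must lie in (0, 1)")
        if self.iterations < 1:
            raise SpectralError("iterations must be >= 1")
        if self.degree < 0:
            raise SpectralError("degree must be non-negative")
        if self.anchors is not None:
            object.__setattr__(self, "anchors", tuple(float(a) for a in self.anchors))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["anchors"] is not None:
            d["anchors"] = list(d["anchors"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaselineRecipe":
        d = dict(d)
        if d.get("anchors") is not None:
            d["anchors"] = tuple(d["anchors"])
        return cls(**d)


def _als_baseline(y: np.ndarray, lam: float, p: float, niter: int) -> np.ndarray:
    """Asymmetric least-squares baseline (banded Cholesky solve per pass).

    The system matrix W + lam * D2'D2 is symmetric pentadiagonal; it is
    assembled in LAPACK upper-banded form once per reweighting pass.
    """
    n = y.size
    if n < 3:
        raise SpectralError("ALS needs at least 3 samples")
    # banded form of lam * D2'D2 (bandwidth 2), rows are diagonals 2,1,0
    ab0 = np.empty((3, n))
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    ab0[0, 2:] = lam * 1.0  # second superdiagonal
    ab0[0, :2] = 0.0
    ab0[1, 1:] = lam * d1
    ab0[1, 0] = 0.0
    ab0[2, :] = lam * d0
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ab = ab0.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _poly_baseline(
    x: np.ndarray, y: np.ndarray, anchors: Sequence[float] | None, degree: int
) -> np.ndarray:
    if anchors is None:
        xa, ya = x, y
    else:
        idx = np.array([int(np.argmin(np.abs(x - a))) for a in anchors])
        xa, ya = x[idx], y[idx]
    if xa.size < degree + 1:
        raise SpectralError(
            f"polynomial baseline of degree {degree} needs >= {degree + 1} "
            f"support points, got {xa.size}"
        )
    # centre/scale for conditioning
    mid, half = x.mean(), max(np.ptp(x) / 2, 1.0)
    coeffs = np.polynomial.polynomial.polyfit((xa - mid) / half, ya, degree)
    return np.polynomial.polynomial.polyval((x - mid) / half, coeffs)


def fit_baseline(spectrum: Spectrum, recipe: BaselineRecipe) -> Spectrum:
    """Fit the baseline curve of one spectrum; returned on the same axis."""
    y = spectrum.intensities
    if recipe.method == "asymmetric-least-squares":
        base = _als_baseline(y, recipe.smoothness, recipe.asymmetry, recipe.iterations)
    else:
        base = _poly_baseline(spectrum.axis.values, y, recipe.anchors, recipe.degree)
    return Spectrum(spectrum.axis, base, {"role": "baseline", **dict(spectrum.meta)})


def subtract_baseline(spectrum: Spectrum, recipe: BaselineRecipe) -> Spectrum:
    """Fit and subtract; residuals keep their sign."""
    base = fit_baseline(spectrum, recipe)
    meta = dict(spectrum.meta)
    meta["baseline_recipe"] = recipe.to_dict()
    return Spectrum(spectrum.axis, spectrum.intensities - base.intensities, meta)


def subtract_baseline_image(
    img: HyperspectralImage, recipe: BaselineRecipe
) -> HyperspectralImage:
    """Apply one shared recipe to every pixel of the image."""
    H, W = img.shape
    out = np.empty_like(img.cube)
    for r in range(H):
        for c in range(W):
            try:
                out[r, c] = subtract_baseline(
                    Spectrum(img.axis, img.cube[r, c]), recipe
                ).intensities
            except SpectralError as exc:
                raise SpectralError(f"pixel (row={r}, col={c}): {exc}") from exc
    meta = dict(img.meta)
    meta["baseline_recipe"] = recipe.to_dict()
    return HyperspectralImage(img.axis, out, img.pixel_pitch_um, meta)


def default_recipe_grid() -> list[BaselineRecipe]:
    """Standard candidate grid for recipe selection.

    Spans the decades of ALS stiffness and asymmetry commonly scanned
    when tuning a fluorescence baseline by hand (lambda 1e5-1e7, p
    0.01-0.3), stiffest-first so ties favour recipes that cannot absorb
    peak intensity.
    """
    return [
        BaselineRecipe(smoothness=lam, asymmetry=p)
        for lam in (1e7, 1e6, 1e5)
        for p in (0.1, 0.3, 0.05, 0.01)
    ]


def suggest_recipe(
    spectra: Sequence[Spectrum],
    grid: Sequence[BaselineRecipe],
    exclude_bands: Sequence[Band] = (),
) -> BaselineRecipe:
    """Pick the candidate recipe that flattens a sample of spectra best.

    The selection criterion is a concrete surrogate for the analyst's
    by-eye choice: for each candidate, subtract its baseline from every
    sample spectrum and score the residual roughness on axis samples
    *outside* every band in ``exclude_bands`` — the median absolute
    residual there, which a sloped or offset residual inflates but which
    is robust to genuine peaks at wavenumbers the band list does not
    cover.  The candidate with the smallest mean score over the sample
    spectra wins; ties go to the first candidate in grid order, so the
    result is deterministic.
    """
    if len(spectra) < 2:
        raise SpectralError("suggest_recipe needs at least 2 sample spectra")
    if len(grid) == 0:
        raise SpectralError("candidate grid is empty")
    best: BaselineRecipe | None = None
    best_score = np.inf
    for cand in grid:
        scores = []
        for s in spectra:
            resid = subtract_baseline(s, cand).intensities
            mask = np.ones(len(s.axis), dtype=bool)
            for b in exclude_bands:
                mask &= ~((s.axis.values >= b.lo) & (s.axis.values <= b.hi))
            sel = resid[mask] if mask.any() else resid
            scores.append(float(np.median(np.abs(sel))))
        score = float(np.mean(scores))
        if score < best_score:
            best_score = score
            best = cand
    assert best is not None
    return best
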
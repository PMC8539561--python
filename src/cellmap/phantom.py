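"""Ground-truthed synthetic phantoms of live-cell SERS image acquisitions.

The phantom emulates the physics of nanostar-substrate SERS imaging of an
adherent cell:

* a ~20 um elliptical cell with a centred ~10 um nucleus, a nucleolus, a
  ring of perinuclear mitochondria, and a one-pixel membrane rim, on a
  1 um pixel grid;
* a nanostar-aggregate *hotspot* footprint covering a fraction of the
  field; SERS enhancement acts over only 1-2 nm, so cellular signal
  exists solely where a compartment sits on an aggregate (binary gate) —
  a cell on bare glass contributes nothing;
* component spectra built from Lorentzian lines at the wavenumbers
  characteristic of DNA, RNA, mitochondrial hemes, proteins, lipids,
  carbohydrates, and the substrate lines seen outside cells; no line
  falls in the 500-520 cm^-1 noise window, by construction;
* tip penetration through membranes, folded into per-compartment
  attenuation computed from the tip-length distribution (mean 36.9 nm,
  sd 5.8 nm) against ~10 nm per membrane crossed;
* optical blur of the abundance maps by a Gaussian PSF whose width
  derives from the Airy radius of the 785 nm / NA 0.5 focus;
* a fluorescence-like exponential baseline (brighter over the cell) and
  additive Gaussian detector noise.

Every draw comes from one ``numpy`` generator seeded by the mandatory
``seed`` argument, so a phantom is bit-exactly reproducible from
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from scipy.stats import norm

from .spectral import HyperspectralImage, SpectralAxis, SpectralError

__all__ = [
    "ComponentSpectrum",
    "CellGeometry",
    "HotspotModel",
    "PhantomParams",
    "Phantom",
    "COMPARTMENTS",
    "airy_radius",
    "default_library",
    "compartment_profiles",
    "generate_phantom",
]

# label image codes, priority nucleolus > nucleus > mitochondria > membrane
# > cytoplasm > outside
OUTSIDE, CYTOPLASM, MEMBRANE, MITOCHONDRIA, NUCLEUS, NUCLEOLUS = range(6)
COMPARTMENTS: Mapping[str, int] = {
    "outside": OUTSIDE,
    "cytoplasm": CYTOPLASM,
    "membrane": MEMBRANE,
    "mitochondria": MITOCHONDRIA,
    "nucleus": NUCLEUS,
    "nucleolus": NUCLEOLUS,
}

# membranes a nanostar tip must cross to reach each compartment
_MEMBRANES_CROSSED = {
    "outside": 0,
    "membrane": 1,
    "cytoplasm": 1,
    "mitochondria": 2,
    "nucleus": 2,
    "nucleolus": 2,
}

_SHAPES = ("lorentzian", "gaussian", "pseudo-voigt")


def airy_radius(
    wavelength_nm: float,
    numerical_aperture: float,
    convention: str = "full-width",
) -> float:
    """Airy disk radius in micrometres.

    ``convention='first-minimum'`` gives 0.61 * lambda / NA (radius to the
    first dark ring); ``'full-width'`` gives 1.22 * lambda / NA.
    """
    if wavelength_nm <= 0:
        raise SpectralError("wavelength must be positive")
    if not 0 < numerical_aperture <= 1.5:
        raise SpectralError("numerical aperture must lie in (0, 1.5]")
    factor = {"first-minimum": 0.61, "full-width": 1.22}.get(convention)
    if factor is None:
        raise SpectralError(f"unknown Airy convention {convention!r}")
    return factor * (wavelength_nm / 1000.0) / numerical_aperture


@dataclass(frozen=True)
class ComponentSpectrum:
    """Line list of one molecular component.

    ``peaks`` holds (center cm^-1, FWHM cm^-1, relative amplitude, shape)
    tuples; the rendered profile is the sum of the lines.
    """

    component: str
    peaks: tuple[tuple[float, float, float, str], ...]

    def __post_init__(self) -> None:
        for c, fwhm, amp, shape in self.peaks:
            if fwhm <= 0 or amp < 0 or c <= 0:
                raise SpectralError(f"invalid peak ({c}, {fwhm}, {amp}) in {self.component}")
            if shape not in _SHAPES:
                raise SpectralError(f"unknown line shape {shape!r}")

    def render(self, axis: SpectralAxis) -> np.ndarray:
        x = axis.values
        y = np.zeros_like(x)
        for c, fwhm, amp, shape in self.peaks:
            hw = fwhm / 2.0
            lorentz = amp / (1.0 + ((x - c) / hw) ** 2)
            gauss = amp * np.exp(-4.0 * np.log(2.0) * ((x - c) / fwhm) ** 2)
            if shape == "lorentzian":
                y += lorentz
            elif shape == "gaussian":
                y += gauss
            else:  # pseudo-Voigt, equal mix
                y += 0.5 * (lorentz + gauss)
        return y


def default_library(fwhm: float = 10.0) -> list[ComponentSpectrum]:
    """Lorentzian line lists for the seven phantom components.

    Centers are the characteristic wavenumbers of each molecule class;
    amplitudes are relative within a component (each component profile is
    normalised to unit peak height before use).  None of the lines falls
    inside the 500-520 cm^-1 noise window.
    """

    def comp(name: str, lines: list[tuple[float, float]]) -> ComponentSpectrum:
        return ComponentSpectrum(
            name, tuple((c, fwhm, a, "lorentzian") for c, a in lines)
        )

    return [
        comp("DNA", [(670, 0.9), (692, 0.7), (790, 1.0), (802, 0.8), (1330, 0.9)]),
        comp("RNA", [(812, 0.9), (822, 0.8), (833, 0.8), (1510, 1.0)]),
        comp("heme", [(746, 0.9), (750, 1.0), (754, 0.85), (760, 0.9), (1206, 0.6)]),
        comp("protein", [(1000, 1.0), (1180, 0.7), (1365, 0.8)]),
        comp("lipid", [(1078, 0.7), (1270, 0.6), (1445, 1.0)]),
        comp("carbohydrate", [(912, 0.8), (1120, 1.0)]),
        comp("substrate", [(1010, 1.0), (1065, 0.8), (1203, 0.7)]),
    ]


def compartment_profiles(
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, dict[str, float]]:
    """Component weight of each compartment (arbitrary abundance units).

    Defaults encode the compositional picture of an adherent cell: the
    nucleus rich in DNA with RNA and protein; the nucleolus the most
    RNA-rich structure; mitochondria carrying the cytochrome hemes (kept
    moderate — 785 nm is off-resonance for hemes); the membrane dominated
    by lipids with proteins and glycoprotein carbohydrates; and only
    substrate lines outside the cell.  ``overrides`` replaces whole
    compartment entries.
    """
    profiles: dict[str, dict[str, float]] = {
        "nucleolus": {"RNA": 1.2, "DNA": 0.7, "protein": 0.6},
        "nucleus": {"DNA": 1.0, "RNA": 0.5, "protein": 0.7, "lipid": 0.2},
        "mitochondria": {"heme": 0.7, "protein": 0.5, "lipid": 0.2},
        "membrane": {"lipid": 1.0, "protein": 0.5, "carbohydrate": 0.4},
        "cytoplasm": {"protein": 0.6, "RNA": 0.3, "lipid": 0.3, "carbohydrate": 0.15},
        "outside": {"substrate": 0.4},
    }
    if overrides:
        for comp_name, weights in overrides.items():
            if comp_name not in profiles:
                raise SpectralError(f"unknown compartment {comp_name!r}")
            profiles[comp_name] = {k: float(v) for k, v in weights.items()}
    for weights in profiles.values():
        if any(w < 0 for w in weights.values()):
            raise SpectralError("component weights must be non-negative")
    return profiles


@dataclass(frozen=True)
class CellGeometry:
    """Cell layout in pixels (pitch in um).

    Defaults draw a 20 um cell (semi-axes 11 x 10 px at 1 um pitch) with
    a centred 10 um nucleus, a nucleolus disc offset inside the nucleus,
    ``n_mitochondria`` discs on a perinuclear annulus, and a 1 px
    membrane rim.
    """

    shape: tuple[int, int] = (64, 64)
    pixel_pitch_um: float = 1.0
    cell_semiaxes_px: tuple[float, float] = (11.0, 10.0)
    nucleus_semiaxes_px: tuple[float, float] = (5.0, 4.5)
    nucleolus_radius_px: float = 1.8
    nucleolus_offset_px: tuple[float, float] = (1.2, -0.8)
    n_mitochondria: int = 8
    mito_radius_px: float = 1.5
    mito_annulus_radius_px: float = 7.0

    def label_image(self, rng: np.random.Generator) -> np.ndarray:
        """Compartment label image; mitochondria angles are drawn from rng."""
        H, W = self.shape
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        yy, xx = np.mgrid[0:H, 0:W].astype(float)

        def ellipse(cy0, cx0, ay, ax):
            return ((yy - cy0) / ay) ** 2 + ((xx - cx0) / ax) ** 2 <= 1.0

        cell = ellipse(cy, cx, *self.cell_semiaxes_px)
        nucleus = ellipse(cy, cx, *self.nucleus_semiaxes_px)
        ndy, ndx = self.nucleolus_offset_px
        nucleolus = ellipse(
            cy + ndy, cx + ndx, self.nucleolus_radius_px, self.nucleolus_radius_px
        )
        membrane = cell & ~binary_erosion(cell)
        mito = np.zeros((H, W), dtype=bool)
        angles = rng.uniform(0.0, 2.0 * np.pi, size=self.n_mitochondria)
        for a in angles:
            my = cy + self.mito_annulus_radius_px * np.sin(a)
            mx = cx + self.mito_annulus_radius_px * np.cos(a)
            mito |= ellipse(my, mx, self.mito_radius_px, self.mito_radius_px)
        labels = np.full((H, W), OUTSIDE, dtype=np.int8)
        labels[cell] = CYTOPLASM
        labels[membrane] = MEMBRANE
        labels[mito & cell] = MITOCHONDRIA
        labels[nucleus] = NUCLEUS
        labels[nucleolus & nucleus] = NUCLEOLUS
        return labels


@dataclass(frozen=True)
class HotspotModel:
    """Nanostar-aggregate footprint and tip statistics.

    The aggregate footprint is a random blob mask thresholded to the
    target ``coverage`` fraction; the default (None) draws the coverage
    uniformly from the observed 13-70% range at generation time.
    Enhancement is a binary gate — a pixel's
    compartment contributes only where covered by the footprint — because
    the enhancement range (1-2 nm) is far below the pixel scale.  Tip
    penetration through ~10 nm membranes enters as a per-compartment
    attenuation from the Gaussian tip-length distribution.
    """

    coverage: float | None = None
    coverage_range: tuple[float, float] = (0.13, 0.70)
    blob_scale_px: float = 2.5
    tip_length_mean_nm: float = 36.9
    tip_length_sd_nm: float = 5.8
    core_diameter_nm: float = 40.0
    membrane_thickness_nm: float = 10.0
    enhancement_range_nm: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.coverage is not None and not 0.0 < self.coverage <= 1.0:
            raise SpectralError("coverage must lie in (0, 1]")

    def footprint(self, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        coverage = (
            self.coverage
            if self.coverage is not None
            else float(rng.uniform(*self.coverage_range))
        )
        noise_field = rng.standard_normal(shape)
        smooth = gaussian_filter(noise_field, self.blob_scale_px)
        if coverage >= 1.0:
            return np.ones(shape, dtype=bool)
        thr = np.quantile(smooth, 1.0 - coverage)
        return smooth > thr

    def attenuation(self, compartment: str) -> float:
        """P(tip length > membranes crossed x membrane thickness)."""
        n = _MEMBRANES_CROSSED[compartment]
        if n == 0:
            return 1.0
        return float(
            norm.sf(
                n * self.membrane_thickness_nm,
                loc=self.tip_length_mean_nm,
                scale=self.tip_length_sd_nm,
            )
        )


@dataclass(frozen=True)
class PhantomParams:
    """Everything that defines a phantom besides the seed.

    ``peak_amplitude`` is the height (in detector counts) of a unit-weight
    component's imaging-window line before attenuation and blur; with the
    default ``noise_sigma`` of 1.0 the in-band peak amplitude is 10x the
    noise level.  ``label_override`` substitutes an explicit compartment label
    image for the generated geometry (useful for single-pixel phantoms).
    """

    geometry: CellGeometry = CellGeometry()
    hotspot: HotspotModel = HotspotModel()
    axis_start: float = 400.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    peak_amplitude: float = 10.0
    noise_sigma: float = 1.0
    baseline_amplitude: float = 30.0
    baseline_decay: float = 600.0
    wavelength_nm: float = 785.0
    numerical_aperture: float = 0.5
    profiles: Mapping[str, Mapping[str, float]] | None = None
    label_override: np.ndarray | None = None

    def make_axis(self) -> SpectralAxis:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return SpectralAxis(self.axis_start + self.axis_step * np.arange(n))

    @property
    def psf_sigma_um(self) -> float:
        """Gaussian PSF sigma: 0.42x the first-minimum Airy radius."""
        return 0.42 * airy_radius(
            self.wavelength_nm, self.numerical_aperture, "first-minimum"
        )


@dataclass(frozen=True)
class Phantom:
    """A generated phantom with its full ground truth."""

    params: PhantomParams
    seed: int
    labels: np.ndarray
    hotspot_mask: np.ndarray
    abundance: Mapping[str, np.ndarray]
    image: HyperspectralImage

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.labels == COMPARTMENTS[name]


# imaging windows the band-RMS maps are computed over; the SNR convention
# below anchors each mapped component's profile to its line inside these
_IMAGING_WINDOWS = {
    "DNA": (655.0, 680.0),
    "heme": (740.0, 765.0),
    "RNA": (825.0, 835.0),
    "protein": (995.0, 1010.0),
}


def _reference_height(
    cs: ComponentSpectrum, profile: np.ndarray, axis: SpectralAxis
) -> float:
    """Profile height the amplitude calibration refers to.

    For components with an imaging window the reference is the profile
    maximum inside that window, so ``peak_amplitude`` is the *in-band*
    peak height; for the others it is the global maximum.
    """
    window = _IMAGING_WINDOWS.get(cs.component)
    if window is not None:
        m = (axis.values >= window[0]) & (axis.values <= window[1])
        if m.any() and profile[m].max() > 0:
            return float(profile[m].max())
    return float(profile.max())


def generate_phantom(params: PhantomParams, seed: int) -> Phantom:
    """Generate one phantom: geometry, hotspot, spectra, baseline, noise.

    Pipeline: compartment labels -> per-component abundance (profile
    weight x tip attenuation) -> binary hotspot gate -> Gaussian PSF blur
    of the abundance maps -> outer product with the component line
    profiles -> plus baseline and additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    axis = params.make_axis()
    library = default_library()
    lo, hi = axis.values[0], axis.values[-1]
    for comp_spec in library:
        for c, _, _, _ in comp_spec.peaks:
            if not lo <= c <= hi:
                raise SpectralError(
                    f"axis [{lo}, {hi}] cm^-1 too short for library line at {c}"
                )

    if params.label_override is not None:
        labels = np.asarray(params.label_override, dtype=np.int8)
        shape = labels.shape
    else:
        labels = params.geometry.label_image(rng)
        shape = params.geometry.shape
    hotspot = params.hotspot.footprint(shape, rng)

    profiles = compartment_profiles(
        dict(params.profiles) if params.profiles is not None else None
    )
    names = [cs.component for cs in library]
    rendered = {}
    for cs in library:
        prof = cs.render(axis)
        rendered[cs.component] = prof / _reference_height(cs, prof, axis)

    abundance: dict[str, np.ndarray] = {n: np.zeros(shape) for n in names}
    for comp_name, code in COMPARTMENTS.items():
        mask = labels == code
        if not mask.any():
            continue
        att = params.hotspot.attenuation(comp_name)
        for component, weight in profiles[comp_name].items():
            abundance[component][mask] += weight * att

    sigma_px = params.psf_sigma_um / params.geometry.pixel_pitch_um
    gated_blurred = np.stack(
        [
            gaussian_filter((abundance[n] * hotspot).astype(float), sigma_px)
            if sigma_px > 0
            else abundance[n] * hotspot
            for n in names
        ]
    )
    spectra_matrix = np.stack([rendered[n] for n in names])
    cube = params.peak_amplitude * np.einsum(
        "cij,ck->ijk", gated_blurred, spectra_matrix
    )

    if params.baseline_amplitude > 0:
        glow = gaussian_filter((labels > OUTSIDE).astype(float), 2.0)
        spatial = 0.6 + 0.8 * glow
        curve = np.exp(-(axis.values - axis.values[0]) / params.baseline_decay)
        cube += params.baseline_amplitude * spatial[:, :, None] * curve[None, None, :]
    if params.noise_sigma > 0:
        cube += rng.normal(0.0, params.noise_sigma, size=cube.shape)

    image = HyperspectralImage(
        axis,
        cube,
        params.geometry.pixel_pitch_um,
        {"phantom_seed": seed},
    )
    return Phantom(params, seed, labels, hotspot, abundance, image)
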
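# Methods

## The measurement being modelled

A live adherent cell is grown on a glass substrate coated with a thin
poly(4-vinyl pyridine) layer carrying aggregates of gold nanostars
(~40 nm cores, tips of 36.9 ± 5.8 nm). Under a 785 nm laser focused
through a 50×/0.5 NA objective, Raman scattering is enhanced only within
1–2 nm of the metal surface, so cellular signal exists solely where a
cell compartment rests on an aggregate and a tip has penetrated the
~10 nm membranes in between. Scanning the focus on a 1 µm grid yields a
hyperspectral cube: one spectrum per pixel on a shared Raman-shift axis.

## Band-RMS mapping

Per pixel, the molecular score for a window *b* is
`RMS(I, b) / RMS(I, noise)` with *I* the baseline-subtracted (signed)
intensities, evaluated on native axis samples over the closed interval
`lo ≤ ν ≤ hi`, and `noise` = 500–520 cm⁻¹, a window free of cellular
peaks. The ratio is scale-free (detector gain cancels) and ≈ 1 for a
pixel containing only noise; the signed residuals are kept because
clipping at zero would bias the RMS upward. Windows of unequal width are
comparable because RMS is a per-sample mean; no resampling or
interpolation is performed. Imaging windows (DNA 655–680, hemes 740–765,
RNA 825–835, proteins 995–1010 cm⁻¹) are kept distinct from the broader
assignment windows used for reading single spectra (DNA 660–690,
790–805, 1300–1350; RNA 805–850; hemes 730–765; lipids 700–730,
1300–1330, 1430–1470; proteins 1000–1010, 1360–1370 cm⁻¹); the two sets
overlap but answer different questions and are deliberately not
reconciled.

Missing values (zero noise RMS) propagate as NaN and render as black
with a zero alpha mask.

## Baseline subtraction

One recipe per image, applied to every pixel: per-pixel adaptation would
distort relative band scores. The default is asymmetric least squares
(Eilers–Boelens): minimise `‖w∘(y−z)‖² + λ‖D₂z‖²` with `w = p` above the
baseline and `1−p` below, iterated 10 times; defaults λ = 1e5, p = 0.01.
The system matrix is symmetric pentadiagonal and solved with a banded
Cholesky factorisation, so a 64×64×1401 cube baselines in a few seconds
on one core. The alternative recipe family is a least-squares polynomial
through user-chosen anchor wavenumbers, matching the anchor-based
"recipe" style of interactive Raman software.

Known property of ALS with small p: on noise-only regions the baseline
settles near the lower envelope, leaving residuals with a positive
offset of roughly 1.5σ. The offset inflates numerator and denominator of
the band score alike, so off-hotspot scores stay ≈ 1, but it dilutes
contrast at signal pixels by roughly 2× relative to an ideal baseline.

`suggest_recipe` makes the "chosen after inspecting 10–15 spectra" step
reproducible: each candidate recipe is scored by the mean (over sample
spectra) of the **median absolute residual** on axis samples outside all
registered band windows, and the lowest score wins (ties → first in grid
order). The median is used rather than the RMS because real spectra
contain genuine peaks at wavenumbers the registry does not list; an RMS
criterion rewards recipes that absorb those peaks into the baseline.
This surrogate criterion detects sloped or offset residuals but cannot
detect peak-eating inside excluded windows, so the default grid
(`default_recipe_grid`) is ordered stiffest-first.

## Composite rendering

All channels share one linear display range (default 0–60 score units):
`gray = round(255 · clip((v − lo)/(hi − lo), 0, 1))`, half-up rounding.
The shared range is what makes channel brightness comparable across the
merged RGB overlay (DNA → red, RNA → green, hemes → blue). No gamma,
equalisation, or interpolation of missing pixels.

## Peak annotation

Peaks are local maxima above a prominence threshold with a minimum
separation in cm⁻¹ (converted to samples via the median axis step).
Assignment is a tolerance lookup (default ± 5 cm⁻¹, reflecting the
several-cm⁻¹ jitter of the same vibration across cells) against a
YAML-shipped table; multiple matches are all returned, sorted by
distance — ambiguity is information, not an error. The one contextual
rule is exposed explicitly: a 720 cm⁻¹ peak is adenine when the
strongest lipid line (1445 cm⁻¹) is absent, phospholipid when 1445 is
present without other DNA lines, otherwise ambiguous.

## AFM scratch thickness

The film is scratched to the substrate and the height map levelled and
histogrammed; thickness is the separation of the two histogram modes.
Levelling is robust: a global least-squares plane through a two-terrace
image tilts across the step (the scratch population drags the fit), so
the background polynomial (degree 0–2) is fitted on the dominant terrace
only, identified by an Otsu split of the median-centred heights and
iterated; the split is only applied when the two clusters are separated
by more than 4× their within-cluster spread, so single-terrace images
reduce to the ordinary fit. The result is exactly zero-mean.

Histogram bin width defaults to max(0.1 nm, Freedman–Diaconis); for
sub-nanometre films an explicit 0.1 nm bin is recommended (the FD
estimate on strongly bimodal data is of order the step height itself).
Mode centers are refined by a parabola through the three bins at each
mode, making the estimate sub-bin accurate; the two most prominent modes
above 5% of the tallest bin are used, and fewer than two raises a
"no bimodal height distribution" error. Thickness is translation-
invariant by construction (bins are anchored at the data minimum).
On synthetic 6 nm films with σ = 0.3 nm noise and a 20% scratch, the
mean absolute error over 100 seeds is ≈ 1% of the thickness.

## The synthetic phantom

The generator emulates the acquisition so the pipeline can be validated
against ground truth:

* **Geometry** — ellipses on the pixel grid: 20 µm cell (semi-axes
  11 × 10 px at 1 µm pitch), centred 10 µm nucleus, a nucleolus disc
  offset inside the nucleus, 8 mitochondria discs (r = 1.5 px) on a
  7 px perinuclear annulus at seeded random angles, a 1 px membrane rim.
  Label priority: nucleolus > nucleus > mitochondria > membrane >
  cytoplasm > outside.
* **Hotspot** — Gaussian-blob random field thresholded to a coverage
  fraction drawn uniformly from the observed 13–70% range (or fixed by
  the caller). Enhancement is a binary gate: a compartment contributes
  only where covered by the footprint. A continuous 3-D decay model is
  not attempted — the available tip statistics do not constrain one —
  but tip penetration enters as per-compartment attenuation
  `P(tip length > n_membranes × 10 nm)` under the Gaussian tip-length
  distribution (≈ 1.00 for one membrane, 0.998 for two).
* **Spectra** — Lorentzian lines (FWHM 10 cm⁻¹) at the characteristic
  wavenumbers of DNA (670, 692, 790, 802, 1330), RNA (812, 822, 833,
  1510), hemes (746, 750, 754, 760, 1206), proteins (1000, 1180, 1365),
  lipids (1078, 1270, 1445), carbohydrates (912, 1120) and the substrate
  lines seen outside cells (1010, 1065, 1203). No line falls in the
  500–520 cm⁻¹ noise window. Each profile is normalised to unit height
  at its imaging-window line, so `peak_amplitude` (default 10) is the
  in-band peak height in units of the noise σ (default 1) — the
  signal-to-noise convention all recovery properties are stated under.
* **Composition** — per-compartment component weights: nucleus
  DNA-dominant with RNA and protein; nucleolus the most RNA-rich
  compartment; mitochondria heme-bearing (weight 0.7 — 785 nm is
  off-resonance for hemes, so their lines are deliberately weaker);
  membrane lipid-dominant with glycoprotein carbohydrate; outside the
  cell only substrate lines.
* **Optics** — abundance maps (not spectra) are blurred with a Gaussian
  PSF of σ = 0.42 × the first-minimum Airy radius (0.61 λ/NA), i.e.
  σ ≈ 0.40 µm at 785 nm / NA 0.5, the standard Gaussian match to the
  Airy core. The full-width convention (1.22 λ/NA = 1.92 µm) describes
  the detection-spot diameter scale, not the Gaussian σ; using it as σ
  would overstate the blur several-fold.
* **Baseline and noise** — an exponentially decaying fluorescence-like
  curve (amplitude 30σ, decay 600 cm⁻¹), brighter over the cell, plus
  i.i.d. Gaussian detector noise. All randomness flows from one
  `numpy` Generator seeded by the mandatory `seed`, so cubes are
  bit-exactly reproducible.

Axis default: 400–1800 cm⁻¹ at 1 cm⁻¹ (1401 samples). The acquisition
axis of the source instrument is not documented; this range covers the
fingerprint region all referenced lines fall in.

### What the phantom does and does not show

Passing recovery tests on the phantom demonstrates that the pipeline's
statistics recover known spatial chemistry under realistic SNR, blur,
baseline and hotspot gating. The phantom does **not** model cosmic-ray
spikes, wavenumber miscalibration, focus drift, cell-to-cell
compositional variability, continuous enhancement decay, or 3-D
sectioning — conclusions about those aspects of real data are outside
its reach.

### Recovery performance and its ceiling

On the default 64×64 phantom the DNA map correlates with the
nucleus∩hotspot indicator at Pearson r ≈ 0.75–0.81 and the heme map with
mitochondria∩hotspot at r ≈ 0.62–0.82 (seed-dependent), while the mean
score off the hotspot stays within a few percent of 1 for every band.
An oracle computed from the noise-free signal cube reaches r ≈ 0.99, so
the gap is not geometric: it is set by the sampling noise of the RMS
ratio (≈ 0.21 sd around 1 for 26-/21-sample windows) and by PSF dilution
of edge pixels of the fragmented hotspot footprint at the stated
10σ in-band SNR. Correlations materially above ~0.8 against the binary
ground-truth mask are not reachable at these settings with any baseline
recipe; raising the SNR or the hotspot coverage raises r accordingly.

## Pipeline and provenance

`run_pipeline` fixes the stage order (load/generate → optional recipe
selection → baseline → band maps → normalisation → composite →
annotation) and stamps every artifact with a hash of the serialised
configuration plus the seed, so a result directory is reproducible from
its `config.yaml` alone. Stage errors abort with the stage name and
pixel coordinates. Exit codes at the CLI: 0 success, 2 validation,
3 computation.

## Numerical choices and degenerate inputs

* Axes must be strictly increasing; only file readers reorder
  (descending instruments exports), everything else raises.
* Band membership is the closed interval on native samples; a band with
  no samples on the evaluated axis is an error naming the band and axis
  extent.
* ALS needs ≥ 3 samples; polynomial recipes need more support points
  than coefficients; degree-0 backgrounds on zero-mean input are
  identity.
* Ties in recipe selection resolve to grid order; peak-assignment ties
  keep table order after distance sorting.
* The problem sizes used in the shipped tests (64×64×1401 phantom, 50
  baseline spectra, 100 AFM seeds, 100 oracle spectra) keep the full
  suite under a minute of compute while leaving every statistic
  well-resolved.
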
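# cellmap

Band-RMS molecular mapping of live-cell SERS hyperspectral images.

In nanostar-substrate SERS microscopy an adherent cell is imaged through a
785 nm confocal Raman microscope over a substrate carrying aggregates of
gold nanostars. Enhancement acts only within 1–2 nm of a nanostar tip, so
cellular Raman signal appears exclusively where the cell sits on an
aggregate ("hotspot"), and the spectra carry molecular fingerprints of
whatever compartment the tips reach — DNA and RNA in the nucleus, cytochrome
hemes in mitochondria, lipids and glycoproteins in the membrane.

`cellmap` implements the full analysis chain for such acquisitions:

1. **Baseline subtraction** — one fixed recipe (asymmetric least squares by
   default, or a polynomial through anchor wavenumbers) chosen from a small
   sample of spectra and applied identically to every pixel.
2. **Band-RMS mapping** — the per-pixel molecular score

   $$s_b = \sqrt{\tfrac{1}{|b|}\sum_{\nu \in b} I(\nu)^2} \Big/
           \sqrt{\tfrac{1}{|n|}\sum_{\nu \in n} I(\nu)^2}$$

   the RMS of baseline-subtracted intensities $I$ over a wavenumber window
   $b$ (DNA 655–680, hemes 740–765, RNA 825–835, proteins 995–1010 cm⁻¹),
   normalised by the RMS over the peak-free noise window $n$ = 500–520 cm⁻¹.
   A pixel without enhanced signal scores ≈ 1; hotspot pixels score several
   noise units.
3. **Composites** — grayscale and merged RGB renderings (DNA red, RNA
   green, hemes blue) on a single shared display range (default 0–60).
4. **Peak annotation** — peak detection plus a literature table of
   wavenumber → molecule assignments (790 cytosine, 750 heme C vs 760
   heme B, the 720 cm⁻¹ adenine/phospholipid ambiguity and its
   1445-cm⁻¹-absence disambiguation rule, …).
5. **AFM scratch thickness** — robust background levelling of a scratched
   film's height map and the film thickness as the separation of the two
   height-histogram modes.
6. **Synthetic phantoms** — ground-truthed emulations of the experiment
   (20 µm cell, 10 µm nucleus, perinuclear mitochondria, nanostar-aggregate
   hotspot gating, Airy-derived optical blur, fluorescence baseline,
   detector noise) so every stage is testable without instrument data.

## Worked example

```python
import numpy as np
import cellmap as cm

registry = cm.default_registry()
phantom = cm.generate_phantom(cm.PhantomParams(), seed=1)
sub = cm.subtract_baseline_image(phantom.image, cm.BaselineRecipe())
noise = registry.noise_band
dna = cm.compute_map(sub, registry.imaging("DNA"), noise)
nucleus = (phantom.compartment_mask("nucleus")
           | phantom.compartment_mask("nucleolus")) & phantom.hotspot_mask
r = np.corrcoef(dna.values.ravel(), nucleus.ravel())[0, 1]
print(f"hotspot coverage:            {phantom.hotspot_mask.mean():.2f}")
print(f"DNA score in nucleus/hotspot: {dna.values[nucleus].mean():.2f}")
print(f"DNA score off the hotspot:    {np.nanmean(dna.values[~phantom.hotspot_mask]):.2f}")
print(f"Pearson r vs ground truth:    {r:.3f}")
```

prints

```
hotspot coverage:            0.44
DNA score in nucleus/hotspot: 3.19
DNA score off the hotspot:    1.03
Pearson r vs ground truth:    0.784
```

i.e. the DNA window scores ~3× the noise level exactly where the phantom's
nucleus overlaps the nanostar footprint, stays at the noise floor (≈1)
everywhere off the hotspot — the signature of contact-range SERS
enhancement — and correlates strongly with the ground-truth indicator.

The same chain is available from the shell:

```bash
cellmap phantom --size 64 --seed 1 out.h5 --truth truth.h5
cellmap baseline out.h5 sub.h5
cellmap map --band DNA sub.h5 dna.csv
cellmap rgb dna.csv rna.csv heme.csv merged.png
cellmap annotate spectrum.txt
cellmap afm-thickness heightmap.txt --bin 0.1
cellmap run --seed 1 --out results_dir
```

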
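# ramancell

Confocal Raman micro-spectroscopy maps single cells label-free: each pixel
of a raster scan holds a full vibrational spectrum, so chemical images of
nucleic acids, proteins, lipids and cytochrome c can be drawn from the same
measurement. `ramancell` implements the standard analysis chain used to
compare pluripotent stem-cell lines with such maps — for spectroscopists
and cell biologists who need a reproducible, scriptable alternative to
point-and-click toolchains — together with a ground-truthed synthetic scene
generator that makes every stage of the chain testable.

## What it computes

**Preprocessing.** The wavenumber axis is calibrated on the sharp silicon
band (offset = 520 − ν̂_Si, with ν̂_Si from parabolic interpolation around
the maximum). Spectra are split into the fingerprint (400–1800 cm⁻¹) and
CH-stretch (2600–3100 cm⁻¹) regions. The background spectrum — the
band-wise mean over pixels surrounding the cell — is subtracted from every
pixel, and each map is normalized by its own maximum per-pixel total
spectral area *A*ₚ = ∫ Iₚ(ν) dν (trapezoidal), so maps recorded at
different times are comparable.

**Multivariate segmentation.** All maps are pooled into one pixel×band
matrix; after subtraction of the overall mean spectrum, PCA is the
eigendecomposition of the sample covariance (loadings keep intensity-like
units, no band standardization). K-means with k = 7 clusters the pixels by
Euclidean distance in the PC1–PC6 score space: six clusters address the
cell interior and one collects the low-intensity extracellular pixels.
Clusters get stable pseudo-colors from their mean spectra — red for the
strongest 785 cm⁻¹ (DNA/RNA) response, yellow for 748+1585 cm⁻¹
(cytochrome c), blue for 1244 cm⁻¹ (Amide III), green for the dimmest
(thin) regions, dark red/dark green for their weaker counterparts, black
outside.

**Statistics.** Per map, each intracellular cluster's percentage of
in-cell area is computed; lines are compared per cluster with an unpaired
pooled-variance two-sample t test, reported as mean ± SEM with a
Bonferroni-adjusted column.

**Band imaging.** Univariate images integrate a window of ±10 cm⁻¹ around
a band (785 DNA/RNA → red, 1670 protein → blue, 2850 lipid → green,
748+1585 cytochrome c → magenta) and compose them into a pseudo-color RGB
image; named intensity ratios such as I₁₂₄₄/I₁₃₀₅ are available.

**Synthetic scenes.** `generate_experiment` builds raster maps of
elliptical cells (nucleoids with perinuclear rim, mitochondrial ring,
lipid droplets, cytoplasm, thin adherent edge) whose pixel spectra are
non-negative mixtures of Lorentzian/Gaussian component spectra at the
literature band positions, plus baseline and Gaussian + shot-like noise.
Two cell-line modes differ only in the DNA/RNA abundance scale, and the
planted truth is retained for scoring.

## Worked example

`examples/05_line_discrimination.py` simulates 3 + 3 cells where one line
carries twice the nucleic-acid abundance, segments them, and compares the
DNA-dominated cluster:

```
red (DNA-dominated) cluster percentage of in-cell area per map:
      hESC-like_00 (hESC-like):   0.00 %
      hESC-like_01 (hESC-like):   0.00 %
      hESC-like_02 (hESC-like):   0.00 %
     hiPSC-like_00 (hiPSC-like):  17.31 %
     hiPSC-like_01 (hiPSC-like):   8.32 %
     hiPSC-like_02 (hiPSC-like):  11.21 %
hESC-like: 0.00 ± 0.00 %  vs  hiPSC-like: 12.28 ± 2.65 %  (mean ± SEM)
two-sample t = -4.63, df = 4, p = 0.009806
```

The red cluster is essentially absent from the low-DNA line and covers
8–17% of the in-cell area in the high-DNA line: pooled clustering assigns
only the brightest nucleic-acid spectra to it, which is exactly the
discrimination logic the percentage-area statistic formalizes. The other
examples walk through component spectra, scene simulation, preprocessing,
band images, and the PCA/K-means stage (which recovers the planted
subcellular regions at adjusted Rand index 1.0 under default noise).

## Command line

The same pipeline is scriptable from a shell, driven by a YAML config
(unknown keys are rejected; every run writes a manifest with config
snapshot and output hashes):

```sh
ramancell simulate --seed 1 --out run/sim
ramancell analyze  --seed 1 --out run/out run/sim/*.map.tsv
ramancell report   run/out
```

Maps travel in two documented TSV dialects (`matrix`: one row per
wavenumber, pixel columns `px_<row>_<col>` in row-major order; `long`: one
record per pixel and band) with `#`-prefixed metadata headers; masks as
PNG or 0/1 text grids; tables as CSV; images as PNG.

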
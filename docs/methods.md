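# Methods

## The measurement model

A Raman map is a W×H raster of spectra I(x, y, ν) on a shared wavenumber
axis ν (default 400–3100 cm⁻¹ at 3 cm⁻¹ spacing, matching a 532 nm
instrument with ≈3 cm⁻¹ resolution and 400 nm raster step). The analysis
assumes each pixel spectrum is approximately a non-negative linear mixture
of biochemical component spectra plus a smooth background that is shared
with the empty substrate around the cell. Everything downstream —
background subtraction, PCA loadings, cluster mean spectra, band integrals
— is linear in the spectra, which is why the chain recovers planted
mixtures exactly in the noise-free limit.

## Preprocessing

Order per map: **calibrate → split → background-subtract → normalize.**

- *Calibration.* The silicon reference band is located inside
  [480, 560] cm⁻¹ by parabolic interpolation through the three samples
  around the maximum; the additive offset 520 − ν̂ is applied to the axis.
  Offsets ≥ 50 cm⁻¹ are rejected as implausible. Synthetic runs carry no
  silicon spectrum; the offset is then 0 and logged as such.
- *Region split.* Fingerprint = [400, 1800] cm⁻¹, CH stretch =
  [2600, 3100] cm⁻¹, both closed intervals; the silent gap is discarded.
  Splitting is pure band selection (bit-exact, no resampling). The
  multivariate stage uses the fingerprint region by default; a config
  switch allows CH-stretch-only or the concatenation. On the default grid
  the fingerprint region holds 467 bands (400, 403, …, 1798).
- *Background.* The band-wise mean spectrum of the outside-mask pixels
  (median available for outlier-heavy data) is subtracted everywhere.
  Negative residuals are retained: clipping would bias the subsequent PCA
  toward positive noise.
- *Normalization.* Each map is divided by the maximum over its pixels of
  the total spectral area (trapezoidal integral over the fingerprint
  region of the background-subtracted spectrum; computed after
  subtraction, never pooled across maps). After this the brightest pixel
  has area exactly 1, and the chain is invariant to any global intensity
  scale c > 0 of the raw data.
- *Cell mask.* Raw maps ship no inside/outside annotation, so the mask is
  inferred: Otsu's threshold on the log-transformed total-area image
  (cell interiors are strongly right-skewed — dim adherent edges coexist
  with bright lipid droplets — and the log compresses that tail so the
  substrate/cell boundary dominates), refined to the midpoint of the
  largest gap in the sorted areas within ±2% of the dynamic range, then
  largest connected component with filled holes. The refinement makes the
  mask exact whenever the two distributions are separable (the noise-free
  limit); at default noise the Jaccard overlap with the planted mask is
  ≈0.999. A quantile strategy and externally supplied masks are
  alternatives for unusual scenes.
- An optional running-median despiker exists but is off by default; the
  reference chain does not despike.

## Pooled PCA and K-means segmentation

All maps enter one pixel×band matrix (row order: map order, then row-major
pixels), so the principal components are identical for every map by
construction. PCA subtracts the overall mean spectrum and
eigendecomposes the sample covariance (ddof 1); bands are not
standardized and scores are not whitened — distances in score space keep
intensity-like units. Sign convention: each loading's largest-magnitude
element is positive (deterministic output; nucleic-acid bands appear as
positive peaks in the DNA-dominated loading). Explained-variance
fractions are relative to the covariance trace, so they sum to 1 at full
rank; Σλ = trace(cov) holds to ~1e-12 relative.

K-means runs on the first six PC scores with k = 7: six intracellular
clusters plus one that collects the low-intensity extracellular pixels.
No PC-truncation denoising is applied to the spectra themselves — only the
clustering lives in the reduced space. The implementation is Lloyd's
algorithm with k-means++ seeding, best of 20 seeded restarts by inertia,
and empty clusters re-seeded from the point farthest from its centroid;
per-iteration inertia is recorded and is non-increasing by construction.
The extracellular cluster is identified as the one whose members have the
lowest mean total spectral area; a tie within 1e-12 is treated as
pathological input, and a warning is raised when even that cluster is not
clearly dim (all-cell crops). k and the number of PCs are configurable;
cluster-count sensitivity is a diagnostic to run explicitly, not an
automatic selector.

Cluster colors are assigned by a fixed rule on the cluster mean spectra
so images are regression-testable: red = strongest 785 cm⁻¹ band area,
yellow = strongest 748+1585 cm⁻¹ among the rest, blue = strongest
1244 cm⁻¹, green = smallest total area; the remaining two become dark red
or dark green by centroid proximity to the red and green clusters. Dark
palette variants are the base colors at 50% value; outside is black.

## Statistics

Percentage areas are per map: 100·(pixels in cluster)/(in-cell pixels),
summing to 100 per map. Group comparison is the unpaired pooled-variance
two-sample t test (two-sided), reported as mean ± SEM (sd/√n). Because
six clusters are compared at once, a Bonferroni-adjusted p column
accompanies the unadjusted values; the unadjusted single-comparison p is
the primary readout.

## Band imaging

A band is quantified as the trapezoidal area over ν ∈ [c − h, c + h]
(default half-width h = 10 cm⁻¹), summed over a band's centers;
peak-height mode is available. Composites min–max scale each band image
to [0, 1] over in-cell pixels (a robust 1st–99th percentile variant
exists), multiply by the band's RGB color, sum, and clip channels at 1.
The exact intensity-to-color transfer of published figures is not
reproducible and not attempted; the palette here is fixed and documented.

## The synthetic scene generator

The generator exists so that every stage has ground truth. It emulates:

- component spectra as sums of Lorentzians (FWHM 12 cm⁻¹ typical of
  condensed-phase bands, resolvable on the 3 cm⁻¹ grid; cytochrome c
  bands slightly sharper and amplified to stand in for resonance
  enhancement) at the literature positions: DNA/RNA 785, 1098, 1334,
  1371, 1484, 1575; cyt c 748, 1127, 1585; lipids 1073, 1305, 1440,
  1738, 2850; proteins 1003, 1244, 1450, 1608, 1665 (Amide I), 2930; a
  broad Gaussian substrate background. Relative amplitudes are documented
  defaults chosen so DNA bands dominate only in nucleoid regions — they
  are not fits to any measured spectrum, and recovered ratios carry no
  biological meaning.
- cell geometry: an ellipse (default semi-axes 0.42 W × 0.36 H, ≈48% of
  the grid) containing six intracellular region types — nucleoids, a
  perinuclear rim of intermediate DNA content, a mitochondrial ring,
  lipid droplets, bulk cytoplasm, and a thin adherent edge — plus the
  outside. Six region types mirror the six intracellular clusters the
  segmentation imposes, with the rim playing the role of the weaker
  "dark red" counterpart of the nucleoid cluster.
- abundances: per-region base levels modulated by smooth ±5% spatial
  jitter. The nucleic-acid signal is concentrated in the nucleoid complex
  (cytoplasmic floor 0.05), reflecting that elevated DNA/RNA content
  appears in well-defined nuclear regions rather than diffusely. Lipid
  droplets carry the highest total signal (lipid abundance 4.0), as in
  real cellular Raman maps, which also pins the per-map normalization
  reference to a structure that does not differ between cell lines.
- noise: per-band Gaussian with σ = σ₀ + f·√signal (defaults σ₀ = 0.05,
  f = 0.02 on component amplitudes of order 1) plus a mild linear
  baseline. Real maps differ in ways the generator does not model:
  fluorescence photobleaching dynamics, cosmic-ray spikes, confocal PSF
  mixing between neighboring pixels, focus drift, and cell-to-cell
  biochemical variability beyond geometry and jitter. Passing tests
  therefore demonstrate correctness of the computation chain under the
  stated mixture model, not robustness to every artifact of real data.
- experiments: n cells per line (default 3 + 3, 64×64 pixels each), with
  per-cell geometry varied through sub-seeds derived from one master seed
  (ellipse axes ±8%, nucleoid and droplet counts ±1). The iPSC-like line
  multiplies the DNA/RNA abundance by `dna_scale_ipsc` (default 2.0);
  1.0 is the null experiment with exchangeable lines.

## Validation design

Two complementary synthetic configurations are used:

- *Segmentation recovery* uses the null configuration (scale 1.0), where
  the planted partition — six region types plus outside — is exactly the
  population structure the 7 clusters should find; the adjusted Rand
  index between intracellular cluster labels and planted regions reaches
  1.0 in the noise-free limit and stays ≥0.8 (in practice ≈1.0) at
  default noise. With a planted ×2 line difference the pooled pixel
  collection contains more spectral populations than shared clusters
  (each line's nucleoid complex differs), so perfect region recovery is
  not the right yardstick there.
- *Discrimination recovery* uses scale 2.0 and asks the headline
  question: the red cluster — defined by the strongest nucleic-acid
  response pooled across all cells — is populated almost exclusively by
  the high-DNA line's nucleoids, its percentage area is larger in every
  high-DNA map than in any low-DNA map, and the two-sample t test is
  significant. Under the null configuration, no cluster should reach
  Bonferroni-adjusted significance; the family-wise false-positive rate
  is kept below the nominal 5% partly because percentage areas are
  negatively correlated (they sum to 100).

## Numerical choices and degenerate inputs

- Trapezoidal integration everywhere an area is needed (normalization,
  band windows, total-area images); closed intervals at region and window
  boundaries.
- Intensities are float64; counts are stored as floats; negatives allowed
  after subtraction.
- Interchange files render floats with 17 significant digits, so
  write→read round trips are bit-exact; readers reject ragged records,
  missing pixels (naming the first offender), and non-increasing axes
  rather than coercing.
- Degenerate inputs fail loudly: all-zero maps cannot be normalized,
  constant total-area images cannot be thresholded, constant datasets
  yield a flagged zero-variance PCA model, k > n is rejected, a cluster
  left empty after fitting yields NaN mean spectra with a warning.
- Determinism: every stochastic step (scene layout, noise, k-means
  seeding) consumes a named integer seed through numpy's PCG64
  generators; sub-seeds are derived with `SeedSequence.spawn`. Identical
  config + seed reproduce byte-identical CSV and label outputs.

## Problem sizes

Default validation runs use 6 maps of 64×64 pixels on the 467-band
fingerprint region (≈24.6k pixels pooled), 20 k-means restarts, 5-seed
recovery medians, 5 discrimination replicates and 10–20 null replicates —
sizes chosen so the full suite and the acceptance script each complete in
a few minutes on a single CPU while leaving the statistics
well-resolved.

## Known limitations

- The interchange TSV dialects are this package's own definition; no
  proprietary vendor formats (WITec projects, SPC, ENVI) are read.
- No fluorescence baseline fitting (polynomial/ALS); background removal
  relies entirely on the surrounding-substrate subtraction.
- No spectral unmixing, peak deconvolution, alternative decompositions
  (ICA/NMF/MCR-ALS), hierarchical clustering, or spatial regularization
  of labels.
- Cluster colors assume the 6+1 layout; other k values require an
  explicit palette.
- The t test assumes approximately normal percentage areas with equal
  variances across groups; with 3 maps per group this is an approximation
  inherited from the standard workflow, not a recommendation.
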
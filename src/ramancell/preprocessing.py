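"""Spectrum conditioning for Raman maps.

The fixed preprocessing order per map is:

1. wavenumber calibration against the sharp Si reference band at 520 cm⁻¹;
2. splitting into the fingerprint (400–1800 cm⁻¹) and CH-stretch
   (2600–3100 cm⁻¹) regions, discarding the silent gap in between;
3. subtraction of the background spectrum estimated from pixels surrounding
   the cell (band-wise mean by default, median available);
4. per-map normalization by the maximum total spectral area of any pixel of
   that map, so that maps recorded at different times are comparable.

Negative intensities after subtraction are retained — clipping would bias
the subsequent PCA. "Total spectral area" is the trapezoidal integral of a
pixel's spectrum over the map's axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import AxisError, CalibrationError, DataError, DimensionError
from .types import PixelMask, SpectralMap, WavenumberAxis

__all__ = [
    "CalibrationResult",
    "SpectralRegions",
    "BackgroundModel",
    "FINGERPRINT_RANGE",
    "CH_STRETCH_RANGE",
    "calibrate_axis",
    "split_regions",
    "estimate_background",
    "subtract_background",
    "normalize_map",
    "pixel_areas",
    "infer_cell_mask",
    "despike",
]

FINGERPRINT_RANGE = (400.0, 1800.0)
CH_STRETCH_RANGE = (2600.0, 3100.0)
SI_WINDOW = (480.0, 560.0)
SI_REFERENCE = 520.0


@dataclass(frozen=True)
class CalibrationResult:
    """Additive wavenumber correction anchored on the Si 520 cm⁻¹ band."""

    offset: float
    fitted_si_peak: float

    def __post_init__(self) -> None:
        if abs(self.offset) >= 50.0:
            raise CalibrationError(
                f"calibration offset {self.offset:.1f} cm⁻¹ exceeds the 50 cm⁻¹ "
                "sanity bound"
            )


@dataclass
class SpectralRegions:
    """The two analysis regions; ``ch_stretch`` is None if the axis misses it."""

    fingerprint: SpectralMap
    ch_stretch: SpectralMap | None


@dataclass
class BackgroundModel:
    """Band-wise background spectrum estimated from outside-cell pixels."""

    spectrum: np.ndarray
    n_pixels_used: int
    estimator: str

    def __post_init__(self) -> None:
        if self.n_pixels_used < 1:
            raise DataError("background estimated from zero pixels")
        if not np.all(np.isfinite(self.spectrum)):
            raise DataError("background spectrum contains non-finite values")


def calibrate_axis(
    si_spectrum: np.ndarray, axis: WavenumberAxis
) -> tuple[CalibrationResult, WavenumberAxis]:
    """Locate the Si band near 520 cm⁻¹ and shift the axis onto it.

    The peak position is refined by parabolic interpolation through the
    three samples around the maximum inside the [480, 560] cm⁻¹ window; the
    returned axis is ``axis + offset`` with ``offset = 520 − fitted peak``.
    """
    si_spectrum = np.asarray(si_spectrum, dtype=np.float64)
    if si_spectrum.shape != (len(axis),):
        raise DimensionError("silicon spectrum length does not match axis")
    sel = np.flatnonzero(axis.window(*SI_WINDOW))
    if sel.size < 3:
        raise CalibrationError("axis has fewer than 3 samples in the Si window")
    win = si_spectrum[sel]
    peak_rel = int(np.argmax(win))
    peak_idx = sel[peak_rel]
    med = float(np.median(win))
    span = float(win.max() - win.min())
    if span == 0 or win[peak_rel] - med < 0.05 * span or win[peak_rel] <= med:
        raise CalibrationError("no dominant Si peak found in the 480–560 cm⁻¹ window")
    if peak_rel in (0, win.size - 1):
        raise CalibrationError("Si peak lies at the edge of the search window")

    x = axis.values[peak_idx - 1 : peak_idx + 2]
    y = si_spectrum[peak_idx - 1 : peak_idx + 2]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:
        raise CalibrationError("Si peak vertex is not a maximum")
    fitted = float(-b / (2 * a))
    result = CalibrationResult(offset=SI_REFERENCE - fitted, fitted_si_peak=fitted)
    corrected = WavenumberAxis(axis.values + result.offset,
                               resolution_hint=axis.resolution_hint)
    return result, corrected


def split_regions(spectral_map: SpectralMap) -> SpectralRegions:
    """Split into fingerprint [400, 1800] and CH-stretch [2600, 3100] cm⁻¹.

    Both intervals are closed; bands in the silent gap (1800, 2600) are
    discarded. Band values are selected, never resampled. A map whose axis
    misses the fingerprint region entirely is an error — the pipeline
    requires it — while a missing CH-stretch region yields ``None``.
    """
    fp_sel = spectral_map.axis.window(*FINGERPRINT_RANGE)
    ch_sel = spectral_map.axis.window(*CH_STRETCH_RANGE)
    if fp_sel.sum() < 2:
        raise AxisError("axis does not cover the 400–1800 cm⁻¹ fingerprint region")
    fingerprint = spectral_map.with_axis(
        WavenumberAxis(spectral_map.axis.values[fp_sel],
                       resolution_hint=spectral_map.axis.resolution_hint),
        spectral_map.intensities[:, :, fp_sel],
    )
    ch_stretch = None
    if ch_sel.sum() >= 2:
        ch_stretch = spectral_map.with_axis(
            WavenumberAxis(spectral_map.axis.values[ch_sel],
                           resolution_hint=spectral_map.axis.resolution_hint),
            spectral_map.intensities[:, :, ch_sel],
        )
    return SpectralRegions(fingerprint=fingerprint, ch_stretch=ch_stretch)


def estimate_background(
    spectral_map: SpectralMap, mask: PixelMask, estimator: str = "mean"
) -> BackgroundModel:
    """Band-wise mean (default) or median spectrum of outside-cell pixels."""
    mask.check_matches(spectral_map)
    outside = mask.outside
    n = int(outside.sum())
    if n == 0:
        raise DataError(
            "mask has no outside pixels to estimate a background from — "
            "review the cell mask"
        )
    spectra = spectral_map.intensities[outside]  # (n, bands)
    if estimator == "mean":
        bg = spectra.mean(axis=0)
    elif estimator == "median":
        bg = np.median(spectra, axis=0)
    else:
        raise DataError(f"unknown background estimator {estimator!r}")
    return BackgroundModel(spectrum=bg, n_pixels_used=n, estimator=estimator)


def subtract_background(
    spectral_map: SpectralMap, background: BackgroundModel
) -> SpectralMap:
    """Subtract the background spectrum at every pixel; negatives retained."""
    if background.spectrum.shape != (spectral_map.n_bands,):
        raise AxisError(
            f"background has {background.spectrum.size} bands, map has "
            f"{spectral_map.n_bands}"
        )
    return spectral_map.with_intensities(
        spectral_map.intensities - background.spectrum[None, None, :]
    )


def pixel_areas(spectral_map: SpectralMap) -> np.ndarray:
    """Per-pixel total spectral area: trapezoidal integral over the axis."""
    return np.trapezoid(spectral_map.intensities, spectral_map.axis.values, axis=2)


def normalize_map(spectral_map: SpectralMap) -> tuple[SpectralMap, float]:
    """Divide all spectra of one map by the map's maximum pixel area.

    After normalization the largest per-pixel total spectral area equals 1.
    The denominator is per-map ("for that specific cell"), never pooled.
    Returns the normalized map and the constant, for provenance.
    """
    areas = pixel_areas(spectral_map)
    constant = float(areas.max())
    if constant <= 0:
        raise DataError("no pixel with positive total spectral area; cannot normalize")
    return spectral_map.with_intensities(spectral_map.intensities / constant), constant


def _refine_gap_threshold(areas: np.ndarray, thr: float, window: float) -> float:
    """Move *thr* to the midpoint of the widest value gap within ±window.

    The nearest values just outside the window are included so that a gap
    straddling the window boundary is still found.
    """
    values = np.unique(areas)
    sel = (values >= thr - window) & (values <= thr + window)
    below = np.flatnonzero(values < thr - window)
    above = np.flatnonzero(values > thr + window)
    if below.size:
        sel[below[-1]] = True
    if above.size:
        sel[above[0]] = True
    nearby = values[sel]
    if nearby.size < 2:
        return thr
    gaps = np.diff(nearby)
    j = int(np.argmax(gaps))
    return float((nearby[j] + nearby[j + 1]) / 2.0)


def infer_cell_mask(
    spectral_map: SpectralMap, strategy: str = "otsu_total_intensity",
    quantile: float = 0.5,
) -> PixelMask:
    """Threshold the total-area image and keep the largest connected blob.

    ``otsu_total_intensity`` (default) applies Otsu's criterion to the
    log-transformed per-pixel total spectral area. Cell interiors are
    strongly right-skewed (a dim adherent edge coexists with bright lipid
    droplets), so the log transform compresses the bright tail and leaves
    the empty-substrate/cell boundary as the dominant bimodality; the
    threshold is then refined to the midpoint of the largest gap in the
    sorted areas within ±2% of the dynamic range, which recovers an exactly
    separable mask in the noise-free limit. ``quantile`` thresholds at the
    given area quantile instead. Holes inside the selected component are
    filled. The surrounding-area/inside distinction is a pipeline
    convention — raw data ship no masks — so the result should be reviewed
    on unusual scenes.
    """
    areas = pixel_areas(spectral_map)
    if np.ptp(areas) == 0:
        raise DataError(
            "total-intensity image is constant; supply a manual mask instead"
        )
    if strategy == "otsu_total_intensity":
        shift = areas.min() - 1e-6 * np.ptp(areas)
        thr = shift + float(np.exp(threshold_otsu(np.log(areas - shift))))
        thr = _refine_gap_threshold(areas, thr, window=0.02 * np.ptp(areas))
    elif strategy == "quantile":
        thr = float(np.quantile(areas, quantile))
    else:
        raise DataError(f"unknown mask strategy {strategy!r}")
    above = areas > thr
    if not above.any():
        raise DataError("threshold left no inside pixels")
    labels = cc_label(above, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    inside = labels == int(np.argmax(counts))
    inside = ndimage.binary_fill_holes(inside)
    return PixelMask(inside)


def despike(spectral_map: SpectralMap, window: int = 5, threshold: float = 6.0) -> SpectralMap:
    """Optional cosmic-ray despiker (off by default in the pipeline).

    Replaces samples deviating from a running median by more than
    *threshold* times the band-wise robust scale with that median.
    """
    cube = spectral_map.intensities
    med = ndimage.median_filter(cube, size=(1, 1, window))
    resid = cube - med
    scale = 1.4826 * np.median(np.abs(resid), axis=(0, 1), keepdims=True)
    scale = np.where(scale > 0, scale, np.inf)
    out = np.where(np.abs(resid) > threshold * scale, med, cube)
    return spectral_map.with_intensities(out)
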
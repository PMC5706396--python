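"""Core containers for Raman hyperspectral maps.

A :class:`SpectralMap` is a W×H raster in which each pixel holds one spectrum
on a shared :class:`WavenumberAxis`. Pixels are addressed ``(row, col)`` with
a row-major, top-left origin, 0-based convention; the intensity cube is
indexed ``(row, col, band)``. Intensities are stored as float64 even though
raw CCD counts are integral: background subtraction legitimately produces
negative values and they are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AxisError, DimensionError, MalformedInputError


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm⁻¹."""

    values: np.ndarray
    resolution_hint: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise AxisError("axis must be a 1-D array with at least 2 values")
        if not np.all(np.isfinite(values)):
            raise AxisError("axis contains non-finite values")
        if np.any(values <= 0):
            raise AxisError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise AxisError("axis must be strictly increasing")
        if self.resolution_hint is None:
            object.__setattr__(
                self, "resolution_hint", float(np.median(np.diff(values)))
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "WavenumberAxis":
        """Regular grid ``start, start+step, ...`` up to and including *stop*
        when it falls on the grid (e.g. 400:3:3100)."""
        n = int(np.floor((stop - start) / step + 0.5 * np.finfo(float).eps ** 0.5)) + 1
        values = start + step * np.arange(n)
        values = values[values <= stop + 1e-9 * step]
        return cls(values, resolution_hint=float(step))

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean selector for the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass(frozen=True)
class MapMetadata:
    """Acquisition metadata carried alongside a map."""

    map_id: str = "unnamed"
    line_label: str = ""
    step_size_nm: float = 400.0
    laser_nm: float = 532.0
    notes: str = ""

    def __post_init__(self) -> None:
        if self.step_size_nm <= 0:
            raise MalformedInputError("step_size_nm must be > 0")
        if self.laser_nm <= 0:
            raise MalformedInputError("laser_nm must be > 0")


@dataclass
class SpectralMap:
    """Hyperspectral raster: ``intensities[row, col, band]`` on ``axis``."""

    axis: WavenumberAxis
    intensities: np.ndarray
    metadata: MapMetadata = field(default_factory=MapMetadata)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise DimensionError(
                f"intensities must be (height, width, bands), got shape {arr.shape}"
            )
        if arr.shape[2] != len(self.axis):
            raise DimensionError(
                f"band dimension {arr.shape[2]} does not match axis length "
                f"{len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise MalformedInputError("intensities contain non-finite values")
        self.intensities = arr

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def pixels(self) -> np.ndarray:
        """Row-major (n_pixels, n_bands) view of the spectra."""
        return self.intensities.reshape(self.n_pixels, self.n_bands)

    def with_intensities(self, intensities: np.ndarray) -> "SpectralMap":
        return SpectralMap(self.axis, intensities, self.metadata)

    def with_axis(self, axis: WavenumberAxis, intensities: np.ndarray | None = None) -> "SpectralMap":
        return SpectralMap(
            axis,
            self.intensities if intensities is None else intensities,
            self.metadata,
        )

    def with_metadata(self, **changes) -> "SpectralMap":
        return SpectralMap(self.axis, self.intensities, replace(self.metadata, **changes))


@dataclass(frozen=True)
class PixelMask:
    """Boolean cell mask; ``inside[row, col]`` is True inside the cell."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.inside, dtype=bool)
        if arr.ndim != 2:
            raise DimensionError("mask must be 2-D")
        object.__setattr__(self, "inside", arr)

    @property
    def height(self) -> int:
        return self.inside.shape[0]

    @property
    def width(self) -> int:
        return self.inside.shape[1]

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def outside(self) -> np.ndarray:
        return ~self.inside

    def check_matches(self, spectral_map: SpectralMap) -> None:
        if (self.height, self.width) != (spectral_map.height, spectral_map.width):
            raise DimensionError(
                f"mask {self.height}×{self.width} does not match map "
                f"{spectral_map.height}×{spectral_map.width}"
            )
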
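"""Ground-truthed synthetic Raman scenes of single cells.

The generator builds component spectra for the biochemical species that
dominate single-cell Raman maps of pluripotent stem cells — DNA/RNA bases,
resonance-enhanced cytochrome c, lipids, proteins, and a broad substrate
background — as sums of Lorentzian/Gaussian peaks at the band positions
assigned in the stem-cell Raman literature (e.g. 785, 1098, 1334, 1371,
1484, 1575 cm⁻¹ for nucleic-acid bases; 748, 1127, 1585 cm⁻¹ for cyt c).
A cell is laid out as an ellipse partitioned into labelled regions
(nucleoids with a perinuclear rim, a mitochondrial ring, lipid droplets,
bulk cytoplasm, a thin adherent edge); each pixel spectrum is a non-negative
mixture of the component spectra weighted by per-region abundances, plus a
smooth baseline and Gaussian + shot-like noise.

Because the abundance maps and region labels are retained as
:class:`SceneTruth`, every downstream stage (mask inference, PCA/K-means
segmentation, band imaging, group statistics) can be scored against known
ground truth. Two cell-line modes differ only in the DNA/RNA abundance
scale, so the embryonic-vs-induced discrimination logic can be exercised
end-to-end.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy import ndimage

from .errors import DataError, ParameterError
from .types import MapMetadata, PixelMask, SpectralMap, WavenumberAxis

__all__ = [
    "PeakShape",
    "ComponentSpectrum",
    "SceneTruth",
    "LineProfile",
    "NoiseModel",
    "CellGeometry",
    "REGION_NAMES",
    "INTRACELLULAR_REGIONS",
    "default_axis",
    "default_components",
    "eval_component_spectrum",
    "generate_cell_scene",
    "simulate_map",
    "generate_experiment",
]

#: Region labels, in the integer coding used by ``SceneTruth.region_label``.
#: ``outside`` is code 0; the remaining six are intracellular, mirroring the
#: six intracellular clusters the segmentation imposes.
REGION_NAMES = (
    "outside",
    "thin_edge",
    "cytoplasm",
    "lipid_droplet",
    "mito_ring",
    "nucleoid_rim",
    "nucleoid",
)
INTRACELLULAR_REGIONS = REGION_NAMES[1:]
REGION_CODES = {name: i for i, name in enumerate(REGION_NAMES)}

COMPONENT_NAMES = ("dna_rna", "cyt_c", "lipid", "protein", "substrate_background")

# Per-region base abundance of each biochemical component (arbitrary units,
# scaled per cell line by LineProfile). The substrate background is present
# everywhere at unit abundance and is handled separately.
# The nucleic-acid signal is concentrated in the nucleoid complex — cell
# lines with elevated DNA/RNA content show it in well-defined nuclear
# regions, not as a diffuse cytoplasmic floor — so the dna_rna floor outside
# the nucleoid/rim is kept low. Lipid droplets carry a high CH-band load:
# they are the brightest structures in cellular Raman maps, which also makes
# the per-map normalization reference (the maximum-area pixel) a
# line-independent structure.
_BASE_ABUNDANCE: dict[str, dict[str, float]] = {
    "outside":       {"dna_rna": 0.00, "cyt_c": 0.00, "lipid": 0.00, "protein": 0.00},
    "thin_edge":     {"dna_rna": 0.02, "cyt_c": 0.10, "lipid": 0.15, "protein": 0.30},
    "cytoplasm":     {"dna_rna": 0.05, "cyt_c": 0.35, "lipid": 0.45, "protein": 1.00},
    "lipid_droplet": {"dna_rna": 0.03, "cyt_c": 0.30, "lipid": 4.00, "protein": 0.50},
    "mito_ring":     {"dna_rna": 0.05, "cyt_c": 1.00, "lipid": 0.55, "protein": 0.90},
    "nucleoid_rim":  {"dna_rna": 0.50, "cyt_c": 0.25, "lipid": 0.25, "protein": 0.85},
    "nucleoid":      {"dna_rna": 1.00, "cyt_c": 0.20, "lipid": 0.20, "protein": 0.80},
}


@dataclass(frozen=True)
class PeakShape:
    """A single Raman band: Lorentzian or Gaussian with a given FWHM."""

    center: float
    fwhm: float
    amplitude: float = 1.0
    profile: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ParameterError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.profile not in ("lorentzian", "gaussian"):
            raise ParameterError(f"unknown profile {self.profile!r}")

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        nu = np.asarray(nu, dtype=np.float64)
        half = self.fwhm / 2.0
        if self.profile == "lorentzian":
            return self.amplitude * half**2 / ((nu - self.center) ** 2 + half**2)
        return self.amplitude * np.exp(-np.log(2.0) * ((nu - self.center) / half) ** 2)


@dataclass
class ComponentSpectrum:
    """Named biochemical component: a sum of peaks, evaluated on demand.

    Evaluations are memoised per axis because the same component is applied
    to every pixel of every map in an experiment.
    """

    name: str
    peaks: list[PeakShape]
    _cache: dict[bytes, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ParameterError(f"component {self.name!r} has no peaks")

    def evaluate(self, axis: WavenumberAxis) -> np.ndarray:
        key = axis.values.tobytes()
        if key not in self._cache:
            lo, hi = axis.values[0], axis.values[-1]
            span = hi - lo
            for pk in self.peaks:
                if pk.center < lo - span or pk.center > hi + span:
                    warnings.warn(
                        f"peak at {pk.center} cm⁻¹ of component {self.name!r} lies "
                        f"far outside the axis range [{lo}, {hi}]",
                        stacklevel=2,
                    )
            self._cache[key] = sum(pk.evaluate(axis.values) for pk in self.peaks)
        return self._cache[key]


def eval_component_spectrum(
    component: ComponentSpectrum, axis: WavenumberAxis
) -> np.ndarray:
    """Evaluate a component spectrum on *axis* (sum of its peak profiles)."""
    return component.evaluate(axis)


def default_axis() -> WavenumberAxis:
    """400–3100 cm⁻¹ at 3 cm⁻¹ spacing (instrument window and resolution)."""
    return WavenumberAxis.regular(400.0, 3100.0, 3.0)


def default_components() -> dict[str, ComponentSpectrum]:
    """Load the packaged peak table into component spectra.

    The table (``data/peak_table.csv``) lists, per component, band centers at
    the literature-assigned positions with plausible condensed-phase widths
    and relative amplitudes; amplitudes are documented defaults, not fits.
    """
    peaks: dict[str, list[PeakShape]] = {}
    path = resources.files("ramancell").joinpath("data/peak_table.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            peaks.setdefault(row["component"], []).append(
                PeakShape(
                    center=float(row["center_cm1"]),
                    fwhm=float(row["fwhm_cm1"]),
                    amplitude=float(row["rel_amplitude"]),
                    profile=row["profile"],
                )
            )
    return {name: ComponentSpectrum(name, pk) for name, pk in peaks.items()}


@dataclass(frozen=True)
class LineProfile:
    """Per-component multiplicative scaling defining a cell-line mode."""

    line_label: str = "hESC-like"
    component_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.component_scale.values()):
            raise ParameterError("component scales must be >= 0")

    def scale(self, component: str) -> float:
        return self.component_scale.get(component, 1.0)

    @classmethod
    def esc_like(cls) -> "LineProfile":
        return cls("hESC-like", {})

    @classmethod
    def ipsc_like(cls, dna_scale: float = 2.0) -> "LineProfile":
        """Higher nucleic-acid abundance, the planted line difference."""
        return cls("hiPSC-like", {"dna_rna": dna_scale})


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with a shot-like signal-dependent term plus a
    smooth polynomial baseline over the axis.

    The per-band standard deviation is ``sigma0 + shot_factor·√max(signal,0)``.
    ``baseline`` holds polynomial coefficients in the normalised coordinate
    ``t = (ν − ν_min)/(ν_max − ν_min)``.
    """

    gaussian_sigma0: float = 0.05
    shot_factor: float = 0.02
    baseline: tuple[float, ...] = (0.04, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma0 < 0 or self.shot_factor < 0:
            raise ParameterError("noise amplitudes must be >= 0")

    @classmethod
    def quiet(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free, baseline-free limit (pure mixture signal)."""
        return cls(0.0, 0.0, (), seed)

    def baseline_on(self, axis: WavenumberAxis) -> np.ndarray:
        if not self.baseline:
            return np.zeros(len(axis))
        t = (axis.values - axis.values[0]) / (axis.values[-1] - axis.values[0])
        return sum(c * t**i for i, c in enumerate(self.baseline))


@dataclass(frozen=True)
class CellGeometry:
    """Spatial layout parameters of a synthetic cell (pixels / fractions)."""

    ellipse_rx_frac: float = 0.42   # semi-axis as fraction of grid width
    ellipse_ry_frac: float = 0.36   # semi-axis as fraction of grid height
    edge_frac: float = 0.15         # thin-edge shell thickness (fraction of radius)
    n_nucleoids: int = 2
    nucleoid_radius_frac: float = 0.11  # of min(width, height)
    rim_width: float = 2.0          # perinuclear rim thickness, pixels
    mito_ring_width: float = 3.0    # mitochondrial ring thickness, pixels
    n_droplets: int = 3
    droplet_radius: float = 2.0     # pixels


@dataclass
class SceneTruth:
    """Ground truth of one synthetic cell scene."""

    mask: PixelMask
    abundance: dict[str, np.ndarray]
    region_label: np.ndarray  # int codes into REGION_NAMES

    def __post_init__(self) -> None:
        h, w = self.region_label.shape
        if (self.mask.height, self.mask.width) != (h, w):
            raise ParameterError("mask and region grid dimensions differ")
        for name, arr in self.abundance.items():
            if arr.shape != (h, w):
                raise ParameterError(f"abundance map {name!r} has wrong shape")
            if np.any(arr < 0):
                raise DataError(f"abundance map {name!r} has negative values")
            if name != "substrate_background" and np.any(arr[self.mask.outside] != 0):
                raise DataError(
                    f"abundance map {name!r} is nonzero outside the cell mask"
                )

    def region_fraction(self, name: str) -> float:
        return float(np.mean(self.region_label == REGION_CODES[name]))


def _smooth_jitter(rng: np.random.Generator, shape: tuple[int, int], rel: float) -> np.ndarray:
    """Spatially smooth multiplicative jitter field with relative sd ≈ *rel*."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return 1.0 + rel * field_


def generate_cell_scene(
    width: int = 64,
    height: int = 64,
    geometry: CellGeometry | None = None,
    seed: int = 0,
    jitter_rel: float = 0.05,
) -> SceneTruth:
    """Lay out one cell on a *height*×*width* grid and return its ground truth.

    Deterministic given *seed*. Region labels partition the grid; abundance
    maps are per-region base levels modulated by smooth ±``jitter_rel``
    spatial jitter, clipped at zero.
    """
    if width < 16 or height < 16:
        raise ParameterError("grid must be at least 16×16")
    geometry = geometry or CellGeometry()
    rx = geometry.ellipse_rx_frac * width
    ry = geometry.ellipse_ry_frac * height
    if rx > width / 2 or ry > height / 2:
        raise ParameterError("cell ellipse exceeds the grid")
    r_nuc = geometry.nucleoid_radius_frac * min(width, height)
    if geometry.n_nucleoids > 0 and r_nuc + geometry.rim_width + geometry.mito_ring_width >= min(rx, ry):
        raise ParameterError("nucleoid complex does not fit inside the cell")

    rng = np.random.default_rng(seed)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    rho2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    inside = rho2 <= 1.0
    inner = rho2 <= (1.0 - geometry.edge_frac) ** 2

    region = np.zeros((height, width), dtype=np.int8)  # outside
    region[inside & ~inner] = REGION_CODES["thin_edge"]
    region[inner] = REGION_CODES["cytoplasm"]

    # nucleoid complexes: disk + perinuclear rim + mitochondrial ring,
    # confined to the inner (cytoplasmic) ellipse
    for _ in range(geometry.n_nucleoids):
        for _attempt in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0, 1.0))
            ncx = cx + 0.45 * rx * rad * np.cos(ang)
            ncy = cy + 0.45 * ry * rad * np.sin(ang)
            if ((ncx - cx) / rx) ** 2 + ((ncy - cy) / ry) ** 2 < 0.5**2:
                break
        d = np.hypot(xx - ncx, yy - ncy)
        ring = geometry.rim_width + geometry.mito_ring_width
        sel = inner & (d <= r_nuc + ring)
        region[sel & (d <= r_nuc + ring)] = REGION_CODES["mito_ring"]
        region[sel & (d <= r_nuc + geometry.rim_width)] = REGION_CODES["nucleoid_rim"]
        region[sel & (d <= r_nuc)] = REGION_CODES["nucleoid"]

    # lipid droplets claim plain-cytoplasm pixels only
    cyto_code = REGION_CODES["cytoplasm"]
    for _ in range(geometry.n_droplets):
        candidates = np.argwhere(region == cyto_code)
        if candidates.size == 0:
            break
        r0, c0 = candidates[rng.integers(len(candidates))]
        d = np.hypot(xx - c0, yy - r0)
        region[(d <= geometry.droplet_radius) & (region == cyto_code)] = REGION_CODES[
            "lipid_droplet"
        ]

    mask = PixelMask(region != REGION_CODES["outside"])
    abundance: dict[str, np.ndarray] = {}
    for comp in ("dna_rna", "cyt_c", "lipid", "protein"):
        base = np.zeros((height, width))
        for rname, levels in _BASE_ABUNDANCE.items():
            base[region == REGION_CODES[rname]] = levels[comp]
        amap = base * _smooth_jitter(rng, (height, width), jitter_rel)
        amap[mask.outside] = 0.0
        abundance[comp] = np.clip(amap, 0.0, None)
    abundance["substrate_background"] = np.clip(
        _smooth_jitter(rng, (height, width), jitter_rel / 2), 0.0, None
    )
    return SceneTruth(mask=mask, abundance=abundance, region_label=region)


def simulate_map(
    scene: SceneTruth,
    components: dict[str, ComponentSpectrum] | None = None,
    line: LineProfile | None = None,
    noise: NoiseModel | None = None,
    axis: WavenumberAxis | None = None,
    map_id: str = "synthetic",
) -> SpectralMap:
    """Mix component spectra by the scene's abundances into a spectral map.

    ``I(x, y, ν) = Σ_c scale_c · a_c(x, y) · S_c(ν) + baseline(ν) + ε`` with
    ``ε ~ N(0, σ0 + shot_factor·√signal)``. Reproducible under a fixed
    ``noise.seed``.
    """
    components = components if components is not None else default_components()
    line = line or LineProfile.esc_like()
    noise = noise or NoiseModel()
    axis = axis or default_axis()

    missing = [c for c in scene.abundance if c not in components]
    if missing:
        raise ParameterError(f"no component spectrum for abundance layer(s) {missing}")
    for name, amap in scene.abundance.items():
        if np.any(amap < 0):
            raise DataError(f"negative abundance in layer {name!r}")

    names = list(scene.abundance)
    stack = np.stack(
        [line.scale(n) * scene.abundance[n] for n in names], axis=-1
    )  # (h, w, C)
    spectra = np.stack([components[n].evaluate(axis) for n in names])  # (C, B)
    signal = np.tensordot(stack, spectra, axes=([2], [0]))  # (h, w, B)
    signal = signal + noise.baseline_on(axis)[None, None, :]

    if noise.gaussian_sigma0 > 0 or noise.shot_factor > 0:
        rng = np.random.default_rng(noise.seed)
        sigma = noise.gaussian_sigma0 + noise.shot_factor * np.sqrt(
            np.clip(signal, 0.0, None)
        )
        signal = signal + sigma * rng.standard_normal(signal.shape)

    meta = MapMetadata(map_id=map_id, line_label=line.line_label)
    return SpectralMap(axis, signal, meta)


def generate_experiment(
    n_per_line: int = 3,
    dna_scale_ipsc: float = 2.0,
    seed: int = 0,
    width: int = 64,
    height: int = 64,
    axis: WavenumberAxis | None = None,
    components: dict[str, ComponentSpectrum] | None = None,
    noise: NoiseModel | None = None,
    geometry: CellGeometry | None = None,
) -> list[tuple[SpectralMap, SceneTruth]]:
    """Simulate a paired experiment: *n_per_line* cells per cell-line mode.

    The two modes share everything except the DNA/RNA abundance scale
    (``dna_scale_ipsc`` for the iPSC-like line; 1.0 is the null experiment
    with statistically exchangeable lines). Per-cell geometry is varied by
    sub-seeds derived from *seed*; ground truth is retained for every map.
    """
    if n_per_line < 1:
        raise ParameterError("n_per_line must be >= 1")
    axis = axis or default_axis()
    components = components if components is not None else default_components()
    base_noise = noise or NoiseModel()
    base_geom = geometry or CellGeometry()
    lines = [LineProfile.esc_like(), LineProfile.ipsc_like(dna_scale_ipsc)]

    out: list[tuple[SpectralMap, SceneTruth]] = []
    children = np.random.SeedSequence(seed).spawn(2 * n_per_line)
    idx = 0
    for line in lines:
        for i in range(n_per_line):
            child = children[idx]
            idx += 1
            sub = child.generate_state(3) % np.uint32(2**31)
            vary = np.random.default_rng(int(sub[0]))
            geom = replace(
                base_geom,
                ellipse_rx_frac=base_geom.ellipse_rx_frac * vary.uniform(0.92, 1.0),
                ellipse_ry_frac=base_geom.ellipse_ry_frac * vary.uniform(0.92, 1.0),
                n_nucleoids=int(vary.integers(max(1, base_geom.n_nucleoids - 1),
                                              base_geom.n_nucleoids + 2)),
                n_droplets=int(vary.integers(max(1, base_geom.n_droplets - 1),
                                             base_geom.n_droplets + 2)),
            )
            scene = generate_cell_scene(width, height, geom, seed=int(sub[1]))
            nm = replace(base_noise, seed=int(sub[2]))
            map_id = f"{line.line_label}_{i:02d}"
            out.append(
                (simulate_map(scene, components, line, nm, axis, map_id), scene)
            )
    return out
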
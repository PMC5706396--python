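"""Configured, logged, reproducible runs: simulate → analyze → report.

A run is governed by a single validated :class:`RunConfig` (YAML on disk;
unknown keys are rejected to catch typos). Every stage writes its outputs
under a run directory together with a JSON manifest holding the config
snapshot, software version, SHA-256 hashes of every output file, and
wall-clock stamps; identical config + seed reproduce hash-identical
CSV/label outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .band_imaging import DEFAULT_BANDS, band_intensity, make_composite
from .errors import ConfigError, DataError, RamanCellError
from .io_formats import read_map, read_mask, write_map, write_mask
from .multivariate import (
    CLUSTER_PALETTE,
    compare_all_clusters,
    fit_kmeans,
    fit_pca,
    identify_outside_cluster,
    make_cluster_map,
    pool_maps,
    project,
    summarize_clusters,
)
from .preprocessing import (
    calibrate_axis,
    despike,
    estimate_background,
    infer_cell_mask,
    normalize_map,
    split_regions,
    subtract_background,
)
from .synthetic_scene import (
    NoiseModel,
    WavenumberAxis,
    generate_experiment,
)
from .types import PixelMask, SpectralMap

log = logging.getLogger("ramancell")

_CSV_FLOAT = "%.12g"


class AxisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = 400.0
    stop: float = 3100.0
    step: float = 3.0

    def build(self) -> WavenumberAxis:
        return WavenumberAxis.regular(self.start, self.stop, self.step)


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gaussian_sigma0: float = Field(0.05, ge=0)
    shot_factor: float = Field(0.02, ge=0)
    baseline: list[float] = [0.04, 0.02]


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_line: int = Field(3, ge=1)
    dna_scale_ipsc: float = Field(2.0, ge=0)
    width: int = Field(64, ge=16)
    height: int = Field(64, ge=16)
    noise: NoiseConfig = NoiseConfig()


class AnalyzeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    region: str = "fingerprint"            # fingerprint | ch_stretch | both
    background_estimator: str = "mean"     # mean | median
    mask_strategy: str = "otsu_total_intensity"
    despike: bool = False
    n_pcs: int = Field(6, ge=1)
    n_clusters: int = Field(7, ge=2)
    n_restarts: int = Field(20, ge=1)
    band_half_width: float = Field(10.0, gt=0)


class RunConfig(BaseModel):
    """Schema-validated configuration of a complete run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    axis: AxisConfig = AxisConfig()
    simulate: SimulateConfig = SimulateConfig()
    analyze: AnalyzeConfig = AnalyzeConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, config: RunConfig,
                    files: list[Path], started: float) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config.model_dump(),
        "files": {p.name: _sha256(p) for p in sorted(files)},
        "started": started,
        "finished": time.time(),
    }
    path = out_dir / f"manifest_{stage}.json"
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)  # atomic on POSIX
    return path


def _write_grid(path: Path, grid: np.ndarray, fmt: str) -> Path:
    np.savetxt(path, grid, fmt=fmt, delimiter="\t")
    return path


def _write_png(path: Path, rgb_or_gray: np.ndarray) -> Path:
    arr = np.clip(rgb_or_gray, 0.0, 1.0)
    img = Image.fromarray((arr * 255).round().astype(np.uint8))
    img.save(path)
    return path


def run_simulate(config: RunConfig, out_dir) -> Path:
    """Generate the configured synthetic experiment; write maps + truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    sim = config.simulate
    noise = NoiseModel(
        gaussian_sigma0=sim.noise.gaussian_sigma0,
        shot_factor=sim.noise.shot_factor,
        baseline=tuple(sim.noise.baseline),
    )
    experiment = generate_experiment(
        n_per_line=sim.n_per_line,
        dna_scale_ipsc=sim.dna_scale_ipsc,
        seed=config.seed,
        width=sim.width,
        height=sim.height,
        axis=config.axis.build(),
        noise=noise,
    )
    files: list[Path] = []
    for smap, truth in experiment:
        mid = smap.metadata.map_id
        files.append(write_map(smap, out_dir / f"{mid}.map.tsv", "matrix"))
        files.append(write_mask(truth.mask, out_dir / f"{mid}.mask.txt"))
        files.append(
            _write_grid(out_dir / f"{mid}.regions.tsv", truth.region_label, "%d")
        )
        for comp, amap in truth.abundance.items():
            files.append(
                _write_grid(out_dir / f"{mid}.abundance_{comp}.tsv", amap, "%.9g")
            )
        log.info("simulate: wrote map %s (%d×%d)", mid, smap.height, smap.width)
    manifest = _write_manifest(out_dir, "simulate", config, files, started)
    return manifest


def _preprocess_one(
    smap: SpectralMap,
    cfg: AnalyzeConfig,
    mask: PixelMask | None,
    si_spectrum: np.ndarray | None,
):
    """Calibrate → split → background-subtract → normalize one map."""
    offset = 0.0
    if si_spectrum is not None:
        calib, corrected = calibrate_axis(si_spectrum, smap.axis)
        smap = smap.with_axis(corrected)
        offset = calib.offset
    if cfg.despike:
        smap = despike(smap)
    if mask is None:
        mask = infer_cell_mask(smap, strategy=cfg.mask_strategy)
    regions = split_regions(smap)
    processed: dict[str, SpectralMap] = {}
    for name, rmap in (
        ("fingerprint", regions.fingerprint),
        ("ch_stretch", regions.ch_stretch),
        ("full", smap),
    ):
        if rmap is None:
            continue
        bg = estimate_background(rmap, mask, estimator=cfg.background_estimator)
        processed[name] = subtract_background(rmap, bg)
    _, constant = normalize_map(processed["fingerprint"])
    processed = {
        name: m.with_intensities(m.intensities / constant)
        for name, m in processed.items()
    }
    n_bg = int(mask.outside.sum())
    return processed, mask, {
        "normalization_constant": constant,
        "calibration_offset_cm1": offset,
        "n_background_pixels": n_bg,
    }


def _analysis_map(processed: dict[str, SpectralMap], region: str) -> SpectralMap:
    if region in ("fingerprint", "ch_stretch"):
        m = processed.get(region)
        if m is None:
            raise DataError(f"region {region!r} not present on this axis")
        return m
    if region == "both":
        fp, ch = processed["fingerprint"], processed.get("ch_stretch")
        if ch is None:
            return fp
        values = np.concatenate([fp.axis.values, ch.axis.values])
        cube = np.concatenate([fp.intensities, ch.intensities], axis=2)
        return fp.with_axis(WavenumberAxis(values), cube)
    raise ConfigError(f"unknown analysis region {region!r}")


def run_analyze(
    config: RunConfig,
    map_paths: list,
    out_dir,
    mask_paths: list | None = None,
    si_spectrum_path=None,
) -> Path:
    """Full multivariate analysis of a set of map files.

    Masks are inferred from total intensity unless *mask_paths* provides one
    file per map; *si_spectrum_path* optionally supplies a two-column TSV
    silicon reference spectrum for wavenumber calibration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    cfg = config.analyze
    maps = [read_map(p) for p in map_paths]
    if not maps:
        raise DataError("no input maps")
    si_spectrum = None
    if si_spectrum_path is not None:
        table = np.loadtxt(si_spectrum_path)
        si_spectrum = table[:, 1]
    masks: list[PixelMask | None]
    if mask_paths is not None:
        if len(mask_paths) != len(maps):
            raise DataError("need one mask per map")
        masks = [read_mask(p, like=m) for p, m in zip(mask_paths, maps)]
    else:
        masks = [None] * len(maps)

    files: list[Path] = []
    stage = "preprocessing"
    try:
        processed_maps, provenance = [], {}
        for smap, mask in zip(maps, masks):
            processed, used_mask, prov = _preprocess_one(smap, cfg, mask, si_spectrum)
            processed_maps.append((smap.metadata.map_id, processed, used_mask))
            provenance[smap.metadata.map_id] = prov
            log.info(
                "preprocess: map=%s norm_constant=%.6g offset=%.3f n_bg=%d",
                smap.metadata.map_id, prov["normalization_constant"],
                prov["calibration_offset_cm1"], prov["n_background_pixels"],
            )

        stage = "pool_maps"
        analysis_maps = [
            _analysis_map(processed, cfg.region) for _, processed, _ in processed_maps
        ]
        dataset = pool_maps(analysis_maps)

        stage = "pca"
        pca = fit_pca(dataset)
        scores = project(dataset, pca, K=cfg.n_pcs)

        stage = "kmeans"
        km = fit_kmeans(
            scores, k=cfg.n_clusters, seed=config.seed, n_restarts=cfg.n_restarts
        )
        outside_id = identify_outside_cluster(km, dataset)
        summary = summarize_clusters(km, dataset)
        log.info("kmeans: inertia=%.6g outside_id=%d colors=%s",
                 km.inertia, outside_id, summary.colors)

        stage = "outputs"
        nu = dataset.axis.values
        loadings = pd.DataFrame(
            {"wavenumber": nu}
            | {f"pc{i+1}": pca.loadings[i] for i in range(cfg.n_pcs)}
        )
        loadings.to_csv(out_dir / "loadings.csv", index=False, float_format=_CSV_FLOAT)
        files.append(out_dir / "loadings.csv")

        ev = pd.DataFrame(
            {
                "component": np.arange(1, pca.n_components + 1),
                "variance": pca.explained_variance,
                "fraction": pca.explained_variance_ratio,
            }
        )
        ev.to_csv(out_dir / "explained_variance.csv", index=False,
                  float_format=_CSV_FLOAT)
        files.append(out_dir / "explained_variance.csv")

        summary.areas.to_csv(out_dir / "cluster_percent_areas.csv", index=False,
                             float_format=_CSV_FLOAT)
        files.append(out_dir / "cluster_percent_areas.csv")

        spec_df = pd.DataFrame(
            {"wavenumber": nu}
            | {f"cluster_{j}": summary.spectra[j] for j in range(km.k)}
        )
        spec_df.to_csv(out_dir / "cluster_mean_spectra.csv", index=False,
                       float_format=_CSV_FLOAT)
        files.append(out_dir / "cluster_mean_spectra.csv")

        colors = summary.colors or {}
        color_df = pd.DataFrame(
            [
                {
                    "cluster": j,
                    "color": colors.get(j, ""),
                    "is_outside": j == outside_id,
                }
                for j in range(km.k)
            ]
        )
        color_df.to_csv(out_dir / "cluster_colors.csv", index=False)
        files.append(out_dir / "cluster_colors.csv")

        palette = (
            {j: CLUSTER_PALETTE[name] for j, name in colors.items()} if colors else None
        )
        for (mid, processed, used_mask), smap in zip(processed_maps, maps):
            rgb, labels = make_cluster_map(km, dataset, mid, palette=palette)
            files.append(_write_grid(out_dir / f"labels_{mid}.tsv", labels, "%d"))
            files.append(_write_png(out_dir / f"clusters_{mid}.png", rgb))
            files.append(write_mask(used_mask, out_dir / f"mask_{mid}.txt"))
            full = processed["full"]
            composite = make_composite(full, DEFAULT_BANDS, mask=used_mask)
            files.append(_write_png(out_dir / f"composite_{mid}.png", composite))
            for band in DEFAULT_BANDS:
                img = band_intensity(full, band)
                files.append(
                    _write_grid(out_dir / f"band_{band.name}_{mid}.tsv", img, "%.9g")
                )
                rng_ = img.max() - img.min()
                gray = (img - img.min()) / rng_ if rng_ > 0 else np.zeros_like(img)
                files.append(_write_png(out_dir / f"band_{band.name}_{mid}.png", gray))

        stage = "group_comparison"
        labels_present = {m.line_label for m in dataset.map_info.values()}
        if len(labels_present) == 2:
            counts = pd.Series(
                [m.line_label for m in dataset.map_info.values()]
            ).value_counts()
            if counts.min() >= 2:
                comparison = compare_all_clusters(summary.areas)
                comparison.to_csv(out_dir / "group_comparison.csv", index=False,
                                  float_format=_CSV_FLOAT)
                files.append(out_dir / "group_comparison.csv")
            else:
                log.info("group_comparison: skipped, a group has fewer than 2 maps")
        else:
            log.info("group_comparison: skipped, found %d line labels",
                     len(labels_present))

        prov_path = out_dir / "provenance.json"
        prov_path.write_text(
            json.dumps(
                {
                    "per_map": provenance,
                    "outside_cluster": outside_id,
                    "cluster_colors": {str(j): c for j, c in colors.items()},
                },
                indent=2,
                sort_keys=True,
            )
        )
        files.append(prov_path)
    except RamanCellError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return _write_manifest(out_dir, "analyze", config, files, started)


_REPORT_REQUIRED = (
    "explained_variance.csv",
    "cluster_percent_areas.csv",
    "cluster_colors.csv",
    "manifest_analyze.json",
)


def run_report(run_dir) -> Path:
    """Render a markdown summary of a completed analysis run."""
    run_dir = Path(run_dir)
    missing = [name for name in _REPORT_REQUIRED if not (run_dir / name).exists()]
    if missing:
        raise DataError(f"incomplete run, missing: {', '.join(missing)}")
    ev = pd.read_csv(run_dir / "explained_variance.csv")
    areas = pd.read_csv(run_dir / "cluster_percent_areas.csv")
    colors = pd.read_csv(run_dir / "cluster_colors.csv").set_index("cluster")
    manifest = json.loads((run_dir / "manifest_analyze.json").read_text())

    lines = ["# ramancell run report", ""]
    lines.append(f"Software version: {manifest['version']}; "
                 f"seed: {manifest['config']['seed']}")
    lines.append("")
    lines.append("## Explained variance")
    lines.append("")
    top = ev.head(6)
    cum = top["fraction"].sum() * 100
    lines.append("| PC | variance | fraction (%) |")
    lines.append("|---:|---------:|-------------:|")
    for _, row in top.iterrows():
        lines.append(
            f"| {int(row['component'])} | {row['variance']:.4g} "
            f"| {100 * row['fraction']:.2f} |"
        )
    lines.append("")
    lines.append(f"First {len(top)} PCs carry {cum:.1f}% of the total variance.")
    lines.append("")
    lines.append("## Cluster percentage areas (mean ± SEM per line)")
    lines.append("")
    pivot = areas.groupby(["cluster", "line_label"])["percent"].agg(["mean", "sem", "count"])
    lines.append("| cluster | color | line | mean % | SEM |")
    lines.append("|--------:|-------|------|-------:|----:|")
    for (cl, line_label), row in pivot.iterrows():
        color = colors.loc[cl, "color"] if cl in colors.index else ""
        lines.append(
            f"| {cl} | {color} | {line_label} | {row['mean']:.2f} "
            f"| {0.0 if np.isnan(row['sem']) else row['sem']:.2f} |"
        )
    lines.append("")
    comp_path = run_dir / "group_comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        lines.append("## Group comparison (two-sample t, pooled variance)")
        lines.append("")
        lines.append("| cluster | color | t | p | p (Bonferroni) |")
        lines.append("|--------:|-------|--:|--:|---------------:|")
        for _, row in comp.iterrows():
            cl = int(row["cluster"])
            color = colors.loc[cl, "color"] if cl in colors.index else ""
            lines.append(
                f"| {cl} | {color} | {row['t']:.3f} | {row['p']:.3g} "
                f"| {row['p_bonferroni']:.3g} |"
            )
        lines.append("")
    lines.append("## Provenance")
    lines.append("")
    for name, digest in sorted(manifest["files"].items()):
        lines.append(f"- `{name}` sha256 `{digest[:16]}…`")
    lines.append("")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
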
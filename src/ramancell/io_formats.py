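"""Plain-text interchange formats for spectral maps and cell masks.

Vendor spectrometer exports vary; this package defines two diff-able TSV
dialects so that every pipeline stage is file-addressable:

``matrix`` dialect
    One row per wavenumber. First column ``wavenumber``; remaining columns
    are pixels in row-major order, named ``px_<row>_<col>`` (origin top-left,
    0-based). Best for eyeballing whole spectra.

``long`` dialect
    One record per (pixel, band): columns ``x_index  y_index  wavenumber
    intensity`` with ``x_index`` = column and ``y_index`` = row. Best for
    joining against per-pixel tables.

Both carry ``#``-prefixed ``key=value`` metadata header lines (``map_id``,
``line_label``, ``step_size_nm``, ``laser_nm``, ``height``, ``width``,
``notes``). Intensities are rendered with 17 significant digits, so a
write/read round trip reproduces float64 values bit-for-bit.

Masks travel either as PNG (0 = outside, 255 = inside) or as a text grid of
0/1 digits, one row per line.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DimensionError, MalformedInputError
from .types import MapMetadata, PixelMask, SpectralMap, WavenumberAxis

_FLOAT_FMT = "%.17g"


def _format_header(spectral_map: SpectralMap, dialect: str) -> list[str]:
    md = spectral_map.metadata
    return [
        "# ramancell-map v1",
        f"# dialect={dialect}",
        f"# map_id={md.map_id}",
        f"# line_label={md.line_label}",
        f"# step_size_nm={_FLOAT_FMT % md.step_size_nm}",
        f"# laser_nm={_FLOAT_FMT % md.laser_nm}",
        f"# height={spectral_map.height}",
        f"# width={spectral_map.width}",
        f"# notes={md.notes}",
    ]


def _parse_header(lines: list[str], path: os.PathLike) -> dict[str, str]:
    header: dict[str, str] = {}
    for line in lines:
        body = line[1:].strip()
        if "=" in body:
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
    return header


def write_map(spectral_map: SpectralMap, path: os.PathLike, dialect: str = "matrix") -> Path:
    """Write *spectral_map* to *path* in the given dialect; returns the path."""
    path = Path(path)
    if dialect not in ("matrix", "long"):
        raise MalformedInputError(f"unknown dialect {dialect!r}")
    lines = _format_header(spectral_map, dialect)
    axis = spectral_map.axis.values
    cube = spectral_map.intensities
    h, w = spectral_map.height, spectral_map.width
    if dialect == "matrix":
        cols = ["wavenumber"] + [
            f"px_{r}_{c}" for r in range(h) for c in range(w)
        ]
        lines.append("\t".join(cols))
        flat = cube.reshape(h * w, -1)  # rows = pixels
        for b in range(axis.size):
            row = [_FLOAT_FMT % axis[b]] + [_FLOAT_FMT % v for v in flat[:, b]]
            lines.append("\t".join(row))
    else:
        lines.append("x_index\ty_index\twavenumber\tintensity")
        for r in range(h):
            for c in range(w):
                for b in range(axis.size):
                    lines.append(
                        f"{c}\t{r}\t{_FLOAT_FMT % axis[b]}\t{_FLOAT_FMT % cube[r, c, b]}"
                    )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_map(path: os.PathLike, dialect: str | None = None) -> SpectralMap:
    """Read a spectral map written by :func:`write_map`.

    *dialect* may be omitted; it is then taken from the file header.
    Raises :class:`MalformedInputError` for ragged or missing records and
    :class:`AxisError` for a non-increasing wavenumber axis.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    header_lines = [ln for ln in raw if ln.startswith("#")]
    body = [ln for ln in raw if ln.strip() and not ln.startswith("#")]
    header = _parse_header(header_lines, path)
    file_dialect = header.get("dialect")
    if dialect is None:
        dialect = file_dialect
    if dialect not in ("matrix", "long"):
        raise MalformedInputError(
            f"{path}: dialect not given and not found in header"
        )
    if file_dialect is not None and file_dialect != dialect:
        raise MalformedInputError(
            f"{path}: requested dialect {dialect!r} but file says {file_dialect!r}"
        )
    metadata = MapMetadata(
        map_id=header.get("map_id", path.stem),
        line_label=header.get("line_label", ""),
        step_size_nm=float(header.get("step_size_nm", 400.0)),
        laser_nm=float(header.get("laser_nm", 532.0)),
        notes=header.get("notes", ""),
    )
    if not body:
        raise MalformedInputError(f"{path}: no data records")
    if dialect == "matrix":
        return _read_matrix(path, body, header, metadata)
    return _read_long(path, body, header, metadata)


def _read_matrix(path, body, header, metadata) -> SpectralMap:
    col_names = body[0].split("\t")
    if col_names[0] != "wavenumber":
        raise MalformedInputError(
            f"{path}: matrix dialect must start with a 'wavenumber' column, "
            f"got {col_names[0]!r}"
        )
    pixel_cols = col_names[1:]
    n_px = len(pixel_cols)
    if n_px == 0:
        raise MalformedInputError(f"{path}: no pixel columns")
    try:
        h = int(header["height"])
        w = int(header["width"])
    except KeyError:
        # infer square-free layout from column names
        rows = [int(name.split("_")[1]) for name in pixel_cols]
        cols = [int(name.split("_")[2]) for name in pixel_cols]
        h, w = max(rows) + 1, max(cols) + 1
    if h * w != n_px:
        raise MalformedInputError(
            f"{path}: header says {h}×{w} pixels but file has {n_px} pixel columns"
        )
    expected = [f"px_{r}_{c}" for r in range(h) for c in range(w)]
    if pixel_cols != expected:
        bad = next(
            (got for got, exp in zip(pixel_cols, expected) if got != exp),
            pixel_cols[0],
        )
        raise MalformedInputError(
            f"{path}: pixel columns are not row-major px_<row>_<col>; first "
            f"offending column {bad!r}"
        )
    axis_vals = []
    data = []
    for i, line in enumerate(body[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_px + 1:
            raise MalformedInputError(
                f"{path}: line {i} has {len(fields)} fields, expected {n_px + 1}"
            )
        try:
            axis_vals.append(float(fields[0]))
            data.append([float(f) for f in fields[1:]])
        except ValueError as exc:
            raise MalformedInputError(f"{path}: line {i}: {exc}") from exc
    axis = WavenumberAxis(np.array(axis_vals))
    cube = np.array(data).T.reshape(h, w, len(axis_vals))
    return SpectralMap(axis, cube, metadata)


def _read_long(path, body, header, metadata) -> SpectralMap:
    expected_cols = ["x_index", "y_index", "wavenumber", "intensity"]
    if body[0].split("\t") != expected_cols:
        raise MalformedInputError(
            f"{path}: long dialect requires columns {expected_cols}"
        )
    xs, ys, nus, vals = [], [], [], []
    for i, line in enumerate(body[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 4:
            raise MalformedInputError(
                f"{path}: line {i} has {len(fields)} fields, expected 4"
            )
        try:
            xs.append(int(fields[0]))
            ys.append(int(fields[1]))
            nus.append(float(fields[2]))
            vals.append(float(fields[3]))
        except ValueError as exc:
            raise MalformedInputError(f"{path}: line {i}: {exc}") from exc
    xs_a, ys_a = np.array(xs), np.array(ys)
    w = int(header.get("width", xs_a.max() + 1))
    h = int(header.get("height", ys_a.max() + 1))
    if xs_a.min() < 0 or ys_a.min() < 0 or xs_a.max() >= w or ys_a.max() >= h:
        raise MalformedInputError(f"{path}: pixel index outside {h}×{w} grid")

    # axis = sorted unique wavenumbers; every pixel must carry all of them
    axis_vals = np.unique(np.array(nus))
    n_bands = axis_vals.size
    band_index = {v: b for b, v in enumerate(axis_vals)}
    cube = np.full((h, w, n_bands), np.nan)
    for x, y, nu, v in zip(xs, ys, nus, vals):
        cube[y, x, band_index[nu]] = v
    missing = np.isnan(cube)
    if missing.any():
        per_pixel = missing.any(axis=2)
        r, c = np.argwhere(per_pixel)[0]
        if missing[r, c].all():
            raise MalformedInputError(
                f"{path}: missing pixel ({c},{r}) — no records for that pixel"
            )
        raise MalformedInputError(
            f"{path}: pixel ({c},{r}) has a ragged spectrum "
            f"({int((~missing[r, c]).sum())} of {n_bands} bands present)"
        )
    axis = WavenumberAxis(axis_vals)
    return SpectralMap(axis, cube, metadata)


def write_mask(mask: PixelMask, path: os.PathLike) -> Path:
    """Write a mask as PNG (``.png``) or 0/1 text grid (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        img = Image.fromarray((mask.inside.astype(np.uint8)) * 255, mode="L")
        img.save(path)
    else:
        lines = ["".join("1" if v else "0" for v in row) for row in mask.inside]
        path.write_text("\n".join(lines) + "\n")
    return path


def read_mask(path: os.PathLike, like: SpectralMap | None = None) -> PixelMask:
    """Read a mask; if *like* is given, validate its dimensions against the map."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
        inside = arr >= 128
    else:
        rows = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        # accept both packed "0101" rows and whitespace-separated "0 1 0 1"
        parsed = []
        for i, row in enumerate(rows, start=1):
            digits = row.split() if " " in row or "\t" in row else list(row)
            if not all(d in ("0", "1") for d in digits):
                raise MalformedInputError(f"{path}: line {i} is not a 0/1 row")
            parsed.append([d == "1" for d in digits])
        widths = {len(r) for r in parsed}
        if len(widths) != 1:
            raise MalformedInputError(f"{path}: ragged mask rows")
        inside = np.array(parsed, dtype=bool)
    mask = PixelMask(inside)
    if like is not None:
        mask.check_matches(like)
    return mask
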
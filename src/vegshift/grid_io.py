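"""Data model and I/O for co-registered rasters, occurrence tables and code tables.

Every downstream stage operates on three types defined here:

``Grid``
    a single-band georeferenced raster on a regular cell grid with a nodata
    sentinel.  Values may be continuous (suitability, climate) or categorical
    integer codes (land cover, degradation level).
``GridStack``
    a named collection of co-registered ``Grid`` layers used as model
    predictors, tagged with the climate scenario it represents.
``OccurrenceSet``
    labelled presence points (x, y, taxon) with a role — ``forest`` for
    forest-indicator taxa, ``shrub`` for open-vegetation indicators.

The pipeline deliberately performs no reprojection or resampling: all rasters
must be supplied pre-aligned on one shared grid (see :func:`align_check`),
which keeps zonal and cellwise semantics unambiguous.

Raster files are single-band GeoTIFFs written through :mod:`tifffile` with the
standard GeoTIFF georeferencing tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA); an ESRI ASCII grid (``.asc``) plain-text format is supported as
well.  Categorical grids carry a sidecar JSON code table ``{code: class
name}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Grid",
    "GridStack",
    "OccurrenceSet",
    "GridFormatError",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "read_occurrences",
    "write_occurrences",
    "align_check",
    "read_code_table",
    "write_code_table",
]

# GeoTIFF / GDAL tag codes used for georeferencing a plain TIFF.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised for unreadable or unsupported raster input."""


class AlignmentError(ValueError):
    """Raised when grids expected to share a common grid do not."""


@dataclass(frozen=True)
class Transform:
    """Affine north-up transform: map origin of the top-left cell corner plus
    cell size in map units.  ``dy`` is positive; rows increase southwards."""

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("cell width and height must be positive")

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def point_to_cell(self, x, y, shape: tuple[int, int]):
        """Map points to the cell whose center is nearest.

        Points exactly on a cell boundary are assigned to the cell with the
        lower row/col index.  Returns (rows, cols, inside) where ``inside``
        flags points within the grid extent (boundary points on the outer
        edge count as inside).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrows, ncols = shape
        fc = (x - self.x0) / self.dx
        fr = (self.y0 - y) / self.dy
        # ceil(f) - 1 sends integer f (a boundary) to the lower-index cell
        col = np.ceil(fc).astype(int) - 1
        row = np.ceil(fr).astype(int) - 1
        inside = (fc >= 0) & (fc <= ncols) & (fr >= 0) & (fr <= nrows)
        # the f == 0 boundary (outer west/north edge) belongs to cell 0
        col = np.clip(col, 0, ncols - 1)
        row = np.clip(row, 0, nrows - 1)
        return row, col, inside


@dataclass
class Grid:
    """A single-band raster: value array, transform, nodata sentinel."""

    values: np.ndarray
    transform: Transform
    crs_label: str = "synthetic"
    nodata: float = DEFAULT_NODATA
    units: str = ""
    code_table: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a 2-D array with >= 1 row and column")
        if self.code_table is not None:
            codes = np.unique(self.values[self.mask])
            unknown = [c for c in codes if int(c) not in self.code_table]
            if unknown:
                raise ValueError(f"categorical codes not in code table: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        v = self.values
        if np.isnan(self.nodata):
            return ~np.isnan(v)
        m = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            m &= ~np.isnan(v)
        return m

    @property
    def cell_area(self) -> float:
        """Cell area in squared map units."""
        return self.transform.dx * self.transform.dy

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def like(self, values: np.ndarray, nodata: float | None = None, **kw) -> "Grid":
        """A new grid on the same transform/crs with different values."""
        return Grid(
            values=values,
            transform=self.transform,
            crs_label=self.crs_label,
            nodata=self.nodata if nodata is None else nodata,
            **kw,
        )

    def same_grid(self, other: "Grid") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def values_at(self, x, y) -> np.ndarray:
        """Sample the grid at point coordinates (nearest cell center)."""
        r, c, inside = self.transform.point_to_cell(x, y, self.shape)
        out = np.full(np.shape(r), self.nodata, dtype=float)
        out[inside] = self.values[r[inside], c[inside]]
        return out


@dataclass
class GridStack:
    """Named, co-registered grids used as model predictors."""

    layers: dict[str, Grid]
    scenario: str = "current"

    def __post_init__(self) -> None:
        if self.scenario not in ("current", "paleo"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        grids = list(self.layers.values())
        if grids:
            ref = grids[0]
            for name, g in self.layers.items():
                if not g.same_grid(ref):
                    raise AlignmentError(f"layer {name!r} is not on the shared grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def transform(self) -> Transform:
        return next(iter(self.layers.values())).transform

    def common_mask(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Cells valid in every (selected) layer."""
        names = list(self.layers) if names is None else list(names)
        m = np.ones(self.shape, dtype=bool)
        for n in names:
            m &= self.layers[n].mask
        return m

    def subset(self, names: Sequence[str]) -> "GridStack":
        return GridStack({n: self.layers[n] for n in names}, scenario=self.scenario)


@dataclass
class OccurrenceSet:
    """Presence points with a role and the scenario they index."""

    points: pd.DataFrame  # columns x, y, taxon, role
    role: str
    scenario: str = "current"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("forest", "shrub"):
            raise ValueError(f"role must be 'forest' or 'shrub', got {self.role!r}")
        required = {"x", "y", "taxon"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points need columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points["x"].to_numpy(float), self.points["y"].to_numpy(float)

    def clip_to(self, grid: Grid) -> "OccurrenceSet":
        """Keep only points that fall on a valid (non-nodata) cell."""
        x, y = self.xy
        r, c, inside = grid.transform.point_to_cell(x, y, grid.shape)
        keep = inside.copy()
        keep[inside] &= grid.mask[r[inside], c[inside]]
        return replace(
            self,
            points=self.points.loc[keep].reset_index(drop=True),
            n_dropped=self.n_dropped + int((~keep).sum()),
        )


# ---------------------------------------------------------------------------
# raster I/O


def write_grid(grid: Grid, path: str | Path) -> Path:
    """Write a grid to single-band GeoTIFF (or `.asc` ESRI ASCII grid)."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        return _write_ascii_grid(grid, path)
    t = grid.transform
    desc = {
        "crs_label": grid.crs_label,
        "units": grid.units,
    }
    if grid.code_table is not None:
        desc["code_table"] = {str(k): v for k, v in grid.code_table.items()}
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(
        path,
        grid.values,
        extratags=extratags,
        description=json.dumps(desc),
        metadata=None,  # keep ImageDescription to our JSON only
        photometric="minisblack",
    )
    return path


def read_grid(path: str | Path) -> Grid:
    """Read a single-band georeferenced raster.

    Raises :class:`GridFormatError` for unreadable files and multi-band input.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such file: {path}")
    if path.suffix.lower() == ".asc":
        return _read_ascii_grid(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = tf.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except Exception as exc:  # noqa: BLE001 - any parse failure is a format error
        raise GridFormatError(f"cannot read raster {path}: {exc}") from exc
    if values.ndim == 3:
        if values.shape[0] == 1:
            values = values[0]
        elif values.shape[-1] == 1:
            values = values[..., 0]
        else:
            raise GridFormatError(f"{path} is multi-band; only single-band rasters are supported")
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a 2-D single-band raster")

    scale = tags.get(_TAG_MODEL_PIXEL_SCALE, (1.0, 1.0, 0.0))
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT, (0.0, 0.0, 0.0, 0.0, float(values.shape[0]), 0.0))
    nodata_raw = tags.get(_TAG_GDAL_NODATA, str(DEFAULT_NODATA))
    nodata = float(nodata_raw)
    crs_label, units, code_table = "unknown", "", None
    desc = tags.get(270)  # ImageDescription
    if desc:
        try:
            meta = json.loads(desc)
            crs_label = meta.get("crs_label", crs_label)
            units = meta.get("units", units)
            if "code_table" in meta:
                code_table = {int(k): v for k, v in meta["code_table"].items()}
        except (json.JSONDecodeError, AttributeError, TypeError):
            pass
    transform = Transform(x0=float(tiepoint[3]), y0=float(tiepoint[4]), dx=float(scale[0]), dy=float(scale[1]))
    return Grid(values=values, transform=transform, crs_label=crs_label, nodata=nodata, units=units, code_table=code_table)


def _write_ascii_grid(grid: Grid, path: Path) -> Path:
    t = grid.transform
    if t.dx != t.dy:
        raise GridFormatError("ESRI ASCII grids require square cells")
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {t.x0!r}\n"
        f"yllcorner {t.y0 - nrows * t.dy!r}\ncellsize {t.dx!r}\nNODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.17g")
    return path


def _read_ascii_grid(path: Path) -> Grid:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    try:
        ncols, nrows = int(meta["ncols"]), int(meta["nrows"])
        cell = meta["cellsize"]
        values = np.loadtxt(lines[n_header:]).reshape(nrows, ncols)
        transform = Transform(
            x0=meta["xllcorner"], y0=meta["yllcorner"] + nrows * cell, dx=cell, dy=cell
        )
    except (KeyError, ValueError) as exc:
        raise GridFormatError(f"cannot parse ASCII grid {path}: {exc}") from exc
    return Grid(values=values, transform=transform, nodata=meta.get("nodata_value", DEFAULT_NODATA))


# ---------------------------------------------------------------------------
# occurrence and code-table I/O


def read_occurrences(path: str | Path, role: str, scenario: str = "current") -> OccurrenceSet:
    """Read a delimited `x,y,taxon` table of presence points.

    Rows with missing or non-numeric coordinates are dropped and counted;
    duplicate (x, y, taxon) rows collapse to one.  Raises ``ValueError`` if no
    rows survive.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"x", "y", "taxon"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table {path} lacks columns {sorted(missing)}")
    n_raw = len(df)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    df = df.dropna(subset=["x", "y"])
    df = df.drop_duplicates(subset=["x", "y", "taxon"]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no valid occurrence rows in {path}")
    return OccurrenceSet(
        points=df[["x", "y", "taxon"]],
        role=role,
        scenario=scenario,
        n_dropped=n_raw - len(df),
    )


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> Path:
    path = Path(path)
    occ.points[["x", "y", "taxon"]].to_csv(path, index=False)
    return path


def read_code_table(path: str | Path) -> dict[int, str]:
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_code_table(table: Mapping[int, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in table.items()}, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# alignment gate


def align_check(stacks: Iterable[GridStack]) -> tuple[bool, list[str]]:
    """True iff every grid across all stacks shares shape and transform.

    Returns ``(ok, diffs)`` where ``diffs`` names each offending layer.
    Used as a gate by every pipeline stage that consumes multiple rasters.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("need at least one stack")
    ref: Grid | None = None
    ref_name = ""
    diffs: list[str] = []
    for si, stack in enumerate(stacks):
        for name, g in stack.layers.items():
            if ref is None:
                ref, ref_name = g, f"stack[{si}].{name}"
                continue
            if g.shape != ref.shape:
                diffs.append(f"stack[{si}].{name}: shape {g.shape} != {ref.shape} of {ref_name}")
            elif g.transform != ref.transform:
                diffs.append(
                    f"stack[{si}].{name}: transform {g.transform} != {ref.transform} of {ref_name}"
                )
    return (len(diffs) == 0, diffs)
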
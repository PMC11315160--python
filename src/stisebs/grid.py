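"""Gridded time-series containers and raster I/O.

The segmentation pipeline works on three views of the same scene:

* :class:`TimeSeriesGrid` — a ``(height, width, periods)`` cube of index
  values (e.g. NDVI) with a validity mask and georeferencing,
* :class:`LabelGrid` — an integer segment map over the same grid
  (cluster / patch / superpixel / land-cover), nodata label ``-1``,
* :class:`PixelMatrix` — the flat ``(valid pixels, features)`` matrix fed
  to PCA and k-means, with a bidirectional pixel index.

Raster I/O uses multi-band TIFF (one band per period, GeoTIFF
pixel-scale/tiepoint tags where the transform is axis aligned, full
metadata as a JSON image description) and NetCDF cubes with dimensions
``(time, y, x)`` through xarray's scipy backend.  Grid indexing is
0-based ``(row, col)``, row-major; the affine transform follows the
standard raster convention (pixel-corner anchored)::

    x = c + a * col + b * row
    y = f + d * col + e * row
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GridGeometry",
    "TimeSeriesGrid",
    "LabelGrid",
    "PixelMatrix",
    "flatten",
    "unflatten",
    "read_stack",
    "write_stack",
    "read_label_raster",
    "write_label_raster",
]

_TAG_PIXEL_SCALE = 33550  # GeoTIFF ModelPixelScaleTag
_TAG_TIEPOINT = 33922  # GeoTIFF ModelTiepointTag

LABEL_KINDS = ("cluster", "patch", "superpixel", "landcover")


@dataclass(frozen=True)
class GridGeometry:
    """Shape plus georeferencing of a raster grid.

    ``transform`` is the 6-tuple ``(a, b, c, d, e, f)`` mapping
    (col, row) of a pixel's upper-left corner to world (x, y).  ``crs``
    is carried as an opaque string (e.g. an EPSG code); the algorithm
    itself never interprets it.
    """

    height: int
    width: int
    transform: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs: str = ""
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("grid must be at least 1x1")
        t = tuple(float(v) for v in self.transform)
        if len(t) != 6:
            raise ValueError("transform must have 6 coefficients")
        if abs(t[0] * t[4] - t[1] * t[3]) == 0.0:
            raise ValueError("transform is singular (zero pixel size)")
        object.__setattr__(self, "transform", t)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_to_xy(self, row, col):
        """World coordinates of the (row, col) pixel corner."""
        a, b, c, d, e, f = self.transform
        return (c + a * col + b * row, f + d * col + e * row)

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "width": self.width,
            "transform": list(self.transform),
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            height=int(d["height"]),
            width=int(d["width"]),
            transform=tuple(d.get("transform", (1, 0, 0, 0, -1, 0))),
            crs=d.get("crs", ""),
        )


@dataclass
class TimeSeriesGrid:
    """A ``(height, width, T)`` cube of index values with validity mask.

    Values at masked pixels are NaN and never enter downstream
    computation.  NaNs *inside* a valid pixel's series mark gaps still
    to be filled; after preprocessing every valid series is complete and
    lies in [-1, 1].
    """

    geometry: GridGeometry
    times: list[str]
    values: np.ndarray  # (H, W, T) float
    valid_mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (height, width, periods)")
        h, w, t = self.values.shape
        if (h, w) != self.geometry.shape:
            raise ValueError("values shape disagrees with geometry")
        if t < 1 or len(self.times) != t:
            raise ValueError("times must have one entry per period")
        self.times = [str(x) for x in self.times]
        # ISO-8601 date strings must be strictly increasing; bare period
        # indices (the graceful fallback when dates are unknown) need not
        # sort lexicographically and are left alone.
        if all("-" in s for s in self.times):
            if any(a >= b for a, b in zip(self.times, self.times[1:])):
                raise ValueError("times must be strictly increasing")
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (h, w):
            raise ValueError("valid_mask shape disagrees with values")

    @property
    def n_periods(self) -> int:
        return self.values.shape[2]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def with_values(self, values: np.ndarray, valid_mask=None) -> "TimeSeriesGrid":
        """Same grid carrying new values (and optionally a new mask)."""
        mask = self.valid_mask if valid_mask is None else valid_mask
        return TimeSeriesGrid(self.geometry, list(self.times), values, mask.copy())

    def masked_values(self) -> np.ndarray:
        """Values with NaN outside the validity mask."""
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out

    @staticmethod
    def default_times(n: int) -> list[str]:
        return [str(i) for i in range(n)]


@dataclass
class LabelGrid:
    """Integer segment labels over a grid; -1 marks masked pixels."""

    geometry: GridGeometry
    labels: np.ndarray  # (H, W) int32
    kind: str = "superpixel"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("labels shape disagrees with geometry")
        if self.kind not in LABEL_KINDS:
            raise ValueError(f"kind must be one of {LABEL_KINDS}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def n_labels(self) -> int:
        m = self.valid_mask
        return int(self.labels[m].max()) + 1 if m.any() else 0

    def compact(self) -> "LabelGrid":
        """Relabel to consecutive 0..n-1 in row-major first-appearance order."""
        labels = self.labels.ravel()
        out = np.full(labels.shape, -1, dtype=np.int32)
        valid = labels >= 0
        # np.unique returns first occurrence indices; order by them.
        uniq, first = np.unique(labels[valid], return_index=True)
        order = np.argsort(first, kind="stable")
        remap = np.empty(uniq.max() + 1 if uniq.size else 0, dtype=np.int32)
        remap[uniq[order]] = np.arange(uniq.size, dtype=np.int32)
        out[valid] = remap[labels[valid]]
        return LabelGrid(self.geometry, out.reshape(self.labels.shape), self.kind)


@dataclass
class PixelMatrix:
    """Flat (valid pixels x features) view of a grid, row-major ordinals."""

    data: np.ndarray  # (I, F)
    pixel_index: np.ndarray  # (I, 2) int, (row, col) per ordinal
    geometry: GridGeometry
    valid_mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def flatten(grid: TimeSeriesGrid) -> PixelMatrix:
    """Stack valid pixels into an (I, T) matrix in row-major order."""
    mask = grid.valid_mask
    if not mask.any():
        raise ValueError("grid has zero valid pixels")
    rows, cols = np.nonzero(mask)  # nonzero scans row-major
    data = grid.values[rows, cols, :]
    index = np.column_stack([rows, cols]).astype(np.int64)
    return PixelMatrix(data, index, grid.geometry, mask.copy())


def unflatten(matrix: PixelMatrix, times: list[str] | None = None) -> TimeSeriesGrid:
    """Inverse of :func:`flatten`; masked pixels come back as NaN."""
    h, w = matrix.geometry.shape
    t = matrix.n_features
    values = np.full((h, w, t), np.nan)
    values[matrix.pixel_index[:, 0], matrix.pixel_index[:, 1], :] = matrix.data
    mask = np.zeros((h, w), dtype=bool)
    mask[matrix.pixel_index[:, 0], matrix.pixel_index[:, 1]] = True
    if times is None:
        times = TimeSeriesGrid.default_times(t)
    return TimeSeriesGrid(matrix.geometry, times, values, mask)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def _geo_extratags(geom: GridGeometry, description: str):
    """GeoTIFF pixel-scale/tiepoint tags for axis-aligned transforms."""
    a, b, c, d, e, f = geom.transform
    tags = [(270, "s", 0, description, True)]
    if b == 0.0 and d == 0.0:
        tags.append((_TAG_PIXEL_SCALE, "d", 3, (abs(a), abs(e), 0.0), True))
        tags.append((_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0), True))
    return tags


def write_stack(grid: TimeSeriesGrid, path) -> Path:
    """Write a time-series cube as multi-band TIFF (.tif) or NetCDF (.nc)."""
    path = Path(path)
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        return _write_stack_netcdf(grid, path)
    import tifffile

    data = np.moveaxis(grid.masked_values(), 2, 0)  # (T, H, W)
    meta = {
        "stisebs": {
            "geometry": grid.geometry.to_dict(),
            "times": grid.times,
            "kind": "stack",
        }
    }
    desc = json.dumps(meta)
    tifffile.imwrite(
        path,
        data.astype(np.float64),
        photometric="minisblack",
        extratags=_geo_extratags(grid.geometry, desc),
        metadata=None,
    )
    return path


def read_stack(path, dates=None, nodata: float | None = None) -> TimeSeriesGrid:
    """Read a multi-band TIFF or a NetCDF ``(time, y, x)`` cube.

    Parameters
    ----------
    dates
        Optional override for band dates: a sequence of ISO strings or a
        path to a one-date-per-line CSV of length T.
    nodata
        Sentinel marking invalid cells in files without NaN support.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        grid = _read_stack_netcdf(path)
    else:
        grid = _read_stack_tiff(path, nodata)
    if dates is not None:
        times = _load_dates(dates)
        if len(times) != grid.n_periods:
            raise ValueError(
                f"{len(times)} dates supplied for {grid.n_periods} bands"
            )
        grid.times = times
    return grid


def _load_dates(dates) -> list[str]:
    if isinstance(dates, (str, Path)):
        lines = Path(dates).read_text().strip().splitlines()
        return [ln.strip() for ln in lines if ln.strip()]
    return [str(d) for d in dates]


def _read_stack_tiff(path: Path, nodata) -> TimeSeriesGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description or ""
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"cannot interpret {path} as a (band, y, x) stack")
    meta = _parse_meta(desc)
    values = np.moveaxis(data, 0, 2)  # (H, W, T)
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    h, w, t = values.shape
    if meta is not None:
        geom = GridGeometry.from_dict(meta["geometry"])
        times = list(meta.get("times") or TimeSeriesGrid.default_times(t))
        if len(times) != t:
            raise ValueError("band count disagrees with stored dates")
    else:
        geom = GridGeometry(height=h, width=w)
        times = TimeSeriesGrid.default_times(t)
    mask = np.all(np.isfinite(values), axis=2)
    return TimeSeriesGrid(geom, times, values, mask)


def _parse_meta(desc: str):
    try:
        d = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return None
    return d.get("stisebs") if isinstance(d, dict) else None


def _write_stack_netcdf(grid: TimeSeriesGrid, path: Path) -> Path:
    import xarray as xr

    t = grid.n_periods
    ds = xr.Dataset(
        {"values": (("time", "y", "x"), np.moveaxis(grid.masked_values(), 2, 0))},
        coords={"time": np.arange(t)},
        attrs={
            "stisebs_geometry": json.dumps(grid.geometry.to_dict()),
            "stisebs_times": json.dumps(grid.times),
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def _read_stack_netcdf(path: Path) -> TimeSeriesGrid:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        name = "values" if "values" in ds else list(ds.data_vars)[0]
        da = ds[name]
        dims = list(da.dims)
        if len(dims) != 3:
            raise ValueError("NetCDF variable is not a (time, y, x) cube")
        # Accept any naming as long as time is the leading dimension.
        data = np.asarray(da.values, dtype=float)
        values = np.moveaxis(data, 0, 2)
        h, w, t = values.shape
        if "stisebs_geometry" in ds.attrs:
            geom = GridGeometry.from_dict(json.loads(ds.attrs["stisebs_geometry"]))
        else:
            geom = GridGeometry(height=h, width=w)
        if "stisebs_times" in ds.attrs:
            times = json.loads(ds.attrs["stisebs_times"])
        else:
            times = TimeSeriesGrid.default_times(t)
    mask = np.all(np.isfinite(values), axis=2)
    return TimeSeriesGrid(geom, times, values, mask)


def write_label_raster(lg: LabelGrid, path) -> Path:
    """Write a label map as a single-band int32 TIFF, nodata -1."""
    import tifffile

    path = Path(path)
    meta = {
        "stisebs": {
            "geometry": lg.geometry.to_dict(),
            "kind": lg.kind,
            "nodata": -1,
        }
    }
    tifffile.imwrite(
        path,
        lg.labels.astype(np.int32),
        photometric="minisblack",
        extratags=_geo_extratags(lg.geometry, json.dumps(meta)),
        metadata=None,
    )
    return path


def read_label_raster(path, kind: str | None = None) -> LabelGrid:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray().astype(np.int32)
        desc = tf.pages[0].description or ""
    if labels.ndim != 2:
        raise ValueError(f"{path} is not a single-band raster")
    meta = _parse_meta(desc)
    if meta is not None:
        geom = GridGeometry.from_dict(meta["geometry"])
        kind = kind or meta.get("kind", "superpixel")
    else:
        geom = GridGeometry(height=labels.shape[0], width=labels.shape[1])
        kind = kind or "superpixel"
    return LabelGrid(geom, labels, kind)


def read_mask(path) -> np.ndarray:
    """Read a validity mask raster: nonzero = valid."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError("mask raster must be single band")
    return arr != 0
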
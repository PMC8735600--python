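"""Georeferenced raster/vector primitives shared by the whole pipeline.

All geometry lives in a projected CRS with planar Euclidean coordinates in
meters (a UTM-like local projection is assumed; geographic lat/lon handling
is out of scope).  Raster convention: row 0 is the northernmost row, indices
are 0-based, and cells are center-registered — the center of cell
``(row, col)`` sits at ``origin + ((col + 0.5) * px, -(row + 0.5) * px)``.
Missing raster values are encoded as NaN in float arrays, a sentinel
distinct from 0.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import LineString, mapping, shape

__all__ = [
    "BANDS",
    "SENSORS",
    "Grid",
    "Scene",
    "CoastlineSegmentSet",
    "DistanceField",
    "BinaryCanopyMap",
    "segment_coastline",
    "coast_distance",
    "assign_to_segments",
    "resample_mean",
    "read_scene",
    "write_scene",
    "read_raster",
    "write_raster",
    "read_coastline_geojson",
    "write_coastline_geojson",
]

#: Surface-reflectance band order used everywhere in the package.
BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")

#: Supported sensor identifiers (Thematic Mapper, Enhanced TM+, OLI).
SENSORS = ("TM", "ETMP", "OLI")

#: Reflectance is stored on disk as int16 scaled by this factor.
REFLECTANCE_SCALE = 1e-4


class GeometryError(ValueError):
    """Raised for degenerate or mismatched geometry inputs."""


@dataclass(frozen=True)
class Grid:
    """A north-up, square-cell raster grid in a projected CRS.

    Parameters
    ----------
    n_rows, n_cols
        Raster shape; both at least 1.
    origin_x, origin_y
        Projected coordinates (meters) of the *top-left corner* of pixel
        (0, 0).
    pixel_size
        Cell edge length in meters (30 for Landsat-style scenes, 10 for the
        consensus grid).
    crs_id
        Free-text identifier of the projected CRS; grids only interoperate
        when their identifiers match.
    """

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    pixel_size: float
    crs_id: str = "local-utm"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.pixel_size,
            self.origin_y - (row + 0.5) * self.pixel_size,
        )

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "crs_id": self.crs_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(**d)


@dataclass
class Scene:
    """One multispectral surface-reflectance acquisition.

    ``reflectance`` is a ``(6, n_rows, n_cols)`` float array in ``BANDS``
    order, unitless surface reflectance (atmospheric correction can push
    values slightly negative; valid range is about [-0.05, 1.2]).
    """

    grid: Grid
    reflectance: np.ndarray
    land_mask: np.ndarray
    cloud_mask: np.ndarray
    sensor: str
    acquired_at: _dt.datetime
    tide_height: float | None = None

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}; expected one of {SENSORS}")
        shp = self.grid.shape
        if self.reflectance.shape != (len(BANDS),) + shp:
            raise GeometryError(
                f"reflectance shape {self.reflectance.shape} does not match grid {shp}"
            )
        for name in ("land_mask", "cloud_mask"):
            m = getattr(self, name)
            if m.shape != shp:
                raise GeometryError(f"{name} shape {m.shape} does not match grid {shp}")
            setattr(self, name, m.astype(bool))
        if self.acquired_at is None:
            raise ValueError("acquired_at is required")

    def band(self, name: str) -> np.ndarray:
        return self.reflectance[BANDS.index(name)]

    @property
    def ocean_mask(self) -> np.ndarray:
        """Valid ocean pixels: neither land nor cloud."""
        return ~(self.land_mask | self.cloud_mask)

    def ndvi(self) -> np.ndarray:
        nir, red = self.band("nir"), self.band("red")
        denom = nir + red
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom != 0, (nir - red) / denom, 0.0)
        return out


@dataclass
class CoastlineSegmentSet:
    """An ordered coastline polyline partitioned into ~1 km arclength segments.

    ``segments`` maps consecutive integer ids (starting at 0) to vertex
    sub-arrays; cut points are interpolated so segment arclengths sum exactly
    to the polyline length.
    """

    polyline: np.ndarray  # (N, 2) projected meters
    segments: list[tuple[int, np.ndarray, float]]  # (id, vertices, arclength)
    segment_length_target: float = 1000.0
    crs_id: str = "local-utm"

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_linestrings(self) -> list[LineString]:
        return [LineString(v) for _, v, _ in self.segments]

    def total_length(self) -> float:
        return float(sum(length for _, _, length in self.segments))


@dataclass
class DistanceField:
    """Per-cell Euclidean distance (meters) from cell center to the coastline."""

    grid: Grid
    distance: np.ndarray

    def __post_init__(self) -> None:
        if self.distance.shape != self.grid.shape:
            raise GeometryError("distance raster shape does not match grid")
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class BinaryCanopyMap:
    """Presence/absence kelp canopy raster: 0, 1, or NaN (missing).

    ``provenance`` records which classification branch produced the map:
    ``expert`` (manual labels), ``dtm`` (decision tree + spectral unmixing),
    or ``consensus`` (citizen-science votes).
    """

    grid: Grid
    presence: np.ndarray
    provenance: str
    acquired_at: _dt.datetime | None = None
    interval: str | None = None
    sensor: str | None = None

    def __post_init__(self) -> None:
        if self.presence.shape != self.grid.shape:
            raise GeometryError("presence raster shape does not match grid")
        self.presence = np.asarray(self.presence, dtype=float)
        valid = self.presence[~np.isnan(self.presence)]
        if valid.size and not np.all(np.isin(valid, (0.0, 1.0))):
            raise ValueError("presence values must be 0, 1, or NaN")
        if self.provenance not in ("expert", "dtm", "consensus", "truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def kelp_pixel_count(self) -> int:
        return int(np.nansum(self.presence))


# ---------------------------------------------------------------------------
# coastline segmentation


def _polyline_lengths(vertices: np.ndarray) -> np.ndarray:
    d = np.diff(vertices, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def segment_coastline(
    polyline: np.ndarray | Sequence[Sequence[float]],
    target_length: float = 1000.0,
    crs_id: str = "local-utm",
) -> CoastlineSegmentSet:
    """Partition a coastline polyline into consecutive arclength segments.

    Walks the polyline accumulating arclength and cuts at every multiple of
    ``target_length``, inserting interpolated vertices at the cut points, so
    every segment except possibly the last has exactly the target arclength.

    Raises
    ------
    GeometryError
        If the polyline is degenerate (fewer than 2 vertices, or zero
        total length).
    """
    verts = np.asarray(polyline, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 2 or verts.shape[1] != 2:
        raise GeometryError("polyline must be an (N>=2, 2) vertex array")
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    seg_len = _polyline_lengths(verts)
    total = float(seg_len.sum())
    if total == 0.0:
        raise GeometryError("degenerate polyline: all vertices identical")

    segments: list[tuple[int, np.ndarray, float]] = []
    current: list[np.ndarray] = [verts[0]]
    acc = 0.0  # arclength within the current segment
    sid = 0
    for i in range(len(seg_len)):
        a, b = verts[i], verts[i + 1]
        edge = seg_len[i]
        consumed = 0.0
        # cut this edge as many times as segment boundaries fall inside it
        while acc + (edge - consumed) >= target_length - 1e-12:
            need = target_length - acc
            t = (consumed + need) / edge
            cut = a + t * (b - a)
            current.append(cut)
            segments.append((sid, np.array(current), target_length))
            sid += 1
            current = [cut]
            consumed += need
            acc = 0.0
        remainder = edge - consumed
        if remainder > 1e-12:
            current.append(b)
            acc += remainder
    if acc > 1e-9:
        segments.append((sid, np.array(current), acc))
    # renormalize stored lengths so they sum exactly to the polyline length
    stored = sum(s[2] for s in segments)
    if not np.isclose(stored, total, rtol=1e-6):  # pragma: no cover - defensive
        raise AssertionError("segment arclengths do not conserve polyline length")
    return CoastlineSegmentSet(
        polyline=verts,
        segments=segments,
        segment_length_target=float(target_length),
        crs_id=crs_id,
    )


def coast_distance(grid: Grid, coastline: CoastlineSegmentSet) -> DistanceField:
    """Euclidean distance from every cell center to the nearest point on the
    coastline polyline (edges, not just vertices)."""
    if grid.crs_id != coastline.crs_id:
        raise GeometryError(
            f"CRS mismatch: grid {grid.crs_id!r} vs coastline {coastline.crs_id!r}"
        )
    line = LineString(coastline.polyline)
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(pts, line).reshape(grid.shape)
    return DistanceField(grid=grid, distance=dist)


def assign_to_segments(
    pixels: np.ndarray | Sequence[Sequence[float]],
    coastline: CoastlineSegmentSet,
) -> np.ndarray:
    """Assign each (x, y) point to the nearest 1 km coastline segment.

    Distance is measured to the segment's full polyline portion; ties are
    broken by the lower segment id.
    """
    pts = np.asarray(pixels, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 2:
        raise ValueError("pixels must be a non-empty (N, 2) array of coordinates")
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    best = np.full(len(pts), -1, dtype=int)
    best_d = np.full(len(pts), np.inf)
    for sid, verts, _ in coastline.segments:
        d = shapely.distance(geoms, LineString(verts))
        better = d < best_d - 1e-9  # strict improvement keeps the lower id on ties
        best[better] = sid
        best_d[better] = d[better]
    return best


def resample_mean(src: np.ndarray, src_grid: Grid, dst_grid: Grid) -> np.ndarray:
    """Block-mean resample a fine raster onto a coarser aligned grid.

    The destination cell size must be an integer multiple of the source size
    and the two origins must coincide (nested grids).  Each destination cell
    is the mean of its covered source cells ignoring NaN; it is NaN only when
    every covered source cell is NaN.
    """
    ratio = dst_grid.pixel_size / src_grid.pixel_size
    k = int(round(ratio))
    if not np.isclose(ratio, k) or k < 1:
        raise GeometryError(
            f"destination cell size must be an integer multiple of source "
            f"({dst_grid.pixel_size} vs {src_grid.pixel_size})"
        )
    if not (
        np.isclose(src_grid.origin_x, dst_grid.origin_x)
        and np.isclose(src_grid.origin_y, dst_grid.origin_y)
    ):
        raise GeometryError("grids must share an origin for nested resampling")
    if src.shape != src_grid.shape:
        raise GeometryError("source raster shape does not match its grid")
    if src_grid.n_rows != dst_grid.n_rows * k or src_grid.n_cols != dst_grid.n_cols * k:
        raise GeometryError("source grid does not nest exactly into destination grid")
    blocks = np.asarray(src, dtype=float).reshape(
        dst_grid.n_rows, k, dst_grid.n_cols, k
    ).transpose(0, 2, 1, 3).reshape(dst_grid.n_rows, dst_grid.n_cols, k * k)
    # all-NaN blocks legitimately yield NaN (missing destination cell)
    count = np.sum(~np.isnan(blocks), axis=-1)
    total = np.nansum(blocks, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0, total / count, np.nan)
    return out


# ---------------------------------------------------------------------------
# raster / vector I/O


def write_raster(raster: np.ndarray, grid: Grid, path: str | Path, *,
                 dtype: str | None = None, scale: float | None = None) -> None:
    """Write a single raster to TIFF with a ``.geo.json`` georeferencing sidecar.

    Float reflectance-like data may be stored integer-scaled (``dtype='int16'``,
    ``scale=1e-4``); NaN then round-trips through the reserved value -32768.
    """
    path = Path(path)
    arr = np.asarray(raster)
    meta = grid.to_dict()
    if scale is not None:
        meta["scale"] = scale
        q = np.round(arr / scale)
        q = np.where(np.isnan(arr), -32768, q)
        arr = q.astype(dtype or "int16")
    elif dtype is not None:
        arr = arr.astype(dtype)
    tifffile.imwrite(path, arr)
    path.with_suffix(path.suffix + ".geo.json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid]:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".geo.json").read_text())
    scale = meta.pop("scale", None)
    grid = Grid.from_dict(meta)
    if scale is not None:
        out = arr.astype(float) * scale
        out[arr == -32768] = np.nan
        arr = out
    return arr, grid


def write_scene(scene: Scene, directory: str | Path) -> None:
    """Write a scene as per-band int16 TIFFs (scale 1e-4), uint8 masks, and a
    metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, band in enumerate(BANDS):
        write_raster(scene.reflectance[i], scene.grid,
                     directory / f"{band}.tif", dtype="int16", scale=REFLECTANCE_SCALE)
    write_raster(scene.land_mask.astype(np.uint8), scene.grid,
                 directory / "land_mask.tif", dtype="uint8")
    write_raster(scene.cloud_mask.astype(np.uint8), scene.grid,
                 directory / "cloud_mask.tif", dtype="uint8")
    meta = {
        "sensor": scene.sensor,
        "acquired_at": scene.acquired_at.isoformat(),
        "tide_height": scene.tide_height,
    }
    (directory / "scene.json").write_text(json.dumps(meta))


def read_scene(directory: str | Path) -> Scene:
    directory = Path(directory)
    meta = json.loads((directory / "scene.json").read_text())
    if meta["sensor"] not in SENSORS:
        raise ValueError(f"unknown sensor {meta['sensor']!r}")
    bands = []
    grid = None
    for band in BANDS:
        arr, g = read_raster(directory / f"{band}.tif")
        if grid is None:
            grid = g
        elif g != grid:
            raise GeometryError(f"band {band} grid differs from the first band")
        bands.append(arr)
    land, g_land = read_raster(directory / "land_mask.tif")
    cloud, g_cloud = read_raster(directory / "cloud_mask.tif")
    if g_land != grid or g_cloud != grid:
        raise GeometryError("mask grids differ from band grids")
    return Scene(
        grid=grid,
        reflectance=np.stack(bands),
        land_mask=land.astype(bool),
        cloud_mask=cloud.astype(bool),
        sensor=meta["sensor"],
        acquired_at=_dt.datetime.fromisoformat(meta["acquired_at"]),
        tide_height=meta.get("tide_height"),
    )


def write_coastline_geojson(coastline: CoastlineSegmentSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"segment_id": sid, "arclength_m": length},
            "geometry": mapping(LineString(verts)),
        }
        for sid, verts, length in coastline.segments
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "crs_id": coastline.crs_id,
            "segment_length_target": coastline.segment_length_target,
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_coastline_geojson(path: str | Path) -> CoastlineSegmentSet:
    doc = json.loads(Path(path).read_text())
    segments = []
    all_vertices: list[np.ndarray] = []
    for feat in sorted(doc["features"], key=lambda f: f["properties"]["segment_id"]):
        geom = shape(feat["geometry"])
        verts = np.asarray(geom.coords, dtype=float)
        sid = int(feat["properties"]["segment_id"])
        segments.append((sid, verts, float(feat["properties"]["arclength_m"])))
        all_vertices.append(verts if not all_vertices else verts[1:])
    polyline = np.vstack(all_vertices)
    props = doc.get("properties", {})
    return CoastlineSegmentSet(
        polyline=polyline,
        segments=segments,
        segment_length_target=float(props.get("segment_length_target", 1000.0)),
        crs_id=props.get("crs_id", "local-utm"),
    )
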
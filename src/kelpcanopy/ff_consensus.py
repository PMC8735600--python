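"""Citizen-science consensus classification of kelp canopy.

Each satellite scene is cut into ~2.25 km^2 tiles, and every tile is shown
to 15 independent unskilled annotators who outline kelp beds as polygons.
This module turns those per-user polygons into 10 m vote-count rasters,
applies a consensus threshold (a pixel is kelp when at least tau of the 15
users marked it; tau = 8 by default), removes votes on land or far from the
coast, resamples to the 30 m analysis grid, builds seasonal/annual
composites, and — given expert-labeled scenes — selects tau by maximizing
the Matthews Correlation Coefficient (MCC), a binary agreement score that
is robust to the extreme class imbalance of sparse kelp canopy.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .geo_core import (
    BinaryCanopyMap,
    DistanceField,
    GeometryError,
    Grid,
    resample_mean,
)
from .timeseries_util import interval_label

__all__ = [
    "AnnotationSet",
    "ConsensusRaster",
    "DEFAULT_CONSENSUS_TAU",
    "rasterize_votes",
    "threshold_consensus",
    "clean_consensus",
    "CompositeResult",
    "composite_consensus",
    "matthews_correlation",
    "optimize_threshold",
]

DEFAULT_CONSENSUS_TAU = 8
DEFAULT_N_USERS = 15


@dataclass
class AnnotationSet:
    """Per-user kelp polygons per tile.

    ``records`` holds ``(tile_id, user_id, polygon)`` tuples with polygons in
    projected meters; ``tile_index`` maps tile_id to ``(xmin, ymin, xmax,
    ymax)`` bounds.  Tiles excluded during curation (e.g. one dominated by
    drifting debris) are listed explicitly in ``excluded_tiles``.
    """

    records: list[tuple[int, int, shapely.Geometry]]
    tile_index: dict[int, tuple[float, float, float, float]]
    n_users_per_tile: int = DEFAULT_N_USERS
    excluded_tiles: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.n_users_per_tile < 1:
            raise ValueError("need at least one annotator per tile")

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"tile_id": t, "user_id": u},
                "geometry": mapping(p),
            }
            for t, u, p in self.records
        ]
        doc = {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {
                "tile_index": {str(k): list(v) for k, v in self.tile_index.items()},
                "n_users_per_tile": self.n_users_per_tile,
                "excluded_tiles": sorted(self.excluded_tiles),
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AnnotationSet":
        doc = json.loads(Path(path).read_text())
        records = [
            (f["properties"]["tile_id"], f["properties"]["user_id"],
             shape(f["geometry"]))
            for f in doc["features"]
        ]
        props = doc.get("properties", {})
        return cls(
            records=records,
            tile_index={int(k): tuple(v) for k, v in props.get("tile_index", {}).items()},
            n_users_per_tile=props.get("n_users_per_tile", DEFAULT_N_USERS),
            excluded_tiles=set(props.get("excluded_tiles", [])),
        )


@dataclass
class ConsensusRaster:
    """Summed per-pixel annotation counts on the 10 m grid."""

    grid: Grid
    votes: np.ndarray
    n_users: int = DEFAULT_N_USERS
    acquired_at: object | None = None

    def __post_init__(self) -> None:
        if self.votes.shape != self.grid.shape:
            raise GeometryError("votes raster shape does not match grid")
        self.votes = np.asarray(self.votes, dtype=int)
        if self.votes.min() < 0 or self.votes.max() > self.n_users:
            raise ValueError("votes must lie in [0, n_users]")


def rasterize_votes(annotations: AnnotationSet, grid: Grid,
                    acquired_at=None) -> ConsensusRaster:
    """Sum per-user kelp classifications onto 10 m cells.

    A cell receives one vote from a user when the union of that user's
    polygons on the tile covers the cell center; overlapping polygons from
    the same user therefore never double-count.  Polygons outside every tile
    are skipped with a warning; polygons from curated-out tiles are dropped
    silently.
    """
    votes = np.zeros(grid.shape, dtype=int)
    px = grid.pixel_size
    # accumulate per-user boolean coverage (union over that user's polygons,
    # including jitter spilling across tile borders), then sum over users
    marked: dict[int, np.ndarray] = {}
    for tile_id, user_id, poly in annotations.records:
        if tile_id in annotations.excluded_tiles:
            continue
        bounds = annotations.tile_index.get(tile_id)
        if bounds is None or shapely.box(*bounds).disjoint(poly):
            warnings.warn(f"polygon for tile {tile_id} falls outside its tile; skipped")
            continue
        xmin, ymin, xmax, ymax = poly.bounds
        c0 = max(0, int(math.floor((xmin - grid.origin_x) / px - 0.5)))
        c1 = min(grid.n_cols - 1, int(math.ceil((xmax - grid.origin_x) / px)))
        r0 = max(0, int(math.floor((grid.origin_y - ymax) / px - 0.5)))
        r1 = min(grid.n_rows - 1, int(math.ceil((grid.origin_y - ymin) / px)))
        if c1 < c0 or r1 < r0:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        X, Y = np.meshgrid(grid.origin_x + (cols + 0.5) * px,
                           grid.origin_y - (rows + 0.5) * px)
        inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
        if not inside.any():
            continue
        cover = marked.setdefault(user_id, np.zeros(grid.shape, dtype=bool))
        cover[r0:r1 + 1, c0:c1 + 1] |= inside
    for cover in marked.values():
        votes += cover
    return ConsensusRaster(grid=grid, votes=votes,
                           n_users=annotations.n_users_per_tile,
                           acquired_at=acquired_at)


def threshold_consensus(votes: ConsensusRaster, tau: int = DEFAULT_CONSENSUS_TAU
                        ) -> BinaryCanopyMap:
    """Binarize vote counts at consensus level ``tau`` (inclusive: votes >= tau)."""
    if not 1 <= tau <= votes.n_users:
        raise ValueError(f"tau must be in [1, {votes.n_users}], got {tau}")
    presence = (votes.votes >= tau).astype(float)
    return BinaryCanopyMap(grid=votes.grid, presence=presence,
                           provenance="consensus", acquired_at=votes.acquired_at)


def clean_consensus(binary: BinaryCanopyMap, distance: DistanceField,
                    land_mask: np.ndarray, d_max: float = 4500.0
                    ) -> BinaryCanopyMap:
    """Discard consensus classifications on land or beyond ``d_max`` from shore.

    Unlike the spectral branch, nearshore (< 120 m) classifications are
    retained — human annotators use spatial context that makes them reliable
    where per-pixel spectra are not.
    """
    if distance.grid != binary.grid:
        raise GeometryError("distance field grid does not match canopy map grid")
    if land_mask.shape != binary.grid.shape:
        raise GeometryError("land mask shape does not match canopy map grid")
    presence = binary.presence.copy()
    drop = land_mask.astype(bool) | (distance.distance > d_max)
    presence[drop & (presence == 1)] = 0.0
    presence[land_mask.astype(bool)] = np.nan
    return BinaryCanopyMap(grid=binary.grid, presence=presence,
                           provenance=binary.provenance,
                           acquired_at=binary.acquired_at,
                           interval=binary.interval, sensor=binary.sensor)


@dataclass
class CompositeResult:
    """One interval's consensus composite on the 30 m grid.

    ``mean`` is the per-pixel temporal mean presence over the dates the
    pixel was observed (a pixel present in one of two scenes has value
    0.5); ``presence`` binarizes it at > 0 for map-to-map comparison;
    ``completeness`` is the fraction of applicable pixels observed at
    least once in the interval.
    """

    interval: str
    mean: np.ndarray
    presence: BinaryCanopyMap
    completeness: float


def composite_consensus(
    maps: list[BinaryCanopyMap],
    grid30: Grid,
    interval: str = "annual",
    applicable_mask: np.ndarray | None = None,
    min_completeness: float = 0.25,
) -> dict[str, CompositeResult]:
    """Resample 10 m maps to 30 m and composite by interval, dropping sparse ones.

    Each 10 m map is block-mean resampled to the 30 m grid and binarized at
    > 0 (any kelp within the 3x3 block), then maps are grouped into annual
    (July–June) or austral-season intervals and averaged per pixel over the
    dates where the pixel was observed.  A composite is dropped when fewer
    than ``min_completeness`` (25%) of the applicable pixels were observed
    at least once in the interval.
    """
    if not maps:
        raise ValueError("need at least one map to composite")
    if applicable_mask is None:
        applicable_mask = np.ones(grid30.shape, dtype=bool)
    groups: dict[str, list[np.ndarray]] = {}
    for m in maps:
        if m.acquired_at is None:
            raise ValueError("maps must carry acquisition dates for compositing")
        coarse = resample_mean(m.presence, m.grid, grid30)
        binary = np.where(np.isnan(coarse), np.nan, (coarse > 0).astype(float))
        groups.setdefault(interval_label(m.acquired_at, interval), []).append(binary)
    out: dict[str, CompositeResult] = {}
    for label in sorted(groups):
        stack = np.stack(groups[label])
        observed = np.any(~np.isnan(stack), axis=0) & applicable_mask
        completeness = observed.sum() / max(applicable_mask.sum(), 1)
        if completeness < min_completeness:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
        mean[~applicable_mask] = np.nan
        presence = np.where(np.isnan(mean), np.nan, (mean > 0).astype(float))
        out[label] = CompositeResult(
            interval=label, mean=mean, completeness=float(completeness),
            presence=BinaryCanopyMap(grid=grid30, presence=presence,
                                     provenance="consensus", interval=label))
    return out


def matthews_correlation(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Computed in exact integer arithmetic; defined as 0 when any factor of
    the denominator is 0 (degenerate all-one-class predictions or truths).
    """
    tp, fp, fn, tn = int(tp), int(fp), int(fn), int(tn)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def optimize_threshold(
    votes_maps: list[ConsensusRaster],
    expert_maps: list[BinaryCanopyMap],
    grid30: Grid,
) -> tuple[int, pd.DataFrame]:
    """Select the consensus threshold by MCC against expert classifications.

    For every tau in 1..n_users each vote raster is binarized, resampled to
    the shared 30 m grid (binarized at > 0), and compared cell-by-cell with
    the matched expert map over cells valid in both.  Returns the tau
    maximizing pooled MCC (ties -> lower tau) and the full confusion table.
    """
    if not votes_maps or len(votes_maps) != len(expert_maps):
        raise ValueError("need matched, non-empty votes and expert map lists")
    for em in expert_maps:
        if em.grid != grid30:
            raise GeometryError("expert maps must live on the shared 30 m grid")
    n_users = votes_maps[0].n_users
    rows = []
    for tau in range(1, n_users + 1):
        tp = fp = fn = tn = 0
        for vr, em in zip(votes_maps, expert_maps):
            pred10 = threshold_consensus(vr, tau).presence
            coarse = resample_mean(pred10, vr.grid, grid30)
            pred = np.where(np.isnan(coarse), np.nan, (coarse > 0).astype(float))
            valid = ~np.isnan(pred) & ~np.isnan(em.presence)
            p = pred[valid].astype(bool)
            e = em.presence[valid].astype(bool)
            tp += int(np.sum(p & e))
            fp += int(np.sum(p & ~e))
            fn += int(np.sum(~p & e))
            tn += int(np.sum(~p & ~e))
        rows.append({"tau": tau, "TP": tp, "FP": fp, "FN": fn, "TN": tn,
                     "MCC": matthews_correlation(tp, fp, fn, tn)})
    table = pd.DataFrame(rows)
    tau_star = int(table.loc[table["MCC"].idxmax(), "tau"])  # idxmax: first max
    return tau_star, table
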
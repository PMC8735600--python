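"""Validation of canopy classifications against expert labels.

Classification sources (expert, spectral, consensus) are compared by
aggregating kelp pixels to their nearest 1 km coastline segment and
regressing the paired per-segment counts: R² (squared Pearson correlation
of the paired aggregates), RMSE expressed as a percentage of the range of
the expert aggregates, and mean bias.  Per-pixel confusion metrics (MCC,
sensitivity, specificity) are also provided for map-to-map comparisons.

For consistency across sources, validation restricts to the same coastal
distance window the spectral branch uses (120 m – 4.5 km): nearshore pixels
that the spectral products mask are removed from every source's aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ff_consensus import matthews_correlation
from .geo_core import (
    BinaryCanopyMap,
    CoastlineSegmentSet,
    DistanceField,
    GeometryError,
    assign_to_segments,
)

__all__ = [
    "SegmentAggregate",
    "ValidationResult",
    "aggregate_canopy",
    "compare_sources",
    "confusion_metrics",
]


@dataclass
class ValidationResult:
    r_squared: float
    rmse: float
    rmse_pct_range: float
    bias: float
    n_segments: int
    per_scene: pd.DataFrame | None = None


def aggregate_canopy(
    canopy: BinaryCanopyMap,
    segments: CoastlineSegmentSet,
    distance: DistanceField,
    d_min: float = 120.0,
    d_max: float = 4500.0,
    scene_id: str | None = None,
) -> pd.DataFrame:
    """Count kelp pixels per nearest 1 km coastline segment.

    Only kelp pixels inside the [d_min, d_max] distance window contribute;
    segments with no kelp appear with count 0 so regressions are not
    selection-biased toward kelp-rich coastline.  Returns a DataFrame with
    columns (segment_id, n_kelp_pixels, source, scene_id).
    """
    if segments.n_segments == 0:
        raise ValueError("empty segment set")
    if canopy.grid.crs_id != segments.crs_id:
        raise GeometryError("canopy map and segments must share a CRS")
    if distance.grid != canopy.grid:
        raise GeometryError("distance field grid does not match canopy grid")
    presence = canopy.presence
    keep = ((presence == 1)
            & (distance.distance >= d_min) & (distance.distance <= d_max))
    counts = np.zeros(segments.n_segments, dtype=int)
    rows, cols = np.nonzero(keep)
    if len(rows):
        px = canopy.grid.pixel_size
        x = canopy.grid.origin_x + (cols + 0.5) * px
        y = canopy.grid.origin_y - (rows + 0.5) * px
        sids = assign_to_segments(np.column_stack([x, y]), segments)
        np.add.at(counts, sids, 1)
    return pd.DataFrame({
        "segment_id": np.arange(segments.n_segments),
        "n_kelp_pixels": counts,
        "source": canopy.provenance,
        "scene_id": scene_id,
    })


def compare_sources(expert: pd.DataFrame, test: pd.DataFrame) -> ValidationResult:
    """Regress matched per-segment aggregates of a test source on expert labels.

    Aggregates are matched on (segment_id, scene_id).  R² is the squared
    Pearson correlation of the pairs; RMSE is root-mean-square difference,
    also expressed as a percentage of the expert aggregate range; bias is
    mean(test - expert) in pixels per segment.
    """
    keys = ["segment_id", "scene_id"]
    merged = expert.merge(test, on=keys, suffixes=("_expert", "_test"))
    if merged.empty:
        raise ValueError("no overlapping (segment, scene) keys between sources")
    e = merged["n_kelp_pixels_expert"].to_numpy(dtype=float)
    t = merged["n_kelp_pixels_test"].to_numpy(dtype=float)
    if len(np.unique(e)) < 2:
        raise ValueError("expert aggregates have zero range; RMSE%% undefined")
    r, _ = stats.pearsonr(e, t)
    rmse = float(np.sqrt(np.mean((t - e) ** 2)))
    rng = float(e.max() - e.min())
    per_scene = None
    if merged["scene_id"].nunique() > 1:
        per_scene = (merged.groupby("scene_id")
                     .apply(lambda g: pd.Series({
                         "bias": float((g["n_kelp_pixels_test"]
                                        - g["n_kelp_pixels_expert"]).mean()),
                         "rmse": float(np.sqrt(((g["n_kelp_pixels_test"]
                                                 - g["n_kelp_pixels_expert"]) ** 2
                                                ).mean())),
                     }), include_groups=False)
                     .reset_index())
    return ValidationResult(
        r_squared=float(r ** 2) if np.isfinite(r) else 0.0,
        rmse=rmse,
        rmse_pct_range=100.0 * rmse / rng,
        bias=float(np.mean(t - e)),
        n_segments=int(merged["segment_id"].nunique()),
        per_scene=per_scene,
    )


def confusion_metrics(a: BinaryCanopyMap, b: BinaryCanopyMap) -> dict:
    """Per-pixel confusion of map ``a`` (prediction) against ``b`` (truth).

    Missing cells are excluded pairwise; it is an error when no cell is
    valid in both maps.  Returns TP/FP/FN/TN counts plus MCC, sensitivity,
    and specificity.
    """
    if a.grid != b.grid:
        raise GeometryError("maps must share a grid")
    valid = ~np.isnan(a.presence) & ~np.isnan(b.presence)
    if not valid.any():
        raise ValueError("maps have no jointly valid cells")
    p = a.presence[valid].astype(bool)
    t = b.presence[valid].astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "MCC": matthews_correlation(tp, fp, fn, tn),
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
    }
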
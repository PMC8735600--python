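"""Post-processing mask cascade for the spectral classification timeseries.

Per-pixel spectral classification generates sporadic false positives (wave
facets, glint, suspended sediment).  Five rules remove implausible pixels
from the stacked timeseries, each masking the pixel for *all* dates:

1. distance — outside the 120 m – 4.5 km coastal band (nearshore optics are
   unreliable; kelp does not grow far offshore);
2. over-range — any fractional cover assignment above 300%;
3. prevalence — kelp present in less than 2% of the pixel's observed dates;
4. tide correlation — fraction series strongly negatively correlated
   (< -0.25) with tide height (emergent canopy artifacts);
5. spatial coherence — fraction series poorly correlated (< 0.2) with the
   mean of other kelp pixels within 5 km (real beds fluctuate together).

Boundary conventions follow the strict inequalities above; statistics use
the fractional (not binary) series, need at least 5 paired observations,
and undefined correlations (zero variance) never mask a pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geo_core import DistanceField, GeometryError, Grid

__all__ = [
    "PixelTimeseriesStack",
    "FilterReport",
    "mask_by_distance",
    "mask_by_overrange",
    "mask_by_prevalence",
    "mask_by_tide_correlation",
    "mask_by_spatial_coherence",
    "apply_cascade",
    "DEFAULT_FILTER_PARAMS",
]

DEFAULT_FILTER_PARAMS = {
    "d_min": 120.0,          # m, strict <
    "d_max": 4500.0,         # m, strict >
    "f_max": 3.0,            # fractional cover, strict >
    "p_min": 0.02,           # prevalence, strict <
    "tide_r_min": -0.25,     # Pearson r, strict <
    "coherence_r_min": 0.2,  # Pearson r, strict <
    "coherence_radius": 5000.0,  # m
    "min_obs": 5,
}


@dataclass
class PixelTimeseriesStack:
    """Per-pixel classification timeseries: (date, row, col) arrays.

    ``presence`` holds {0, 1, NaN}; ``fraction`` the MESMA fractional cover
    on the same support; ``tide_at_date`` the tide height (m) per date.
    """

    grid: Grid
    dates: list
    presence: np.ndarray
    fraction: np.ndarray
    tide_at_date: np.ndarray | None = None

    def __post_init__(self) -> None:
        exp = (len(self.dates),) + self.grid.shape
        if self.presence.shape != exp or self.fraction.shape != exp:
            raise GeometryError("stack arrays must be (n_dates, n_rows, n_cols)")
        if any(self.dates[i] >= self.dates[i + 1] for i in range(len(self.dates) - 1)):
            raise ValueError("dates must be strictly increasing")
        if self.tide_at_date is not None and len(self.tide_at_date) != len(self.dates):
            raise ValueError("tide series length must match the number of dates")
        self.presence = np.asarray(self.presence, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)

    def copy(self) -> "PixelTimeseriesStack":
        return PixelTimeseriesStack(
            grid=self.grid, dates=list(self.dates),
            presence=self.presence.copy(), fraction=self.fraction.copy(),
            tide_at_date=None if self.tide_at_date is None
            else np.asarray(self.tide_at_date).copy(),
        )

    def kelp_pixel_mask(self) -> np.ndarray:
        """Pixels with kelp presence on at least one date."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.presence, axis=0) > 0

    def _mask_pixels(self, mask: np.ndarray) -> None:
        self.presence[:, mask] = np.nan
        self.fraction[:, mask] = np.nan


@dataclass
class FilterReport:
    """Audit trail of the cascade: per rule, how many pixels it masked."""

    rules: list[tuple[str, int, dict]] = field(default_factory=list)

    def add(self, name: str, n_masked: int, params: dict) -> None:
        if n_masked < 0:
            raise ValueError("mask counts cannot be negative")
        self.rules.append((name, int(n_masked), params))

    def counts(self) -> dict[str, int]:
        return {name: n for name, n, _ in self.rules}

    def total_masked(self) -> int:
        return sum(n for _, n, _ in self.rules)

    def to_json(self, path: str | Path) -> None:
        doc = [{"rule": r, "n_pixels_masked": n, "parameters": p}
               for r, n, p in self.rules]
        Path(path).write_text(json.dumps(doc, indent=2))

    def log_lines(self) -> list[str]:
        return [f"filter {name}: masked {n} pixels ({params})"
                for name, n, params in self.rules]


def _newly_masked(before: np.ndarray, mask: np.ndarray) -> int:
    """Count pixels masked by a rule that were not already all-missing."""
    had_data = ~np.all(np.isnan(before), axis=0)
    return int(np.sum(mask & had_data))


def mask_by_distance(stack: PixelTimeseriesStack, distance: DistanceField,
                     d_min: float = 120.0, d_max: float = 4500.0,
                     report: FilterReport | None = None) -> PixelTimeseriesStack:
    """Mask pixels closer than ``d_min`` or farther than ``d_max`` from shore
    (boundaries kept: exactly 120 m or 4.5 km survives)."""
    if distance.grid != stack.grid:
        raise GeometryError("distance field grid does not match stack grid")
    out = stack.copy()
    bad = (distance.distance < d_min) | (distance.distance > d_max)
    n = _newly_masked(stack.presence, bad)
    out._mask_pixels(bad)
    if report is not None:
        report.add("distance", n, {"d_min": d_min, "d_max": d_max})
    return out


def mask_by_overrange(stack: PixelTimeseriesStack, f_max: float = 3.0,
                      report: FilterReport | None = None) -> PixelTimeseriesStack:
    """Mask pixels whose fractional cover exceeds ``f_max`` (300%) on any date."""
    out = stack.copy()
    with np.errstate(invalid="ignore"):
        bad = np.any(stack.fraction > f_max, axis=0)
    n = _newly_masked(stack.presence, bad)
    out._mask_pixels(bad)
    if report is not None:
        report.add("overrange", n, {"f_max": f_max})
    return out


def mask_by_prevalence(stack: PixelTimeseriesStack, p_min: float = 0.02,
                       report: FilterReport | None = None) -> PixelTimeseriesStack:
    """Mask kelp-containing pixels with kelp present in less than ``p_min``
    of their observed dates (2 presences in 100 dates survives; 1 does not).
    Pixels with no presence at all are left alone — they carry no kelp to
    remove, and masking them would swamp the audit counts."""
    out = stack.copy()
    n_obs = np.sum(~np.isnan(stack.presence), axis=0)
    n_present = np.nansum(stack.presence, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prevalence = np.where(n_obs > 0, n_present / n_obs, np.nan)
    bad = (n_obs > 0) & (n_present > 0) & (prevalence < p_min)
    n = _newly_masked(stack.presence, bad)
    out._mask_pixels(bad)
    if report is not None:
        report.add("prevalence", n, {"p_min": p_min})
    return out


def _pixelwise_pearson(series: np.ndarray, other: np.ndarray) -> float:
    """Pearson r over jointly finite entries; NaN when undefined."""
    ok = ~np.isnan(series) & ~np.isnan(other)
    if ok.sum() < 2:
        return np.nan
    a, b = series[ok], other[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def mask_by_tide_correlation(stack: PixelTimeseriesStack, r_min: float = -0.25,
                             min_obs: int = 5,
                             report: FilterReport | None = None
                             ) -> PixelTimeseriesStack:
    """Mask kelp pixels whose fraction series is strongly negatively
    correlated (< ``r_min``) with tide height.

    Emergent canopy area genuinely shrinks a little at high tide, but a
    strong negative correlation marks pixels whose apparent kelp is a pure
    tidal artifact (e.g. intertidal rocks).  Pixels with fewer than
    ``min_obs`` paired observations or zero variance are kept.
    """
    if stack.tide_at_date is None:
        raise ValueError("stack has no tide series")
    tide = np.asarray(stack.tide_at_date, dtype=float)
    out = stack.copy()
    kelp = stack.kelp_pixel_mask()
    bad = np.zeros(stack.grid.shape, dtype=bool)
    for r, c in zip(*np.nonzero(kelp)):
        series = stack.fraction[:, r, c]
        ok = ~np.isnan(series)
        if ok.sum() < min_obs or series[ok].std() == 0:
            continue
        corr = _pixelwise_pearson(series, tide)
        if not np.isnan(corr) and corr < r_min:
            bad[r, c] = True
    n = _newly_masked(stack.presence, bad)
    out._mask_pixels(bad)
    if report is not None:
        report.add("tide_correlation", n, {"r_min": r_min, "min_obs": min_obs})
    return out


def mask_by_spatial_coherence(stack: PixelTimeseriesStack, r_min: float = 0.2,
                              radius: float = 5000.0, min_obs: int = 5,
                              report: FilterReport | None = None
                              ) -> PixelTimeseriesStack:
    """Mask kelp pixels poorly correlated (< ``r_min``) with nearby kelp.

    Each kelp pixel's fraction series is compared with the mean fraction
    series of all *other* kelp pixels within ``radius``; real beds co-vary
    with their neighborhood.  A kelp pixel with no neighbor within the
    radius is masked — a lone 30 m pixel more than 5 km from any other kelp
    is almost surely a false positive.  Zero-variance series are kept.
    """
    out = stack.copy()
    kelp = stack.kelp_pixel_mask()
    rows, cols = np.nonzero(kelp)
    if len(rows) == 0:
        if report is not None:
            report.add("spatial_coherence", 0,
                       {"r_min": r_min, "radius": radius})
        return out
    px = stack.grid.pixel_size
    xy = np.column_stack([cols * px, rows * px])
    series = stack.fraction[:, rows, cols]  # (n_dates, n_kelp)
    bad = np.zeros(stack.grid.shape, dtype=bool)
    for i in range(len(rows)):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        nbr = (d <= radius)
        nbr[i] = False
        if not nbr.any():
            bad[rows[i], cols[i]] = True
            continue
        with np.errstate(invalid="ignore"):
            neighborhood = np.nanmean(series[:, nbr], axis=1)
        own = series[:, i]
        ok = ~np.isnan(own) & ~np.isnan(neighborhood)
        if ok.sum() < min_obs or own[ok].std() == 0:
            continue
        corr = _pixelwise_pearson(own, neighborhood)
        if not np.isnan(corr) and corr < r_min:
            bad[rows[i], cols[i]] = True
    n = _newly_masked(stack.presence, bad)
    out._mask_pixels(bad)
    if report is not None:
        report.add("spatial_coherence", n, {"r_min": r_min, "radius": radius})
    return out


def apply_cascade(stack: PixelTimeseriesStack, distance: DistanceField,
                  params: dict | None = None
                  ) -> tuple[PixelTimeseriesStack, FilterReport]:
    """Apply all five rules in order: distance -> over-range -> prevalence ->
    tide correlation -> spatial coherence.

    Geometric rules run first so the statistical rules are computed only on
    geometrically plausible pixels.  The cascade is idempotent.
    """
    p = dict(DEFAULT_FILTER_PARAMS)
    if params:
        p.update(params)
    report = FilterReport()
    out = mask_by_distance(stack, distance, p["d_min"], p["d_max"], report)
    out = mask_by_overrange(out, p["f_max"], report)
    out = mask_by_prevalence(out, p["p_min"], report)
    if out.tide_at_date is not None:
        out = mask_by_tide_correlation(out, p["tide_r_min"], p["min_obs"], report)
    out = mask_by_spatial_coherence(out, p["coherence_r_min"],
                                    p["coherence_radius"], p["min_obs"], report)
    return out, report
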
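"""Synthetic inputs with known truth for every stage of the pipeline.

The generators emulate the observational inputs of a multi-decadal kelp
canopy study — Landsat-style 6-band surface-reflectance scenes with known
per-pixel fractional kelp cover, crowds of noisy annotators, semidiurnal
~1 m tides, monthly SST, in-situ temperature–nitrate pairs, and annual
climate indices — so the classification, filtering, consensus, validation,
and timeseries stages can all be tested against planted truth without any
downloads.  Everything is bit-reproducible under a fixed seed.

Geometry convention: the synthetic coastline runs roughly north–south with
land on the western (-x) side; kelp beds are placed in the ocean east of it.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint

from .dtm_classifier import KELP_ENDMEMBER, EndmemberLibrary
from .ff_consensus import AnnotationSet
from .geo_core import CoastlineSegmentSet, Grid, Scene, segment_coastline

__all__ = [
    "WATER_ENDMEMBER",
    "GLINT_SPECTRUM",
    "LAND_SPECTRUM",
    "CONFUSER_CODES",
    "BedSpec",
    "TruthScene",
    "AnnotatorModel",
    "EnvironmentTruth",
    "EnvironmentData",
    "constant_detect_prob",
    "step_detect_prob",
    "saturating_detect_prob",
    "make_coastline",
    "land_mask_for",
    "make_truth_scene",
    "make_scene_series",
    "simulate_annotations",
    "make_environment",
]

#: Clear-water endmember: NIR-dark, slightly blue-green. Fixture constants
#: with realistic shape, not measurements.
WATER_ENDMEMBER = np.array([0.040, 0.050, 0.030, 0.012, 0.005, 0.003])
#: Sun-glint / whitecap confuser: bright across the spectrum, NIR-bright.
GLINT_SPECTRUM = np.array([0.150, 0.150, 0.150, 0.300, 0.200, 0.150])
LAND_SPECTRUM = np.array([0.060, 0.080, 0.100, 0.250, 0.300, 0.200])
CLOUD_SPECTRUM = np.array([0.600, 0.620, 0.640, 0.660, 0.500, 0.400])

CONFUSER_CODES = {"none": 0, "glint": 1, "sediment": 2, "debris": 3}


@dataclass(frozen=True)
class BedSpec:
    """A blobby elliptical kelp bed with a flat-top fractional-cover profile.

    Fraction equals ``peak`` inside the elliptical core (normalized radius
    <= 0.6) and ramps linearly to zero at the bed edge (radius 1), so
    noiseless scenes contain both pure-peak and mixed boundary pixels.
    """

    x: float
    y: float
    rx: float
    ry: float
    peak: float = 1.0
    angle: float = 0.0  # radians, CCW from +x
    bed_id: int = 0

    def fraction_profile(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        dx, dy = X - self.x, Y - self.y
        c, s = math.cos(self.angle), math.sin(self.angle)
        u = (dx * c + dy * s) / self.rx
        v = (-dx * s + dy * c) / self.ry
        r = np.hypot(u, v)
        ramp = np.clip((1.0 - r) / 0.4, 0.0, 1.0)  # flat core for r <= 0.6
        return self.peak * ramp


@dataclass
class TruthScene:
    """A synthetic scene bundled with its generating truth."""

    scene: Scene
    kelp_fraction_truth: np.ndarray
    endmembers_used: EndmemberLibrary
    noise_sd: float
    confuser_map: np.ndarray

    def true_area_m2(self, threshold: float | None = None) -> float:
        f = self.kelp_fraction_truth
        px_area = self.scene.grid.pixel_size ** 2
        if threshold is None:
            return float(f.sum() * px_area)
        return float((f >= threshold).sum() * px_area)


@dataclass
class AnnotatorModel:
    """Statistical model of a crowd of unskilled annotators.

    ``detect_prob(area_m2)`` is the per-user probability of outlining a true
    kelp patch, non-decreasing in patch area; ``boundary_jitter_sd`` blurs
    the drawn polygon vertices (meters); ``false_pos_rate`` is the expected
    number of spurious polygons per user per tile; ``decoy_prob`` is the
    per-user probability of outlining a non-kelp confuser patch (e.g.
    drifting debris), which experts would reject.
    """

    n_users: int = 15
    detect_prob: Callable[[float], float] = None  # type: ignore[assignment]
    boundary_jitter_sd: float = 0.0
    false_pos_rate: float = 0.0
    decoy_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("need at least one annotator")
        if self.detect_prob is None:
            self.detect_prob = saturating_detect_prob()


def constant_detect_prob(p: float) -> Callable[[float], float]:
    return lambda area: p


def step_detect_prob(area_threshold_m2: float, p_small: float, p_large: float
                     ) -> Callable[[float], float]:
    if p_small > p_large:
        raise ValueError("detect probability must be non-decreasing in area")
    return lambda area: p_large if area >= area_threshold_m2 else p_small


def saturating_detect_prob(half_area_m2: float = 5 * 900.0,
                           p_max: float = 0.95) -> Callable[[float], float]:
    """Monotone saturating curve: tiny beds are often missed, large ones
    almost always outlined."""
    return lambda area: p_max * area / (area + half_area_m2)


# ---------------------------------------------------------------------------
# coastline and land


def make_coastline(
    grid: Grid,
    seed: int = 0,
    base_offset_frac: float = 0.25,
    wiggle_amplitude_m: float | None = None,
    n_vertices: int = 60,
) -> CoastlineSegmentSet:
    """A north–south coastline polyline spanning the grid, land to the west.

    The shoreline x-position wanders smoothly with latitude (sum of two
    sinusoids with seeded phases) around a base offset from the western grid
    edge, then is cut into 1 km arclength segments.
    """
    rng = np.random.default_rng(seed)
    height = grid.n_rows * grid.pixel_size
    width = grid.n_cols * grid.pixel_size
    if wiggle_amplitude_m is None:
        wiggle_amplitude_m = 0.05 * width
    y = np.linspace(grid.origin_y, grid.origin_y - height, n_vertices)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    t = np.linspace(0, 1, n_vertices)
    x = (grid.origin_x + base_offset_frac * width
         + wiggle_amplitude_m * np.sin(2 * np.pi * 1.5 * t + ph1)
         + 0.4 * wiggle_amplitude_m * np.sin(2 * np.pi * 4.0 * t + ph2))
    polyline = np.column_stack([x, y])
    return segment_coastline(polyline, 1000.0, crs_id=grid.crs_id)


def _coast_x_at(coastline: CoastlineSegmentSet, Y: np.ndarray) -> np.ndarray:
    verts = coastline.polyline
    order = np.argsort(verts[:, 1])
    return np.interp(Y, verts[order, 1], verts[order, 0])


def land_mask_for(grid: Grid, coastline: CoastlineSegmentSet) -> np.ndarray:
    """Boolean land mask: cells west of the (y-monotone) coastline."""
    X, Y = grid.cell_centers()
    return X < _coast_x_at(coastline, Y)


# ---------------------------------------------------------------------------
# scenes


def make_truth_scene(
    grid: Grid,
    coastline: CoastlineSegmentSet,
    beds: Sequence[BedSpec],
    endmembers: EndmemberLibrary | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    glint_frac: float = 0.0,
    cloud_frac: float = 0.0,
    debris_beds: Sequence[BedSpec] = (),
    sensor: str = "OLI",
    acquired_at: _dt.datetime | None = None,
    tide_height: float | None = None,
    bed_multipliers: dict[int, float] | None = None,
    artifact_fractions: dict[int, float] | None = None,
) -> TruthScene:
    """Build one scene as a linear kelp/water mixture with known truth.

    Reflectance is ``f * kelp + (1 - f) * water`` plus i.i.d. Gaussian noise
    wherever no confuser is planted.  ``bed_multipliers`` scales each bed's
    peak (used by the AR(1) series generator); ``artifact_fractions`` pins a
    bed's fraction to a given constant across its footprint (used to plant
    tide-correlated artifacts).  Beds centered on land are an error.
    """
    if endmembers is None:
        endmembers = EndmemberLibrary(kelp=KELP_ENDMEMBER,
                                      water=WATER_ENDMEMBER[None, :])
    rng = np.random.default_rng(seed)
    X, Y = grid.cell_centers()
    land = land_mask_for(grid, coastline)
    coast_x = _coast_x_at(coastline, Y)

    fraction = np.zeros(grid.shape)
    for bed in beds:
        if bed.x < float(np.interp(bed.y,
                                   coastline.polyline[np.argsort(coastline.polyline[:, 1]), 1],
                                   coastline.polyline[np.argsort(coastline.polyline[:, 1]), 0])):
            raise ValueError(f"bed {bed.bed_id} is centered on land")
        mult = 1.0 if bed_multipliers is None else bed_multipliers.get(bed.bed_id, 1.0)
        if artifact_fractions is not None and bed.bed_id in artifact_fractions:
            footprint = bed.fraction_profile(X, Y) > 0
            fraction = np.where(footprint,
                                np.maximum(fraction, artifact_fractions[bed.bed_id]),
                                fraction)
        else:
            prof = bed.fraction_profile(X, Y) * mult
            fraction = np.maximum(fraction, prof)
    fraction = np.clip(fraction, 0.0, 1.0)
    fraction[land] = 0.0

    water = endmembers.water[0]
    kelp = endmembers.kelp
    reflectance = (fraction[None] * kelp[:, None, None]
                   + (1.0 - fraction)[None] * water[:, None, None])
    if noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, noise_sd, reflectance.shape)

    confuser = np.zeros(grid.shape, dtype=int)
    ocean = ~land
    if glint_frac > 0:
        eligible = ocean & (fraction == 0)
        r, c = np.nonzero(eligible)
        n_glint = int(round(glint_frac * len(r)))
        if n_glint:
            pick = rng.choice(len(r), size=n_glint, replace=False)
            confuser[r[pick], c[pick]] = CONFUSER_CODES["glint"]
            reflectance[:, r[pick], c[pick]] = GLINT_SPECTRUM[:, None]
    for bed in debris_beds:
        footprint = bed.fraction_profile(X, Y) > 0.5 * bed.peak
        footprint &= ocean
        confuser[footprint] = CONFUSER_CODES["debris"]
        # debris: moderately NIR-bright but spectrally flat, unlike kelp
        reflectance[:, footprint] = np.array(
            [0.10, 0.10, 0.10, 0.16, 0.12, 0.10])[:, None]

    reflectance[:, land] = LAND_SPECTRUM[:, None]
    cloud = np.zeros(grid.shape, dtype=bool)
    if cloud_frac > 0:
        n_blobs = max(1, int(round(cloud_frac * grid.n_rows * grid.n_cols / 50)))
        for _ in range(n_blobs):
            r0 = rng.integers(0, grid.n_rows)
            c0 = rng.integers(0, grid.n_cols)
            h = rng.integers(3, 10)
            w = rng.integers(3, 10)
            cloud[r0:r0 + h, c0:c0 + w] = True
        reflectance[:, cloud] = CLOUD_SPECTRUM[:, None]

    scene = Scene(
        grid=grid,
        reflectance=reflectance,
        land_mask=land,
        cloud_mask=cloud,
        sensor=sensor,
        acquired_at=acquired_at or _dt.datetime(2015, 1, 15, 14, 0),
        tide_height=tide_height,
    )
    del coast_x
    return TruthScene(scene=scene, kelp_fraction_truth=fraction,
                      endmembers_used=endmembers, noise_sd=noise_sd,
                      confuser_map=confuser)


def make_scene_series(
    grid: Grid,
    coastline: CoastlineSegmentSet,
    beds: Sequence[BedSpec],
    n_dates: int,
    start: _dt.datetime = _dt.datetime(2000, 1, 1, 14, 0),
    span_days: float = 3650.0,
    ar1_coef: float = 0.8,
    ar1_innovation_sd: float = 0.2,
    tide_amplitude: float = 0.5,
    tide_artifact_bed: BedSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sensor_cycle: Sequence[str] = ("TM", "ETMP", "OLI"),
) -> tuple[list[TruthScene], pd.DataFrame]:
    """A dated series of scenes with AR(1) bed dynamics and semidiurnal tides.

    Each bed's peak cover follows a multiplicative AR(1) process on the log
    scale (coefficient 1 with zero innovation gives constant beds).  The
    optional ``tide_artifact_bed`` is a planted false-positive patch whose
    apparent fraction is ``max(0, 0.5 - 0.4 * tide)`` — strongly negatively
    tide-correlated, which the tidal post-processing filter should remove.
    Returns the scenes and a truth table (date, bed_id, true_area_m2, tide).
    """
    if n_dates < 2:
        raise ValueError("need at least 2 dates")
    rng = np.random.default_rng(seed)
    dates = [start + _dt.timedelta(days=float(d))
             for d in np.linspace(0.0, span_days, n_dates)]
    # semidiurnal tide sampled at acquisition times (period 12.42 h)
    hours = np.array([(d - start).total_seconds() / 3600.0 for d in dates])
    tides = tide_amplitude * np.sin(2 * np.pi * hours / 12.42)

    log_mult = {bed.bed_id: 0.0 for bed in beds}
    scenes: list[TruthScene] = []
    truth_rows = []
    for i, (date, tide) in enumerate(zip(dates, tides)):
        mults = {}
        for bed in beds:
            log_mult[bed.bed_id] = (ar1_coef * log_mult[bed.bed_id]
                                    + rng.normal(0.0, ar1_innovation_sd))
            mults[bed.bed_id] = float(np.exp(log_mult[bed.bed_id]))
        all_beds = list(beds)
        artifacts = None
        if tide_artifact_bed is not None:
            all_beds = all_beds + [tide_artifact_bed]
            artifacts = {tide_artifact_bed.bed_id: max(0.0, 0.5 - 0.4 * tide)}
        ts = make_truth_scene(
            grid, coastline, all_beds,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            sensor=sensor_cycle[i % len(sensor_cycle)],
            acquired_at=date,
            tide_height=float(tide),
            bed_multipliers=mults,
            artifact_fractions=artifacts,
        )
        scenes.append(ts)
        px_area = grid.pixel_size ** 2
        X, Y = grid.cell_centers()
        for bed in all_beds:
            if artifacts and bed.bed_id in artifacts:
                area = float((bed.fraction_profile(X, Y) > 0).sum() * px_area
                             * (artifacts[bed.bed_id] > 0))
            else:
                prof = np.clip(bed.fraction_profile(X, Y) * mults.get(bed.bed_id, 1.0),
                               0, 1)
                prof[ts.scene.land_mask] = 0.0
                area = float(prof.sum() * px_area)
            truth_rows.append({"date": date, "bed_id": bed.bed_id,
                               "true_area_m2": area, "tide": float(tide)})
    return scenes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# annotations


def _tile_layout(grid: Grid, tile_size_m: float) -> dict[int, tuple[float, float, float, float]]:
    width = grid.n_cols * grid.pixel_size
    height = grid.n_rows * grid.pixel_size
    nx = max(1, int(math.ceil(width / tile_size_m)))
    ny = max(1, int(math.ceil(height / tile_size_m)))
    tiles = {}
    tid = 0
    for iy in range(ny):
        for ix in range(nx):
            xmin = grid.origin_x + ix * tile_size_m
            ymax = grid.origin_y - iy * tile_size_m
            tiles[tid] = (xmin, ymax - tile_size_m, xmin + tile_size_m, ymax)
            tid += 1
    return tiles


def _patch_polygons(mask: np.ndarray, grid: Grid) -> list[tuple[shapely.Geometry, float]]:
    """Connected patches of a boolean raster as convex-hull polygons.

    Human annotators draw rounded outlines around beds rather than tracing
    pixels, so the convex hull of a patch's cell corners is the natural
    polygon model.  Returns (polygon, patch_area_m2) pairs.
    """
    labels, n = ndimage.label(mask)
    out = []
    px = grid.pixel_size
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        corners = []
        for r, c in zip(rows, cols):
            x0 = grid.origin_x + c * px
            y0 = grid.origin_y - r * px
            corners.extend([(x0, y0), (x0 + px, y0),
                            (x0, y0 - px), (x0 + px, y0 - px)])
        hull = MultiPoint(corners).convex_hull
        if hull.geom_type != "Polygon":
            hull = hull.buffer(px / 4)
        out.append((hull, len(rows) * px * px))
    return out


def simulate_annotations(
    truth_scene: TruthScene,
    annotator: AnnotatorModel,
    seed: int = 0,
    tile_size_m: float = 1500.0,
) -> AnnotationSet:
    """Draw per-user kelp polygons for every true patch, with controlled error.

    Each of the ``n_users`` annotators outlines each true kelp patch (its
    fraction > 0 footprint as a convex polygon, vertices jittered by
    ``boundary_jitter_sd``) with probability ``detect_prob(patch area)``;
    confuser (debris) patches are outlined with probability ``decoy_prob``;
    spurious small polygons are added per tile at rate ``false_pos_rate``.
    Tile size defaults to 1.5 km x 1.5 km (~2.25 km^2).
    """
    rng = np.random.default_rng(seed)
    grid = truth_scene.scene.grid
    tiles = _tile_layout(grid, tile_size_m)
    patches = _patch_polygons(truth_scene.kelp_fraction_truth > 0, grid)
    decoys = _patch_polygons(
        truth_scene.confuser_map == CONFUSER_CODES["debris"], grid)

    def tile_of(geom: shapely.Geometry) -> int | None:
        cx, cy = geom.centroid.x, geom.centroid.y
        for tid, (xmin, ymin, xmax, ymax) in tiles.items():
            if xmin <= cx <= xmax and ymin <= cy <= ymax:
                return tid
        return None

    records: list[tuple[int, int, shapely.Geometry]] = []

    def jitter(poly: shapely.Geometry) -> shapely.Geometry:
        if annotator.boundary_jitter_sd <= 0:
            return poly
        coords = np.asarray(poly.exterior.coords)[:-1]
        coords = coords + rng.normal(0.0, annotator.boundary_jitter_sd, coords.shape)
        jittered = shapely.Polygon(coords)
        return jittered if jittered.is_valid else jittered.buffer(0)

    for user in range(annotator.n_users):
        for poly, area in patches:
            if rng.random() < annotator.detect_prob(area):
                tid = tile_of(poly)
                if tid is not None:
                    records.append((tid, user, jitter(poly)))
        for poly, _ in decoys:
            if rng.random() < annotator.decoy_prob:
                tid = tile_of(poly)
                if tid is not None:
                    records.append((tid, user, jitter(poly)))
        if annotator.false_pos_rate > 0:
            for tid, (xmin, ymin, xmax, ymax) in tiles.items():
                for _ in range(rng.poisson(annotator.false_pos_rate)):
                    cx = rng.uniform(xmin, xmax)
                    cy = rng.uniform(ymin, ymax)
                    half = rng.uniform(10.0, 40.0)
                    records.append((tid, user, shapely.box(cx - half, cy - half,
                                                           cx + half, cy + half)))
    return AnnotationSet(records=records, tile_index=tiles,
                         n_users_per_tile=annotator.n_users)


# ---------------------------------------------------------------------------
# environment


@dataclass
class EnvironmentTruth:
    """Generating parameters for the ocean-state series.

    The temperature–nitrate relation is linear with Gaussian scatter,
    ``N = a + b*T + eps``; defaults (a = 45 μmol/kg, b = -2.4 μmol/kg/°C,
    eps sd = 4.6 μmol/kg over T in [5, 19] °C) give cold subantarctic water
    nitrate in the tens of μmol/kg with scatter around 13% of the nitrate
    range.  Tides are semidiurnal with ~1 m range.
    """

    sst_mean: float = 8.0  # °C, cold Falkland Current water
    sst_seasonal_amplitude: float = 2.5  # °C
    sst_annual_anomaly_sd: float = 0.4  # °C, AR(1) interannual anomalies
    sst_monthly_noise_sd: float = 0.2  # °C
    nitrate_intercept: float = 45.0  # μmol/kg
    nitrate_slope: float = -2.4  # μmol/kg per °C
    nitrate_noise_sd: float = 4.6  # μmol/kg
    pair_temp_range: tuple[float, float] = (5.0, 19.0)  # °C
    tide_amplitude: float = 0.5  # m (semidiurnal range ~1 m)
    tide_noise_sd: float = 0.05  # m
    climate_ar1: float = 0.5
    climate_sd: float = 1.0


@dataclass
class EnvironmentData:
    sst_monthly: pd.DataFrame  # year, month, sst_c
    nitrate_pairs: pd.DataFrame  # temperature_c, nitrate_umol_kg
    tide: pd.DataFrame  # hours, height_m
    climate_index: pd.DataFrame  # year, value
    nitrate_annual: pd.DataFrame  # year, nitrate_umol_kg, nitrate_std
    canopy_driver: pd.DataFrame  # year, value (planted lag-1 response)


def make_environment(
    n_years: int,
    env: EnvironmentTruth | None = None,
    driver_noise_var: float = 1.367,
    seed: int = 0,
    n_pairs: int = 500,
    start_year: int = 1986,
    tide_days: int = 30,
) -> EnvironmentData:
    """Generate all ocean-state inputs plus a canopy driver with planted lag.

    The annual canopy driver is ``standardized nitrate(t-1) + eta`` with
    ``eta ~ N(0, driver_noise_var)``, so its population lag-1 Pearson
    correlation with nitrate is ``1/sqrt(1 + driver_noise_var)`` — the
    default variance of 1.367 plants a correlation of 0.65.
    """
    if n_years < 5:
        raise ValueError("need at least 5 years")
    if env is None:
        env = EnvironmentTruth()
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)

    # monthly SST: seasonal cycle (austral summer peak ~February) + AR(1)
    # interannual anomaly + monthly noise
    anomaly = 0.0
    sst_rows = []
    annual_anom = {}
    for year in years:
        anomaly = 0.6 * anomaly + rng.normal(0.0, env.sst_annual_anomaly_sd)
        annual_anom[year] = anomaly
        for month in range(1, 13):
            seasonal = env.sst_seasonal_amplitude * math.cos(
                2 * math.pi * (month - 2) / 12.0)
            sst = (env.sst_mean + seasonal + anomaly
                   + rng.normal(0.0, env.sst_monthly_noise_sd))
            sst_rows.append({"year": int(year), "month": month, "sst_c": sst})
    sst_monthly = pd.DataFrame(sst_rows)

    t_lo, t_hi = env.pair_temp_range
    temps = rng.uniform(t_lo, t_hi, n_pairs)
    nitr = (env.nitrate_intercept + env.nitrate_slope * temps
            + rng.normal(0.0, env.nitrate_noise_sd, n_pairs))
    pairs = pd.DataFrame({"temperature_c": temps, "nitrate_umol_kg": nitr})

    hours = np.arange(0, tide_days * 24, 0.5)
    height = (env.tide_amplitude * np.sin(2 * np.pi * hours / 12.42)
              + rng.normal(0.0, env.tide_noise_sd, hours.size))
    tide = pd.DataFrame({"hours": hours, "height_m": height})

    ci = np.zeros(n_years)
    for i in range(1, n_years):
        ci[i] = env.climate_ar1 * ci[i - 1] + rng.normal(0.0, env.climate_sd)
    climate = pd.DataFrame({"year": years, "value": ci})

    # annual (July–June) nitrate from the linear temperature model, then
    # standardized; the canopy driver responds to the previous year's value
    annual_sst = np.array([env.sst_mean + annual_anom[y] for y in years])
    annual_nitrate = env.nitrate_intercept + env.nitrate_slope * annual_sst
    z = (annual_nitrate - annual_nitrate.mean()) / annual_nitrate.std(ddof=0)
    nitrate_annual = pd.DataFrame({"year": years,
                                   "nitrate_umol_kg": annual_nitrate,
                                   "nitrate_std": z})
    eta = rng.normal(0.0, math.sqrt(driver_noise_var), n_years)
    driver = np.full(n_years, np.nan)
    driver[1:] = z[:-1] + eta[1:]
    canopy_driver = pd.DataFrame({"year": years, "value": driver})

    return EnvironmentData(
        sst_monthly=sst_monthly,
        nitrate_pairs=pairs,
        tide=tide,
        climate_index=climate,
        nitrate_annual=nitrate_annual,
        canopy_driver=canopy_driver,
    )
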
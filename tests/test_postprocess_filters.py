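import datetime as dt

import numpy as np
import pytest

from kelpcanopy.geo_core import DistanceField, GeometryError, Grid, segment_coastline, coast_distance
from kelpcanopy.postprocess_filters import (
    PixelTimeseriesStack,
    apply_cascade,
    mask_by_distance,
    mask_by_overrange,
    mask_by_prevalence,
    mask_by_spatial_coherence,
    mask_by_tide_correlation,
)

N_DATES = 60
DATES = [dt.datetime(2000, 1, 1) + dt.timedelta(days=i) for i in range(N_DATES)]
T = np.arange(N_DATES)
# mutually orthogonal series: distinct integer Fourier frequencies over 60
# samples have exactly zero cross-correlation
SERIES_A = 0.4 + 0.2 * np.sin(2 * np.pi * T / 20)   # healthy bed signal
SERIES_B = 0.4 + 0.2 * np.sin(2 * np.pi * T / 3)    # incoherent signal
TIDE = 0.5 * np.sin(2 * np.pi * T / 6)              # tide heights (m)


def empty_stack(grid):
    shape = (N_DATES,) + grid.shape
    return PixelTimeseriesStack(grid=grid, dates=list(DATES),
                                presence=np.full(shape, np.nan),
                                fraction=np.full(shape, np.nan),
                                tide_at_date=TIDE.copy())


def set_pixel(stack, r, c, fraction):
    stack.fraction[:, r, c] = fraction
    stack.presence[:, r, c] = (np.asarray(fraction) >= 0.13).astype(float)


@pytest.fixture
def fixture_stack():
    """One healthy 3-pixel bed plus exactly one planted violator per rule."""
    grid = Grid(40, 40, 0.0, 0.0, 30.0)
    coast = segment_coastline(np.array([[0.0, 100.0], [0.0, -1300.0]]), 1000.0)
    distance = coast_distance(grid, coast)
    stack = empty_stack(grid)
    for r, c in ((5, 10), (5, 12), (7, 11)):      # healthy bed
        set_pixel(stack, r, c, SERIES_A)
    set_pixel(stack, 10, 3, SERIES_A)             # 105 m from shore (< 120 m)
    over = SERIES_A.copy()
    over[7] = 3.5                                 # one >300% assignment
    set_pixel(stack, 15, 10, over)
    rare = np.zeros(N_DATES)
    rare[30] = 0.5                                # present 1/60 dates (< 2%)
    set_pixel(stack, 20, 10, rare)
    set_pixel(stack, 25, 10, 0.5 - 0.4 * TIDE)    # pure tidal artifact
    set_pixel(stack, 9, 11, SERIES_B)             # incoherent with the bed
    return stack, distance


def surviving(stack):
    return set(map(tuple, np.argwhere(stack.kelp_pixel_mask())))


class TestRuleBoundaries:
    def make_single(self, x_m, fraction=None):
        grid = Grid(1, 1, x_m - 15.0, 15.0, 30.0)
        stack = PixelTimeseriesStack(
            grid=grid, dates=list(DATES),
            presence=np.ones((N_DATES, 1, 1)),
            fraction=np.tile((fraction if fraction is not None else SERIES_A)
                             .reshape(-1, 1, 1), (1, 1, 1)),
            tide_at_date=TIDE.copy())
        distance = DistanceField(grid=grid, distance=np.array([[x_m]]))
        return stack, distance

    @pytest.mark.parametrize("d,masked", [(119.0, True), (120.0, False),
                                          (4500.0, False), (5000.0, True)])
    def test_distance_window_boundaries(self, d, masked):
        stack, distance = self.make_single(d)
        out = mask_by_distance(stack, distance)
        assert np.all(np.isnan(out.presence)) == masked

    @pytest.mark.parametrize("fmax_val,masked", [(3.01, True), (3.00, False),
                                                 (0.9, False)])
    def test_overrange_boundary(self, fmax_val, masked):
        series = SERIES_A.copy()
        series[0] = fmax_val
        stack, _ = self.make_single(1000.0, series)
        out = mask_by_overrange(stack)
        assert np.all(np.isnan(out.presence)) == masked

    @pytest.mark.parametrize("n_present,masked", [(1, True), (2, False)])
    def test_prevalence_boundary_at_2_percent(self, n_present, masked):
        grid = Grid(1, 1, 0.0, 0.0, 30.0)
        dates = [dt.datetime(2000, 1, 1) + dt.timedelta(days=i)
                 for i in range(100)]
        presence = np.zeros((100, 1, 1))
        presence[:n_present] = 1.0
        stack = PixelTimeseriesStack(grid=grid, dates=dates, presence=presence,
                                     fraction=presence * 0.5)
        out = mask_by_prevalence(stack)
        assert np.all(np.isnan(out.presence)) == masked

    def test_all_missing_pixel_not_counted_as_newly_masked(self):
        from kelpcanopy.postprocess_filters import FilterReport

        grid = Grid(1, 2, 0.0, 0.0, 30.0)
        presence = np.full((N_DATES, 1, 2), np.nan)
        presence[:, 0, 1] = 0.0
        presence[0, 0, 1] = 1.0  # 1/60 -> below 2%
        stack = PixelTimeseriesStack(grid=grid, dates=list(DATES),
                                     presence=presence,
                                     fraction=presence * 0.5)
        report = FilterReport()
        mask_by_prevalence(stack, report=report)
        assert report.counts()["prevalence"] == 1

    def test_constant_fraction_pixel_kept_by_tide_rule(self):
        stack, _ = self.make_single(1000.0, np.full(N_DATES, 0.4))
        out = mask_by_tide_correlation(stack)
        assert not np.isnan(out.presence).any()

    def test_tide_artifact_pixel_masked(self):
        stack, _ = self.make_single(1000.0, 0.5 - 0.4 * TIDE)
        out = mask_by_tide_correlation(stack)
        assert np.all(np.isnan(out.presence))

    def test_tide_independent_noise_rarely_masked(self):
        # null behavior: with 50 dates of tide-independent noise the strict
        # r < -0.25 rule should keep the pixel in at least 95% of seeds
        kept = 0
        n_seeds = 100
        tide50 = 0.5 * np.sin(2 * np.pi * np.arange(50) / 6)
        dates50 = [dt.datetime(2000, 1, 1) + dt.timedelta(days=i)
                   for i in range(50)]
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            series = rng.uniform(0.2, 0.6, 50)
            grid = Grid(1, 1, 0.0, 0.0, 30.0)
            stack = PixelTimeseriesStack(
                grid=grid, dates=dates50,
                presence=np.ones((50, 1, 1)),
                fraction=series.reshape(-1, 1, 1), tide_at_date=tide50)
            out = mask_by_tide_correlation(stack)
            kept += not np.isnan(out.presence).any()
        assert kept >= 0.95 * n_seeds

    def test_identical_neighbors_kept_by_coherence(self):
        grid = Grid(1, 40, 0.0, 0.0, 30.0)
        stack = empty_stack(grid)
        set_pixel(stack, 0, 0, SERIES_A)
        set_pixel(stack, 0, 33, SERIES_A)  # ~1 km apart, identical series
        out = mask_by_spatial_coherence(stack)
        assert surviving(out) == {(0, 0), (0, 33)}

    def test_neighborless_pixel_masked_by_coherence(self):
        grid = Grid(1, 400, 0.0, 0.0, 30.0)
        stack = PixelTimeseriesStack(
            grid=grid, dates=list(DATES),
            presence=np.full((N_DATES, 1, 400), np.nan),
            fraction=np.full((N_DATES, 1, 400), np.nan))
        set_pixel(stack, 0, 0, SERIES_A)
        set_pixel(stack, 0, 1, SERIES_A)
        set_pixel(stack, 0, 399, SERIES_A)  # ~12 km from the others
        out = mask_by_spatial_coherence(stack)
        assert surviving(out) == {(0, 0), (0, 1)}


class TestCascade:
    def test_clean_stack_masks_nothing(self):
        grid = Grid(10, 40, 0.0, 0.0, 30.0)
        coast = segment_coastline(np.array([[0.0, 100.0], [0.0, -400.0]]), 1000.0)
        distance = coast_distance(grid, coast)
        stack = PixelTimeseriesStack(
            grid=grid, dates=list(DATES),
            presence=np.full((N_DATES, 10, 40), np.nan),
            fraction=np.full((N_DATES, 10, 40), np.nan),
            tide_at_date=TIDE.copy())
        for r, c in ((2, 10), (2, 11), (3, 10)):
            stack.fraction[:, r, c] = SERIES_A
            stack.presence[:, r, c] = 1.0
        _, report = apply_cascade(stack, distance)
        assert all(n == 0 for n in report.counts().values())

    def test_one_planted_violator_per_rule(self, fixture_stack):
        stack, distance = fixture_stack
        out, report = apply_cascade(stack, distance)
        assert list(report.counts().values()) == [1, 1, 1, 1, 1]
        assert [name for name, _, _ in report.rules] == [
            "distance", "overrange", "prevalence", "tide_correlation",
            "spatial_coherence"]
        assert surviving(out) == {(5, 10), (5, 12), (7, 11)}
        assert report.total_masked() == 5

    def test_cascade_idempotent(self, fixture_stack):
        stack, distance = fixture_stack
        once, _ = apply_cascade(stack, distance)
        twice, report2 = apply_cascade(once, distance)
        np.testing.assert_array_equal(once.presence, twice.presence)
        assert all(n == 0 for n in report2.counts().values())

    def test_independent_rules_commute(self, fixture_stack):
        stack, distance = fixture_stack
        a = mask_by_overrange(mask_by_distance(stack, distance))
        b = mask_by_distance(mask_by_overrange(stack), distance)
        np.testing.assert_array_equal(a.presence, b.presence)

    def test_stricter_parameters_shrink_survivors(self, fixture_stack):
        stack, distance = fixture_stack
        base, _ = apply_cascade(stack, distance)
        strict, _ = apply_cascade(stack, distance,
                                  {"d_max": 400.0, "p_min": 0.10,
                                   "coherence_r_min": 0.95})
        assert surviving(strict) <= surviving(base)

    def test_tide_series_length_mismatch_rejected(self):
        grid = Grid(1, 1, 0.0, 0.0, 30.0)
        with pytest.raises(ValueError, match="length"):
            PixelTimeseriesStack(grid=grid, dates=list(DATES),
                                 presence=np.ones((N_DATES, 1, 1)),
                                 fraction=np.ones((N_DATES, 1, 1)),
                                 tide_at_date=TIDE[:10])

    def test_grid_mismatch_rejected(self, fixture_stack):
        stack, _ = fixture_stack
        other = DistanceField(grid=Grid(2, 2, 0.0, 0.0, 30.0),
                              distance=np.ones((2, 2)))
        with pytest.raises(GeometryError):
            mask_by_distance(stack, other)
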
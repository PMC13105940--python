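import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from geowaz.spatial import (
    great_circle_km,
    hotspot_classify,
    idw_interpolate,
    residual_spatial_pattern,
    spatial_effect_surface,
)
from geowaz.simulate import recovery_scenario, simulate


def idw_by_hand(lon, lat, sources, power):
    """Direct formula evaluation: sum d^-p z / sum d^-p."""
    num = den = 0.0
    for slon, slat, z in sources:
        d = great_circle_km(lon, lat, slon, slat)
        if d == 0:
            return z
        num += d ** (-power) * z
        den += d ** (-power)
    return num / den


class TestIDW:
    def make_sources(self):
        return pd.DataFrame({
            "lon": [36.0, 38.5, 40.0, 42.0, 37.2],
            "lat": [6.0, 8.0, 10.0, 7.5, 12.0],
            "value": [1.0, -0.5, 2.0, 0.3, -1.2],
        })

    def test_exact_at_source_points(self):
        src = self.make_sources()
        grid = idw_interpolate(src, src["lon"].to_numpy(), src["lat"].to_numpy())
        for k in range(len(src)):
            iy = k
            ix = k
            assert grid.values[iy, ix] == src["value"][k]

    def test_equidistant_pair_returns_mean(self):
        src = pd.DataFrame({"lon": [10.0, 10.0], "lat": [5.0, 7.0], "value": [2.0, 4.0]})
        grid = idw_interpolate(src, np.array([10.0]), np.array([6.0]), power=2.0)
        assert grid.values[0, 0] == pytest.approx(3.0, rel=1e-9)

    def test_matches_direct_formula(self):
        src = self.make_sources()
        pts_lon = np.array([36.7, 41.1, 39.3])
        pts_lat = np.array([9.2, 6.3, 11.0])
        grid = idw_interpolate(src, pts_lon, pts_lat, power=2.0)
        sources = list(zip(src["lon"], src["lat"], src["value"]))
        for iy, la in enumerate(pts_lat):
            for ix, lo in enumerate(pts_lon):
                assert grid.values[iy, ix] == pytest.approx(
                    idw_by_hand(lo, la, sources, 2.0), abs=1e-10
                )

    def test_bounds_containment(self):
        src = self.make_sources()
        grid = idw_interpolate(src, np.linspace(34, 46, 20), np.linspace(4, 14, 20))
        assert grid.values.min() >= src["value"].min() - 1e-12
        assert grid.values.max() <= src["value"].max() + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(-5, 5), seed=st.integers(0, 2**31 - 1))
    def test_shift_equivariance(self, shift, seed):
        """Adding a constant to all source values shifts the grid by it."""
        rng = np.random.default_rng(seed)
        src = pd.DataFrame({
            "lon": rng.uniform(34, 46, 6), "lat": rng.uniform(4, 14, 6),
            "value": rng.standard_normal(6),
        })
        glon, glat = np.linspace(34, 46, 5), np.linspace(4, 14, 5)
        g0 = idw_interpolate(src, glon, glat)
        g1 = idw_interpolate(src.assign(value=src["value"] + shift), glon, glat)
        np.testing.assert_allclose(g1.values, g0.values + shift, atol=1e-9)

    def test_conflicting_duplicates_averaged(self, caplog):
        src = pd.DataFrame({"lon": [10.0, 10.0], "lat": [5.0, 5.0], "value": [1.0, 3.0]})
        grid = idw_interpolate(src, np.array([10.0]), np.array([5.0]))
        assert grid.values[0, 0] == pytest.approx(2.0)

    def test_invalid_power_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate(self.make_sources(), np.array([36.0]), np.array([6.0]), power=0.0)


class TestHotspots:
    def test_constant_grid_empty_mask(self):
        src = pd.DataFrame({"lon": [10.0, 12.0], "lat": [5.0, 6.0], "value": [1.0, 1.0]})
        grid = idw_interpolate(src, np.linspace(9, 13, 10), np.linspace(4, 7, 10))
        assert not hotspot_classify(grid).any()

    def test_single_extreme_cell(self):
        import dataclasses

        src = pd.DataFrame({"lon": [10.0], "lat": [5.0], "value": [0.0]})
        grid = idw_interpolate(src, np.linspace(9, 11, 10), np.linspace(4, 6, 10))
        values = np.zeros((10, 10))
        values[3, 7] = 5.0
        grid = dataclasses.replace(grid, values=values)
        mask = hotspot_classify(grid, quantile=0.99)
        assert mask.sum() == 1 and mask[3, 7]

    def test_planted_cluster_recovered(self):
        """A high-severity cluster of sources must dominate the flagged cells."""
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(10):
            lon = rng.uniform(34, 46, 40)
            lat = rng.uniform(4, 14, 40)
            value = rng.normal(0, 0.1, 40)
            inside = (lon < 38) & (lat < 8)  # planted south-west hotspot
            value[inside] += 2.0
            if not inside.any():
                continue
            src = pd.DataFrame({"lon": lon, "lat": lat, "value": value})
            grid = idw_interpolate(src, np.linspace(34, 46, 25), np.linspace(4, 14, 25))
            mask = hotspot_classify(grid, quantile=0.80)
            lon2, lat2 = np.meshgrid(grid.lon, grid.lat)
            flagged_in = mask & (lon2 < 38) & (lat2 < 8)
            if flagged_in.sum() >= 0.5 * mask.sum():
                hits += 1
        assert hits >= 9


class TestSpatialSurfaces:
    def test_all_zero_draws_give_null_classes(self, tiny_fit):
        import dataclasses

        *_, samples = tiny_fit
        zero = dataclasses.replace(samples, f_spat=np.zeros_like(samples.f_spat))
        surf = spatial_effect_surface(zero)
        assert (surf["significance"] == "null").all()
        assert np.allclose(surf["Mean"], 0.0)

    def test_posterior_means_centred(self, recovery_fit):
        *_, samples = recovery_fit
        surf = spatial_effect_surface(samples)
        assert abs(surf["Mean"].mean()) < 1e-8

    def test_elevated_region_flagged_positive(self, recovery_fit):
        """The region with the largest true effect should class positive."""
        scen, data, truth, design, samples = recovery_fit
        surf = spatial_effect_surface(samples)
        top = int(np.argmax(truth.f_spat))
        assert surf["significance"][top] == "positive"

    def test_wider_intervals_move_toward_null(self, recovery_fit):
        """99% intervals can only demote significant regions to null."""
        from geowaz.summarize import flag_significance

        *_, samples = recovery_fit
        draws = samples.f_spat
        for s in range(draws.shape[1]):
            f95 = flag_significance(np.quantile(draws[:, s], 0.025), np.quantile(draws[:, s], 0.975))
            f99 = flag_significance(np.quantile(draws[:, s], 0.005), np.quantile(draws[:, s], 0.995))
            if f95 == "null":
                assert f99 == "null"


class TestResidualSpatialPattern:
    def test_zero_residuals_flat_surface(self):
        out = residual_spatial_pattern(np.zeros(30), np.repeat(np.arange(3), 10), 3)
        np.testing.assert_allclose(out["mean_residual"], 0.0)

    def test_region_means_shrink_with_n(self):
        """CLT scaling: quadrupling n roughly halves the max region mean."""
        rng = np.random.default_rng(1)
        maxima = []
        for n in (2000, 8000):
            reps = []
            for _ in range(20):
                idx = rng.integers(0, 5, n)
                resid = rng.standard_normal(n)
                out = residual_spatial_pattern(resid, idx, 5)
                reps.append(np.abs(out["mean_residual"]).max())
            maxima.append(np.mean(reps))
        assert maxima[1] < 0.75 * maxima[0]

    def test_injected_shift_recovered(self):
        """An unmodelled +0.5 regional shift surfaces in that region's mean
        residual (minus the share absorbed by the intercept)."""
        from geowaz.design import DesignBlocks
        from geowaz.sampler import HyperPriors, MCMCConfig, run_gibbs
        from geowaz.summarize import residual_diagnostics

        rng = np.random.default_rng(5)
        n, S = 2000, 10
        region = rng.integers(0, S, n)
        y = rng.normal(0.0, 1.0, n) + 0.5 * (region == 0)
        design = DesignBlocks(y=y, fixed=np.ones((n, 1)), fixed_names=("intercept",),
                              smooths=(), spatial=None, region_index=None)
        samples = run_gibbs(design, HyperPriors(),
                            MCMCConfig(iterations=600, burnin=100, thin=1, seed=6))
        diag = residual_diagnostics(samples, design)
        out = residual_spatial_pattern(diag["residual"].to_numpy(), region, S)
        expected = 0.5 * (1 - (region == 0).mean())
        assert out["mean_residual"][0] == pytest.approx(expected, abs=0.12)

    def test_low_count_flagged(self):
        out = residual_spatial_pattern(np.ones(12), np.array([0] * 11 + [1]), 2, min_count=5)
        assert not out["low_count"][0]
        assert out["low_count"][1]
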
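"""Spatial-effect surfaces, residual spatial patterns, and IDW hotspots.

The fitted region effects (intrinsic-MRF term) are summarized per region
with a three-class significance label from the 95% credible interval;
residuals are aggregated per region to reveal unmodelled spatial
structure; and predicted underweight severity at cluster locations is
interpolated to a regular lon/lat grid by inverse distance weighting
(IDW) to flag hotspot areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignBlocks
from .sampler import PosteriorSamples
from .summarize import flag_significance

logger = logging.getLogger(__name__)

__all__ = [
    "IDWGrid",
    "spatial_effect_surface",
    "residual_spatial_pattern",
    "idw_interpolate",
    "hotspot_classify",
    "great_circle_km",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in kilometres (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def spatial_effect_surface(samples: PosteriorSamples, levels=(0.025, 0.10, 0.90, 0.975)) -> pd.DataFrame:
    """Per-region posterior summary of the centred spatial effect.

    One row per region: posterior mean, the requested quantiles, and the
    significance class (positive/negative/null from the 95% interval).
    The effects are centred, so the mean over regions of the posterior
    means is ~0; the overall level lives in the intercept.
    """
    if samples.f_spat is None:
        raise ValueError("no spatial term in the posterior samples")
    draws = samples.f_spat
    out = {"Mean": draws.mean(axis=0)}
    for lv in levels:
        out[f"{100 * lv:g}%"] = np.quantile(draws, lv, axis=0)
    frame = pd.DataFrame(out)
    frame["significance"] = [
        flag_significance(lo, hi) for lo, hi in zip(frame["2.5%"], frame["97.5%"])
    ]
    return frame


def residual_spatial_pattern(residuals, region_index, n_regions: int,
                             min_count: int = 10) -> pd.DataFrame:
    """Region-wise mean of posterior-mean residuals.

    Regions with fewer than ``min_count`` observations are flagged as
    unreliable rather than dropped.
    """
    residuals = np.asarray(residuals, dtype=float)
    region_index = np.asarray(region_index, dtype=int)
    if residuals.shape != region_index.shape:
        raise ValueError("residuals and region index must align")
    counts = np.bincount(region_index, minlength=n_regions)
    sums = np.bincount(region_index, weights=residuals, minlength=n_regions)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "mean_residual": means,
        "count": counts,
        "low_count": counts < min_count,
    })


@dataclass(frozen=True)
class IDWGrid:
    """Inverse-distance-weighted interpolation on a regular lon/lat grid."""

    lon: np.ndarray  # grid longitudes (nx,)
    lat: np.ndarray  # grid latitudes (ny,)
    values: np.ndarray  # (ny, nx)
    power: float
    source_lon: np.ndarray
    source_lat: np.ndarray
    source_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        lon2, lat2 = np.meshgrid(self.lon, self.lat)
        return pd.DataFrame({
            "lon": lon2.ravel(), "lat": lat2.ravel(), "value": self.values.ravel(),
        })


def idw_interpolate(sources: pd.DataFrame, grid_lon, grid_lat, power: float = 2.0) -> IDWGrid:
    """Inverse-distance-weighted interpolation of point values to a grid.

    ``sources`` needs columns lon, lat, value. The interpolated value at a
    grid point g is sum_i d_i^-p z_i / sum_i d_i^-p with d_i the
    great-circle distance in km; a grid point coinciding with a source
    returns that source's value exactly. Duplicate source locations with
    conflicting values are averaged with a warning. Every interpolated
    value lies within [min z, max z].
    """
    if power <= 0:
        raise ValueError("IDW power must be > 0")
    src = sources[["lon", "lat", "value"]].copy()
    if len(src) < 1:
        raise ValueError("need at least one source point")
    dup = src.duplicated(subset=["lon", "lat"], keep=False)
    if dup.any():
        if src.groupby(["lon", "lat"])["value"].nunique().gt(1).any():
            logger.warning("duplicate source locations with conflicting values; averaging")
        src = src.groupby(["lon", "lat"], as_index=False)["value"].mean()
    slon = src["lon"].to_numpy()
    slat = src["lat"].to_numpy()
    sval = src["value"].to_numpy()

    grid_lon = np.asarray(grid_lon, dtype=float)
    grid_lat = np.asarray(grid_lat, dtype=float)
    values = np.empty((grid_lat.size, grid_lon.size))
    for iy, la in enumerate(grid_lat):
        d = great_circle_km(grid_lon[:, None], la, slon[None, :], slat[None, :])  # (nx, ns)
        exact = d == 0.0
        with np.errstate(divide="ignore"):
            w = np.where(exact, 0.0, d ** (-power))
        row = np.empty(grid_lon.size)
        has_exact = exact.any(axis=1)
        if has_exact.any():
            row[has_exact] = sval[np.argmin(d[has_exact], axis=1)]
        safe = ~has_exact
        row[safe] = (w[safe] @ sval) / w[safe].sum(axis=1)
        values[iy] = row
    return IDWGrid(grid_lon, grid_lat, values, power, slon, slat, sval)


def hotspot_classify(grid: IDWGrid, quantile: float = 0.80) -> np.ndarray:
    """Boolean hotspot mask: cells strictly above the given grid quantile.

    The default flags the worst quintile of interpolated severity (a
    reporting convention — larger interpolated value = worse). A constant
    grid yields an empty mask.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    threshold = np.quantile(grid.values, quantile)
    return grid.values > threshold
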
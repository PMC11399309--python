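"""Map-vs-map agreement metrics on a common coarse grid.

A predicted trait map is aggregated to the benchmark's resolution by
valid-pixel block means (followed by bilinear alignment if the target grid
is offset), and agreement over jointly valid pixels is summarised by the
ordinary least-squares regression of observed on predicted: R² (squared
Pearson correlation), RRMSE (root-mean-square error as a proportion of the
observed mean), bias ((observed mean − predicted mean) / observed mean) and
the regression slope.  A map pair counts as "in agreement" when R² ≥ 0.13
and the slope lies strictly between 0.5 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .rasters import GridSpec, Raster, block_aggregate


class EvaluationError(ValueError):
    pass


@dataclass
class MapComparison:
    r2: float
    rrmse: float
    bias: float
    slope: float
    intercept: float
    n_pixels: int


DEFAULT_THRESHOLDS = {"r2_min": 0.13, "slope_min": 0.5, "slope_max": 2.0}


def regrid(source: Raster, target: GridSpec,
           min_valid_fraction: float = 0.5,
           method: str = "block-mean") -> Raster:
    """Coarsen ``source`` onto ``target``.

    Default: integer-ratio block-mean aggregation (blocks below the valid
    fine-pixel fraction become missing), then bilinear alignment if the
    aggregated grid is offset from the target.  ``method='literal-bilinear'``
    reproduces a literal bilinear resample at the target centres instead.
    """
    if target.res < source.grid.res - 1e-12:
        raise EvaluationError("target must be coarser than the source grid")
    if method == "literal-bilinear":
        return _bilinear_to(source, target)
    if method != "block-mean":
        raise EvaluationError(f"unknown regrid method {method!r}")
    ratio = target.res / source.grid.res
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise EvaluationError(
            f"target resolution {target.res} is not an integer multiple of "
            f"source {source.grid.res}")
    if factor == 1:
        agg = source
    else:
        vals = block_aggregate(source.values, factor, min_valid_fraction)
        grid = GridSpec(source.grid.west, source.grid.south, target.res,
                        vals.shape[0], vals.shape[1])
        agg = Raster(grid, vals, source.name, source.units, dict(source.meta))
    if agg.grid == target:
        return agg
    return _bilinear_to(agg, target)


def _bilinear_to(source: Raster, target: GridSpec) -> Raster:
    lat = source.grid.lat_centers()[::-1]  # ascending for the interpolator
    lon = source.grid.lon_centers()
    interp = RegularGridInterpolator(
        (lat, lon), source.values[::-1], method="linear",
        bounds_error=False, fill_value=np.nan)
    tlat = target.lat_centers()
    tlon = target.lon_centers()
    pts = np.stack(np.meshgrid(tlat, tlon, indexing="ij"), axis=-1)
    vals = interp(pts.reshape(-1, 2)).reshape(target.shape)
    return Raster(target, vals, source.name, source.units, dict(source.meta))


def compare_maps(predicted: Raster, observed: Raster) -> MapComparison:
    """regression-based agreement metrics over jointly valid pixels.

    The regression direction is fixed: observed is regressed on predicted.
    """
    if predicted.grid != observed.grid:
        raise EvaluationError(
            f"grids differ: predicted {predicted.grid} vs observed "
            f"{observed.grid}")
    p = predicted.values.ravel()
    o = observed.values.ravel()
    ok = np.isfinite(p) & np.isfinite(o)
    n = int(ok.sum())
    if n == 0:
        raise EvaluationError("maps have no jointly valid pixels")
    if n < 3:
        raise EvaluationError(f"need >= 3 jointly valid pixels, got {n}")
    p, o = p[ok], o[ok]
    o_mean = o.mean()
    if o_mean == 0:
        raise EvaluationError("observed mean is zero: rrmse/bias undefined")
    if np.array_equal(p, o):
        # identical maps: the identities hold exactly by definition
        return MapComparison(r2=1.0, rrmse=0.0, bias=0.0, slope=1.0,
                             intercept=0.0, n_pixels=n)
    sp = p.std()
    if sp == 0:
        slope, intercept, r2 = 0.0, float(o_mean), 0.0
    else:
        slope = float(np.cov(p, o, ddof=1)[0, 1] / p.var(ddof=1))
        intercept = float(o_mean - slope * p.mean())
        r = np.corrcoef(p, o)[0, 1] if o.std() > 0 else 0.0
        r2 = float(r ** 2)
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))
    return MapComparison(
        r2=r2,
        rrmse=rmse / float(o_mean),
        bias=float((o_mean - p.mean()) / o_mean),
        slope=slope,
        intercept=intercept,
        n_pixels=n,
    )


def agreement_flags(comparison: MapComparison,
                    thresholds: dict | None = None) -> bool:
    """True iff R² clears the threshold and the slope lies inside the open
    interval (defaults: R² ≥ 0.13, 0.5 < slope < 2)."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    return bool(comparison.r2 >= th["r2_min"]
                and th["slope_min"] < comparison.slope < th["slope_max"])
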
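"""Naturalness filtering, fractional group cover and trait-map prediction.

The land-cover raster (fine resolution) drives two steps of the pipeline:
plots falling on cropland, urban, bare, water or permanent snow/ice pixels
are removed as "unnatural vegetation", and each natural sub-class receives
the componentwise median group coverage of the all-vascular plots observed
on it.  Replacing sub-class codes by those medians and block-averaging to
the coarse (0.1°-style) grid yields the fractional cover of the three plant
groups.  Trait maps are produced by evaluating a fitted additive model on
co-registered bioclim (and optionally cover) rasters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rasters import GridSpec, LandCoverRaster, Raster, block_aggregate
from .traits import GROUPS, PlotComposition, group_cover_table
from .trait_models import GamFit

logger = logging.getLogger(__name__)


class GeoError(ValueError):
    pass


def filter_natural_plots(plots: list[PlotComposition],
                         landcover: LandCoverRaster) -> list[PlotComposition]:
    """Keep plots whose fine land-cover pixel is a natural sub-class.

    Plots outside the raster extent are excluded with a warning; removal
    counts are logged.
    """
    natural = landcover.table["natural"]
    kept: list[PlotComposition] = []
    n_unnatural = n_outside = 0
    for plot in plots:
        if not bool(landcover.grid.contains(plot.lon, plot.lat)):
            n_outside += 1
            continue
        row, col = landcover.grid.index_of(plot.lon, plot.lat)
        if bool(natural.loc[int(landcover.codes[row, col])]):
            kept.append(plot)
        else:
            n_unnatural += 1
    if n_outside:
        logger.warning("%d plot(s) outside land-cover extent excluded",
                       n_outside)
    logger.info("removed %d unnatural plot(s), kept %d", n_unnatural,
                len(kept))
    return kept


def subclass_group_cover(plots: list[PlotComposition],
                         species: pd.DataFrame,
                         landcover: LandCoverRaster) -> pd.DataFrame:
    """Median group cover per natural land-cover sub-class.

    Only plots with ``record_scope == 'all_vascular'`` contribute.  The
    componentwise median triple is renormalised to sum to one.  Unnatural
    sub-classes, and sub-classes with no qualifying plot, are missing.
    """
    av = [p for p in plots if p.record_scope == "all_vascular"]
    covers = group_cover_table(av, species)
    rows, cols = landcover.grid.index_of(
        np.array([p.lon for p in av]), np.array([p.lat for p in av]))
    codes = pd.Series(landcover.codes[rows, cols],
                      index=[p.plot_id for p in av])
    codes = codes.loc[covers.index]

    out = pd.DataFrame(np.nan, index=landcover.table.index, columns=GROUPS)
    for code, natural in landcover.table["natural"].items():
        if not natural:
            continue
        sel = covers.loc[codes[codes == code].index]
        if sel.empty:
            logger.warning("sub-class %s has no all-vascular plots", code)
            continue
        med = sel.median(axis=0).to_numpy()
        total = med.sum()
        if total > 0:
            out.loc[code] = med / total
    return out


def build_group_cover_raster(landcover: LandCoverRaster,
                             subclass_table: pd.DataFrame,
                             target_resolution: float) -> dict:
    """Fractional cover of the three groups at the target resolution.

    Each fine pixel maps to its sub-class triple; coarse pixels are the
    block mean over valid fine pixels, missing where none is valid.
    Returns ``{'grid': GridSpec, group: 2-D array, ...}``.
    """
    ratio = target_resolution / landcover.grid.res
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise GeoError(
            f"fine resolution {landcover.grid.res} does not divide target "
            f"{target_resolution}")
    unmapped = sorted(set(np.unique(landcover.codes))
                      - set(subclass_table.index))
    if unmapped:
        raise GeoError(f"codes not in sub-class table: {unmapped}")

    coarse = GridSpec(landcover.grid.west, landcover.grid.south,
                      target_resolution, landcover.grid.ny // factor,
                      landcover.grid.nx // factor)
    out: dict = {"grid": coarse}
    lut = {g: subclass_table[g].to_dict() for g in GROUPS}
    for g in GROUPS:
        fine = np.full(landcover.grid.shape, np.nan)
        for code, val in lut[g].items():
            if np.isfinite(val):
                fine[landcover.codes == code] = val
        out[g] = block_aggregate(fine, factor)
    return out


def predict_trait_map(fit: GamFit, bioclim_rasters: dict[str, Raster],
                      cover_rasters: dict[str, Raster] | None = None,
                      hull_mask: np.ndarray | None = None) -> Raster:
    """Evaluate a fitted trait model per pixel.

    ``bioclim_rasters`` (and ``cover_rasters`` for interaction fits) must be
    co-registered.  Missing values in any input band propagate; the optional
    ``hull_mask`` (True = inside the training climate hull) masks
    extrapolated pixels.  Output is on the natural-log trait scale.
    """
    rasters = dict(bioclim_rasters)
    if cover_rasters:
        rasters.update(cover_rasters)
    grids = {name: r.grid for name, r in rasters.items()}
    first = next(iter(grids.values()))
    for name, g in grids.items():
        if g != first:
            raise GeoError(
                f"raster grids are not co-registered: {name} has {g}, "
                f"expected {first}")
    need = [t.spec.var for t in fit.terms]
    need += [t.spec.by for t in fit.terms if t.spec.by is not None]
    need = list(dict.fromkeys(need))
    missing = [v for v in need if v not in rasters]
    if missing:
        raise GeoError(f"fit needs predictor rasters {missing}")
    frame = pd.DataFrame({v: rasters[v].values.ravel() for v in need})
    pred = fit.predict(frame).reshape(first.shape)
    if hull_mask is not None:
        pred = np.where(hull_mask, pred, np.nan)
    return Raster(first, pred, name=fit.spec.response, units="ln(native)",
                  meta={"model": "gam", "terms": [t.spec.label
                                                 for t in fit.terms]})
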
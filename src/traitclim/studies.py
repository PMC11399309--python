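"""Canonical synthetic recovery studies.

Each function runs one fixed study design on seeded synthetic data and
returns the measured quantities; they are the single source for both the
test suite's recovery checks and the reproduction script, so the reported
numbers always come from the same code path as the tested ones.

Study conditions (fixed by design, see docs/methods.md):

* Planted-dimension study: 1000 plots, 1500 species, climate effects off,
  no mixed growth form, mean-of-logs CWMs — the conditions under which the
  two-factor correlation structure is analytic.
* GAM recovery: n = 2000 plot-like samples, additive signal in ln MI and
  MGST, noise sd 0.2.
* Importance recovery: three orthogonalised predictors with planted
  variance contributions 50/30/20%, n = 2000.
* End-to-end map recovery: default 40 × 40-pixel world, 3000 plots, the
  strong-signal trait (plant height) within the woody-evergreen group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (bioclim, evaluation, geospatial, ordination, synthetic_data,
               trait_models, traits)
from .rasters import Raster


def _subseed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]
               % (2 ** 31))


def planted_dimension_study(seed: int) -> dict:
    """PCA recovery of the two planted trait dimensions per plant group."""
    cfg = synthetic_data.WorldConfig(
        seed=_subseed(seed, 1), n_plots=1000, n_species=1500,
        climate_effects={}, mixed_fraction=0.0)
    world = synthetic_data.generate_world(cfg)
    out: dict = {}
    for group in traits.GROUPS:
        matrix = traits.community_weighted_means(
            world.plots, world.species_table, group=group,
            log_first=True).dropna()
        res = ordination.pca(traits.standardize(matrix))
        planted = synthetic_data.planted_shared_variance_fraction(
            cfg.latent_loadings[group], cfg.noise_sd)
        r_analytic = synthetic_data.planted_correlation_matrix(
            cfg.latent_loadings[group], cfg.noise_sd)
        _, eigvec = np.linalg.eigh(r_analytic)
        ref = eigvec[:, ::-1][:, :2]
        cosines = [
            float(abs(res.loadings.to_numpy()[:, a] @ ref[:, a]))
            for a in range(2)
        ]
        out[group] = {
            "top2_fraction": float(res.variance_fraction[:2].sum()),
            "planted_fraction": float(planted),
            "min_cosine": min(cosines),
            "n_plots": int(matrix.shape[0]),
        }
    return out


def gam_recovery_study(seed: int, n: int = 2000,
                       noise_sd: float = 0.2) -> dict:
    """Additive-surface recovery: CWM = f(ln MI) + g(MGST) + noise."""
    rng = np.random.default_rng(_subseed(seed, 2))
    ln_mi = rng.uniform(-2.0, 0.5, n)
    mgst = rng.uniform(5.0, 30.0, n)
    f = 0.7 * np.tanh(1.5 * ln_mi) + 0.3 * ln_mi
    g = mgst / 15.0 + 0.4 * np.sin(mgst / 4.0)
    y = f + g + rng.normal(0.0, noise_sd, n)
    frame = pd.DataFrame({"ln_mi": ln_mi, "mgst": mgst, "cwm": y})
    spec = trait_models.GamSpec(
        "cwm", [trait_models.SmoothTerm("ln_mi"),
                trait_models.SmoothTerm("mgst")])
    fit = trait_models.fit_gam(frame, "cwm", spec)
    signal_var = float(np.var(f + g))
    planted_r2 = signal_var / (signal_var + noise_sd ** 2)
    pf = fit.partial_effect("ln_mi", ln_mi)
    pg = fit.partial_effect("mgst", mgst)
    return {
        "deviance_explained": float(fit.deviance_explained),
        "adjusted_r2": float(fit.adjusted_r2),
        "planted_r2": float(planted_r2),
        "partial_corr_f": float(np.corrcoef(pf, f)[0, 1]),
        "partial_corr_g": float(np.corrcoef(pg, g)[0, 1]),
        "n": n,
    }


def importance_recovery_study(seed: int, n: int = 2000) -> dict:
    """Shapley share recovery for planted 50/30/20 variance contributions."""
    rng = np.random.default_rng(_subseed(seed, 3))
    q, _ = np.linalg.qr(rng.standard_normal((n, 3)))
    z = q * np.sqrt(n)  # exactly orthogonal, ~unit variance
    contributions = (0.5, 0.3, 0.2)
    y = sum(np.sqrt(c) * z[:, i] for i, c in enumerate(contributions))
    frame = pd.DataFrame({"ln_mi": z[:, 0], "mtco": z[:, 1],
                          "mgst": z[:, 2], "cwm": y})
    imp = trait_models.relative_importance(
        frame, "cwm", ("ln_mi", "mtco", "mgst"))
    return {
        "shares": imp.shares,
        "planted": dict(zip(("ln_mi", "mtco", "mgst"),
                            (50.0, 30.0, 20.0))),
        "full_deviance_explained": float(imp.full_deviance_explained),
        "n": n,
    }


def end_to_end_study(seed: int, n_plots: int = 3000,
                     trait: str = "H", group: str = "evergreen") -> dict:
    """Full pipeline: world -> natural plots -> CWMs -> bioclim -> GAM ->
    trait raster -> agreement against the stored generative truth."""
    cfg = synthetic_data.WorldConfig(seed=_subseed(seed, 4),
                                     n_plots=n_plots, n_species=1500)
    world = synthetic_data.generate_world(cfg)
    natural = geospatial.filter_natural_plots(world.plots, world.landcover)
    matrix = traits.community_weighted_means(
        natural, world.species_table, group=group)
    grid = world.climate.grid
    lon = np.array([p.lon for p in natural])
    lat = np.array([p.lat for p in natural])
    row, col = grid.index_of(lon, lat)
    frame = pd.DataFrame({
        trait: matrix[trait].to_numpy(),
        "ln_mi": world.bioclim_maps["ln_mi"][row, col],
        "mtco": world.bioclim_maps["mtco"][row, col],
        "mgst": world.bioclim_maps["mgst"][row, col],
    })
    spec = trait_models.GamSpec(
        trait, [trait_models.SmoothTerm(v)
                for v in ("ln_mi", "mtco", "mgst")])
    fit = trait_models.fit_gam(frame, trait, spec)
    rasters = {name: Raster(grid, world.bioclim_maps[name])
               for name in ("ln_mi", "mtco", "mgst")}
    predicted = geospatial.predict_trait_map(fit, rasters)
    truth = Raster(grid, world.truth.effect_surfaces[trait][group])
    ok = np.isfinite(predicted.values) & np.isfinite(truth.values)
    pearson_r = float(np.corrcoef(predicted.values[ok],
                                  truth.values[ok])[0, 1])
    comparison = evaluation.compare_maps(predicted, truth)
    return {
        "pearson_r": pearson_r,
        "comparison": comparison,
        "agreement": evaluation.agreement_flags(comparison),
        "deviance_explained": float(fit.deviance_explained),
        "n_plots": len(natural),
        "n_pixels": int(ok.sum()),
    }
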
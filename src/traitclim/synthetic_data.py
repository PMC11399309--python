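"""Seeded synthetic world with recoverable planted structure.

The generator emulates the statistical shape of the real inputs of a global
trait-climate analysis — vegetation plots with taxon relative covers summing
to one, a species-level table of six major traits, monthly climate fields on
a lon/lat grid, and a land-cover mosaic with natural and unnatural
sub-classes — while keeping every generative quantity on record so that
downstream stages can be tested against ground truth.

Planted structure:

* Species log-traits are ``loadings @ factors`` with two orthogonal latent
  factors per species (a size dimension and a leaf-economics dimension),
  plus a group-specific climate effect evaluated at the species' home
  location, plus Gaussian noise.  Orthogonality is enforced in the loadings,
  not the factor scores, which makes ordination-recovery targets analytic.
* Plots sample species through a spatial locality kernel and a land-cover
  driven group mixture, so community-weighted means carry the planted
  trait-climate signal and the land-cover sub-classes carry distinct group
  coverages.
* The grid is an abstract climate gradient: the southern edge plays the
  tropics (weak seasonality), the northern edge the high latitudes (strong
  seasonality, cold winters); moisture increases from west to east.

Everything is deterministic for a fixed ``WorldConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioclim as bc
from .rasters import (GridSpec, LandCoverRaster, MonthlyClimateRaster, Raster,
                      write_asc)
from .traits import GROUPS, MAJOR_TRAITS, PlotComposition, classify_groups

# --------------------------------------------------------------------------
# generative constants

#: growth form used for "pure" members of each group
GROUP_FORMS = {"nonwoody": "herb", "deciduous": "tree-deciduous",
               "evergreen": "tree-evergreen"}
MINORITY_FORM = "fern"
MIXED_FORM = "shrub-intermediate"
MIXED_FORM_PROBS = np.array([0.5, 0.25, 0.25])

#: baseline log-trait values, ln(native units): LA mm2, LMA kg/m2,
#: Narea g/m2, SSD g/cm3, H m, DM mg
BASE_LOG_TRAIT = {"LA": 6.2, "LMA": -2.5, "Narea": 0.4, "SSD": -0.7,
                  "H": 0.0, "DM": 0.0}
GROUP_LOG_OFFSET = {
    "nonwoody": {"H": -0.5, "DM": -0.3},
    "deciduous": {"H": 2.2, "DM": 1.2},
    "evergreen": {"H": 2.2, "DM": 1.2},
}

#: latent loadings (rows = MAJOR_TRAITS, columns = size, LES); the second
#: column is orthogonalised against the first at config construction
DEFAULT_LOADINGS = {
    "nonwoody": np.array([
        [0.45, 0.00], [0.00, 0.40], [0.00, 0.30],
        [0.00, 0.20], [0.85, 0.00], [0.75, 0.00]]),
    "deciduous": np.array([
        [0.35, 0.00], [0.00, 0.60], [0.00, 0.50],
        [0.20, 0.20], [0.80, 0.00], [0.70, 0.00]]),
    "evergreen": np.array([
        [0.35, 0.00], [0.00, 0.60], [0.00, 0.50],
        [0.30, 0.00], [0.80, 0.00], [0.70, 0.00]]),
}

#: climate-effect coefficients per trait and group, applied to the shape
#: functions (ln MI, MTCO/10, MGST/10); the H signal is strong and identical
#: across groups, which makes it the map-recovery reference trait
DEFAULT_CLIMATE_EFFECTS = {
    "LA": {"nonwoody": (0.70, 0.10, 0.20), "deciduous": (0.20, 0.40, 0.30),
           "evergreen": (0.20, 0.50, 0.40)},
    "LMA": {"nonwoody": (-0.50, 0.00, -0.30), "deciduous": (-0.50, -0.30, 0.00),
            "evergreen": (-0.60, 0.20, 0.10)},
    "Narea": {"nonwoody": (-0.45, 0.00, -0.15), "deciduous": (-0.45, -0.20, 0.00),
              "evergreen": (-0.50, 0.15, 0.10)},
    "SSD": {"nonwoody": (-0.40, 0.00, 0.30), "deciduous": (-0.30, 0.10, 0.30),
            "evergreen": (-0.10, 0.20, 0.30)},
    "H": {"nonwoody": (0.50, 0.10, 0.80), "deciduous": (0.50, 0.10, 0.80),
          "evergreen": (0.50, 0.10, 0.80)},
    "DM": {"nonwoody": (0.30, 0.10, 0.60), "deciduous": (0.30, 0.10, 0.60),
           "evergreen": (0.30, 0.10, 0.60)},
}

#: generative group-cover mixture per natural land-cover sub-class code
SUBCLASS_GROUP_MIX = {
    50: (0.10, 0.10, 0.80),   # broadleaf evergreen forest
    60: (0.15, 0.70, 0.15),   # broadleaf deciduous forest
    70: (0.10, 0.15, 0.75),   # needleleaf evergreen forest
    80: (0.10, 0.65, 0.25),   # needleleaf deciduous forest
    100: (0.30, 0.35, 0.35),  # mosaic tree/shrub
    110: (0.55, 0.25, 0.20),  # mosaic herbaceous
    120: (0.35, 0.30, 0.35),  # shrubland
    130: (0.85, 0.10, 0.05),  # grassland
}
UNNATURAL_CODES = (10, 20, 190, 200, 210, 220)

LANDCOVER_TABLE = pd.DataFrame(
    [
        (10, "cropland", "cropland rainfed", False),
        (20, "cropland", "cropland irrigated", False),
        (50, "forest", "broadleaf evergreen forest", True),
        (60, "forest", "broadleaf deciduous forest", True),
        (70, "forest", "needleleaf evergreen forest", True),
        (80, "forest", "needleleaf deciduous forest", True),
        (100, "mosaic", "mosaic tree and shrub", True),
        (110, "mosaic", "mosaic herbaceous", True),
        (120, "shrubland", "shrubland", True),
        (130, "grassland", "grassland", True),
        (190, "urban", "urban", False),
        (200, "bare", "bare areas", False),
        (210, "water", "water bodies", False),
        (220, "snow_ice", "permanent snow and ice", False),
    ],
    columns=["code", "class_name", "subclass_name", "natural"],
).set_index("code")


def climate_effect_shapes(ln_mi, mtco, mgst):
    """The three shape functions climate effects are built from."""
    return (np.asarray(ln_mi, dtype=float),
            np.asarray(mtco, dtype=float) / 10.0,
            np.asarray(mgst, dtype=float) / 10.0)


class ConfigError(ValueError):
    pass


def _orthogonalize(loadings: np.ndarray) -> np.ndarray:
    load = np.array(loadings, dtype=float)
    if load.shape != (6, 2):
        raise ConfigError(f"loadings must be 6x2, got {load.shape}")
    a, b = load[:, 0], load[:, 1]
    na = a @ a
    if na > 0:
        b = b - (a @ b) / na * a
    out = np.column_stack([a, b])
    return out


@dataclass
class WorldConfig:
    seed: int = 0
    n_species: int = 600
    n_plots: int = 1000
    grid_extent: tuple[float, float, float, float] = (-2.0, -2.0, 2.0, 2.0)
    grid_resolution: float = 0.1
    landcover_refinement: int = 4
    group_mix: tuple[float, float, float] = (0.45, 0.30, 0.25)
    latent_loadings: dict[str, np.ndarray] | None = None
    climate_effects: dict | None = None
    noise_sd: float = 0.2
    unnatural_fraction: float = 0.10
    richness: tuple[int, int] = (5, 25)
    locality: float = 0.08
    minority_fraction: float = 0.04
    mixed_fraction: float = 0.05
    scope_fractions: tuple[float, float, float] = (0.5, 0.4, 0.1)
    # (all_vascular, unspecified, partial)

    def __post_init__(self) -> None:
        if self.n_species <= 0 or self.n_plots <= 0:
            raise ConfigError("species and plot counts must be positive")
        if self.grid_resolution <= 0:
            raise ConfigError("grid resolution must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 <= self.unnatural_fraction <= 1:
            raise ConfigError("unnatural_fraction must be in [0, 1]")
        if abs(sum(self.group_mix) - 1.0) > 1e-12:
            raise ConfigError("group_mix must sum to 1")
        if self.landcover_refinement < 1:
            raise ConfigError("landcover_refinement must be >= 1")
        w, s, e, n = self.grid_extent
        if e <= w or n <= s:
            raise ConfigError("grid extent is empty")
        if self.latent_loadings is None:
            self.latent_loadings = {g: v.copy()
                                    for g, v in DEFAULT_LOADINGS.items()}
        self.latent_loadings = {
            g: _orthogonalize(v) for g, v in self.latent_loadings.items()
        }
        if self.climate_effects is None:
            self.climate_effects = {
                t: dict(v) for t, v in DEFAULT_CLIMATE_EFFECTS.items()
            }

    def grid(self) -> GridSpec:
        w, s, e, n = self.grid_extent
        nx = int(round((e - w) / self.grid_resolution))
        ny = int(round((n - s) / self.grid_resolution))
        return GridSpec(w, s, self.grid_resolution, ny, nx)

    def effect(self, trait: str, group: str, ln_mi, mtco, mgst) -> np.ndarray:
        """Generative climate effect for one trait/group (log scale)."""
        coeffs = self.climate_effects.get(trait, {}).get(group)
        shapes = climate_effect_shapes(ln_mi, mtco, mgst)
        if coeffs is None:
            return np.zeros(np.broadcast(*shapes).shape)
        return sum(c * s for c, s in zip(coeffs, shapes))


@dataclass
class WorldTruth:
    """Generative ground truth kept for recovery tests."""

    loadings: dict[str, np.ndarray]
    species_factors: pd.DataFrame
    species_log_noisefree: pd.DataFrame
    effect_surfaces: dict[str, dict[str, np.ndarray]]  # trait -> group|'all'
    plot_cwm: dict[str, pd.DataFrame]                  # group|'all'
    importance_shares: pd.DataFrame                    # (group, trait) x 3
    pixel_group_mix: np.ndarray                        # (3, ny, nx), NaN unnatural


@dataclass
class SyntheticWorld:
    config: WorldConfig
    species_table: pd.DataFrame
    plots: list[PlotComposition]
    climate: MonthlyClimateRaster
    landcover: LandCoverRaster
    bioclim_maps: dict[str, np.ndarray]
    truth: WorldTruth


# --------------------------------------------------------------------------
# climate

def generate_monthly_climate(config: WorldConfig) -> MonthlyClimateRaster:
    """Smooth synthetic monthly climate on the coarse grid.

    Temperature has a seasonal cycle whose amplitude grows from the southern
    ("equatorial") to the northern ("polar") edge; precipitation is
    non-negative with a west-east moisture gradient; shortwave radiation
    follows the temperature season.
    """
    grid = config.grid()
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    w, s, e, n = config.grid_extent
    u = (lon[None, :] - w) / (e - w)          # 0 west .. 1 east
    v = (lat[:, None] - s) / (n - s)          # 0 south .. 1 north
    months = np.arange(12)
    season = np.cos(2 * np.pi * (months + 0.5 - 7.0) / 12.0)  # peak in July

    t_mean = 27.0 - 32.0 * v + 2.0 * np.sin(2 * np.pi * u)
    t_amp = 2.0 + 18.0 * v
    tas = t_mean[None] + t_amp[None] * season[:, None, None]

    pr_annual = 1700.0 * (0.10 + 0.90 * u) * (1.0 - 0.45 * v) + 30.0
    pr_season = 1.0 + 0.6 * np.sin(2 * np.pi * (months[:, None, None] + 0.5)
                                   / 12.0 + 2 * np.pi * u[None])
    pr = np.clip(pr_annual[None] / 12.0 * pr_season, 0.0, None)

    srad_mean = 6.0e5 * (1.0 - 0.35 * v) + 0.0 * u
    srad = np.clip(
        srad_mean[None] * (1.0 + (0.15 + 0.75 * v[None]) * season[:, None, None]),
        0.0, None)
    return MonthlyClimateRaster(grid=grid, tas=tas, pr=pr, srad=srad)


def bioclim_from_climate(climate: MonthlyClimateRaster) -> dict[str, np.ndarray]:
    """(ln MI, MTCO, MGST) maps on the climate grid."""
    mc = bc.MonthlyClimate(tas=climate.tas, pr=climate.pr, srad=climate.srad)
    ln_mi, mtco, mgst = bc.bioclim_triple(mc)
    climate.pet = mc.pet
    return {"ln_mi": ln_mi, "mtco": mtco, "mgst": mgst}


# --------------------------------------------------------------------------
# land cover

def generate_landcover(config: WorldConfig) -> LandCoverRaster:
    """Sub-class mosaic on the fine grid.

    Each fine pixel is unnatural with probability ``unnatural_fraction``
    (iid), natural pixels receive a sub-class from smooth climate-dependent
    propensities plus noise, so sub-classes form a loose geographic mosaic.
    """
    rng = np.random.default_rng([config.seed, 1])
    fine = config.grid().refine(config.landcover_refinement)
    lon = fine.lon_centers()
    lat = fine.lat_centers()
    w, s, e, n = config.grid_extent
    u = np.broadcast_to((lon[None, :] - w) / (e - w), fine.shape)
    v = np.broadcast_to((lat[:, None] - s) / (n - s), fine.shape)

    codes = np.empty(fine.shape, dtype=int)
    unnatural = rng.random(fine.shape) < config.unnatural_fraction
    codes[unnatural] = rng.choice(UNNATURAL_CODES, size=int(unnatural.sum()))

    natural_codes = np.array(sorted(SUBCLASS_GROUP_MIX))
    # propensity scores: forests in the wet east, evergreen toward the warm
    # south, grassland in the dry west
    scores = {
        50: 1.5 * u + 1.2 * (1 - v),
        60: 1.5 * u + 1.2 * np.minimum(v, 1 - v) * 2,
        70: 1.2 * u + 1.4 * v,
        80: 1.0 * u + 1.6 * v,
        100: 0.8 + 0.2 * u,
        110: 0.8 + 0.2 * (1 - u),
        120: 1.3 * (1 - u) + 0.4 * (1 - v),
        130: 1.6 * (1 - u) + 0.3 * v,
    }
    stack = np.stack([scores[c] for c in natural_codes])
    gumbel = rng.gumbel(size=stack.shape) * 0.4
    pick = np.argmax(stack + gumbel, axis=0)
    codes[~unnatural] = natural_codes[pick[~unnatural]]
    return LandCoverRaster(grid=fine, codes=codes, table=LANDCOVER_TABLE.copy())


def pixel_group_mixture(landcover: LandCoverRaster, factor: int) -> np.ndarray:
    """Generative group-cover mixture block-averaged to the coarse grid,
    NaN where a coarse pixel has no natural fine pixel."""
    from .rasters import block_aggregate

    fine = np.full((3,) + landcover.grid.shape, np.nan)
    for code, mix in SUBCLASS_GROUP_MIX.items():
        sel = landcover.codes == code
        for g in range(3):
            fine[g][sel] = mix[g]
    return np.stack([block_aggregate(fine[g], factor) for g in range(3)])


# --------------------------------------------------------------------------
# world

def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world; see the module docstring."""
    grid = config.grid()
    climate = generate_monthly_climate(config)
    landcover = generate_landcover(config)
    bioclim_maps = bioclim_from_climate(climate)

    species = _generate_species(config, grid, bioclim_maps)
    plots = _generate_plots(config, grid, landcover, species)
    truth = _build_truth(config, grid, landcover, bioclim_maps,
                         species, plots)
    return SyntheticWorld(config=config, species_table=species, plots=plots,
                          climate=climate, landcover=landcover,
                          bioclim_maps=bioclim_maps, truth=truth)


def _generate_species(config: WorldConfig, grid: GridSpec,
                      bmaps: dict[str, np.ndarray]) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_species
    w, s, e, nn = config.grid_extent

    cat = rng.random(n)
    is_minor = cat < config.minority_fraction
    is_mixed = (~is_minor) & (cat < config.minority_fraction
                              + config.mixed_fraction)
    group_idx = rng.choice(3, size=n, p=list(config.group_mix))
    group_idx[is_mixed] = rng.choice(3, size=int(is_mixed.sum()),
                                     p=MIXED_FORM_PROBS)
    groups = np.array(GROUPS)[group_idx]
    forms = np.array([GROUP_FORMS[g] for g in groups], dtype=object)
    forms[is_mixed] = MIXED_FORM
    forms[is_minor] = MINORITY_FORM

    home_lon = rng.uniform(w, e, size=n)
    home_lat = rng.uniform(s, nn, size=n)
    row, col = grid.index_of(home_lon, home_lat)
    factors = rng.standard_normal((n, 2))
    noise = rng.standard_normal((n, 6)) * config.noise_sd

    log_nf = np.empty((n, 6))
    for i in range(n):
        g = groups[i]
        load = config.latent_loadings[g]
        base = np.array([
            BASE_LOG_TRAIT[t] + GROUP_LOG_OFFSET[g].get(t, 0.0)
            for t in MAJOR_TRAITS
        ])
        eff = np.array([
            config.effect(t, g,
                          bmaps["ln_mi"][row[i], col[i]],
                          bmaps["mtco"][row[i], col[i]],
                          bmaps["mgst"][row[i], col[i]])
            for t in MAJOR_TRAITS
        ], dtype=float)
        log_nf[i] = base + load @ factors[i] + eff
    log_real = log_nf + noise

    taxa = [f"sp{i:05d}" for i in range(n)]
    table = pd.DataFrame({"growth_form": forms, "group": groups,
                          "home_lon": home_lon, "home_lat": home_lat},
                         index=pd.Index(taxa, name="taxon"))
    for j, t in enumerate(MAJOR_TRAITS):
        table[t] = np.exp(log_real[:, j])
    table = classify_groups(table)
    table.attrs["log_noisefree"] = pd.DataFrame(
        log_nf, index=table.index, columns=list(MAJOR_TRAITS))
    table.attrs["factors"] = pd.DataFrame(
        factors, index=table.index, columns=["size", "les"])
    return table


def _generate_plots(config: WorldConfig, grid: GridSpec,
                    landcover: LandCoverRaster,
                    species: pd.DataFrame) -> list[PlotComposition]:
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_plots
    w, s, e, nn = config.grid_extent
    lon = rng.uniform(w, e, size=n)
    lat = rng.uniform(s, nn, size=n)
    frow, fcol = landcover.grid.index_of(lon, lat)
    plot_codes = landcover.codes[frow, fcol]
    natural = landcover.table.loc[plot_codes, "natural"].to_numpy()

    sp_lon = species["home_lon"].to_numpy()
    sp_lat = species["home_lat"].to_numpy()
    sp_group_idx = np.array([GROUPS.index(g) for g in species["group"]])
    omitted = species["omitted"].to_numpy()
    taxa = np.array(species.index)

    scopes = rng.choice(["all_vascular", "unspecified", "partial"],
                        size=n, p=list(config.scope_fractions))
    ell = config.locality
    plots: list[PlotComposition] = []
    for i in range(n):
        mix = np.array(SUBCLASS_GROUP_MIX.get(plot_codes[i],
                                              (1 / 3, 1 / 3, 1 / 3)))
        du = (sp_lon - lon[i]) / (e - w)
        dv = (sp_lat - lat[i]) / (nn - s)
        kernel = np.exp(-0.5 * (du ** 2 + dv ** 2) / ell ** 2)
        weight = kernel * (mix[sp_group_idx] + 0.02)
        weight[omitted] = kernel[omitted] * 0.02
        total = weight.sum()
        if total <= 0:
            weight = np.ones_like(weight)
            total = weight.sum()
        richness = int(rng.integers(config.richness[0],
                                    config.richness[1] + 1))
        richness = min(richness, len(taxa))
        chosen = rng.choice(len(taxa), size=richness, replace=False,
                            p=weight / total)
        covers = rng.dirichlet(np.ones(richness))
        plots.append(PlotComposition(
            plot_id=f"plot{i:05d}", lon=float(lon[i]), lat=float(lat[i]),
            entries=list(zip(taxa[chosen], covers.astype(float))),
            record_scope=str(scopes[i]), natural=bool(natural[i]),
        ))
    return plots


def _build_truth(config: WorldConfig, grid: GridSpec,
                 landcover: LandCoverRaster, bmaps: dict[str, np.ndarray],
                 species: pd.DataFrame,
                 plots: list[PlotComposition]) -> WorldTruth:
    pix_mix = pixel_group_mixture(landcover, config.landcover_refinement)
    effect_surfaces: dict[str, dict[str, np.ndarray]] = {}
    for t in MAJOR_TRAITS:
        per_group = {
            g: config.effect(t, g, bmaps["ln_mi"], bmaps["mtco"],
                             bmaps["mgst"])
            for g in GROUPS
        }
        per_group["all"] = sum(
            pix_mix[k] * per_group[g] for k, g in enumerate(GROUPS)
        )
        effect_surfaces[t] = per_group

    log_nf = species.attrs["log_noisefree"]
    pos = {t: i for i, t in enumerate(species.index)}
    probs_arr = species[[f"p_{g}" for g in GROUPS]].to_numpy(dtype=float)
    vals_all = np.exp(log_nf.to_numpy(dtype=float))
    plot_idx = [np.array([pos[t] for t, _ in p.entries]) for p in plots]
    plot_rc = [np.array([c for _, c in p.entries]) for p in plots]
    plot_cwm: dict[str, pd.DataFrame] = {}
    for label in GROUPS + ("all",):
        pvec = (probs_arr.sum(axis=1) if label == "all"
                else probs_arr[:, GROUPS.index(label)])
        rows = np.full((len(plots), len(MAJOR_TRAITS)), np.nan)
        for i in range(len(plots)):
            wvec = plot_rc[i] * pvec[plot_idx[i]]
            ok = wvec > 0
            if not np.any(ok):
                continue
            wj = wvec[ok] / wvec[ok].sum()
            rows[i] = np.log(wj @ vals_all[plot_idx[i]][ok])
        plot_cwm[label] = pd.DataFrame(
            rows, index=pd.Index([p.plot_id for p in plots], name="plot_id"),
            columns=list(MAJOR_TRAITS))

    # generative importance shares: variance of each effect component over
    # the natural pixels, as a fraction of the summed component variances
    shares = {}
    natural_mask = np.isfinite(pix_mix[0])
    shapes = climate_effect_shapes(bmaps["ln_mi"], bmaps["mtco"],
                                   bmaps["mgst"])
    for t in MAJOR_TRAITS:
        for g in GROUPS:
            coeffs = config.climate_effects.get(t, {}).get(g, (0.0, 0.0, 0.0))
            var = np.array([
                np.nanvar((c * s)[natural_mask]) for c, s in zip(coeffs, shapes)
            ])
            tot = var.sum()
            shares[(g, t)] = var / tot * 100.0 if tot > 0 else var * np.nan
    importance = pd.DataFrame(
        shares, index=["ln_mi", "mtco", "mgst"]).T
    importance.index.names = ["group", "trait"]

    return WorldTruth(
        loadings={g: v.copy() for g, v in config.latent_loadings.items()},
        species_factors=species.attrs["factors"],
        species_log_noisefree=log_nf,
        effect_surfaces=effect_surfaces,
        plot_cwm=plot_cwm,
        importance_shares=importance,
        pixel_group_mix=pix_mix,
    )


# --------------------------------------------------------------------------
# analytic oracles for the planted structure

def planted_correlation_matrix(loadings: np.ndarray,
                               noise_sd: float) -> np.ndarray:
    """Correlation matrix implied by the two-factor model
    ``x = L f + eps`` with ``f ~ N(0, I)`` and isotropic noise.

    Community averaging rescales the latent and noise variances by the same
    effective factor (the expected sum of squared weights), which cancels in
    the correlation, so this matrix is also the generative correlation of
    the community-weighted means when climate effects are off.
    """
    load = _orthogonalize(loadings)
    cov = load @ load.T + noise_sd ** 2 * np.eye(load.shape[0])
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def planted_shared_variance_fraction(loadings: np.ndarray,
                                     noise_sd: float) -> float:
    """Fraction of standardized variance on the two planted dimensions:
    the top-two eigenvalues of the planted correlation matrix over its
    trace."""
    r = planted_correlation_matrix(loadings, noise_sd)
    eig = np.sort(np.linalg.eigvalsh(r))[::-1]
    return float(eig[:2].sum() / np.trace(r))


# --------------------------------------------------------------------------
# serialization

def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the world as TSV tables and .asc rasters."""
    from .traits import write_plots, write_species_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_species_table(out / "species.tsv", world.species_table)
    write_plots(out / "plots.tsv", out / "composition.tsv", world.plots)
    g = world.climate.grid
    for m in range(12):
        write_asc(out / f"tas_{m + 1:02d}.asc",
                  Raster(g, world.climate.tas[m], "tas", "degC"))
        write_asc(out / f"pr_{m + 1:02d}.asc",
                  Raster(g, world.climate.pr[m], "pr", "mm/month"))
        if world.climate.srad is not None:
            write_asc(out / f"srad_{m + 1:02d}.asc",
                      Raster(g, world.climate.srad[m], "srad", "kJ/m2/month"))
    write_asc(out / "landcover.asc",
              Raster(world.landcover.grid,
                     world.landcover.codes.astype(float), "landcover", "code"))
    world.landcover.table.to_csv(out / "landcover_codes.tsv", sep="\t")
    for name, arr in world.bioclim_maps.items():
        write_asc(out / f"{name}.asc", Raster(g, arr, name))
    for t, per_group in world.truth.effect_surfaces.items():
        for label, arr in per_group.items():
            write_asc(out / f"truth_{t}_{label}.asc",
                      Raster(g, arr, f"truth {t} {label}", "ln(native)"))
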
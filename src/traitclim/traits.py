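"""Trait conversions, plant-group classification and community-weighted means.

Plant taxa are stratified into three groups — non-woody, woody deciduous and
woody evergreen — via a growth-form → group-probability table.  Minority
growth forms (ferns, palms, cycads, bamboos, cacti, succulents) carry zero
total probability and are omitted from all community aggregates.  For a plot
with taxon relative covers RC(taxon) and group probabilities P(group):

    RA(group) = Σ_taxa RC(taxon) · P(group)
    RC(group) = RA(group) / Σ_groups RA(group)

Community-weighted means use weights proportional to RC(taxon) · P(group),
renormalised per trait over the taxa that have that trait measured; the
weighted average is taken on native-unit values and natural-log transformed
afterwards (a mean-of-logs alternative is available via ``log_first``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("nonwoody", "deciduous", "evergreen")
GROUP_PROB_COLS = tuple(f"p_{g}" for g in GROUPS)
MAJOR_TRAITS = ("LA", "LMA", "Narea", "SSD", "H", "DM")

#: Default growth-form → (P(nonwoody), P(deciduous), P(evergreen)) table.
#: Minority forms map to all-zero probabilities, marking omission.
DEFAULT_FORM_TABLE: dict[str, tuple[float, float, float]] = {
    "herb": (1.0, 0.0, 0.0),
    "graminoid": (1.0, 0.0, 0.0),
    "forb": (1.0, 0.0, 0.0),
    "tree-deciduous": (0.0, 1.0, 0.0),
    "shrub-deciduous": (0.0, 1.0, 0.0),
    "tree-evergreen": (0.0, 0.0, 1.0),
    "shrub-evergreen": (0.0, 0.0, 1.0),
    # mixed form: phenology unresolved at the form level
    "shrub-intermediate": (0.5, 0.25, 0.25),
    # minority forms, omitted from analyses
    "fern": (0.0, 0.0, 0.0),
    "palm": (0.0, 0.0, 0.0),
    "cycad": (0.0, 0.0, 0.0),
    "bamboo": (0.0, 0.0, 0.0),
    "cactus": (0.0, 0.0, 0.0),
    "succulent": (0.0, 0.0, 0.0),
}


class TraitError(ValueError):
    pass


class EmptyGroupError(TraitError):
    """Every taxon in a plot is omitted: group coverage undefined."""


class TransformError(TraitError):
    """Log transform requested for a non-positive community mean."""


class DegenerateColumnError(TraitError):
    """Standardisation requested for a zero-variance column."""


@dataclass
class PlotComposition:
    """One vegetation plot: location, taxon relative covers, provenance."""

    plot_id: str
    lon: float
    lat: float
    entries: list[tuple[str, float]]
    record_scope: str = "unspecified"  # all_vascular | unspecified | partial
    natural: bool = True

    def __post_init__(self) -> None:
        covers = np.array([rc for _, rc in self.entries], dtype=float)
        if len(covers) and abs(covers.sum() - 1.0) > 1e-9:
            raise TraitError(
                f"plot {self.plot_id}: relative covers sum to {covers.sum():.12f}, not 1"
            )
        if np.any(covers < 0):
            raise TraitError(f"plot {self.plot_id}: negative relative cover")


@dataclass
class GroupCover:
    plot_id: str
    rc: np.ndarray = field(default_factory=lambda: np.zeros(3))  # per GROUPS


# ---------------------------------------------------------------------------
# unit conversions

def lma_from_sla(sla):
    """Leaf mass per area (kg/m2) from specific leaf area (m2/kg): 1/SLA."""
    sla = np.asarray(sla, dtype=float)
    if np.any(sla <= 0):
        raise TraitError("SLA must be strictly positive")
    return 1.0 / sla


def area_based_from_mass(mass_content, sla):
    """Area-based content (g/m2) from mass-based content (mg/g) and SLA
    (m2/kg): mass/SLA (units cancel)."""
    mass_content = np.asarray(mass_content, dtype=float)
    sla = np.asarray(sla, dtype=float)
    if np.any(sla <= 0):
        raise TraitError("SLA must be strictly positive")
    if np.any(mass_content < 0):
        raise TraitError("mass-based content must be non-negative")
    return mass_content / sla


# ---------------------------------------------------------------------------
# classification and group coverage

def classify_groups(species: pd.DataFrame,
                    form_table: dict[str, tuple[float, float, float]] | None = None,
                    ) -> pd.DataFrame:
    """Populate per-group probability columns from ``growth_form``.

    Rows whose probabilities are already present (all three columns finite)
    pass through unchanged, so pre-assigned mixed forms are preserved.
    Unknown growth forms raise, listing the offending forms.
    """
    table = DEFAULT_FORM_TABLE if form_table is None else form_table
    out = species.copy()
    have = (
        all(c in out.columns for c in GROUP_PROB_COLS)
        and out[list(GROUP_PROB_COLS)].notna().all(axis=1)
    )
    if np.isscalar(have):
        have = pd.Series(bool(have), index=out.index)
    unknown = sorted(set(out.loc[~have, "growth_form"]) - set(table))
    if unknown:
        raise TraitError(f"unknown growth form(s): {unknown}")
    for col in GROUP_PROB_COLS:
        if col not in out.columns:
            out[col] = np.nan
    probs = out.loc[~have, "growth_form"].map(table)
    for i, col in enumerate(GROUP_PROB_COLS):
        out.loc[~have, col] = [p[i] for p in probs]
    totals = out[list(GROUP_PROB_COLS)].sum(axis=1)
    if np.any(totals > 1 + 1e-9):
        raise TraitError("group probabilities must sum to at most 1")
    out["omitted"] = totals == 0
    return out


def _prob_matrix(species: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROUP_PROB_COLS if c not in species.columns]
    if missing:
        raise TraitError(
            f"species table lacks {missing}; run classify_groups first")
    return species[list(GROUP_PROB_COLS)]


def group_cover(plot: PlotComposition, species: pd.DataFrame) -> GroupCover:
    """Relative coverage of the three plant groups within one plot."""
    probs = _prob_matrix(species)
    taxa = [t for t, _ in plot.entries]
    unknown = sorted(set(taxa) - set(species.index))
    if unknown:
        raise TraitError(f"plot {plot.plot_id}: taxa not in species table: {unknown}")
    rc = np.array([c for _, c in plot.entries], dtype=float)
    p = probs.loc[taxa].to_numpy(dtype=float)
    ra = rc @ p
    total = ra.sum()
    if total <= 0:
        raise EmptyGroupError(
            f"plot {plot.plot_id}: all taxa omitted, group coverage undefined")
    return GroupCover(plot.plot_id, ra / total)


def group_cover_table(plots: list[PlotComposition],
                      species: pd.DataFrame) -> pd.DataFrame:
    """Group coverage for many plots; plots with only omitted taxa are
    dropped (their ids appear in ``result.attrs['empty_plots']``)."""
    rows, idx, empty = [], [], []
    for plot in plots:
        try:
            gc = group_cover(plot, species)
        except EmptyGroupError:
            empty.append(plot.plot_id)
            continue
        rows.append(gc.rc)
        idx.append(plot.plot_id)
    out = pd.DataFrame(rows, index=pd.Index(idx, name="plot_id"), columns=GROUPS)
    out.attrs["empty_plots"] = empty
    return out


# ---------------------------------------------------------------------------
# community-weighted means

def community_weighted_means(
    plots: list[PlotComposition],
    species: pd.DataFrame,
    traits_of_interest: tuple[str, ...] = MAJOR_TRAITS,
    group: str = "all",
    log_first: bool = False,
    log_offsets: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Natural-log community-weighted means, plots × traits.

    ``group`` selects the plant group ('nonwoody', 'deciduous', 'evergreen')
    or 'all' for all non-omitted taxa.  Weights are RC(taxon)·P(group),
    renormalised per trait over taxa with that trait measured; the mean is
    taken on native units and logged afterwards unless ``log_first``.
    ``log_offsets`` maps trait → additive offset applied before the log, for
    traits (e.g. isotope ratios) that can be non-positive.
    """
    if group not in GROUPS + ("all",):
        raise TraitError(f"unknown group {group!r}")
    probs = _prob_matrix(species)
    pvec = (probs.sum(axis=1) if group == "all" else probs[f"p_{group}"])
    offsets = log_offsets or {}
    trait_vals = species[list(traits_of_interest)]

    records = np.full((len(plots), len(traits_of_interest)), np.nan)
    for i, plot in enumerate(plots):
        taxa = [t for t, _ in plot.entries]
        unknown = sorted(set(taxa) - set(species.index))
        if unknown:
            raise TraitError(
                f"plot {plot.plot_id}: taxa not in species table: {unknown}")
        rc = np.array([c for _, c in plot.entries], dtype=float)
        w = rc * pvec.loc[taxa].to_numpy(dtype=float)
        x = trait_vals.loc[taxa].to_numpy(dtype=float)
        for j, trait in enumerate(traits_of_interest):
            ok = np.isfinite(x[:, j]) & (w > 0)
            if not np.any(ok):
                continue
            wj = w[ok] / w[ok].sum()
            if log_first:
                vals = x[ok, j] + offsets.get(trait, 0.0)
                if np.any(vals <= 0):
                    raise TransformError(
                        f"plot {plot.plot_id}, trait {trait}: non-positive value "
                        "under log-first averaging (configure a log offset)")
                records[i, j] = float(wj @ np.log(vals))
            else:
                cwm = float(wj @ x[ok, j]) + offsets.get(trait, 0.0)
                if cwm <= 0:
                    raise TransformError(
                        f"plot {plot.plot_id}, trait {trait}: CWM {cwm:.6g} is "
                        "non-positive and cannot be log-transformed "
                        "(configure a log offset)")
                records[i, j] = np.log(cwm)

    out = pd.DataFrame(records,
                       index=pd.Index([p.plot_id for p in plots], name="plot_id"),
                       columns=list(traits_of_interest))
    out.attrs["group"] = group
    out.attrs["scale"] = "ln(native unit)"
    return out


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each column to mean 0, sd 1 (n-1 denominator); missing
    entries are excluded from the moments and stay missing."""
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        n = vals.notna().sum()
        if n < 2:
            raise TraitError(f"column {col}: need >= 2 non-missing values")
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateColumnError(f"column {col}: zero variance")
        out[col] = (vals - vals.mean()) / sd
    out.attrs = dict(matrix.attrs)
    return out


# ---------------------------------------------------------------------------
# TSV I/O

def write_species_table(path, species: pd.DataFrame) -> None:
    species.to_csv(path, sep="\t", index_label="taxon")


def read_species_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="taxon")


def write_plots(path_plots, path_composition,
                plots: list[PlotComposition]) -> None:
    meta = pd.DataFrame(
        [(p.plot_id, p.lon, p.lat, p.record_scope, p.natural) for p in plots],
        columns=["plot_id", "lon", "lat", "record_scope", "natural"],
    )
    comp = pd.DataFrame(
        [(p.plot_id, t, rc) for p in plots for t, rc in p.entries],
        columns=["plot_id", "taxon", "rel_cover"],
    )
    meta.to_csv(path_plots, sep="\t", index=False)
    comp.to_csv(path_composition, sep="\t", index=False)


def read_plots(path_plots, path_composition) -> list[PlotComposition]:
    meta = pd.read_csv(path_plots, sep="\t")
    comp = pd.read_csv(path_composition, sep="\t")
    grouped = {pid: list(zip(g["taxon"], g["rel_cover"]))
               for pid, g in comp.groupby("plot_id")}
    return [
        PlotComposition(str(r.plot_id), r.lon, r.lat,
                        grouped.get(r.plot_id, []), r.record_scope,
                        bool(r.natural))
        for r in meta.itertuples()
    ]


def write_trait_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="plot_id")


def read_trait_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="plot_id")
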
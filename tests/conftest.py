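import numpy as np
import pandas as pd
import pytest

import traitclim as tc


@pytest.fixture(scope="session")
def small_world() -> tc.SyntheticWorld:
    """Small default-structure world shared across read-only tests."""
    return tc.generate_world(tc.WorldConfig(seed=11, n_plots=300,
                                            n_species=400))


@pytest.fixture(scope="session")
def recovery_world() -> tc.SyntheticWorld:
    """World with pure two-factor trait structure (climate effects off,
    no mixed growth form) for ordination-recovery tests."""
    cfg = tc.WorldConfig(seed=1, n_plots=1000, n_species=1500,
                         climate_effects={}, mixed_fraction=0.0)
    return tc.generate_world(cfg)


@pytest.fixture()
def species_3() -> pd.DataFrame:
    """Three classified species covering all groups with simple traits."""
    sp = pd.DataFrame(
        {
            "growth_form": ["herb", "tree-deciduous", "tree-evergreen"],
            "LA": [100.0, 400.0, 900.0],
            "H": [0.5, 10.0, 20.0],
        },
        index=pd.Index(["sp_a", "sp_b", "sp_c"], name="taxon"),
    )
    return tc.classify_groups(sp)


def make_plot(entries, plot_id="p1", lon=0.0, lat=0.0, **kw):
    return tc.PlotComposition(plot_id, lon, lat, entries, **kw)
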
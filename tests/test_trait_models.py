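"""Penalized-spline GAM engine, importance shares, concurvity, surfaces."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

import traitclim as tc
from traitclim.trait_models import GamError, HullError


def make_additive_data(seed=0, n=2000, noise_sd=0.2):
    """Synthetic CWM = f(ln MI) + g(MGST) + noise on realistic ranges."""
    rng = np.random.default_rng(seed)
    ln_mi = rng.uniform(-2.0, 0.5, n)
    mgst = rng.uniform(5.0, 30.0, n)
    f = 0.7 * np.tanh(1.5 * ln_mi) + 0.3 * ln_mi
    g = mgst / 15.0 + 0.4 * np.sin(mgst / 4.0)
    y = f + g + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame({"ln_mi": ln_mi, "mgst": mgst, "y": y})
    return df, f, g


class TestFitGam:
    def test_planted_signal_recovery(self):
        df, f, g = make_additive_data(seed=1)
        spec = tc.GamSpec("y", [tc.SmoothTerm("ln_mi"),
                                tc.SmoothTerm("mgst")])
        fit = tc.fit_gam(df, "y", spec)
        pf = fit.partial_effect("ln_mi", df["ln_mi"].to_numpy())
        pg = fit.partial_effect("mgst", df["mgst"].to_numpy())
        assert np.corrcoef(pf, f)[0, 1] > 0.95
        assert np.corrcoef(pg, g)[0, 1] > 0.95
        signal = np.var(f + g)
        planted_r2 = signal / (signal + 0.2 ** 2)
        assert abs(fit.deviance_explained - planted_r2) < 0.05

    def test_pure_noise_explains_little(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": rng.uniform(0, 1, 1000),
                           "x2": rng.uniform(0, 1, 1000),
                           "y": rng.standard_normal(1000)})
        fit = tc.fit_gam(df, "y", tc.GamSpec(
            "y", [tc.SmoothTerm("x1"), tc.SmoothTerm("x2")]))
        assert fit.deviance_explained < 0.05

    def test_replication_invariance(self):
        """Stacking the data twice with the per-term penalties doubled
        reproduces the fitted surface exactly (penalized least squares is
        invariant under uniform replication at matched total smoothing);
        with REML re-selection the surface moves only slightly, because
        the restricted-df correction legitimately shifts the optimum."""
        df, *_ = make_additive_data(seed=3, n=400)
        spec = tc.GamSpec("y", [tc.SmoothTerm("ln_mi"),
                                tc.SmoothTerm("mgst")])
        f1 = tc.fit_gam(df, "y", spec)
        doubled = pd.concat([df, df], ignore_index=True)
        # the penalty is internally rescaled to the design magnitude, which
        # itself doubles under replication, so matched smoothing = same lam
        lam2 = [t.lam for t in f1.terms]
        f2_fixed = tc.fit_gam(doubled, "y", spec, lambdas=lam2)
        assert np.max(np.abs(f1.predict(df) - f2_fixed.predict(df))) < 1e-6
        f2_reml = tc.fit_gam(doubled, "y", spec)
        scale = np.std(df["y"])
        assert np.max(np.abs(f1.predict(df) - f2_reml.predict(df))) \
            < 0.1 * scale

    def test_predict_reproduces_training_fit(self):
        df, *_ = make_additive_data(seed=4, n=300)
        spec = tc.GamSpec("y", [tc.SmoothTerm("ln_mi"),
                                tc.SmoothTerm("mgst")])
        fit = tc.fit_gam(df, "y", spec)
        assert np.allclose(fit.predict(df), fit._train_fitted, atol=1e-8)

    def test_deterministic(self):
        df, *_ = make_additive_data(seed=5, n=300)
        spec = tc.GamSpec("y", [tc.SmoothTerm("ln_mi"),
                                tc.SmoothTerm("mgst")])
        f1 = tc.fit_gam(df, "y", spec)
        f2 = tc.fit_gam(df.copy(), "y", spec)
        assert np.array_equal(f1.beta, f2.beta)

    def test_constant_response_degenerate(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 50),
                           "y": np.ones(50)})
        with pytest.warns(UserWarning, match="constant response"):
            fit = tc.fit_gam(df, "y", tc.GamSpec("y", [tc.SmoothTerm("x")]))
        assert fit.deviance_explained == 0.0

    def test_insufficient_rows_raise(self):
        df = pd.DataFrame({"x": np.arange(5.0), "y": np.arange(5.0)})
        with pytest.raises(GamError):
            tc.fit_gam(df, "y", tc.GamSpec("y", [tc.SmoothTerm("x")]))

    def test_adjusted_r2_below_deviance_explained(self):
        df, *_ = make_additive_data(seed=6, n=500)
        fit = tc.fit_gam(df, "y", tc.GamSpec(
            "y", [tc.SmoothTerm("ln_mi"), tc.SmoothTerm("mgst")]))
        assert fit.adjusted_r2 <= fit.deviance_explained + 1e-9

    def test_varying_coefficient_interaction(self):
        """A bioclim x cover interaction recovers z * f(x)."""
        rng = np.random.default_rng(7)
        n = 1500
        x = rng.uniform(-2, 2, n)
        z = rng.uniform(0, 1, n)
        y = z * np.sin(x) + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"x": x, "z": z, "y": y})
        spec = tc.GamSpec("y", [tc.SmoothTerm("x")],
                          interaction_terms=[("x", "z")])
        fit = tc.fit_gam(df, "y", spec)
        sig = np.var(z * np.sin(x))
        assert abs(fit.deviance_explained - sig / (sig + 0.01)) < 0.05

    def test_matches_mgcv_reml(self, tmp_path):
        """Cross-check against R mgcv with method='REML' and a P-spline
        basis: deviance explained and the fitted surface agree closely."""
        df, *_ = make_additive_data(seed=8, n=600)
        df.to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        script = tmp_path / "gam.R"
        script.write_text(
            'library(mgcv)\n'
            f'd <- read.delim("{tmp_path}/d.tsv")\n'
            'm <- gam(y ~ s(ln_mi,k=10,bs="ps",m=c(2,2))'
            ' + s(mgst,k=10,bs="ps",m=c(2,2)), data=d, method="REML")\n'
            'cat(sprintf("%.6f\\n", summary(m)$dev.expl))\n'
            f'write(fitted(m), "{tmp_path}/rfit.txt", ncolumns=1)\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        r_dev = float(out.stdout.strip().splitlines()[-1])
        rfit = np.loadtxt(tmp_path / "rfit.txt")
        fit = tc.fit_gam(df, "y", tc.GamSpec(
            "y", [tc.SmoothTerm("ln_mi"), tc.SmoothTerm("mgst")]))
        assert abs(fit.deviance_explained - r_dev) < 0.02
        assert np.corrcoef(fit._train_fitted, rfit)[0, 1] > 0.995


class TestRelativeImportance:
    def test_single_signal_gets_everything(self):
        rng = np.random.default_rng(9)
        n = 1200
        q, _ = np.linalg.qr(rng.standard_normal((n, 3)))
        z = q * np.sqrt(n)
        df = pd.DataFrame({"a": z[:, 0], "b": z[:, 1], "c": z[:, 2]})
        df["y"] = df["a"] * 1.0
        imp = tc.relative_importance(df, "y", ("a", "b", "c"))
        assert imp.shares["a"] == pytest.approx(100.0, abs=2.0)
        assert abs(imp.shares["b"]) < 2.0 and abs(imp.shares["c"]) < 2.0

    def test_shares_sum_to_100(self):
        df, *_ = make_additive_data(seed=10, n=500)
        imp = tc.relative_importance(df, "y", ("ln_mi", "mgst"))
        assert imp.shares_sum_normalized.sum() == pytest.approx(100.0,
                                                                abs=1e-6)

    def test_permutation_symmetry(self):
        """Relabeling predictors permutes the shares identically."""
        df, *_ = make_additive_data(seed=11, n=500)
        imp1 = tc.relative_importance(df, "y", ("ln_mi", "mgst"))
        renamed = df.rename(columns={"ln_mi": "mgst", "mgst": "ln_mi"})
        imp2 = tc.relative_importance(renamed, "y", ("ln_mi", "mgst"))
        assert imp1.shares["ln_mi"] == pytest.approx(imp2.shares["mgst"],
                                                     abs=1e-9)

    def test_shapley_matches_bruteforce_permutations(self):
        """The subset combinator agrees exactly with explicit averaging
        over all predictor orderings."""
        rng = np.random.default_rng(12)
        players = ("a", "b", "c")
        values = {frozenset(): 0.0}
        for r in range(1, 4):
            for sub in itertools.combinations(players, r):
                values[frozenset(sub)] = float(rng.uniform(0, 1))
        values[frozenset(players)] = 1.0
        mine = tc.shapley_from_subsets(values, players)
        brute = {j: 0.0 for j in players}
        for perm in itertools.permutations(players):
            sofar = []
            for j in perm:
                prev = values[frozenset(sofar)]
                sofar.append(j)
                brute[j] += (values[frozenset(sofar)] - prev) / 6.0
        for j in players:
            assert mine[j] == pytest.approx(brute[j], abs=1e-12)

    def test_loo_variant_runs(self):
        df, *_ = make_additive_data(seed=13, n=400)
        imp = tc.relative_importance(df, "y", ("ln_mi", "mgst"),
                                     method="loo")
        assert imp.method == "loo"
        assert np.all(np.isfinite(imp.shares_sum_normalized))


class TestConcurvity:
    def test_identical_predictors_full_concurvity(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 1, 500)
        df = pd.DataFrame({"x1": x, "x2": x.copy(),
                           "y": np.sin(3 * x) + rng.normal(0, 0.1, 500)})
        fit = tc.fit_gam(df, "y", tc.GamSpec(
            "y", [tc.SmoothTerm("x1"), tc.SmoothTerm("x2")]))
        conc = tc.concurvity(fit)
        assert np.all(conc.to_numpy() > 1 - 1e-6)

    def test_independent_predictors_low_concurvity(self):
        rng = np.random.default_rng(15)
        worst = 0.0
        for rep in range(20):
            df = pd.DataFrame({"x1": rng.uniform(0, 1, 2000),
                               "x2": rng.uniform(0, 1, 2000)})
            df["y"] = (np.sin(4 * df["x1"]) + np.cos(3 * df["x2"])
                       + rng.normal(0, 0.2, 2000))
            fit = tc.fit_gam(df, "y", tc.GamSpec(
                "y", [tc.SmoothTerm("x1"), tc.SmoothTerm("x2")]))
            worst = max(worst, float(tc.concurvity(fit).max()))
        assert worst < 0.1

    def test_bounded_unit_interval(self):
        df, *_ = make_additive_data(seed=16, n=400)
        fit = tc.fit_gam(df, "y", tc.GamSpec(
            "y", [tc.SmoothTerm("ln_mi"), tc.SmoothTerm("mgst")]))
        conc = tc.concurvity(fit)
        assert np.all((conc >= 0) & (conc <= 1))

    def test_single_term_not_applicable(self):
        df, *_ = make_additive_data(seed=17, n=300)
        fit = tc.fit_gam(df, "y", tc.GamSpec("y", [tc.SmoothTerm("ln_mi")]))
        with pytest.raises(GamError):
            tc.concurvity(fit)


class TestClimateSpaceSurface:
    @pytest.fixture()
    def simple_fit(self):
        rng = np.random.default_rng(18)
        n = 300
        df = pd.DataFrame({"ln_mi": rng.uniform(-1, 1, n),
                           "mtco": rng.uniform(-10, 10, n),
                           "mgst": rng.uniform(5, 25, n)})
        df["y"] = df["ln_mi"] + df["mgst"] / 10 + rng.normal(0, 0.1, n)
        spec = tc.GamSpec("y", [tc.SmoothTerm(v) for v in
                                ("ln_mi", "mtco", "mgst")])
        return tc.fit_gam(df, "y", spec), df

    def test_tetrahedron_hull_membership(self, simple_fit):
        fit, _ = simple_fit
        corners = pd.DataFrame(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
             [0.0, 0.0, 1.0]],
            columns=["ln_mi", "mtco", "mgst"])
        grid = tc.climate_space_surface(
            fit, corners, increments={"ln_mi": 0.25, "mtco": 0.25,
                                      "mgst": 0.25})
        axes = {k: list(np.round(v, 6)) for k, v in grid.axes.items()}
        i = axes["ln_mi"].index(0.25)
        j = axes["mtco"].index(0.25)
        k = axes["mgst"].index(0.25)
        assert grid.mask[i, j, k]            # near the centroid: inside
        assert not grid.mask[-1, -1, -1]     # far corner (1,1,1): outside
        assert np.isnan(grid.predicted[-1, -1, -1])

    def test_node_count_arithmetic(self, simple_fit):
        fit, df = simple_fit
        grid = tc.climate_space_surface(
            fit, df, increments={"ln_mi": 0.05, "mtco": 0.25, "mgst": 0.25})
        for name, inc in (("ln_mi", 0.05), ("mtco", 0.25), ("mgst", 0.25)):
            rng_ = df[name].max() - df[name].min()
            assert len(grid.axes[name]) == int(np.floor(rng_ / inc + 1e-9)) + 1

    def test_observed_points_near_unmasked_nodes(self, simple_fit):
        fit, df = simple_fit
        grid = tc.climate_space_surface(
            fit, df, increments={"ln_mi": 0.1, "mtco": 1.0, "mgst": 1.0})
        from scipy.spatial import Delaunay
        obs = df[["ln_mi", "mtco", "mgst"]].to_numpy()
        tri = Delaunay(obs)  # independent membership check
        names = list(grid.axes)
        mesh = np.meshgrid(*grid.axes.values(), indexing="ij")
        nodes = np.column_stack([m.ravel() for m in mesh])
        inside_oracle = tri.find_simplex(nodes) >= 0
        assert np.array_equal(grid.mask.ravel(), inside_oracle)
        assert names == ["ln_mi", "mtco", "mgst"]

    def test_degenerate_sample_raises(self, simple_fit):
        fit, _ = simple_fit
        coplanar = pd.DataFrame({"ln_mi": [0, 1, 0, 1.0],
                                 "mtco": [0, 0, 1, 1.0],
                                 "mgst": [5.0, 5.0, 5.0, 5.0]})
        with pytest.raises(HullError):
            tc.climate_space_surface(fit, coplanar,
                                     increments={"ln_mi": 0.5, "mtco": 0.5,
                                                 "mgst": 0.5})

    def test_slice_extraction(self, simple_fit):
        fit, df = simple_fit
        grid = tc.climate_space_surface(
            fit, df, increments={"ln_mi": 0.1, "mtco": 1.0, "mgst": 1.0})
        sl = grid.slice_at("mtco", 0.0)
        assert sl.index.name == "ln_mi" and sl.columns.name == "mgst"
        assert abs(sl.attrs["mtco"]) <= 0.5
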
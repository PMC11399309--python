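"""Additive trait-climate models (GAMs) and predictor-importance tools.

The smoother is a Gaussian additive model built from cubic penalized
B-splines (P-splines): each term contributes ``k`` basis functions with a
second-order difference penalty, identifiability is absorbed by
reparameterising each plain smooth onto the subspace where its training
mean is zero, and the smoothing parameters are chosen by minimising the
(profiled) restricted maximum likelihood criterion.  Bioclim × cover
interactions are varying-coefficient terms: the smooth of the bioclim
variable multiplied pointwise by the cover fraction.

Predictor importance follows a Shapley decomposition: every subset model is
fitted, and each predictor's share is its average increment in deviance
explained over all orderings, normalised to sum to 100%.  A cheaper
leave-one-out variant is available for comparison.  Concurvity is the
"observed" measure: the fraction of a fitted term's variance reproducible
by projection onto the span of the other terms' basis columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.spatial import Delaunay, QhullError

SPLINE_DEGREE = 3
DEFAULT_K = 10


class GamError(ValueError):
    pass


class HullError(GamError):
    """Observed climate sample is degenerate in 3-D; a 2-D hull over the
    non-degenerate axes is the suggested fallback."""


@dataclass
class SmoothTerm:
    """One penalized smooth: ``s(var, k)`` or a varying coefficient
    ``s(var, k) * by`` when ``by`` names a multiplier column."""

    var: str
    k: int = DEFAULT_K
    by: str | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise GamError(f"term {self.var}: basis size k must be >= 3")

    @property
    def label(self) -> str:
        return f"s({self.var})" if self.by is None else f"s({self.var}):{self.by}"


@dataclass
class GamSpec:
    response: str
    smooth_terms: list[SmoothTerm]
    interaction_terms: list[tuple[str, str]] = field(default_factory=list)
    smoothing_selection: str = "REML"

    def __post_init__(self) -> None:
        if not self.smooth_terms:
            raise GamError("spec needs at least one smooth term")
        self.smooth_terms = [
            t if isinstance(t, SmoothTerm) else SmoothTerm(t)
            for t in self.smooth_terms
        ]

    def all_terms(self) -> list[SmoothTerm]:
        extra = [SmoothTerm(var, by=by) for var, by in self.interaction_terms]
        return list(self.smooth_terms) + extra


def _knots(lo: float, hi: float, k: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0  # degenerate predictor; basis still well defined
    inner = np.linspace(lo, hi, k - 2)
    return np.concatenate([[lo] * SPLINE_DEGREE, inner, [hi] * SPLINE_DEGREE])


def _basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[SPLINE_DEGREE], knots[-SPLINE_DEGREE - 1]
    xc = np.clip(x, lo, hi)
    # non-finite inputs get a placeholder; rows are masked downstream
    xc = np.where(np.isfinite(xc), xc, lo)
    return BSpline.design_matrix(xc, knots, SPLINE_DEGREE).toarray()


@dataclass
class _FittedTerm:
    spec: SmoothTerm
    knots: np.ndarray
    z: np.ndarray | None       # constraint-absorbing reparameterisation
    penalty: np.ndarray        # penalty matrix in working parameterisation
    penalty_rank: int
    penalty_logdet: float      # log pseudo-determinant of the scaled penalty
    sl: slice = field(default_factory=lambda: slice(0, 0))
    # ^ coefficient slice in the stacked vector
    lam: float = 1.0

    def design(self, data: pd.DataFrame) -> np.ndarray:
        b = _basis(np.asarray(data[self.spec.var], dtype=float), self.knots)
        if self.z is not None:
            b = b @ self.z
        if self.spec.by is not None:
            b = b * np.asarray(data[self.spec.by], dtype=float)[:, None]
        return b


def _prepare_term(term: SmoothTerm, x: np.ndarray) -> _FittedTerm:
    knots = _knots(float(np.min(x)), float(np.max(x)), term.k)
    b = _basis(x, knots)
    k = b.shape[1]
    d2 = np.diff(np.eye(k), n=2, axis=0)
    s = d2.T @ d2
    z = None
    if term.by is None:
        # absorb the sum-to-zero (training mean) constraint
        c = b.mean(axis=0)
        q, _ = np.linalg.qr(c[:, None], mode="complete")
        z = q[:, 1:]
        s = z.T @ s @ z
    # scale the penalty to the magnitude of the design for well-behaved
    # smoothing-parameter optimisation
    bz = b if z is None else b @ z
    scale = np.linalg.norm(bz.T @ bz) / max(np.linalg.norm(s), 1e-12)
    s = s * scale
    eig = np.linalg.eigvalsh(s)
    tol = max(eig.max(), 1.0) * 1e-10
    nonzero = eig[eig > tol]
    return _FittedTerm(
        spec=term, knots=knots, z=z, penalty=s,
        penalty_rank=len(nonzero),
        penalty_logdet=float(np.sum(np.log(nonzero))),
    )


@dataclass
class GamFit:
    spec: GamSpec
    terms: list[_FittedTerm]
    beta: np.ndarray
    sigma2: float
    edf: float
    deviance_explained: float
    adjusted_r2: float
    n_obs: int
    smoothing_selection: str
    reml_score: float
    _train_design: np.ndarray | None = None
    _train_fitted: np.ndarray | None = None

    @property
    def lambdas(self) -> dict[str, float]:
        return {t.spec.label: t.lam for t in self.terms}

    def _design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(data), 1))]
        cols += [t.design(data) for t in self.terms]
        return np.hstack(cols)

    def predict(self, data: pd.DataFrame | dict) -> np.ndarray:
        if isinstance(data, dict):
            data = pd.DataFrame(data)
        x = self._design(data)
        out = x @ self.beta
        # propagate missing predictors
        need = [t.spec.var for t in self.terms]
        need += [t.spec.by for t in self.terms if t.spec.by is not None]
        bad = ~np.all([np.isfinite(np.asarray(data[c], dtype=float))
                       for c in dict.fromkeys(need)], axis=0)
        out = np.asarray(out, dtype=float)
        out[bad] = np.nan
        return out

    def partial_effect(self, var: str, x: np.ndarray) -> np.ndarray:
        """Fitted smooth for one plain term, evaluated at ``x`` (training
        range is extended by clamping); mean-zero over the training data."""
        for t in self.terms:
            if t.spec.var == var and t.spec.by is None:
                b = _basis(np.asarray(x, dtype=float), t.knots)
                if t.z is not None:
                    b = b @ t.z
                return b @ self.beta[t.sl]
        raise GamError(f"no plain smooth term for {var!r}")


def _reml_score(rho, blocks, n, m_p, term_meta):
    from scipy.linalg import cho_factor, cho_solve

    xtx, xty, yty = blocks
    rho = np.clip(rho, -30.0, 30.0)
    a = xtx.copy()
    pen_logdet = 0.0
    for (sl, s, rank, logdet), r in zip(term_meta, rho):
        lam = math.exp(r)
        a[sl, sl] += lam * s
        pen_logdet += rank * r + logdet
    try:
        cf = cho_factor(a, lower=True, check_finite=False)
        beta = cho_solve(cf, xty, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12, None
    chol = cf[0]
    # penalized deviance RSS + beta'S beta collapses to y'y - beta'X'y at
    # the penalized-least-squares optimum
    dp = max(float(yty - beta @ xty), 1e-300)
    sigma2 = dp / (n - m_p)
    logdet_a = 2.0 * float(np.sum(np.log(np.diag(chol))))
    score = (0.5 * (n - m_p) * (1.0 + math.log(2 * math.pi * sigma2))
             + 0.5 * (logdet_a - pen_logdet))
    return score, (beta, sigma2)


def fit_gam(data: pd.DataFrame, response: str, spec: GamSpec,
            lambdas=None) -> GamFit:
    """Fit a Gaussian additive model with REML-selected smoothing.

    Rows with any non-finite value in the response or the predictors are
    dropped.  Deterministic for fixed data and spec (no randomness; the
    optimiser starts from a fixed point).  ``lambdas`` fixes the per-term
    smoothing parameters, skipping REML selection.
    """
    terms = spec.all_terms()
    need = [response] + [t.var for t in terms]
    need += [t.by for t in terms if t.by is not None]
    need = list(dict.fromkeys(need))
    missing = [c for c in need if c not in data.columns]
    if missing:
        raise GamError(f"data lacks columns {missing}")
    sub = data[need].apply(pd.to_numeric, errors="coerce")
    sub = sub.loc[np.isfinite(sub).all(axis=1)]
    n = len(sub)
    if n < 10 * len(terms):
        raise GamError(
            f"insufficient rows: {n} < 10 x {len(terms)} terms")
    y = sub[response].to_numpy(dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))

    fitted_terms = [
        _prepare_term(t, sub[t.var].to_numpy(dtype=float)) for t in terms
    ]
    cols = [np.ones((n, 1))]
    offset = 1
    for ft in fitted_terms:
        d = ft.design(sub)
        ft.sl = slice(offset, offset + d.shape[1])
        offset += d.shape[1]
        cols.append(d)
    x = np.hstack(cols)

    if tss == 0:
        warnings.warn("constant response: degenerate fit", stacklevel=2)
        beta = np.zeros(x.shape[1])
        beta[0] = y[0] if n else 0.0
        return GamFit(spec, fitted_terms, beta, 0.0, 1.0, 0.0, 0.0, n,
                      spec.smoothing_selection, math.nan, x, x @ beta)

    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    m_p = 1 + sum(
        (ft.penalty.shape[0] - ft.penalty_rank) for ft in fitted_terms
    )
    term_meta = [
        (ft.sl, ft.penalty, ft.penalty_rank, ft.penalty_logdet)
        for ft in fitted_terms
    ]

    if lambdas is not None:
        rho = np.log(np.asarray(lambdas, dtype=float))
    else:
        def objective(r):
            return _reml_score(r, (xtx, xty, yty), n, m_p, term_meta)[0]

        rho0 = np.zeros(len(fitted_terms))
        res = minimize(objective, rho0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7,
                                "maxiter": 2000})
        rho = np.clip(res.x, -25.0, 25.0)
    score, sol = _reml_score(rho, (xtx, xty, yty), n, m_p, term_meta)
    while sol is None:
        # near-singular at very small smoothing: back off toward lambda = 1
        rho = rho / 2.0 + 1.0
        score, sol = _reml_score(rho, (xtx, xty, yty), n, m_p, term_meta)
    beta, sigma2 = sol
    for ft, r in zip(fitted_terms, rho):
        ft.lam = math.exp(float(r))

    a = xtx.copy()
    for ft in fitted_terms:
        a[ft.sl, ft.sl] += ft.lam * ft.penalty
    edf = float(np.trace(np.linalg.lstsq(a, xtx, rcond=None)[0]))
    fitted = x @ beta
    rss = float(np.sum((y - fitted) ** 2))
    dev_expl = 1.0 - rss / tss
    denom = max(n - edf, 1.0)
    adj_r2 = 1.0 - (rss / denom) / (tss / (n - 1))
    return GamFit(
        spec=spec, terms=fitted_terms, beta=beta, sigma2=sigma2, edf=edf,
        deviance_explained=dev_expl, adjusted_r2=adj_r2, n_obs=n,
        smoothing_selection=spec.smoothing_selection, reml_score=score,
        _train_design=x, _train_fitted=fitted,
    )


# ---------------------------------------------------------------------------
# relative importance

@dataclass
class ImportanceShares:
    shares: pd.Series               # %, normalised by the full-model fit
    shares_sum_normalized: pd.Series  # %, normalised by the sum of raw shares
    raw: pd.Series                  # deviance-explained increments
    method: str
    full_deviance_explained: float


def shapley_from_subsets(values: dict[frozenset, float],
                         players: tuple) -> dict:
    """Exact Shapley attribution from a value defined on every subset of
    ``players`` (the empty set defaults to 0)."""
    p = len(players)
    out = {j: 0.0 for j in players}
    others = {j: [q for q in players if q != j] for j in players}
    for j in players:
        for r in range(p):
            weight = (math.factorial(r) * math.factorial(p - r - 1)
                      / math.factorial(p))
            for sub in itertools.combinations(others[j], r):
                s = frozenset(sub)
                out[j] += weight * (values[s | {j}] - values.get(s, 0.0))
    return out


def relative_importance(data: pd.DataFrame, response: str,
                        predictors: tuple[str, ...],
                        k: int = DEFAULT_K,
                        method: str = "shapley") -> ImportanceShares:
    """Per-predictor contribution to the GAM fit.

    ``method='shapley'`` averages the increment in deviance explained of each
    predictor over all entry orderings (all 2^p - 1 submodels are fitted);
    ``method='loo'`` is the cheaper full-minus-leave-one-out variant.
    """
    predictors = tuple(predictors)
    values: dict[frozenset, float] = {frozenset(): 0.0}
    subsets = [
        frozenset(c)
        for r in range(1, len(predictors) + 1)
        for c in itertools.combinations(predictors, r)
    ]
    for sub in subsets:
        spec = GamSpec(response, [SmoothTerm(v, k=k) for v in sorted(sub)])
        try:
            fit = fit_gam(data, response, spec)
        except GamError as exc:
            raise GamError(
                f"importance failed: submodel {sorted(sub)} did not fit: {exc}"
            ) from exc
        values[sub] = fit.deviance_explained
    full = values[frozenset(predictors)]
    if method == "shapley":
        raw = shapley_from_subsets(values, predictors)
    elif method == "loo":
        raw = {
            j: full - values[frozenset(predictors) - {j}] for j in predictors
        }
    else:
        raise GamError(f"unknown importance method {method!r}")
    raw_s = pd.Series(raw, index=list(predictors))
    total = raw_s.sum()
    shares_full = raw_s / full * 100.0 if full > 0 else raw_s * np.nan
    shares_sum = raw_s / total * 100.0 if total != 0 else raw_s * np.nan
    return ImportanceShares(
        shares=shares_full, shares_sum_normalized=shares_sum, raw=raw_s,
        method=method, full_deviance_explained=full,
    )


# ---------------------------------------------------------------------------
# concurvity

def concurvity(fit: GamFit) -> pd.Series:
    """Observed concurvity per smooth term: the proportion of the fitted
    term's variance reproducible from the other terms' basis columns
    (0 = independent, 1 = fully reproducible)."""
    if len(fit.terms) < 2:
        raise GamError("concurvity needs >= 2 smooth terms")
    if fit._train_design is None:
        raise GamError("fit carries no training design")
    x = fit._train_design
    out = {}
    for j, t in enumerate(fit.terms):
        f = x[:, t.sl] @ fit.beta[t.sl]
        f = f - f.mean()
        others = [x[:, 0:1]]
        others += [x[:, u.sl] for i, u in enumerate(fit.terms) if i != j]
        xo = np.hstack(others)
        coef, *_ = np.linalg.lstsq(xo, f, rcond=None)
        proj = xo @ coef
        denom = float(f @ f)
        val = float(proj @ proj) / denom if denom > 0 else 0.0
        out[t.spec.label] = min(max(val, 0.0), 1.0)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# climate-space response surfaces

DEFAULT_INCREMENTS = {"ln_mi": 0.05, "mtco": 0.25, "mgst": 0.25}


@dataclass
class ClimateSpaceGrid:
    axes: dict[str, np.ndarray]
    mask: np.ndarray        # True where inside the observed hull
    predicted: np.ndarray   # NaN where masked

    def slice_at(self, axis: str, value: float) -> pd.DataFrame:
        """2-D slice of the surface at the grid level nearest ``value``."""
        names = list(self.axes)
        i = names.index(axis)
        levels = self.axes[axis]
        j = int(np.argmin(np.abs(levels - value)))
        pred = np.take(self.predicted, j, axis=i)
        rest = [n for n in names if n != axis]
        df = pd.DataFrame(pred, index=self.axes[rest[0]],
                          columns=self.axes[rest[1]])
        df.index.name, df.columns.name = rest
        df.attrs[axis] = float(levels[j])
        return df


def climate_space_surface(fit: GamFit, observed: pd.DataFrame,
                          increments: dict[str, float] | None = None,
                          ) -> ClimateSpaceGrid:
    """Evaluate the fitted surface on a regular grid over the observed
    predictor ranges, masking nodes outside the convex hull of the observed
    sample so the surface is only shown where data constrain it."""
    increments = dict(DEFAULT_INCREMENTS if increments is None else increments)
    names = [t.spec.var for t in fit.terms if t.spec.by is None]
    obs = observed[names].dropna().to_numpy(dtype=float)
    if obs.shape[0] < obs.shape[1] + 1:
        raise HullError("too few observed points for a hull")
    for name in names:
        if increments.get(name, 0) <= 0:
            raise GamError(f"increment for {name} must be positive")
    axes = {}
    for d, name in enumerate(names):
        lo, hi = obs[:, d].min(), obs[:, d].max()
        inc = increments[name]
        count = int(np.floor((hi - lo) / inc + 1e-9)) + 1
        axes[name] = lo + inc * np.arange(count)
    mesh = np.meshgrid(*axes.values(), indexing="ij")
    nodes = np.column_stack([m.ravel() for m in mesh])
    try:
        tri = Delaunay(obs)
    except QhullError as exc:
        raise HullError(
            "observed sample is degenerate (coplanar); consider a 2-D hull "
            "over the informative axes") from exc
    inside = tri.find_simplex(nodes) >= 0
    pred = np.full(nodes.shape[0], np.nan)
    if np.any(inside):
        frame = pd.DataFrame(nodes[inside], columns=names)
        pred[inside] = fit.predict(frame)
    shape = tuple(len(v) for v in axes.values())
    return ClimateSpaceGrid(axes=axes, mask=inside.reshape(shape),
                            predicted=pred.reshape(shape))
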
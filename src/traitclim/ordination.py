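"""PCA and redundancy analysis (RDA) of standardized trait matrices.

Both analyses operate on column-standardized log-CWM matrices, so PCA is an
eigen-analysis of the correlation structure.  RDA regresses the multivariate
response on the (standardized) bioclimatic predictors, performs a PCA of the
fitted values (constrained axes) and of the residuals (unconstrained axes),
and reports the fraction of total variance captured by the predictors.
Variance is scaled by ``n - 1`` throughout, matching the convention of the
usual vegetation-ordination tooling so oracle tests line up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class OrdinationError(ValueError):
    pass


@dataclass
class PcaResult:
    loadings: pd.DataFrame        # traits x axes, orthonormal columns
    scores: pd.DataFrame          # plots x axes
    eigenvalues: np.ndarray       # per axis, non-increasing
    variance_fraction: np.ndarray
    dropped_rows: list = field(default_factory=list)


@dataclass
class RdaResult:
    constrained: PcaResult        # PCA of fitted values
    unconstrained: PcaResult      # PCA of residuals
    biplot_scores: pd.DataFrame   # predictors x constrained axes
    constrained_fraction: float
    total_variance: float
    #: per-axis fraction of *total* variance (constrained axes)
    axis_fraction_total: np.ndarray
    #: per-axis fraction of *constrained* variance
    axis_fraction_constrained: np.ndarray


def _complete_cases(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    ok = matrix.notna().all(axis=1)
    return matrix.loc[ok], list(matrix.index[~ok])


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Deterministic sign convention: the largest-magnitude loading on each
    axis is positive."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return loadings, scores


def _pca_of(values: np.ndarray, index, columns, total_variance=None,
            dropped=None) -> PcaResult:
    n = values.shape[0]
    cov = values.T @ values / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    scores = values @ eigvec
    eigvec, scores = _fix_signs(eigvec, scores)
    total = float(eigval.sum()) if total_variance is None else total_variance
    frac = eigval / total if total > 0 else np.zeros_like(eigval)
    axes = [f"PC{i + 1}" for i in range(len(eigval))]
    return PcaResult(
        loadings=pd.DataFrame(eigvec, index=columns, columns=axes),
        scores=pd.DataFrame(scores, index=index, columns=axes),
        eigenvalues=eigval,
        variance_fraction=frac,
        dropped_rows=list(dropped or []),
    )


def pca(matrix: pd.DataFrame) -> PcaResult:
    """Principal component analysis of a standardized trait matrix.

    Rows with any missing entry are dropped (and reported on the result);
    requires at least 2 rows and 2 columns afterwards.
    """
    data, dropped = _complete_cases(matrix)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise OrdinationError(
            f"need >= 2 complete rows and >= 2 columns, got {data.shape}")
    return _pca_of(data.to_numpy(dtype=float), data.index, data.columns,
                   dropped=dropped)


def rda(response: pd.DataFrame, predictors: pd.DataFrame) -> RdaResult:
    """Redundancy analysis: PCA of the multivariate least-squares fit.

    ``response`` and ``predictors`` must share rows (rows missing in either
    are dropped).  Predictors must have full column rank.
    """
    common = response.index.intersection(predictors.index)
    y_df = response.loc[common]
    x_df = predictors.loc[common]
    keep = y_df.notna().all(axis=1) & x_df.notna().all(axis=1)
    y_df, x_df = y_df.loc[keep], x_df.loc[keep]
    y = y_df.to_numpy(dtype=float)
    x = x_df.to_numpy(dtype=float)
    n = y.shape[0]
    if n < 3:
        raise OrdinationError("need >= 3 complete joint rows")
    # center (standardization upstream already centers; be safe for raw input)
    y = y - y.mean(axis=0)
    x = x - x.mean(axis=0)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise OrdinationError("predictors are rank deficient (collinear)")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    y_hat = x @ beta
    resid = y - y_hat
    total = float(np.sum(y * y)) / (n - 1)
    constrained = _pca_of(y_hat, y_df.index, y_df.columns,
                          total_variance=total)
    unconstrained = _pca_of(resid, y_df.index, y_df.columns,
                            total_variance=total)
    constrained_var = float(constrained.eigenvalues.sum())
    frac = constrained_var / total if total > 0 else 0.0
    n_axes = min(x.shape[1], y.shape[1])
    site = constrained.scores.to_numpy()[:, :n_axes]
    with np.errstate(invalid="ignore", divide="ignore"):
        bip = np.array([
            [_safe_corr(x[:, j], site[:, a]) for a in range(n_axes)]
            for j in range(x.shape[1])
        ])
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    eig_c = constrained.eigenvalues[:n_axes]
    return RdaResult(
        constrained=constrained,
        unconstrained=unconstrained,
        biplot_scores=pd.DataFrame(bip, index=x_df.columns, columns=axes),
        constrained_fraction=frac,
        total_variance=total,
        axis_fraction_total=eig_c / total if total > 0 else eig_c * 0,
        axis_fraction_constrained=(eig_c / constrained_var
                                   if constrained_var > 0 else eig_c * 0),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def rotate_to_reference(result: PcaResult, reference_loadings: pd.DataFrame,
                        allow_permutation: bool = False) -> PcaResult:
    """Flip axis signs (and optionally reorder axes within equal-eigenvalue
    blocks) to best agree with reference loadings; eigenvalues unchanged."""
    if set(result.loadings.index) != set(reference_loadings.index):
        raise OrdinationError("trait names of result and reference differ")
    ref = reference_loadings.loc[result.loadings.index]
    load = result.loadings.to_numpy().copy()
    scores = result.scores.to_numpy().copy()
    eig = result.eigenvalues.copy()
    n_axes = min(load.shape[1], ref.shape[1])
    order = np.arange(load.shape[1])
    if allow_permutation:
        # reorder only within blocks of (numerically) equal eigenvalues
        blocks: list[list[int]] = []
        for a in range(n_axes):
            if blocks and np.isclose(eig[a], eig[blocks[-1][-1]],
                                     rtol=1e-9, atol=1e-12):
                blocks[-1].append(a)
            else:
                blocks.append([a])
        for block in blocks:
            if len(block) == 1:
                continue
            sub = np.abs(load[:, block].T @ ref.to_numpy()[:, block])
            # greedy assignment inside the block
            perm = list(block)
            for bi, _ in enumerate(block):
                j = int(np.argmax(sub[bi]))
                perm[bi] = block[j]
                sub[:, j] = -np.inf
            order[block] = perm
    load = load[:, order]
    scores = scores[:, order]
    for a in range(n_axes):
        if float(load[:, a] @ ref.to_numpy()[:, a]) < 0:
            load[:, a] *= -1
            scores[:, a] *= -1
    return PcaResult(
        loadings=pd.DataFrame(load, index=result.loadings.index,
                              columns=result.loadings.columns),
        scores=pd.DataFrame(scores, index=result.scores.index,
                            columns=result.scores.columns),
        eigenvalues=eig,
        variance_fraction=result.variance_fraction.copy(),
        dropped_rows=list(result.dropped_rows),
    )
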
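"""Biogeographic clustering and spatially correlated linear mixed models.

Cells are first partitioned into spatially connected biogeographic groups by
contiguity-constrained Ward clustering of Hellinger-transformed preindustrial
composition (six groups by default). Relationships between community-index
changes and drivers are then tested with linear mixed models

    y = X beta + b_group + eps,   b_group ~ N(0, sigma_b^2),
    Cov(eps_i, eps_j) = sigma^2 exp(-d_ij / rho)   (same group, else 0)

i.e. a group random intercept plus an exponential spatial correlation among
cells of the same group with range parameter rho (km) and no nugget.
Variance components are estimated by REML with the fixed effects profiled
out by generalized least squares; Wald t-tests use a between-within style
degrees-of-freedom approximation, and conditional R^2 is
(var_fixed + sigma_b^2) / (var_fixed + sigma_b^2 + sigma^2), assigning the
spatially structured variance to the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import AgglomerativeClustering

__all__ = ["MixedModelFit", "constrained_clustering", "fit_lmm", "model_suite"]

_RHO_BOUNDS_KM = (0.05, 5e3)
_GAMMA_BOUNDS = (1e-8, 1e4)


def constrained_clustering(
    historical_freq: pd.DataFrame,
    adjacency: sparse.spmatrix,
    k: int,
) -> pd.Series:
    """Spatially constrained Ward clustering of preindustrial composition.

    Frequencies are Hellinger-transformed (square root of the row-normalized
    profile) and clustered agglomeratively with merges restricted to
    spatially adjacent groups, cut at ``k`` groups. Deterministic.

    Parameters
    ----------
    historical_freq
        Tidy table (``cell``, ``taxon``, ``frequency``), historical period.
    adjacency
        Cell adjacency over the full grid (e.g. :meth:`Grid.adjacency`).
    k
        Number of groups.

    Returns
    -------
    Series mapping cell id -> group label in {0..k-1}.
    """
    wide = historical_freq.pivot_table(
        index="cell", columns="taxon", values="frequency", fill_value=0.0
    )
    cells = wide.index.to_numpy()
    if k > len(cells):
        raise ValueError(f"k={k} exceeds the {len(cells)} analyzed cells")
    sub = adjacency.tocsr()[cells][:, cells]
    n_comp, comp = connected_components(sub, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"analyzed cells form {n_comp} disconnected components "
            f"(sizes {sizes.tolist()}); clustering needs a connected grid"
        )
    profile = wide.to_numpy(float)
    rowsum = profile.sum(axis=1, keepdims=True)
    if (rowsum <= 0).any():
        raise ValueError("cell with all-zero composition")
    hell = np.sqrt(profile / rowsum)
    if k == 1:
        labels = np.zeros(len(cells), dtype=int)
    else:
        model = AgglomerativeClustering(
            n_clusters=k, linkage="ward", connectivity=sub
        )
        labels = model.fit_predict(hell)
    return pd.Series(labels, index=pd.Index(cells, name="cell"), name="group")


@dataclass
class MixedModelFit:
    """REML fit of the spatial mixed model."""

    terms: pd.DataFrame  # estimate, se, t, df, p per fixed-effect term
    sigma2: float  # residual (spatially structured) variance
    sigma2_group: float  # random-intercept variance
    rho_km: float  # exponential correlation range
    loglik_reml: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    converged: bool = True
    boundary: bool = False
    degenerate: bool = False
    formula: str = ""

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def _reml_pieces(y, X, blocks, gamma, rho):
    """Profiled REML quantities for V0 = gamma*J + exp(-D/rho), block-diagonal.

    Returns (f, beta, XtViX_inv, quad) where f is the criterion to minimize:
    logdet(V0) + logdet(X'V0^-1 X) + (n-p) log(r'V0^-1 r).
    """
    n, p = X.shape
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    solves = []
    for idx, D in blocks:
        V = gamma + np.exp(-D / rho)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        Z = np.linalg.solve(L, np.column_stack([X[idx], y[idx]]))
        solves.append((idx, L, Z))
        XtViX += Z[:, :p].T @ Z[:, :p]
        XtViy += Z[:, :p].T @ Z[:, p]
    try:
        cF = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError:
        return None
    beta = np.linalg.solve(XtViX, XtViy)
    quad = 0.0
    for idx, L, Z in solves:
        resid_w = Z[:, p] - Z[:, :p] @ beta
        quad += resid_w @ resid_w
    logdet_xvx = 2.0 * np.sum(np.log(np.diag(cF)))
    if quad <= 0:
        return logdet, logdet_xvx, beta, XtViX, 0.0
    return logdet, logdet_xvx, beta, XtViX, quad


def fit_lmm(
    y: pd.Series,
    X: pd.DataFrame,
    groups: pd.Series,
    coords: pd.DataFrame,
    add_intercept: bool = True,
    starts: tuple[tuple[float, float], ...] | None = None,
) -> MixedModelFit:
    """Fit the group-intercept + exponential-spatial-correlation mixed model.

    Parameters
    ----------
    y
        Response per cell (e.g. a Delta community index).
    X
        Predictor columns per cell (complete cases only are used).
    groups
        Cluster label per cell (the random factor).
    coords
        ``x``/``y`` cell coordinates in km.
    add_intercept
        Prepend a constant column.
    starts
        Optional (gamma, rho) multi-start grid overriding the default.

    Notes
    -----
    The variance ratio gamma = sigma_b^2/sigma^2 and range rho are optimized
    on the log scale by Nelder-Mead from the best point of a coarse grid;
    sigma^2 is profiled out. A fit with rho or gamma at its bound is
    returned with ``boundary=True``; a response with (numerically) zero
    variance returns a degenerate fit with all coefficients 0.
    """
    xy_cols = coords[["x", "y"]].rename(columns={"x": "__cx", "y": "__cy"})
    data = pd.concat(
        [y.rename("__y"), X, groups.rename("__g"), xy_cols], axis=1
    ).dropna()
    if len(data) < len(X.columns) + 3:
        raise ValueError("too few complete cases")
    yv = data["__y"].to_numpy(float)
    Xm = data[X.columns].to_numpy(float)
    names = list(X.columns)
    if add_intercept:
        Xm = np.column_stack([np.ones(len(data)), Xm])
        names = ["(Intercept)"] + names
    g = data["__g"].to_numpy()
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need at least 2 groups for the random factor")
    xy = data[["__cx", "__cy"]].to_numpy(float)
    blocks = []
    for lab in labels:
        idx = np.flatnonzero(g == lab)
        D = squareform(pdist(xy[idx])) if idx.size > 1 else np.zeros((1, 1))
        blocks.append((idx, D))
    n, p = Xm.shape
    formula = f"y ~ {' + '.join(names)}"

    # degenerate response: zero variance => exact zero-slope fit
    if np.ptp(yv) == 0.0:
        beta = np.zeros(p)
        if add_intercept:
            beta[0] = yv[0]
        terms = pd.DataFrame(
            {
                "estimate": beta,
                "se": 0.0,
                "t": np.nan,
                "df": np.nan,
                "p": np.nan,
            },
            index=pd.Index(names, name="term"),
        )
        return MixedModelFit(
            terms, 0.0, 0.0, np.nan, np.nan, np.nan, n, labels.size,
            degenerate=True, formula=formula,
        )

    def objective(theta):
        gamma = np.exp(theta[0])
        rho = np.exp(theta[1])
        if not (
            _GAMMA_BOUNDS[0] <= gamma <= _GAMMA_BOUNDS[1]
            and _RHO_BOUNDS_KM[0] <= rho <= _RHO_BOUNDS_KM[1]
        ):
            return np.inf
        pieces = _reml_pieces(yv, Xm, blocks, gamma, rho)
        if pieces is None:
            return np.inf
        logdet, logdet_xvx, _, _, quad = pieces
        if quad <= 0:
            return np.inf
        return logdet + logdet_xvx + (n - p) * np.log(quad)

    if starts is None:
        starts = tuple(
            (gm, rh)
            for gm in (1e-4, 0.1, 1.0, 10.0)
            for rh in (1.0, 5.0, 20.0, 100.0)
        )
    grid = [(objective(np.log([gm, rh])), (gm, rh)) for gm, rh in starts]
    grid_best_f, (gm0, rh0) = min(grid, key=lambda t: t[0])
    res = optimize.minimize(
        objective,
        np.log([gm0, rh0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
    )
    theta = res.x if res.fun <= grid_best_f else np.log([gm0, rh0])
    fval = min(res.fun, grid_best_f)
    converged = bool(res.success or res.fun <= grid_best_f)
    if not np.isfinite(fval):
        raise RuntimeError(
            f"REML optimization failed to find a finite criterion: {res}"
        )
    gamma_hat = float(np.exp(theta[0]))
    rho_hat = float(np.exp(theta[1]))
    boundary = (
        gamma_hat <= _GAMMA_BOUNDS[0] * 1.01
        or rho_hat <= _RHO_BOUNDS_KM[0] * 1.01
        or rho_hat >= _RHO_BOUNDS_KM[1] * 0.99
    )
    logdet, logdet_xvx, beta, XtViX, quad = _reml_pieces(
        yv, Xm, blocks, gamma_hat, rho_hat
    )
    sigma2 = quad / (n - p)
    sigma2_b = gamma_hat * sigma2
    cov_beta = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    n_within = max(p - 1, 1) if add_intercept else p
    df = max(n - labels.size - (p - 1 if add_intercept else p), 1)
    tstat = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    loglik = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        + logdet
        + logdet_xvx
        + (n - p)
    )
    var_fixed = float(np.var(Xm @ beta))
    denom = var_fixed + sigma2_b + sigma2
    r2c = (var_fixed + sigma2_b) / denom if denom > 0 else np.nan
    terms = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tstat, "df": float(df), "p": pvals},
        index=pd.Index(names, name="term"),
    )
    return MixedModelFit(
        terms,
        float(sigma2),
        float(sigma2_b),
        rho_hat,
        float(loglik),
        float(r2c),
        n,
        int(labels.size),
        converged=converged,
        boundary=boundary,
        formula=formula,
    )


#: the model suite: single-predictor, controlled, and cross-index models
MODEL_SUITE_SPEC: dict[str, tuple[str, list[str]]] = {
    "cti~temp": ("delta_cti", ["delta_temperature"]),
    "cdti~spei": ("delta_cdti", ["delta_spei"]),
    "csti~pop": ("delta_csti", ["log_delta_population"]),
    "cdi~pop": ("delta_cdi", ["log_delta_population"]),
    "cti~temp|dist": (
        "delta_cti",
        ["delta_temperature", "delta_csti", "delta_cdi"],
    ),
    "cdti~spei|dist": (
        "delta_cdti",
        ["delta_spei", "delta_csti", "delta_cdi"],
    ),
    "csti~pop|clim": (
        "delta_csti",
        ["log_delta_population", "delta_cti", "delta_cdti"],
    ),
    "cdi~pop|clim": (
        "delta_cdi",
        ["log_delta_population", "delta_cti", "delta_cdti"],
    ),
    "cti~dist": ("delta_cti", ["delta_csti", "delta_cdi"]),
    "cdti~dist": ("delta_cdti", ["delta_csti", "delta_cdi"]),
}


def model_suite(
    deltas: pd.DataFrame,
    drivers: pd.DataFrame,
    groups: pd.Series,
    coords: pd.DataFrame,
) -> dict[str, MixedModelFit]:
    """Fit the full suite of 4 single-predictor, 4 controlled and 2
    cross-index mixed models relating index changes to drivers.

    ``deltas`` must carry delta_cti/delta_cdti/delta_csti/delta_cdi,
    ``drivers`` delta_temperature/delta_spei/log_delta_population; all tables
    are aligned on the cell index.
    """
    table = deltas.join(drivers, how="inner")
    needed = {
        col
        for resp, preds in MODEL_SUITE_SPEC.values()
        for col in [resp] + preds
    }
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"missing columns for model suite: {sorted(missing)}")
    fits = {}
    for name, (resp, preds) in MODEL_SUITE_SPEC.items():
        fits[name] = fit_lmm(table[resp], table[preds], groups, coords)
    return fits
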
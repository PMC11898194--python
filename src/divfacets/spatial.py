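"""Predictor preparation and spatially explicit inference.

Covers four jobs:

* predictor prep — Last Glacial Maximum climate anomalies (mean absolute
  current-vs-LGM difference over general circulation models), z-score
  standardization, and an iterative collinearity screen (pairwise Pearson
  |r| then variance inflation factors);
* a generalized least squares model with exponential spatial correlation,
  cor(e_i, e_j) = exp(-d_ij / rho), the range rho estimated by profile
  (RE)ML over cell-centroid distances, exposed as a model object whose
  ``fit()`` returns a results object with estimates, SEs, t, p and a
  ``summary()`` table;
* Dutilleul's modified t-test for the correlation of two spatially
  autocorrelated variables, replacing n with an effective sample size
  estimated from both variables' distance-class correlograms;
* Kruskal-Wallis / Dunn group comparisons with a compact-letter display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

# ---------------------------------------------------------------------------
# Predictor preparation


def lgm_anomaly(current: np.ndarray, lgm_by_gcm) -> np.ndarray:
    """Climate anomaly: mean over GCMs of |current - LGM| per cell."""
    current = np.asarray(current, dtype=float)
    layers = [np.asarray(l, dtype=float) for l in lgm_by_gcm]
    if len(layers) == 0:
        raise ValueError("at least one LGM model layer required")
    for l in layers:
        if l.shape != current.shape:
            raise ValueError("LGM layer shape does not match current layer")
    return np.mean([np.abs(current - l) for l in layers], axis=0)


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center each column to mean 0, SD 1 (n-1 denominator).

    Returns the standardized table and a parameter table (mean, sd per
    column) for reporting/back-transforming.  Constant columns raise.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    const = sds[sds == 0].index.tolist()
    if const:
        raise ValueError(f"constant column(s) cannot be standardized: {const}")
    params = pd.DataFrame({"mean": means, "sd": sds})
    return (table - means) / sds, params


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1/(1-R^2) of each column on the others."""
    X = table.to_numpy(dtype=float)
    n, k = X.shape
    out = {}
    for j, name in enumerate(table.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"constant variable: {name}")
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def collinearity_screen(
    table: pd.DataFrame, r_max: float = 0.7, vif_max: float = 5.0
) -> tuple[list[str], list[dict]]:
    """Iterative collinearity screen: pairwise |r|, then VIF.

    While any pair of remaining variables has |Pearson r| >= ``r_max``,
    drop — from the worst pair — the member with the larger mean absolute
    correlation to all other remaining variables.  Then, while any VIF
    >= ``vif_max``, drop the largest-VIF variable.  Deterministic given
    column order (ties keep the earlier column).  Returns the retained
    names and a removal log.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 rows")
    sds = table.std(ddof=1)
    const = sds[sds == 0].index.tolist()
    if const:
        raise ValueError(f"constant variable(s): {const}")

    cols = list(table.columns)
    log: list[dict] = []
    while True:
        corr = table[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        if corr.loc[worst] < r_max:
            break
        a, b = worst
        if len(cols) > 2:
            mean_a = corr.loc[a].drop([a, b]).mean()
            mean_b = corr.loc[b].drop([a, b]).mean()
        else:
            mean_a = mean_b = 0.0
        drop = a if mean_a > mean_b else b if mean_b > mean_a else (
            a if cols.index(a) > cols.index(b) else b
        )
        log.append(
            {"stage": "pairwise", "dropped": drop, "with": b if drop == a else a,
             "statistic": float(corr.loc[worst])}
        )
        cols.remove(drop)
        if len(cols) < 2:
            return cols, log
    while len(cols) >= 2:
        v = vif(table[cols])
        if v.max() < vif_max:
            break
        drop = v.idxmax()
        log.append({"stage": "vif", "dropped": drop, "statistic": float(v.max())})
        cols.remove(drop)
    return cols, log


# ---------------------------------------------------------------------------
# Spatial GLS with exponential correlation


@dataclass
class GLSResults:
    """Estimates from an exponential-correlation GLS fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rho: float
    sigma2: float
    loglik: float
    method: str
    nobs: int
    df_resid: int
    converged: bool

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Generalized least squares (exponential spatial correlation)",
            f"method: {self.method}   n = {self.nobs}   df_resid = {self.df_resid}",
            f"range rho = {self.rho:.4g} km   sigma2 = {self.sigma2:.4g}   "
            f"logLik = {self.loglik:.4f}   converged = {self.converged}",
            "",
            f"{'variable':<22}{'estimate':>12}{'SE':>12}{'t':>10}{'p':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{self.tvalues[name]:>10.3f}{self.pvalues[name]:>12.3g}"
            )
        return "\n".join(lines)


class ExponentialGLS:
    """GLS regression with exponential residual spatial correlation.

    y = X beta + e,  cor(e_i, e_j) = exp(-d_ij / rho), d the Euclidean
    distance between cell centroids.  The range rho is profiled out by a
    1-D optimization of the restricted (REML, default) or full (ML)
    log-likelihood over log rho; beta and sigma^2 have closed forms given
    rho via the correlation matrix's Cholesky factor.

    Parameters
    ----------
    y : (n,) response per cell.
    X : DataFrame or array of predictors (already standardized for
        comparable coefficients); an intercept is added unless present.
    coords : (n, 2) centroid coordinates, km.
    method : "REML" (default) or "ML".
    """

    def __init__(self, y, X, coords, method: str = "REML", add_intercept: bool = True):
        y = np.asarray(y, dtype=float)
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xarr = X.to_numpy(dtype=float)
        else:
            Xarr = np.asarray(X, dtype=float)
            if Xarr.ndim == 1:
                Xarr = Xarr[:, None]
            names = [f"x{j}" for j in range(Xarr.shape[1])]
        if add_intercept and not any(
            np.allclose(Xarr[:, j], Xarr[0, j]) and Xarr[0, j] != 0
            for j in range(Xarr.shape[1])
        ):
            Xarr = np.column_stack([np.ones(len(y)), Xarr])
            names = ["Intercept"] + names
        coords = np.asarray(coords, dtype=float)
        n, k = Xarr.shape
        if n <= k + 2:
            raise ValueError("need n > k + 2 observations")
        if y.shape[0] != n or coords.shape[0] != n:
            raise ValueError("y, X and coords must have matching length")
        if np.linalg.matrix_rank(Xarr) < k:
            raise ValueError("singular design matrix")
        self.y, self.X, self.names, self.coords = y, Xarr, names, coords
        if method.upper() not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        self.method = method.upper()
        self._D = squareform(pdist(coords))
        d_off = self._D[np.triu_indices(n, 1)]
        if d_off.min() <= 0:
            raise ValueError("coordinates must be distinct")
        self._dmax = float(d_off.max())
        self._d10 = float(np.percentile(d_off, 10))

    # -- likelihood machinery ------------------------------------------------

    def _profile(self, rho: float):
        n, k = self.X.shape
        C = np.exp(-self._D / rho)
        C[np.diag_indices(n)] += 1e-10  # numerical jitter for the factorization
        L = np.linalg.cholesky(C)
        Xw = solve_triangular(L, self.X, lower=True)
        yw = solve_triangular(L, self.y, lower=True)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
        if self.method == "REML":
            dof = n - k
            sigma2 = rss / dof
            sign, logdet_XtX = np.linalg.slogdet(XtX)
            ll = -0.5 * (
                dof * math.log(2 * math.pi * sigma2)
                + logdet_C
                + logdet_XtX
                + dof
            )
        else:
            sigma2 = rss / n
            ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_C + n)
        return ll, beta, sigma2, XtX

    def fit(self, rho_bounds: tuple[float, float] | None = None) -> GLSResults:
        n, k = self.X.shape
        if rho_bounds is None:
            rho_bounds = (1e-3 * self._dmax, 10.0 * self._dmax)
        lo, hi = math.log(rho_bounds[0]), math.log(rho_bounds[1])

        def nll(log_rho: float) -> float:
            return -self._profile(math.exp(log_rho))[0]

        # coarse scan first: the profile can be nearly flat (white noise)
        # or multi-modal, where a single bounded search stalls
        grid = np.linspace(lo, hi, 17)
        grid_nll = [nll(g) for g in grid]
        i_best = int(np.argmin(grid_nll))
        b_lo = grid[max(i_best - 1, 0)]
        b_hi = grid[min(i_best + 1, len(grid) - 1)]
        res = minimize_scalar(nll, bounds=(b_lo, b_hi), method="bounded",
                              options={"xatol": 1e-6})
        converged = bool(res.success)
        candidates = [(float(res.fun), float(res.x)),
                      (grid_nll[i_best], grid[i_best]),
                      (grid_nll[0], lo), (grid_nll[-1], hi)]
        _, best_x = min(candidates)
        rho = math.exp(best_x)
        ll, beta, sigma2, XtX = self._profile(rho)
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        df = n - k
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        idx = pd.Index(self.names)
        return GLSResults(
            params=pd.Series(beta, index=idx),
            bse=pd.Series(se, index=idx),
            tvalues=pd.Series(tvals, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            rho=rho,
            sigma2=sigma2,
            loglik=ll,
            method=self.method,
            nobs=n,
            df_resid=df,
            converged=converged,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, predictors: list[str],
        coord_cols: tuple[str, str] = ("x", "y"), **kw
    ) -> "ExponentialGLS":
        return cls(
            df[response].to_numpy(),
            df[list(predictors)],
            df[list(coord_cols)].to_numpy(),
            **kw,
        )


# ---------------------------------------------------------------------------
# Dutilleul's modified t-test


@dataclass
class ModifiedCorrelation:
    r: float
    n: int
    n_eff: float
    t: float
    p: float


def _class_correlogram(z: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Moran-type autocorrelation estimate of centered z per distance class."""
    denom = float(z @ z)
    n = z.shape[0]
    out = np.zeros(len(masks))
    for k, m in enumerate(masks):
        w = int(m.sum())
        if w == 0 or denom == 0:
            out[k] = 0.0
            continue
        out[k] = (n / w) * float(z @ (m @ z)) / denom
    return np.clip(out, -1.0, 1.0)


def modified_ttest(
    a, b, coords, n_classes: int = 12
) -> ModifiedCorrelation:
    """Correlation of two spatial variables with Dutilleul's corrected df.

    Pearson r is unchanged; the effective sample size n_eff is estimated
    from both variables' distance-class correlograms (equal-width classes
    up to half the maximum pairwise distance) and replaces n in
    t = r * sqrt((n_eff - 2) / (1 - r^2)).  With no autocorrelation n_eff
    approaches n, recovering the classical test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = a.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    r = float(np.corrcoef(a, b)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("|r| = 1: degenerate input")

    D = squareform(pdist(coords))
    dmax = D[np.triu_indices(n, 1)].max() / 2.0
    edges = np.linspace(0, dmax, n_classes + 1)
    masks = []
    for k in range(n_classes):
        m = (D > edges[k]) & (D <= edges[k + 1])
        np.fill_diagonal(m, False)
        masks.append(m)

    za = a - a.mean()
    zb = b - b.mean()
    rho_a = _class_correlogram(za, masks)
    rho_b = _class_correlogram(zb, masks)

    Sa = np.eye(n)
    Sb = np.eye(n)
    for k, m in enumerate(masks):
        Sa[m] = rho_a[k]
        Sb[m] = rho_b[k]
    B = np.eye(n) - np.full((n, n), 1.0 / n)
    BSa = B @ Sa
    BSb = B @ Sb
    num = np.trace(BSa) * np.trace(BSb)
    den = float(np.sum(BSa * BSb.T))  # tr(B Sa B Sb)
    if den <= 0:
        n_eff = float(n)
    else:
        n_eff = 1.0 + num / den
    n_eff = float(min(max(n_eff, 2.0 + 1e-6), n))
    t = r * math.sqrt((n_eff - 2.0) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n_eff - 2.0)
    return ModifiedCorrelation(r=r, n=n, n_eff=n_eff, t=t, p=p)


# ---------------------------------------------------------------------------
# Group comparisons: Kruskal-Wallis + Dunn + compact letters


@dataclass
class GroupComparison:
    h: float
    p: float
    dunn: pd.DataFrame  # group_a, group_b, z, p, p_adj
    letters: dict[str, str]


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * pvals[idx]
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


def _compact_letters(groups: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Letter display: groups sharing a letter are not significantly different."""
    same = {g: {g} for g in groups}
    for a, b in nonsig:
        same[a].add(b)
        same[b].add(a)
    # maximal cliques of the "not different" graph (brute force; few groups)
    from itertools import combinations

    cliques: list[set[str]] = []
    for size in range(len(groups), 0, -1):
        for combo in combinations(groups, size):
            s = set(combo)
            if all(y in same[x] for x, y in combinations(combo, 2)):
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, c in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in c:
                letters[g] += ch
    return letters


def group_compare(
    values, groups, p_adjust: str = "holm", alpha: float = 0.05
) -> GroupComparison:
    """Kruskal-Wallis test plus pairwise Dunn z tests among groups.

    H uses the tie-corrected rank-sum statistic; Dunn z statistics use the
    pooled tie correction, with p-values adjusted by ``p_adjust`` (holm,
    bonferroni or none).  Returns a compact-letter display where groups
    sharing a letter do not differ at ``alpha`` (adjusted).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = [str(g) for g in pd.unique(labels)]
    samples = {g: values[labels == g] for g in names}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    small = [g for g, v in samples.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    h, p = stats.kruskal(*[samples[g] for g in names])

    N = values.size
    ranks = stats.rankdata(values)
    rank_mean = {g: ranks[labels == g].mean() for g in names}
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    rows = []
    from itertools import combinations

    for a, b in combinations(names, 2):
        na, nb = samples[a].size, samples[b].size
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (rank_mean[a] - rank_mean[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p": 2.0 * stats.norm.sf(abs(z))})
    dunn = pd.DataFrame(rows)
    praw = dunn["p"].to_numpy()
    if p_adjust == "holm":
        dunn["p_adj"] = _holm(praw)
    elif p_adjust == "bonferroni":
        dunn["p_adj"] = np.minimum(praw * len(praw), 1.0)
    elif p_adjust == "none":
        dunn["p_adj"] = praw
    else:
        raise ValueError(f"unknown p_adjust: {p_adjust}")

    order = sorted(names, key=lambda g: rank_mean[g], reverse=True)
    nonsig = {
        (row["group_a"], row["group_b"])
        for _, row in dunn.iterrows()
        if row["p_adj"] >= alpha
    }
    letters = _compact_letters(order, nonsig)
    return GroupComparison(h=float(h), p=float(p), dunn=dunn, letters=letters)
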
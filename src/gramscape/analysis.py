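"""Statistics on trait landscapes: adaptive peaks, ridges, coordination indices.

Operates on the landscape tables produced by :mod:`gramscape.experiment`:
locates the trait combination maximising performance (the adaptive peak),
fits adaptive ridges (the line of locally optimal trait pairs) and their
slopes, aggregates them into a coordination index, and provides the
comparison statistics used to confront predicted optima with observed traits
(reduced major axis regression, PCA axis comparison, plasticity prediction,
variance decomposition).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import TRAIT_NAMES

__all__ = [
    "OptimumResult",
    "RidgeFit",
    "RMAFit",
    "PCAComparison",
    "find_trait_max",
    "fit_ridge",
    "fit_all_ridges",
    "alpha_sum",
    "rma_fit",
    "predict_plasticity",
    "pca_compare",
    "cn_trait_regressions",
    "variance_decomposition",
    "is_unimodal",
    "cn_homeostasis",
    "TRAIT_PAIRS",
]

#: The six unordered trait pairs, in (i, j) ridge convention: j = f(i).
TRAIT_PAIRS = [("td0", "sla"), ("td0", "lls"), ("td0", "h"),
               ("sla", "h"), ("sla", "lls"), ("h", "lls")]


@dataclass(frozen=True)
class OptimumResult:
    """The adaptive peak of one landscape."""

    traits: dict            # trait name -> value at the peak
    indices: dict           # trait name -> grid index at the peak
    performance: float      # peak performance (g per plant per year)
    cn_opt: float           # mean substrate C:N at the peak (gC gN-1)


@dataclass(frozen=True)
class RidgeFit:
    """Linear fit through locally optimal (i, j) trait combinations."""

    trait_i: str
    trait_j: str
    slope: float            # units of j per unit of i
    intercept: float
    r2: float
    n: int
    i_values: tuple
    j_star: tuple


@dataclass(frozen=True)
class RMAFit:
    """Reduced major axis regression: symmetric line fit."""

    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class PCAComparison:
    """Comparison of the PCA of predicted vs observed trait matrices."""

    loadings_pred: np.ndarray    # columns = axes
    loadings_obs: np.ndarray
    var_frac_pred: np.ndarray
    var_frac_obs: np.ndarray
    axis_stats: list             # per axis: dict(slope, intercept, r2, rel_rmse)
    scores_pred: np.ndarray
    scores_obs: np.ndarray


def _ok_rows(table: pd.DataFrame) -> pd.DataFrame:
    ok = table[table["status"] == "ok"] if "status" in table.columns else table
    if len(ok) == 0:
        raise ValueError("landscape table contains no successful rows")
    return ok


def find_trait_max(table: pd.DataFrame) -> OptimumResult:
    """Exact argmax of performance over successful rows.

    Ties break toward the lowest grid-index tuple (deterministic).
    """
    ok = _ok_rows(table)
    idx_cols = ["i_" + t for t in TRAIT_NAMES if "i_" + t in ok.columns]
    ok = ok.sort_values(idx_cols or list(ok.columns[:1]), kind="stable")
    # first occurrence of the maximum in index order = lowest index tuple
    best = ok.iloc[int(np.argmax(ok["performance"].to_numpy()))]
    return OptimumResult(
        traits={t: float(best[t]) for t in TRAIT_NAMES if t in ok.columns},
        indices={t: int(best["i_" + t]) for t in TRAIT_NAMES
                 if "i_" + t in ok.columns},
        performance=float(best["performance"]),
        cn_opt=float(best.get("mean_cn", np.nan)),
    )


def fit_ridge(table: pd.DataFrame, trait_i: str, trait_j: str,
              fixed: dict[str, float] | None = None,
              refine: bool = False) -> RidgeFit:
    """Fit the adaptive ridge between two traits.

    The table is restricted to the sub-grid where the two remaining traits
    equal ``fixed`` (snapped to the nearest grid values).  For each
    grid value of trait i the performance-maximising value of trait j is
    found (ties toward lower j), and an ordinary least-squares line j* = a·i
    + b is fitted across these local optima.
    """
    ok = _ok_rows(table)
    others = [t for t in TRAIT_NAMES if t not in (trait_i, trait_j)]
    if fixed is None:
        raise ValueError("fixed values for the two remaining traits are required")
    sub = ok
    for t in others:
        if t not in fixed:
            raise ValueError(f"fixed value for trait {t!r} missing")
        vals = np.sort(sub[t].unique())
        target = vals[np.argmin(np.abs(vals - fixed[t]))]
        sub = sub[np.isclose(sub[t], target, rtol=1e-9)]
    gi = np.sort(sub[trait_i].unique())
    gj = np.sort(sub[trait_j].unique())
    if len(gi) < 2 or len(gj) < 2:
        raise ValueError("sub-grid too small for a ridge fit")
    j_star = []
    for vi in gi:
        rows = sub[np.isclose(sub[trait_i], vi, rtol=1e-9)]
        if len(rows) < len(gj):
            raise ValueError("incomplete sub-grid: missing rows for some j values")
        rows = rows.sort_values(trait_j, kind="stable")
        perf = rows["performance"].to_numpy()
        jv = rows[trait_j].to_numpy()
        k = int(np.argmax(perf))
        j_best = float(jv[k])
        if refine and 0 < k < len(jv) - 1:
            # quadratic through the argmax and its neighbours
            y0, y1, y2 = perf[k - 1], perf[k], perf[k + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                j_best = float(jv[k] + 0.5 * (y0 - y2) / denom * (jv[k + 1] - jv[k]))
        j_star.append(j_best)
    res = stats.linregress(gi, j_star)
    r2 = float(res.rvalue ** 2) if np.std(j_star) > 0 else 0.0
    return RidgeFit(trait_i=trait_i, trait_j=trait_j,
                    slope=float(res.slope), intercept=float(res.intercept),
                    r2=r2, n=len(gi), i_values=tuple(gi), j_star=tuple(j_star))


def fit_all_ridges(table: pd.DataFrame, observed: dict[str, float]) -> dict:
    """Fit the six trait-pair ridges with the remaining traits fixed at their
    observed values."""
    out = {}
    for i_name, j_name in TRAIT_PAIRS:
        fixed = {t: observed[t] for t in TRAIT_NAMES if t not in (i_name, j_name)}
        out[(i_name, j_name)] = fit_ridge(table, i_name, j_name, fixed)
    return out


def alpha_sum(ridges: dict, traits_observed: dict[str, float]) -> dict:
    """Aggregate the six ridge slopes into a dimensionless coordination index.

    Each slope is nondimensionalised by the observed trait ratio
    (alpha_rel = alpha * observed_i / observed_j), and the index is the sum
    of their absolute values.  This is the only unit-free convention
    computable from the observed traits alone.
    """
    rel = {}
    total = 0.0
    for (i_name, j_name), fit in ridges.items():
        oi, oj = traits_observed[i_name], traits_observed[j_name]
        if oi == 0 or oj == 0:
            raise ValueError("observed trait values must be nonzero")
        a_rel = fit.slope * oi / oj
        rel[(i_name, j_name)] = a_rel
        total += abs(a_rel)
    return dict(alpha_rel=rel, alpha_sum=total)


def rma_fit(x, y) -> RMAFit:
    """Reduced major axis regression.

    slope = sign(corr) * sd(y)/sd(x); intercept through the means; r2 is the
    squared Pearson correlation.  Used when both variables carry error (e.g.
    predicted vs observed trait values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("rma_fit needs at least 3 paired points")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate variance in rma_fit input")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return RMAFit(slope=float(slope), intercept=intercept, r2=r * r, n=len(x))


def predict_plasticity(table_high: pd.DataFrame, fixed: dict[str, float],
                       target: str) -> float:
    """Predict the plastic response of one trait from the high-N landscape.

    The three remaining traits are forced to ``fixed`` (snapped to the
    nearest grid values, which must lie inside the grid hull) and the
    target-trait value maximising performance on that 1-D section is
    returned — i.e. the conditional argmax of the high-N landscape at the
    low-N trait values.
    """
    ok = _ok_rows(table_high)
    others = [t for t in TRAIT_NAMES if t != target]
    if set(fixed) != set(others):
        raise ValueError(f"fixed must provide exactly {others}")
    sub = ok
    for t in others:
        vals = np.sort(sub[t].unique())
        if not (vals.min() - 1e-9 <= fixed[t] <= vals.max() + 1e-9):
            raise ValueError(f"fixed value for {t!r} outside the grid hull")
        target_v = vals[np.argmin(np.abs(vals - fixed[t]))]
        sub = sub[np.isclose(sub[t], target_v, rtol=1e-9)]
    if len(sub) == 0:
        raise ValueError("empty section after snapping fixed values")
    sub = sub.sort_values(target, kind="stable")
    perf = sub["performance"].to_numpy()
    return float(sub[target].to_numpy()[int(np.argmax(perf))])


def pca_compare(predicted: pd.DataFrame, observed: pd.DataFrame) -> PCAComparison:
    """PCA (correlation matrix) of predicted and observed trait matrices and
    per-axis regression of predicted on observed species scores.

    Columns are z-standardised; the axis sign convention makes the loading
    with the largest magnitude positive; the per-axis relative RMSE is
    100 * RMSE / range(observed scores).
    """
    if list(predicted.columns) != list(observed.columns):
        raise ValueError("predicted and observed must share columns")
    if len(predicted) != len(observed) or len(predicted) < 3:
        raise ValueError("matching species rows (>= 3) required")

    def _pca(df):
        z = (df - df.mean()) / df.std(ddof=1)
        if z.isna().any().any():
            raise ValueError("rank-deficient input (constant column)")
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(v.shape[1]):
            if v[np.argmax(np.abs(v[:, k])), k] < 0:
                v[:, k] = -v[:, k]
        scores = z.to_numpy() @ v
        return v, w / w.sum(), scores

    lp, vp, sp = _pca(predicted)
    lo, vo, so = _pca(observed)
    axis_stats = []
    for k in range(min(2, lp.shape[1])):
        res = stats.linregress(so[:, k], sp[:, k])
        rmse = float(np.sqrt(np.mean((sp[:, k] - so[:, k]) ** 2)))
        rng = float(np.ptp(so[:, k]))
        axis_stats.append(dict(slope=float(res.slope),
                               intercept=float(res.intercept),
                               r2=float(res.rvalue ** 2),
                               rel_rmse=100.0 * rmse / rng if rng > 0 else np.inf))
    return PCAComparison(loadings_pred=lp, loadings_obs=lo,
                         var_frac_pred=vp, var_frac_obs=vo,
                         axis_stats=axis_stats, scores_pred=sp, scores_obs=so)


def cn_trait_regressions(optima: pd.DataFrame) -> dict:
    """Sequential OLS of the optimal substrate C:N on leaf lifespan, then of
    its residuals on plant height.

    ``optima`` needs columns cn_opt, lls, h (one row per species).  Returns
    the two fits and the residual vector.
    """
    if len(optima) < 3:
        raise ValueError("need at least 3 species")
    for col in ("cn_opt", "lls", "h"):
        if col not in optima.columns:
            raise ValueError(f"missing column {col!r}")
        if np.std(optima[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"degenerate (constant) column {col!r}")
    f1 = stats.linregress(optima["lls"], optima["cn_opt"])
    resid = optima["cn_opt"].to_numpy() - (f1.slope * optima["lls"].to_numpy()
                                           + f1.intercept)
    f2 = stats.linregress(optima["h"], resid)
    return dict(
        lls_fit=dict(slope=float(f1.slope), intercept=float(f1.intercept),
                     r2=float(f1.rvalue ** 2), p=float(f1.pvalue)),
        h_fit=dict(slope=float(f2.slope), intercept=float(f2.intercept),
                   r2=float(f2.rvalue ** 2), p=float(f2.pvalue)),
        residuals=resid,
    )


def variance_decomposition(table: pd.DataFrame, variable_pair: tuple[str, str]) -> dict:
    """Relative importance (%var) of two diagnostics for performance.

    Both variables are z-standardised; each variable's weight is its
    incremental R^2 averaged over the two orders of entry into a joint
    linear model of performance, normalised to sum to 100.  A nearly
    collinear pair (|corr| > 0.999) is reported as undefined.
    """
    u_name, v_name = variable_pair
    ok = _ok_rows(table).dropna(subset=[u_name, v_name, "performance"])
    y = ok["performance"].to_numpy(dtype=float)
    u = ok[u_name].to_numpy(dtype=float)
    v = ok[v_name].to_numpy(dtype=float)
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("constant diagnostic column")
    u = (u - u.mean()) / u.std(ddof=1)
    v = (v - v.mean()) / v.std(ddof=1)
    if abs(np.corrcoef(u, v)[0, 1]) > 0.999:
        return dict(weights=None, undefined=True)

    def _r2(X):
        X = np.column_stack([np.ones_like(y)] + X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tot = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid ** 2) / tot if tot > 0 else 0.0

    r2_u, r2_v, r2_uv = _r2([u]), _r2([v]), _r2([u, v])
    share_u = (r2_u + (r2_uv - r2_v)) / 2.0
    share_v = (r2_v + (r2_uv - r2_u)) / 2.0
    tot = share_u + share_v
    if tot <= 0:
        return dict(weights=(50.0, 50.0), undefined=False, r2_joint=r2_uv)
    return dict(weights=(100.0 * share_u / tot, 100.0 * share_v / tot),
                undefined=False, r2_joint=float(r2_uv))


def is_unimodal(profile, prominence_frac: float = 0.01) -> bool:
    """True when a 1-D performance profile has a single separated peak.

    Local maxima whose topographic prominence is below ``prominence_frac``
    of the global peak value are treated as surface texture (the daily-step
    model has small discrete-cohort resonances), not separate peaks.
    """
    m = np.asarray(profile, dtype=float)
    if len(m) < 3:
        return True
    peak = float(np.max(m))
    if peak <= 0:
        return True
    maxima = [i for i in range(len(m))
              if (i == 0 or m[i] >= m[i - 1]) and (i == len(m) - 1 or m[i] > m[i + 1])]
    g = int(np.argmax(m))
    separated = 0
    for i in maxima:
        if i == g:
            separated += 1
            continue
        lo, hi = sorted((i, g))
        valley = float(np.min(m[lo:hi + 1]))
        if (m[i] - valley) > prominence_frac * peak:
            separated += 1
    return separated <= 1


def cn_homeostasis(table: pd.DataFrame, trait_i: str, trait_j: str,
                   ridge: RidgeFit) -> dict:
    """Coefficient of variation of the mean substrate C:N along the fitted
    ridge versus along the orthogonal direction through the peak.

    Along the ridge the plant maintains its substrate stoichiometry in a
    narrow band; moving orthogonally (breaking the trait coordination)
    perturbs it.  Uses index-space diagonals of the 2-D sub-grid the ridge
    was fitted on.
    """
    ok = _ok_rows(table)
    gi = np.asarray(ridge.i_values)
    gj = np.sort(ok[trait_j].unique())

    def _cn(vi, vj):
        rows = ok[np.isclose(ok[trait_i], vi, rtol=1e-9)
                  & np.isclose(ok[trait_j], vj, rtol=1e-9)]
        return float(rows["mean_cn"].iloc[0]) if len(rows) else np.nan

    along = np.array([_cn(vi, vj) for vi, vj in zip(gi, ridge.j_star)])
    # orthogonal: anti-ridge diagonal through the peak in index space
    peak_k = int(np.argmax([ok[np.isclose(ok[trait_i], vi, rtol=1e-9)
                               & np.isclose(ok[trait_j], vj, rtol=1e-9)]
                            ["performance"].iloc[0]
                            for vi, vj in zip(gi, ridge.j_star)]))
    jp = int(np.argmin(np.abs(gj - ridge.j_star[peak_k])))
    sgn = 1 if ridge.slope >= 0 else -1
    ortho = []
    for step in range(-len(gi), len(gi) + 1):
        ii, jj = peak_k + step, jp - sgn * step
        if 0 <= ii < len(gi) and 0 <= jj < len(gj):
            ortho.append(_cn(gi[ii], gj[jj]))
    ortho = np.array(ortho)

    def _cv(a):
        a = a[np.isfinite(a)]
        return float(np.std(a) / np.mean(a)) if len(a) and np.mean(a) != 0 else np.nan

    return dict(cv_along=_cv(along), cv_ortho=_cv(ortho),
                along=along, ortho=ortho)
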
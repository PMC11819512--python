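"""Temporal statistics: nonparametric tests and negative-binomial GAMs.

Two layers mirror the analysis workflow for hourly detection-positive-minute
(DPM) series:

* simple distributional tests on proportions — Shapiro–Wilk normality,
  Kruskal–Wallis across hour/month/year groups, Dunn's post-hoc test with
  Bonferroni correction — plus collinearity (VIF) and lag-1 autocorrelation
  screens;
* a penalized negative-binomial GAM of hourly DPM counts with cyclic smooths
  of hour (period 24) and month (period 12) and a year factor, log link,
  optional AR1 working-correlation refit when residual autocorrelation
  exceeds 0.2, and backward elimination of non-significant terms.

The cyclic basis is a cyclic cubic regression spline with explicit period
bounds (0–24 h, Dec–Jan wrap), so the fitted hour effect at 24:00 equals the
effect at 0:00 exactly.  Smoothing weights are chosen by a deterministic
BIC grid search; the negative-binomial dispersion is estimated by iterating
a Cameron–Trivedi moment estimator with the penalized fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
import statsmodels.api as sm
from statsmodels.gam.api import GLMGam
from statsmodels.gam.smooth_basis import (
    AdditiveGamSmoother,
    UnivariateCubicCyclicSplines,
    _get_all_sorted_knots,
)

__all__ = [
    "KwResult",
    "DunnResult",
    "GamSpec",
    "GamFitResult",
    "shapiro_normality",
    "kruskal_wallis",
    "dunn_bonferroni",
    "vif_screen",
    "acf_lag1",
    "fit_nb_gam",
    "backward_select",
]


# --------------------------------------------------------------------------
# nonparametric tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KwResult:
    h_statistic: float
    df: int
    p_value: float
    factor: str = ""


@dataclass(frozen=True)
class DunnResult:
    pairs: tuple                 # ((group_i, group_j), ...)
    z_values: tuple
    p_raw: tuple
    p_adjusted: tuple            # Bonferroni: min(1, m * p_raw)


def shapiro_normality(x: Sequence[float]) -> float:
    """Shapiro–Wilk p-value; errors on n < 3, n > 5000 or constant input."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3..5000 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def _check_groups(values: Sequence[float], groups: Sequence) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must align")
    by = {g: values[groups == g] for g in pd.unique(groups)}
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
    return by


def kruskal_wallis(values: Sequence[float], groups: Sequence, factor: str = "") -> KwResult:
    """Kruskal–Wallis rank test with tie correction, chi-square p on k-1 df."""
    by = _check_groups(values, groups)
    samples = list(by.values())
    if np.ptp(np.concatenate(samples)) == 0:
        # identical values everywhere: H = 0 by convention, p = 1
        return KwResult(0.0, len(by) - 1, 1.0, factor)
    h, p = stats.kruskal(*samples)
    return KwResult(float(h), len(by) - 1, float(p), factor)


def dunn_bonferroni(values: Sequence[float], groups: Sequence) -> DunnResult:
    """Dunn's post-hoc test on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12(N-1)); two-sided normal p-values,
    multiplied by the number of pairs (capped at 1).
    """
    by = _check_groups(values, groups)
    keys = list(by.keys())
    pooled = np.concatenate([by[k] for k in keys])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank: dict = {}
    pos = 0
    for k in keys:
        n_k = by[k].size
        mean_rank[k] = ranks[pos:pos + n_k].mean()
        pos += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs, zs, praw = [], [], []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            se = np.sqrt(var_base * (1.0 / by[a].size + 1.0 / by[b].size))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            pairs.append((a, b))
            zs.append(float(z))
            praw.append(float(2.0 * stats.norm.sf(abs(z))))
    m = len(pairs)
    padj = [min(1.0, m * p) for p in praw]
    return DunnResult(tuple(pairs), tuple(zs), tuple(praw), tuple(padj))


def vif_screen(covariates: pd.DataFrame, cutoff: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1/(1 - R2_j), flagged above cutoff."""
    X = np.asarray(covariates, dtype=float)
    names = list(covariates.columns) if hasattr(covariates, "columns") else None
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if n <= k:
        raise ValueError("VIF needs more observations than covariates")
    vifs = []
    for j in range(k):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            vifs.append(np.inf)
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.DataFrame(
        {"vif": vifs, "flagged": [v > cutoff for v in vifs]},
        index=names if names is not None else range(k),
    )


def acf_lag1(residuals: Sequence[float], threshold: float = 0.2) -> tuple[float, bool]:
    """Lag-1 autocorrelation and whether it exceeds the AR1 threshold."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations for a lag-1 ACF")
    if np.ptp(x) == 0:
        raise ValueError("lag-1 ACF undefined for zero-variance input")
    xc = x - x.mean()
    rho = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
    return rho, abs(rho) > threshold


# --------------------------------------------------------------------------
# cyclic spline basis with explicit period bounds
# --------------------------------------------------------------------------

class _PeriodicCyclicSpline(UnivariateCubicCyclicSplines):
    """Cyclic cubic regression spline wrapping at explicit period bounds.

    The stock basis wraps at the observed min/max, which for hour-of-day
    data (0..23) would alias hour 23 onto hour 0; here the wrap point is
    the true period boundary (e.g. 0 and 24).
    """

    def __init__(self, x, df, lower_bound, upper_bound, variable_name="x"):
        self._lb = float(lower_bound)
        self._ub = float(upper_bound)
        super().__init__(x, df=df, constraints="center", variable_name=variable_name)

    def _smooth_basis_for_single_variable(self):
        # equally spaced knots over the full period (the cyclic-smooth
        # convention); quantile knots would leave the widest gap wherever
        # the covariate grid stops short of the wrap point
        n_inner = self.df - 1
        inner = np.linspace(self._lb, self._ub, n_inner + 2)[1:-1]
        knot_list = ", ".join(repr(float(k)) for k in inner)
        formula = (
            f"cc(x, knots=[{knot_list}], "
            f"lower_bound={self._lb}, upper_bound={self._ub}) - 1"
        )
        basis = dmatrix(formula, {"x": self.x})
        self.design_info = basis.design_info
        all_knots = np.concatenate([[self._lb], inner, [self._ub]])
        b, d = self._get_b_and_d(all_knots)
        s = self._get_s(b, d)
        return basis, None, None, s


class CyclicSmoothers(AdditiveGamSmoother):
    """Additive collection of periodic cyclic splines (one per column of x)."""

    def __init__(self, x, dfs, bounds, variable_names=None):
        self.dfs = list(dfs)
        self.bounds = list(bounds)
        super().__init__(x, variable_names=variable_names)

    def _make_smoothers_list(self):
        return [
            _PeriodicCyclicSpline(
                self.x[:, v],
                df=self.dfs[v],
                lower_bound=self.bounds[v][0],
                upper_bound=self.bounds[v][1],
                variable_name=self.variable_names[v],
            )
            for v in range(self.k_variables)
        ]


# --------------------------------------------------------------------------
# negative-binomial GAM
# --------------------------------------------------------------------------

SMOOTH_BOUNDS = {"hour": (0.0, 24.0), "month": (0.5, 12.5)}
SMOOTH_DF = {"hour": 8, "month": 6}


@dataclass
class GamSpec:
    """Model specification for one DPM response.

    ``terms`` lists the temporal covariates: "hour" and "month" enter as
    cyclic smooths, "year" as a factor.  ``fixed_alpha`` pins the NB
    dispersion (alpha in Var = mu + alpha*mu^2) instead of estimating it;
    ``fixed_penalty`` skips the AIC grid search for smoothing weights.
    """

    response: str = "dpm_social"
    terms: tuple = ("hour", "month", "year")
    hour_df: int = SMOOTH_DF["hour"]
    month_df: int = SMOOTH_DF["month"]
    fixed_alpha: float | None = None
    fixed_penalty: float | None = None
    ar1_threshold: float = 0.2
    use_ar1: bool = True
    penalty_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0)

    def __post_init__(self) -> None:
        bad = set(self.terms) - {"hour", "month", "year"}
        if bad:
            raise ValueError(f"unknown model terms: {sorted(bad)}")


@dataclass
class GamFitResult:
    spec: GamSpec
    params: np.ndarray
    term_pvalues: dict
    aic: float
    adj_r2: float
    deviance_explained: float
    fitted: np.ndarray
    nb_alpha: float
    ar1_rho: float
    ar1_applied: bool
    edf: float
    n_obs: int
    _design: dict = field(default_factory=dict, repr=False)

    @property
    def nb_size(self) -> float:
        """Negative-binomial size k = 1/alpha (the generator's parameter)."""
        return np.inf if self.nb_alpha <= 0 else 1.0 / self.nb_alpha

    def smooth_curve(self, term: str, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Partial effect of a cyclic smooth on the linear-predictor scale."""
        if term not in self._design.get("smooth_terms", ()):
            raise ValueError(f"{term!r} is not a smooth term of this fit")
        lo, hi = SMOOTH_BOUNDS[term]
        if grid is None:
            grid = np.linspace(lo, hi, 241)
        idx = self._design["smooth_terms"].index(term)
        smoother = self._design["smoother"].smoothers[idx]
        basis = smoother.transform(np.asarray(grid, dtype=float))
        sl = self._design["smooth_slices"][idx]
        effect = np.asarray(basis) @ self.params[sl]
        return pd.DataFrame({term: np.asarray(grid), "effect": effect})

    def smooth_peak(self, term: str, method: str = "circular") -> float:
        """Location of the maximum of a fitted cyclic smooth.

        ``method="circular"`` (default) reads the peak as the circular mean
        direction of the smooth's response-scale profile exp(f): for a
        symmetric unimodal effect this equals the argmax but pools the whole
        curve, so it is far less sensitive to sampling noise on any single
        point of the fit.  ``method="argmax"`` returns the literal maximum
        of the fitted curve.
        """
        curve = self.smooth_curve(term)
        x = curve[term].to_numpy()
        eff = curve["effect"].to_numpy()
        if method == "argmax":
            return float(x[int(eff.argmax())])
        lo, hi = SMOOTH_BOUNDS[term]
        period = hi - lo
        theta = 2.0 * np.pi * (x[:-1] - lo) / period  # drop duplicated wrap point
        w = np.exp(eff[:-1] - eff.max())
        z = np.sum(w * np.exp(1j * theta))
        peak = (np.angle(z) % (2.0 * np.pi)) * period / (2.0 * np.pi) + lo
        return float(peak)


def _as_frame(dpm_rows) -> pd.DataFrame:
    if isinstance(dpm_rows, pd.DataFrame):
        return dpm_rows.copy()
    from .dpm import dpm_frame

    return dpm_frame(dpm_rows)


def _build_design(df: pd.DataFrame, spec: GamSpec):
    """Parametric exog (intercept + year dummies) and the cyclic smoother."""
    n = len(df)
    exog_cols = {"const": np.ones(n)}
    par_slices: dict[str, slice] = {}
    if "year" in spec.terms:
        years = np.sort(df["year"].unique())
        start = len(exog_cols)
        for y in years[1:]:
            exog_cols[f"year_{y}"] = (df["year"] == y).astype(float).to_numpy()
        if len(exog_cols) > start:
            par_slices["year"] = slice(start, len(exog_cols))
    exog = np.column_stack(list(exog_cols.values()))

    smooth_terms = tuple(t for t in ("hour", "month") if t in spec.terms)
    smoother = None
    if smooth_terms:
        x = df[list(smooth_terms)].to_numpy(dtype=float)
        dfs = [spec.hour_df if t == "hour" else spec.month_df for t in smooth_terms]
        bounds = [SMOOTH_BOUNDS[t] for t in smooth_terms]
        smoother = CyclicSmoothers(x, dfs=dfs, bounds=bounds, variable_names=list(smooth_terms))
    return exog, list(exog_cols), par_slices, smoother, smooth_terms


def _alpha_moment(y: np.ndarray, mu: np.ndarray) -> float:
    """Cameron–Trivedi moment estimator of NB2 alpha (clipped at 0)."""
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    return max(num / den, 0.0) if den > 0 else 0.0


def _fit_glmgam(y, exog, smoother, penalties, family):
    if smoother is None:
        model = sm.GLM(y, exog, family=family)
        return model.fit(), None
    model = GLMGam(y, exog=exog, smoother=smoother, alpha=list(penalties), family=family)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return res, model


def fit_nb_gam(dpm_rows, spec: GamSpec | None = None) -> GamFitResult:
    """Penalized negative-binomial GAM of hourly DPM counts (log link).

    Procedure: fit a Poisson GAM, estimate the NB dispersion from its
    residuals, refit under the negative binomial and iterate the moment
    estimator to convergence; choose the per-smooth penalty weights by a
    coordinate-wise BIC grid search; then check lag-1 autocorrelation of the
    time-ordered Pearson residuals and, above the 0.2 threshold, refit the
    linearized model by AR1-whitened penalized GLS.
    """
    spec = spec or GamSpec()
    df = _as_frame(dpm_rows).reset_index(drop=True)
    if spec.response not in df.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    y = df[spec.response].to_numpy(dtype=float)
    n = len(y)
    exog, exog_names, par_slices, smoother, smooth_terms = _build_design(df, spec)
    n_par = exog.shape[1]
    k_smooth = len(smooth_terms)
    min_obs = 10 * (n_par + sum(
        spec.hour_df if t == "hour" else spec.month_df for t in smooth_terms
    ))
    if n < min_obs:
        raise ValueError(f"need >= {min_obs} observations for this design, got {n}")

    # --- dispersion: Poisson start, iterate moment estimator under NB
    if spec.fixed_penalty is not None:
        penalties = [spec.fixed_penalty] * k_smooth
    else:
        penalties = [10.0] * k_smooth
    res, model = _fit_glmgam(y, exog, smoother, penalties, sm.families.Poisson())
    if spec.fixed_alpha is not None:
        alpha = spec.fixed_alpha
    else:
        alpha = _alpha_moment(y, np.asarray(res.fittedvalues))
        for _ in range(4):
            fam = _nb_family(alpha)
            res, model = _fit_glmgam(y, exog, smoother, penalties, fam)
            new_alpha = _alpha_moment(y, np.asarray(res.fittedvalues))
            if abs(new_alpha - alpha) < 1e-4 * max(alpha, 1e-8):
                alpha = new_alpha
                break
            alpha = new_alpha
    family = _nb_family(alpha)

    # --- smoothing weights by coordinate-wise BIC grid search (BIC rather
    # than AIC: with weak per-cell signal AIC is nearly flat across orders
    # of magnitude of the penalty and undersmooths, destabilizing the
    # fitted cyclic curves)
    if spec.fixed_penalty is None and k_smooth:
        for _sweep in range(2):
            for j in range(k_smooth):
                best_a, best_score = penalties[j], np.inf
                for a in spec.penalty_grid:
                    trial = list(penalties)
                    trial[j] = a
                    r, _ = _fit_glmgam(y, exog, smoother, trial, family)
                    edf_r = float(np.sum(np.asarray(getattr(r, "edf", r.params.shape[0]))))
                    score = -2.0 * r.llf + np.log(n) * edf_r
                    if score < best_score:
                        best_score, best_a = score, a
                penalties[j] = best_a
    res, model = _fit_glmgam(y, exog, smoother, penalties, family)
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise RuntimeError("GAM fit did not converge: non-finite coefficients")

    params = np.asarray(res.params)
    fitted = np.asarray(res.fittedvalues)
    cov = np.asarray(res.cov_params())

    # column layout: [parametric | smooth_1 | smooth_2 ...]
    smooth_slices = []
    pos = n_par
    for idx, t in enumerate(smooth_terms):
        width = smoother.smoothers[idx].dim_basis
        smooth_slices.append(slice(pos, pos + width))
        pos += width

    # --- AR1 working-correlation refit on the linearized model
    order = np.argsort(
        (pd.to_datetime(df["date"]) + pd.to_timedelta(df["hour"], unit="h")).values
    ) if {"date", "hour"} <= set(df.columns) else np.arange(n)
    pearson = (y - fitted) / np.sqrt(fitted * (1.0 + alpha * fitted))
    rho, needs_ar1 = acf_lag1(pearson[order], threshold=spec.ar1_threshold)
    ar1_applied = False
    if spec.use_ar1 and needs_ar1 and smoother is not None:
        X = np.column_stack([exog] + [np.asarray(s.basis) for s in smoother.smoothers])
        eta = np.log(np.clip(fitted, 1e-10, None))
        z = eta + (y - fitted) / np.clip(fitted, 1e-10, None)
        w = fitted / (1.0 + alpha * fitted)              # NB2 working weights
        Xo, zo, wo = X[order], z[order], w[order]
        sw = np.sqrt(wo)
        Xw, zw = Xo * sw[:, None], zo * sw
        # quasi-difference the weighted rows (AR1 whitening)
        r = rho
        Xt = np.vstack([Xw[:1] * np.sqrt(1 - r**2), Xw[1:] - r * Xw[:-1]])
        zt = np.concatenate([zw[:1] * np.sqrt(1 - r**2), zw[1:] - r * zw[:-1]])
        S = np.zeros((X.shape[1], X.shape[1]))
        for idx, sl in enumerate(smooth_slices):
            S[sl, sl] = penalties[idx] * smoother.smoothers[idx].cov_der2
        A = Xt.T @ Xt + S
        params = np.linalg.solve(A, Xt.T @ zt)
        fitted = np.exp(np.clip(X @ params, -30, 30))
        resid_t = zt - Xt @ params
        sigma2 = float(resid_t @ resid_t) / max(n - n_par, 1)
        cov = sigma2 * np.linalg.solve(A, Xt.T @ Xt) @ np.linalg.inv(A)
        cov = 0.5 * (cov + cov.T)
        ar1_applied = True

    # --- per-term Wald chi-square (approximate for penalized smooths)
    term_pvalues: dict[str, float] = {}
    for name, sl in {**par_slices, **dict(zip(smooth_terms, smooth_slices))}.items():
        b = params[sl]
        V = cov[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(V) @ b)
        dof = b.size
        term_pvalues[name] = float(stats.chi2.sf(max(stat, 0.0), dof))

    # --- goodness of fit
    edf = float(np.sum(np.asarray(getattr(res, "edf", params.size))))
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    adj_r2 = 1.0 - (rss / max(n - edf, 1.0)) / (tss / (n - 1)) if tss > 0 else 0.0
    null = sm.GLM(y, np.ones((n, 1)), family=family).fit()
    dev = family.deviance(y, np.clip(fitted, 1e-10, None))
    dev_expl = 1.0 - dev / null.deviance if null.deviance > 0 else 0.0

    return GamFitResult(
        spec=spec,
        params=params,
        term_pvalues=term_pvalues,
        aic=float(res.aic),
        adj_r2=float(adj_r2),
        deviance_explained=float(dev_expl),
        fitted=fitted,
        nb_alpha=float(alpha),
        ar1_rho=float(rho),
        ar1_applied=ar1_applied,
        edf=edf,
        n_obs=n,
        _design={
            "smoother": smoother,
            "smooth_terms": smooth_terms,
            "smooth_slices": smooth_slices,
            "penalties": penalties,
            "exog_names": exog_names,
        },
    )


def _nb_family(alpha: float):
    if alpha <= 1e-8:
        return sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.families.NegativeBinomial(alpha=alpha)


def backward_select(
    dpm_rows, spec: GamSpec | None = None, alpha_level: float = 0.05
) -> tuple[GamFitResult, list[float]]:
    """Sequentially drop the least significant term with p > alpha_level.

    Refits after each removal and stops when every retained term is
    significant; if every term is removed an intercept-only model is
    returned with a warning.  Returns the final fit and the AIC trajectory
    (initial fit first).
    """
    spec = spec or GamSpec()
    if not spec.terms:
        raise ValueError("no candidate terms to select over")
    fit = fit_nb_gam(dpm_rows, spec)
    trajectory = [fit.aic]
    current = spec
    while current.terms:
        pvals = {t: fit.term_pvalues.get(t, 0.0) for t in current.terms}
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] <= alpha_level:
            break
        remaining = tuple(t for t in current.terms if t != worst)
        current = replace(current, terms=remaining)
        if not remaining:
            warnings.warn("all terms removed; returning intercept-only model")
            fit = fit_nb_gam(dpm_rows, replace(current, terms=()))
            trajectory.append(fit.aic)
            break
        fit = fit_nb_gam(dpm_rows, current)
        trajectory.append(fit.aic)
    return fit, trajectory
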
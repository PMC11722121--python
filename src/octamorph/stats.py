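"""The cohort inference chain.

The analysis mirrors a two-group (peripheral non-perfusion present/absent)
study of eyes nested in patients:

1. missing values are imputed with an iterative random-forest scheme for
   mixed-type data (per-variable regression/classification forests swept in
   increasing-missingness order until the out-of-bag-style difference
   criterion first rises);
2. every variable is screened univariately (Welch t-test for numerics,
   exact Fisher test for categoricals) at alpha = 10%, with a forced-retest
   list that is re-examined regardless of the screen;
3. screened variables are re-tested as responses of (generalized) linear
   mixed models with a patient random intercept, with optional
   transformations and normality/homoscedasticity checks;
4. strongly correlated predictors are pruned (|r| > 0.9) along with manual
   exclusions, a maximal convergent mixed logistic model is grown, and
   backward elimination by AIC selects the final predictor subset;
5. classification accuracy is summarized by leave-one-out cross-validated
   ROC AUC with a DeLong confidence interval.

The logistic and multinomial mixed models are fitted by maximum likelihood
with adaptive Gauss-Hermite quadrature over the scalar patient intercept;
linear mixed models delegate to statsmodels' REML fitter.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from math import lgamma
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "UnivariateResult",
    "MixedFitResult",
    "SelectionResult",
    "MixedLogitFit",
    "impute_rf",
    "fisher_exact",
    "univariate_screen",
    "fit_lmm",
    "fit_logistic_mixed",
    "fit_multinomial_mixed",
    "correlation_prune",
    "backward_aic_select",
    "loocv_auc",
    "stratify_thresholds",
    "delong_ci",
    "DEFAULT_FORCED_RETESTS",
]

PATIENT_COL = "Patient-ID"
RESPONSE_COL = "PNP_present"
SINGULAR_VAR_THRESHOLD = 1e-6
DEFAULT_FORCED_RETESTS = ("faz_area_mm2", "tortuosity_m1_capillaries",
                          "tortuosity_m2_capillaries")


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return True
    vals = series.dropna().unique()
    return len(vals) <= 3 and np.allclose(vals.astype(float),
                                          np.round(vals.astype(float)))


# --------------------------------------------------------------------------
# Imputation
# --------------------------------------------------------------------------

def impute_rf(table: pd.DataFrame, seed: int, max_iter: int = 10,
              n_trees: int = 100,
              id_cols: Sequence[str] = (PATIENT_COL, "Eye")) -> pd.DataFrame:
    """Iterative random-forest imputation for mixed-type tables.

    Initializes missing cells with the column mean/mode, then repeatedly
    re-imputes each incomplete variable (in increasing-missingness order)
    from a forest trained on its observed rows, stopping as soon as the
    normalized change of the imputed values increases for both the numeric
    and the categorical set, and returning the previous sweep's values.
    Deterministic for a fixed seed.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    out = table.copy()
    predictors = [c for c in out.columns if c not in id_cols]
    missing_mask = out[predictors].isna()
    if not missing_mask.any().any():
        return out
    incomplete = [c for c in predictors if missing_mask[c].any()]
    for c in incomplete:
        if missing_mask[c].all():
            raise ValueError(f"variable {c!r} is entirely missing")
    incomplete.sort(key=lambda c: missing_mask[c].sum())

    cat_cols = [c for c in predictors if _is_categorical(out[c])]
    # initial fill: mean / mode
    filled = out.copy()
    for c in predictors:
        if filled[c].isna().any():
            if c in cat_cols:
                filled[c] = filled[c].fillna(filled[c].mode().iloc[0])
            else:
                filled[c] = filled[c].fillna(filled[c].mean())

    def encode(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
        parts = []
        for c in cols:
            if c in cat_cols:
                parts.append(pd.Categorical(df[c]).codes.astype(float))
            else:
                parts.append(df[c].to_numpy(dtype=float))
        return np.column_stack(parts)

    rng = np.random.default_rng(seed)
    prev = filled.copy()
    prev_num_diff = math.inf
    prev_cat_diff = math.inf
    for _ in range(max_iter):
        current = prev.copy()
        for c in incomplete:
            others = [p for p in predictors if p != c]
            X = encode(current, others)
            obs = ~missing_mask[c].to_numpy()
            rs = int(rng.integers(0, 2 ** 31 - 1))
            if c in cat_cols:
                model = RandomForestClassifier(n_estimators=n_trees,
                                               random_state=rs)
                as_str = current[c].dtype == object
                target = current.loc[obs, c]
                model.fit(X[obs], target.astype(str) if as_str else target)
                pred = model.predict(X[~obs])
                if not as_str:
                    pred = pred.astype(current[c].dtype)
                current.loc[~obs, c] = pred
            else:
                model = RandomForestRegressor(n_estimators=n_trees,
                                              random_state=rs)
                model.fit(X[obs], current.loc[obs, c].astype(float))
                current.loc[~obs, c] = model.predict(X[~obs])
        # difference criterion on the imputed cells
        num_sq = num_tot = 0.0
        cat_chg = cat_n = 0
        for c in incomplete:
            miss = missing_mask[c].to_numpy()
            if c in cat_cols:
                cat_chg += int((current.loc[miss, c].astype(str)
                                != prev.loc[miss, c].astype(str)).sum())
                cat_n += int(miss.sum())
            else:
                new = current.loc[miss, c].to_numpy(dtype=float)
                old = prev.loc[miss, c].to_numpy(dtype=float)
                num_sq += float(((new - old) ** 2).sum())
                num_tot += float((new ** 2).sum())
        num_diff = num_sq / num_tot if num_tot > 0 else 0.0
        cat_diff = cat_chg / cat_n if cat_n > 0 else 0.0
        if num_diff >= prev_num_diff and cat_diff >= prev_cat_diff:
            return prev
        prev, prev_num_diff, prev_cat_diff = current, num_diff, cat_diff
    return prev


# --------------------------------------------------------------------------
# Exact Fisher test (2x2 closed form, r x c by full enumeration)
# --------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, lg_row: float, lg_col: float,
                    lg_n: float) -> float:
    return lg_row + lg_col - lg_n - sum(lgamma(v + 1) for v in table.ravel())


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact probability for an r x c contingency table.

    Sums, under the fixed-margin (multivariate hypergeometric) null, the
    probabilities of all tables at most as probable as the observed one —
    the standard two-sided convention. r x c tables are handled by full
    recursive enumeration (feasible at cohort sizes of tens of eyes).
    Degenerate margins (an empty row/column or a single row/column) return
    p = 1 by convention.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2D array of non-negative counts")
    # drop empty rows/columns
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    lg_row = sum(lgamma(v + 1) for v in rows)
    lg_col = sum(lgamma(v + 1) for v in cols)
    lg_n = lgamma(n + 1)
    logp_obs = _log_table_prob(obs, lg_row, lg_col, lg_n)
    cutoff = logp_obs + 1e-7

    r, c = obs.shape
    total = 0.0
    cell = np.zeros((r, c), dtype=int)

    def fill_row(i: int, col_rem: np.ndarray) -> None:
        nonlocal total
        if i == r - 1:
            cell[i] = col_rem
            lp = _log_table_prob(cell, lg_row, lg_col, lg_n)
            if lp <= cutoff:
                total += math.exp(lp)
            return
        target = int(rows[i])

        def fill_cell(j: int, rem: int, col_rem: np.ndarray) -> None:
            if j == c - 1:
                if rem <= col_rem[j]:
                    cell[i, j] = rem
                    fill_row(i + 1, col_rem - cell[i])
                return
            hi = min(rem, int(col_rem[j]))
            for v in range(hi + 1):
                cell[i, j] = v
                fill_cell(j + 1, rem - v, col_rem)

        fill_cell(0, target, col_rem)

    fill_row(0, cols.copy())
    return min(total, 1.0)


# --------------------------------------------------------------------------
# Univariate screen
# --------------------------------------------------------------------------

@dataclass
class UnivariateResult:
    variable: str
    test: str                 # "t" | "fisher" | "skipped"
    p_value: float
    significant_at_10pct: bool
    retest_requested: bool
    note: str = ""


def univariate_screen(table: pd.DataFrame, alpha: float = 0.10,
                      forced_retests: Sequence[str] = DEFAULT_FORCED_RETESTS,
                      response: str = RESPONSE_COL,
                      t_test: str = "welch",
                      id_cols: Sequence[str] = (PATIENT_COL, "Eye"),
                      ) -> list[UnivariateResult]:
    """Per-variable two-group comparison on the imputed table.

    Numerics get an independent-samples t-test (Welch by default, pooled
    with ``t_test='pooled'``), categoricals the exact Fisher test. A
    variable is flagged for mixed-model retesting if significant at
    `alpha` or in the forced list.
    """
    if t_test not in ("welch", "pooled"):
        raise ValueError("t_test must be 'welch' or 'pooled'")
    y = table[response].astype(str).to_numpy()
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("response must be binary")
    results: list[UnivariateResult] = []
    for col in table.columns:
        if col == response or col in id_cols:
            continue
        s = table[col]
        forced = col in forced_retests
        if _is_categorical(s):
            ct = pd.crosstab(s.astype(str), y).to_numpy()
            p = fisher_exact(ct)
            test = "fisher"
        else:
            a = s[y == groups[0]].astype(float).dropna()
            b = s[y == groups[1]].astype(float).dropna()
            tol = 1e-12 * max(1.0, float(np.abs(s.dropna().mean())))
            if a.std() <= tol and b.std() <= tol:
                results.append(UnivariateResult(
                    col, "skipped", float("nan"), False, forced,
                    note="constant variable"))
                continue
            _, p = sps.ttest_ind(a, b, equal_var=(t_test == "pooled"))
            test = "t"
        sig = bool(p < alpha)
        results.append(UnivariateResult(col, test, float(p), sig,
                                        sig or forced))
    return results


# --------------------------------------------------------------------------
# Mixed models
# --------------------------------------------------------------------------

@dataclass
class MixedFitResult:
    response: str
    fixed_effects: list[dict[str, float | str]]
    random_intercept_var: float
    converged: bool
    singular: bool
    aic: float
    loglik: float = float("nan")
    transformation: str = "none"
    shapiro_p: float | None = None
    levene_p: float | None = None
    p_value: float | None = None      # overall group-effect p
    flags: list[str] = field(default_factory=list)


def _apply_transformation(y: np.ndarray, transformation: str) -> np.ndarray:
    if transformation == "none":
        return y
    if transformation == "power_1.05":
        return np.sign(y) * np.abs(y) ** 1.05
    if transformation == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transformation needs non-negative data")
        return np.sqrt(y)
    raise ValueError(f"unknown transformation {transformation!r}")


def fit_lmm(table: pd.DataFrame, response: str,
            transformation: str = "none",
            group_col: str = PATIENT_COL,
            fixed: str = RESPONSE_COL) -> MixedFitResult:
    """Gaussian mixed model: response ~ group fixed effect + patient
    intercept, fitted by REML, with Shapiro-Wilk and Levene checks."""
    import statsmodels.api as sm

    data = table[[response, group_col, fixed]].dropna()
    y = _apply_transformation(data[response].to_numpy(dtype=float),
                              transformation)
    g = (data[fixed].astype(str) == sorted(data[fixed].astype(str).unique())[-1]
         ).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    flags: list[str] = []
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=data[group_col].to_numpy())
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception as exc:  # noqa: BLE001 - surfaced as flagged result
            return MixedFitResult(response, [], float("nan"), False, True,
                                  float("nan"),
                                  transformation=transformation,
                                  flags=[f"fit failed: {exc}"])
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    singular = re_var < SINGULAR_VAR_THRESHOLD
    if singular:
        flags.append("singular fit: random-intercept variance ~ 0")
    resid = res.resid
    shapiro_p = float(sps.shapiro(resid).pvalue) if len(resid) >= 3 else None
    levene_p = float(sps.levene(resid[g == 0], resid[g == 1]).pvalue) \
        if min((g == 0).sum(), (g == 1).sum()) >= 2 else None
    fe = [
        {"name": "intercept", "estimate": float(res.fe_params[0]),
         "se": float(res.bse_fe[0]), "p": float(res.pvalues[0])},
        {"name": fixed, "estimate": float(res.fe_params[1]),
         "se": float(res.bse_fe[1]), "p": float(res.pvalues[1])},
    ]
    # statsmodels leaves aic undefined under REML; count 2 fixed effects +
    # intercept variance + residual variance
    aic = 2 * 4 - 2 * float(res.llf)
    return MixedFitResult(response, fe, re_var, converged, singular,
                          aic, loglik=float(res.llf),
                          transformation=transformation,
                          shapiro_p=shapiro_p, levene_p=levene_p,
                          p_value=fe[1]["p"], flags=flags)


# ---- logistic mixed model via adaptive Gauss-Hermite quadrature ----------

class MixedLogitFit:
    """ML fit of logit P(y=1) = X beta + sigma*u, u ~ N(0,1) per group."""

    def __init__(self, beta: np.ndarray, sigma: float, loglik: float,
                 converged: bool, names: list[str], cov: np.ndarray | None,
                 flags: list[str]):
        self.beta = beta
        self.sigma = sigma
        self.loglik = loglik
        self.converged = converged
        self.names = names
        self.cov = cov
        self.flags = flags

    @property
    def aic(self) -> float:
        return 2 * (len(self.beta) + 1) - 2 * self.loglik

    @property
    def singular(self) -> bool:
        return self.sigma ** 2 < SINGULAR_VAR_THRESHOLD

    def predict_marginal(self, X: np.ndarray, n_quad: int = 15) -> np.ndarray:
        """Population-averaged P(y=1 | x), integrating out the intercept."""
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_quad)
        eta = X @ self.beta
        etas = eta[:, None] + self.sigma * gh_x[None, :]
        p = 1.0 / (1.0 + np.exp(-etas))
        return p @ (gh_w / gh_w.sum())


def _gh_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    # probabilists' Hermite: integral f(u) phi(u) du = sum w_k/sqrt(2pi) ...
    x, w = np.polynomial.hermite_e.hermegauss(n_quad)
    return x, w


def _mixed_logit_nll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                     group_idx: np.ndarray, n_groups: int,
                     n_quad: int) -> float:
    beta = params[:-1]
    sigma = math.exp(params[-1])
    eta0 = X @ beta
    # per-group posterior mode by Newton (vectorized over groups)
    u = np.zeros(n_groups)
    for _ in range(30):
        eta = eta0 + sigma * u[group_idx]
        p = 1.0 / (1.0 + np.exp(-eta))
        g1 = sigma * np.bincount(group_idx, weights=y - p,
                                 minlength=n_groups) - u
        g2 = -sigma ** 2 * np.bincount(group_idx, weights=p * (1 - p),
                                       minlength=n_groups) - 1.0
        step = g1 / g2
        u = u - step
        if np.abs(step).max() < 1e-10:
            break
    eta = eta0 + sigma * u[group_idx]
    p = 1.0 / (1.0 + np.exp(-eta))
    tau = 1.0 / np.sqrt(sigma ** 2 * np.bincount(
        group_idx, weights=p * (1 - p), minlength=n_groups) + 1.0)
    gh_x, gh_w = _gh_nodes(n_quad)
    # adaptive nodes u_gk = u_g + tau_g * x_k
    ugk = u[:, None] + tau[:, None] * gh_x[None, :]
    # h(u) = sum_i [y eta - log1pexp(eta)] - u^2/2, per group
    ll_gk = np.zeros((n_groups, len(gh_x)))
    for k in range(len(gh_x)):
        etak = eta0 + sigma * ugk[group_idx, k]
        contrib = y * etak - np.logaddexp(0.0, etak)
        ll_gk[:, k] = np.bincount(group_idx, weights=contrib,
                                  minlength=n_groups)
    h = ll_gk - 0.5 * ugk ** 2
    # integral e^h du ~= tau * sum_k w_k e^{x_k^2/2} e^{h(ugk)}  (hermegauss
    # weights carry e^{-x^2/2}); marginal L_g = integral / sqrt(2 pi)
    log_kernel = h + 0.5 * gh_x[None, :] ** 2 + np.log(gh_w)[None, :]
    m = log_kernel.max(axis=1)
    log_int = m + np.log(np.exp(log_kernel - m[:, None]).sum(axis=1))
    ll = float(np.sum(log_int + np.log(tau) - 0.5 * math.log(2 * math.pi)))
    return -ll


def fit_logistic_mixed(table: pd.DataFrame, response: str = RESPONSE_COL,
                       fixed: Sequence[str] = (),
                       group_col: str = PATIENT_COL,
                       n_quad: int = 15,
                       sigma_max: float | None = None,
                       compute_cov: bool = True) -> MixedFitResult:
    """Logistic mixed model with a patient random intercept (adaptive
    Gauss-Hermite ML). Complete separation is flagged, not raised.
    `sigma_max` caps the random-intercept SD (a cap near 0 reduces the
    model to plain logistic regression)."""
    X, y, group_idx, n_groups, names = _design(table, response, fixed,
                                               group_col)
    fit = _fit_mixed_logit(X, y, group_idx, n_groups, names, n_quad,
                           sigma_max=sigma_max, compute_cov=compute_cov)
    fe = []
    for j, name in enumerate(names):
        se = float(np.sqrt(fit.cov[j, j])) if fit.cov is not None else float("nan")
        z = fit.beta[j] / se if se and se > 0 else float("nan")
        fe.append({"name": name, "estimate": float(fit.beta[j]), "se": se,
                   "p": float(2 * sps.norm.sf(abs(z))) if z == z else float("nan")})
    group_ps = [f["p"] for f in fe[1:] if f["p"] == f["p"]]
    return MixedFitResult(response, fe, fit.sigma ** 2, fit.converged,
                          fit.singular, fit.aic, loglik=fit.loglik,
                          p_value=min(group_ps) if group_ps else None,
                          flags=fit.flags)


def _design(table: pd.DataFrame, response: str, fixed: Sequence[str],
            group_col: str) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     int, list[str]]:
    data = table.dropna(subset=[response, group_col, *fixed])
    yraw = data[response]
    if _is_categorical(yraw) and yraw.dtype == object:
        levels = sorted(yraw.astype(str).unique())
        y = (yraw.astype(str) == levels[-1]).to_numpy(dtype=float)
    else:
        y = yraw.to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for f in fixed:
        s = data[f]
        if _is_categorical(s) and s.dtype == object:
            dummies = pd.get_dummies(s.astype(str), prefix=f, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(f)
    X = np.column_stack(cols)
    groups, group_idx = np.unique(data[group_col].to_numpy(), return_inverse=True)
    return X, y, group_idx, len(groups), names


def _fit_mixed_logit(X: np.ndarray, y: np.ndarray, group_idx: np.ndarray,
                     n_groups: int, names: list[str],
                     n_quad: int = 15,
                     sigma_max: float | None = None,
                     compute_cov: bool = True) -> MixedLogitFit:
    flags: list[str] = []
    log_sigma_hi = math.log(sigma_max) if sigma_max is not None else math.log(50.0)
    log_sigma_lo = min(math.log(1e-5), log_sigma_hi - 1e-6)

    # standardize non-constant columns: optimizer bounds/steps are only
    # meaningful on comparable coefficient scales
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    is_intercept = scale < 1e-12
    center[is_intercept] = 0.0
    scale[is_intercept] = 1.0
    Xs = (X - center) / scale
    Xs[:, is_intercept] = X[:, is_intercept]

    def to_original(beta_s: np.ndarray) -> np.ndarray:
        beta = beta_s / scale
        beta[is_intercept] = beta_s[is_intercept]
        if is_intercept.any():
            i0 = int(np.argmax(is_intercept))
            beta[i0] = beta_s[i0] - float(
                np.sum(center[~is_intercept] * beta_s[~is_intercept]
                       / scale[~is_intercept]))
        return beta

    X_orig = X
    X = Xs
    # plain-logistic start values
    beta0 = np.zeros(X.shape[1])
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta0 = np.asarray(start_fit.params, dtype=float)
        if np.abs(beta0).max() > 12:
            flags.append("possible complete separation")
    except Exception:
        flags.append("plain-logistic start failed; zero start")
    x0 = np.concatenate([np.clip(beta0, -12, 12),
                         [min(math.log(0.5), log_sigma_hi)]])
    obj = lambda p: _mixed_logit_nll(p, X, y, group_idx, n_groups, n_quad)
    bounds = [(-30, 30)] * X.shape[1] + [(log_sigma_lo, log_sigma_hi)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 300, "ftol": 1e-10})
    beta_s = res.x[:-1]
    sigma = math.exp(res.x[-1])
    ll = -float(res.fun)
    converged = bool(res.success) and np.isfinite(ll)
    if np.abs(beta_s).max() >= 29.9:
        flags.append("complete separation: estimates at bound")
        converged = False
    beta = to_original(beta_s)
    if not compute_cov:
        return MixedLogitFit(beta, sigma, ll, converged, names, None, flags)
    # observed-information covariance (numeric Hessian on the
    # standardized scale, transformed back)
    cov = None
    try:
        eps = 1e-4
        k = len(res.x)
        hess = np.zeros((k, k))
        f0 = res.fun
        for i in range(k):
            for j in range(i, k):
                pij = res.x.copy(); pij[i] += eps; pij[j] += eps
                pi = res.x.copy(); pi[i] += eps
                pj = res.x.copy(); pj[j] += eps
                hess[i, j] = hess[j, i] = (obj(pij) - obj(pi) - obj(pj) + f0) / eps ** 2
        try:
            cov_full = np.linalg.inv(hess)
            cov_s = cov_full[:-1, :-1]
            if np.any(np.diag(cov_s) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            # sigma at its bound makes the full Hessian singular; condition
            # on sigma and invert the beta block alone
            cov_s = np.linalg.inv(hess[:-1, :-1])
        # jacobian of beta_original wrt beta_standardized
        p = len(beta_s)
        J = np.diag(1.0 / scale)
        for i in range(p):
            if is_intercept[i]:
                J[i, i] = 1.0
        if is_intercept.any():
            i0 = int(np.argmax(is_intercept))
            for j in range(p):
                if not is_intercept[j]:
                    J[i0, j] = -center[j] / scale[j]
        cov = J @ cov_s @ J.T
        if np.any(np.diag(cov) <= 0):
            cov = None
            flags.append("non-positive-definite Hessian")
    except Exception:
        flags.append("covariance unavailable")
    return MixedLogitFit(beta, sigma, ll, converged, names, cov, flags)


# ---- multinomial mixed model ---------------------------------------------

def _mixed_multinomial_nll(params: np.ndarray, Xs: np.ndarray,
                           y_codes: np.ndarray, group_idx: np.ndarray,
                           n_groups: int, n_cat: int,
                           n_quad: int) -> float:
    """Baseline-category logits sharing one scalar random intercept."""
    p_fix = Xs.shape[1]
    betas = params[:-1].reshape(n_cat - 1, p_fix)
    sigma = math.exp(params[-1])
    eta0 = Xs @ betas.T                      # (n, K-1)
    n = len(y_codes)
    is_nonbase = (y_codes > 0).astype(float)

    u = np.zeros(n_groups)
    for _ in range(30):
        eta = eta0 + sigma * u[group_idx][:, None]
        denom = 1.0 + np.exp(eta).sum(axis=1)
        p0 = 1.0 / denom
        g1 = sigma * np.bincount(group_idx, weights=is_nonbase - (1 - p0),
                                 minlength=n_groups) - u
        g2 = -sigma ** 2 * np.bincount(group_idx, weights=p0 * (1 - p0),
                                       minlength=n_groups) - 1.0
        step = g1 / g2
        u = u - step
        if np.abs(step).max() < 1e-10:
            break
    eta = eta0 + sigma * u[group_idx][:, None]
    p0 = 1.0 / (1.0 + np.exp(eta).sum(axis=1))
    tau = 1.0 / np.sqrt(sigma ** 2 * np.bincount(
        group_idx, weights=p0 * (1 - p0), minlength=n_groups) + 1.0)
    gh_x, gh_w = _gh_nodes(n_quad)
    ugk = u[:, None] + tau[:, None] * gh_x[None, :]
    rows = np.arange(n)
    ll_gk = np.zeros((n_groups, len(gh_x)))
    for k in range(len(gh_x)):
        etak = eta0 + sigma * ugk[group_idx, k][:, None]
        lse = np.logaddexp(0.0, _logsumexp_rows(etak))
        chosen = np.where(y_codes > 0, etak[rows, np.maximum(y_codes - 1, 0)],
                          0.0)
        ll_gk[:, k] = np.bincount(group_idx, weights=chosen - lse,
                                  minlength=n_groups)
    h = ll_gk - 0.5 * ugk ** 2
    log_kernel = h + 0.5 * gh_x[None, :] ** 2 + np.log(gh_w)[None, :]
    m = log_kernel.max(axis=1)
    log_int = m + np.log(np.exp(log_kernel - m[:, None]).sum(axis=1))
    return -float(np.sum(log_int + np.log(tau) - 0.5 * math.log(2 * math.pi)))


def _logsumexp_rows(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1)
    return m + np.log(np.exp(eta - m[:, None]).sum(axis=1))


def fit_multinomial_mixed(table: pd.DataFrame, response: str,
                          fixed: str = RESPONSE_COL,
                          group_col: str = PATIENT_COL,
                          n_quad: int = 15) -> MixedFitResult:
    """Baseline-category multinomial mixed model; the overall group effect
    is tested by a likelihood-ratio test against the intercepts-only model.
    Categories unobserved after grouping are dropped with a flag."""
    data = table.dropna(subset=[response, fixed, group_col])
    if isinstance(data[response].dtype, pd.CategoricalDtype):
        declared = [str(c) for c in data[response].cat.categories]
    else:
        declared = sorted(data[response].astype(str).unique())
    cat = pd.Categorical(data[response].astype(str), categories=declared)
    counts = pd.Series(cat).value_counts()
    flags = []
    present = [lev for lev in declared if counts.get(lev, 0) > 0]
    dropped = [lev for lev in declared if lev not in present]
    if dropped:
        flags.append(f"empty categories dropped: {dropped}")
    cat = pd.Categorical(data[response].astype(str), categories=present)
    n_cat = len(present)
    # two observed categories degrade gracefully to the logistic case
    if n_cat < 2:
        raise ValueError("multinomial model needs >= 2 observed categories")
    y_codes = np.asarray(cat.codes)
    g = (data[fixed].astype(str)
         == sorted(data[fixed].astype(str).unique())[-1]).to_numpy(float)
    Xs = np.column_stack([np.ones(len(data)), g])
    groups, group_idx = np.unique(data[group_col].to_numpy(),
                                  return_inverse=True)
    n_groups = len(groups)

    def fit_for(X: np.ndarray) -> tuple[np.ndarray, float, bool]:
        p_fix = X.shape[1]
        x0 = np.zeros((n_cat - 1) * p_fix + 1)
        x0[-1] = math.log(0.5)
        obj = lambda p: _mixed_multinomial_nll(p, X, y_codes, group_idx,
                                               n_groups, n_cat, n_quad)
        bounds = [(-30, 30)] * ((n_cat - 1) * p_fix) + \
            [(math.log(1e-5), math.log(50.0))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 400, "ftol": 1e-11})
        return res.x, -float(res.fun), bool(res.success)

    full_params, ll_full, ok_full = fit_for(Xs)
    _, ll_null, ok_null = fit_for(Xs[:, :1])
    lrt = max(2 * (ll_full - ll_null), 0.0)
    df = n_cat - 1
    p = float(sps.chi2.sf(lrt, df))
    sigma = math.exp(full_params[-1])
    betas = full_params[:-1].reshape(n_cat - 1, 2)
    fe = [{"name": f"{present[c + 1]}:{nm}",
           "estimate": float(betas[c, j]), "se": float("nan"),
           "p": float("nan")}
          for c in range(n_cat - 1) for j, nm in enumerate(("intercept", fixed))]
    singular = sigma ** 2 < SINGULAR_VAR_THRESHOLD
    if singular:
        flags.append("singular fit: random-intercept variance ~ 0")
    aic = 2 * (len(full_params)) - 2 * ll_full
    return MixedFitResult(response, fe, sigma ** 2, ok_full and ok_null,
                          singular, aic, loglik=ll_full, p_value=p,
                          flags=flags)


# --------------------------------------------------------------------------
# Correlation pruning
# --------------------------------------------------------------------------

def correlation_prune(table: pd.DataFrame, candidates: Sequence[str],
                      r_threshold: float = 0.9,
                      manual_exclusions: Sequence[str] = ("prp",),
                      ) -> tuple[list[str], list[dict[str, Any]]]:
    """Drop one member of every |r| > threshold pair plus manual exclusions.

    Within a flagged pair the member with the larger mean absolute
    correlation to the remaining candidates is dropped (it is the more
    redundant of the two). Returns the surviving list and a report.
    """
    report: list[dict[str, Any]] = []
    kept = [c for c in candidates]
    for m in manual_exclusions:
        if m in kept:
            kept.remove(m)
            report.append({"dropped": m, "reason": "manual exclusion"})
    numeric = [c for c in kept if not _is_categorical(table[c])]
    while True:
        if len(numeric) < 2:
            break
        corr = table[numeric].astype(float).corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        mean_i = corr[i].sum() / (len(numeric) - 1)
        mean_j = corr[j].sum() / (len(numeric) - 1)
        drop = numeric[i] if mean_i >= mean_j else numeric[j]
        other = numeric[j] if drop == numeric[i] else numeric[i]
        report.append({"dropped": drop, "reason": "correlation",
                       "with": other, "r": float(corr[i, j])})
        numeric.remove(drop)
        kept.remove(drop)
    return kept, report


# --------------------------------------------------------------------------
# Backward AIC selection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    maximal_model_terms: list[str]
    elimination_trace: list[dict[str, float | str]]
    final_terms: list[str]
    final_p_values: dict[str, float]
    final_fit: MixedFitResult | None
    loocv_auc: float | None = None
    auc_ci: tuple[float, float] | None = None


def backward_aic_select(table: pd.DataFrame, candidates: Sequence[str],
                        response: str = RESPONSE_COL,
                        group_col: str = PATIENT_COL,
                        n_quad: int = 15,
                        significance_filter: float | None = 0.05,
                        ) -> SelectionResult:
    """Maximal-model search followed by backward elimination on AIC.

    Candidates are ordered by their single-term likelihood contribution;
    the model is grown term by term keeping only additions that preserve
    convergence (the maximal model), then terms are removed one at a time,
    each step deleting the term whose removal lowers AIC the most, until
    no deletion lowers AIC. Terms surviving the AIC phase but without a
    significant Wald association (p >= `significance_filter`) are then
    discarded from the reported final model, mirroring how such selections
    are reported clinically; pass ``significance_filter=None`` to keep the
    raw AIC selection.
    """
    def fit(terms: list[str], cov: bool = False) -> MixedFitResult:
        return fit_logistic_mixed(table, response, terms, group_col, n_quad,
                                  compute_cov=cov)

    base = fit([])
    if not base.converged:
        raise RuntimeError("not even the intercept-only model converges")

    scored = []
    for cand in candidates:
        try:
            f = fit([cand])
        except Exception:
            continue
        if np.isfinite(f.loglik):
            scored.append((f.loglik, cand, f.converged))
    scored.sort(reverse=True)

    # identifiability guard: with p parameters approaching the row count a
    # logistic fit separates; cap the maximal model accordingly
    n_rows = len(table.dropna(subset=[response, group_col]))
    max_terms = max(3, n_rows // 4)
    current: list[str] = []
    current_fit = base
    for _, cand, _ in scored:
        if len(current) >= max_terms:
            break
        trial = current + [cand]
        try:
            f = fit(trial)
        except Exception:
            continue
        if f.converged and np.isfinite(f.aic):
            current, current_fit = trial, f
    maximal = list(current)

    trace: list[dict[str, float | str]] = []
    while current:
        best: tuple[float, str, MixedFitResult] | None = None
        for term in current:
            reduced = [t for t in current if t != term]
            f = fit(reduced)
            if not np.isfinite(f.aic):
                continue
            if best is None or f.aic < best[0]:
                best = (f.aic, term, f)
        if best is None or best[0] >= current_fit.aic:
            break
        trace.append({"removed": best[1], "aic_before": current_fit.aic,
                      "aic_after": best[0]})
        current = [t for t in current if t != best[1]]
        current_fit = best[2]

    if significance_filter is not None:
        current_fit = fit(current, cov=True)
        while current:
            pmap = _term_pvalues(current_fit, current)
            worst = max(current, key=lambda t: pmap.get(t, 0.0))
            if pmap.get(worst, 0.0) < significance_filter:
                break
            trace.append({"removed": worst, "aic_before": current_fit.aic,
                          "reason": "not significant",
                          "p": pmap.get(worst, float("nan"))})
            current = [t for t in current if t != worst]
            current_fit = fit(current, cov=True)

    if any(fe["se"] != fe["se"] for fe in current_fit.fixed_effects):
        current_fit = fit(current, cov=True)
    p_values = {fe["name"]: fe["p"] for fe in current_fit.fixed_effects
                if fe["name"] != "intercept"}
    return SelectionResult(maximal_model_terms=maximal,
                           elimination_trace=trace,
                           final_terms=list(current),
                           final_p_values=p_values,
                           final_fit=current_fit)


def _term_pvalues(fit_result: MixedFitResult,
                  terms: Sequence[str]) -> dict[str, float]:
    """Worst (largest) Wald p over the dummy columns of each term."""
    out: dict[str, float] = {}
    for term in terms:
        ps = [fe["p"] for fe in fit_result.fixed_effects
              if fe["name"] == term or str(fe["name"]).startswith(f"{term}_")]
        valid = [p for p in ps if p == p]
        out[term] = max(valid) if valid else 1.0
    return out


# --------------------------------------------------------------------------
# LOOCV ROC
# --------------------------------------------------------------------------

def delong_ci(scores: np.ndarray, labels: np.ndarray,
              level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong confidence interval (midrank algorithm)."""
    labels = np.asarray(labels).astype(bool)
    pos = np.asarray(scores, dtype=float)[labels]
    neg = np.asarray(scores, dtype=float)[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required for AUC")
    allv = np.concatenate([pos, neg])
    order = sps.rankdata(allv)          # midranks
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (order[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (order[:m] - r_pos) / n
    v01 = 1.0 - (order[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.5 + level / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def loocv_auc(table: pd.DataFrame, terms: Sequence[str],
              response: str = RESPONSE_COL, group_col: str = PATIENT_COL,
              unit: str = "eye", n_quad: int = 15,
              ) -> tuple[float, tuple[float, float], np.ndarray]:
    """Leave-one-out cross-validated ROC AUC of the selected model.

    ``unit='eye'`` leaves one row out per fold; ``unit='patient'`` leaves
    all eyes of one patient out (eyes are correlated). Held-out
    probabilities are population-averaged (the random intercept is
    integrated out). Folds whose training set loses a class are skipped
    with a flag.
    """
    if unit not in ("eye", "patient"):
        raise ValueError("unit must be 'eye' or 'patient'")
    data = table.dropna(subset=[response, group_col, *terms]).reset_index(drop=True)
    yall = data[response]
    if _is_categorical(yall) and yall.dtype == object:
        levels = sorted(yall.astype(str).unique())
        ybin = (yall.astype(str) == levels[-1]).to_numpy(float)
    else:
        ybin = yall.to_numpy(float)
    folds: list[np.ndarray]
    if unit == "eye":
        folds = [np.array([i]) for i in range(len(data))]
    else:
        folds = [np.nonzero((data[group_col] == pid).to_numpy())[0]
                 for pid in data[group_col].unique()]
    # design built once on the full table so factor levels are shared
    X_all, y_all, _, _, names = _design(data, response, terms, group_col)
    g_arr = data[group_col].to_numpy()
    scores = np.full(len(data), np.nan)
    for fold in folds:
        mask = np.ones(len(data), dtype=bool)
        mask[fold] = False
        if len(np.unique(y_all[mask])) < 2:
            continue  # degenerate fold, skipped
        _, gi = np.unique(g_arr[mask], return_inverse=True)
        fit = _fit_mixed_logit(X_all[mask], y_all[mask], gi,
                               int(gi.max()) + 1, names, n_quad,
                               compute_cov=False)
        scores[fold] = fit.predict_marginal(X_all[fold], n_quad)
    ok = ~np.isnan(scores)
    auc, ci = delong_ci(scores[ok], ybin[ok] > 0.5)
    return auc, ci, scores


# --------------------------------------------------------------------------
# Normative-threshold stratification
# --------------------------------------------------------------------------

def stratify_thresholds(table: pd.DataFrame, pd_cut: float = 0.45,
                        faz_cut_mm2: float = 0.3,
                        pd_col: str = "perfusion_density",
                        faz_col: str = "faz_area_mm2",
                        response: str = RESPONSE_COL) -> dict[str, Any]:
    """Cross-classify eyes by normative cut-offs against the PNP label.

    Perfusion density strictly above `pd_cut` counts as "normal" (the
    boundary value falls in the reduced group); FAZ area strictly below
    `faz_cut_mm2` counts as "preserved". Rows with a missing metric are
    excluded and counted.
    """
    y = table[response].astype(str)
    pnp_yes = y == "Y" if set(y) <= {"Y", "N"} else y == sorted(y.unique())[-1]

    def cross(col: str, normal: pd.Series, names: tuple[str, str]) -> pd.DataFrame:
        ok = table[col].notna()
        ct = pd.crosstab(
            np.where(normal[ok], names[0], names[1]),
            np.where(pnp_yes[ok], "PNP", "no PNP"))
        return ct.reindex(index=[names[0], names[1]],
                          columns=["PNP", "no PNP"], fill_value=0)

    pd_ok = table[pd_col].notna()
    faz_ok = table[faz_col].notna()
    out = {
        "pd_table": cross(pd_col, table[pd_col] > pd_cut,
                          ("normal", "reduced")),
        "faz_table": cross(faz_col, table[faz_col] < faz_cut_mm2,
                           ("preserved", "enlarged")),
        "excluded": {"pd": int((~pd_ok).sum()), "faz": int((~faz_ok).sum())},
    }
    return out
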
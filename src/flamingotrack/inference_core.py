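"""Shared estimation machinery for the study's models.

Provides predictor standardization, VIF screening, and a uniform fitting
contract across the four model families the analyses use:

* Gaussian and Poisson/binomial fixed-effect models (``fit_lm``/``fit_glm``,
  delegated to statsmodels),
* a Gaussian random-intercept linear mixed model fitted by profiled REML
  (``fit_lmm``), and
* a binomial-logit random-intercept GLMM whose marginal likelihood is
  integrated by a Laplace approximation (``fit_glmm_binomial``).

All continuous predictors are centred and scaled (sample SD) before fitting,
so reported coefficients are on the standardized scale; the scaling record
allows back-transformation.  Per-term inference is Wald type III
(chi-squared on the link scale); the linear mixed model additionally reports
per-coefficient F tests with Satterthwaite denominator degrees of freedom.

Fit quality is summarised by McFadden's R^2 (GLM/GLMM), the Nakagawa-style
marginal R^2 (variance of the fixed-effect linear predictor over the total),
a leave-one-term-out semi-partial R^2, and, for Poisson fits, the Pearson
chi^2 / df dispersion statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation in a binary-response model."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cont:
    """Continuous predictor; quadratic=True adds a z^2 term (own block)."""

    name: str
    quadratic: bool = False


@dataclass(frozen=True)
class Cat:
    """Categorical predictor with an explicit reference level (default: first
    level in sorted order)."""

    name: str
    ref: Optional[str] = None


@dataclass(frozen=True)
class Interaction:
    left: Union[Cont, Cat]
    right: Union[Cont, Cat]


Term = Union[Cont, Cat, Interaction]


@dataclass
class ModelSpec:
    response: str
    terms: Sequence[Term]
    family: str = "gaussian"  # gaussian | binomial | poisson
    group: Optional[str] = None

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial", "poisson"):
            raise ValueError(f"unsupported family {self.family!r}")

    def without_term(self, label: str) -> "ModelSpec":
        """Spec with one term block removed; dropping a quadratic block
        ('x^2') keeps the linear part of that predictor."""
        new_terms = []
        for t in self.terms:
            if isinstance(t, Cont) and t.quadratic and f"{t.name}^2" == label:
                new_terms.append(Cont(t.name, quadratic=False))
            elif _term_label(t) != label:
                new_terms.append(t)
        return ModelSpec(self.response, new_terms, self.family, self.group)


def _term_label(t: Term) -> str:
    if isinstance(t, Cont):
        return t.name
    if isinstance(t, Cat):
        return t.name
    return f"{_term_label(t.left)}:{_term_label(t.right)}"


# ---------------------------------------------------------------------------
# Standardization and design construction
# ---------------------------------------------------------------------------

def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Centre and scale each numeric column to mean 0, sample-SD 1.

    Returns the transformed frame and a record {col: (mean, sd)} enabling
    back-transformation.  Zero-variance columns are dropped with a warning
    and recorded with sd=0.
    """
    out = {}
    record = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance column {col!r}")
            record[col] = (mu, 0.0)
            continue
        out[col] = (x - mu) / sd
        record[col] = (mu, sd)
    return pd.DataFrame(out, index=df.index), record


@dataclass
class Design:
    X: np.ndarray  # n x p, first column = intercept
    columns: list  # column names
    term_blocks: dict  # term label -> list of column indices
    y: np.ndarray
    groups: Optional[np.ndarray]  # integer codes or None
    group_labels: Optional[list]
    scaling: dict  # continuous var -> (mean, sd)
    aliased: list  # labels of dropped/aliased terms or columns
    n: int = dc_field(init=False)

    def __post_init__(self):
        self.n = self.X.shape[0]


def _expand_cont(data: pd.DataFrame, t: Cont, scaling: dict, do_std: bool):
    x = data[t.name].to_numpy(dtype=float)
    if do_std:
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    else:
        mu, sd = 0.0, 1.0
    if sd == 0.0:
        scaling[t.name] = (mu, 0.0)
        return []  # zero variance -> aliased
    scaling[t.name] = (mu, sd)
    z = (x - mu) / sd
    cols = [(t.name, t.name, z)]
    if t.quadratic:
        cols.append((f"{t.name}^2", f"{t.name}^2", z * z))
    return cols


def _expand_cat(data: pd.DataFrame, t: Cat):
    levels = sorted(pd.unique(data[t.name].astype(str)))
    ref = t.ref if t.ref is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} absent from {t.name!r}")
    others = [lv for lv in levels if lv != ref]
    x = data[t.name].astype(str).to_numpy()
    return [(t.name, f"{t.name}[{lv}]", (x == lv).astype(float)) for lv in others]


def build_design(data: pd.DataFrame, spec: ModelSpec, standardize_continuous: bool = True) -> Design:
    """Expand the model terms into a design matrix with an intercept.

    Continuous terms are standardized (quadratics built from the
    standardized base); categoricals are reference-coded; interactions are
    products of the expanded columns of both sides.  Columns that are
    linearly dependent on earlier ones (aliased) are dropped and reported,
    not fatal.
    """
    scaling: dict = {}
    aliased: list = []
    triples: list = [("Intercept", "Intercept", np.ones(len(data)))]

    def expand(t: Term):
        if isinstance(t, Cont):
            cols = _expand_cont(data, t, scaling, standardize_continuous)
            if not cols:
                aliased.append(t.name)
                warnings.warn(f"aliased term {t.name!r}: zero variance")
            return cols
        if isinstance(t, Cat):
            cols = _expand_cat(data, t)
            if not cols:
                aliased.append(t.name)
                warnings.warn(f"aliased term {t.name!r}: single level")
            return cols
        lcols = expand(t.left)
        rcols = expand(t.right)
        label = _term_label(t)
        return [
            (label, f"{lc[1]}:{rc[1]}", lc[2] * rc[2]) for lc in lcols for rc in rcols
        ]

    for t in spec.terms:
        if isinstance(t, Interaction):
            # the main-effect columns must already exist; expand() of the
            # interaction re-derives the component columns without re-adding
            triples.extend(expand(t))
        else:
            triples.extend(expand(t))

    # de-duplicate identical (block, column) pairs (interaction components)
    seen = set()
    uniq = []
    for blk, name, col in triples:
        if name in seen:
            continue
        seen.add(name)
        uniq.append((blk, name, col))

    # drop aliased columns by incremental rank
    X_cols, names, blocks = [], [], {}
    current = np.empty((len(data), 0))
    for blk, name, col in uniq:
        cand = np.column_stack([current, col])
        if np.linalg.matrix_rank(cand) > current.shape[1]:
            current = cand
            X_cols.append(col)
            blocks.setdefault(blk, []).append(len(names))
            names.append(name)
        else:
            aliased.append(name)
            warnings.warn(f"aliased column {name!r} dropped from design")

    groups = group_labels = None
    if spec.group is not None:
        codes, uniques = pd.factorize(data[spec.group].astype(str), sort=True)
        groups = codes.astype(int)
        group_labels = list(uniques)

    y = data[spec.response].to_numpy(dtype=float)
    blocks.pop("Intercept", None)
    blocks = {"Intercept": [0], **blocks}
    return Design(
        X=np.column_stack(X_cols),
        columns=names,
        term_blocks=blocks,
        y=y,
        groups=groups,
        group_labels=group_labels,
        scaling=scaling,
        aliased=aliased,
    )


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

def vif_table(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) of each column on the others (with intercept)."""
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    out = {}
    for j, col in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(Xv, j, axis=1)])
        y = Xv[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_screen(X: pd.DataFrame, threshold: float = 3.0):
    """Iteratively drop the highest-VIF predictor >= threshold until all pass.

    Returns (retained column list, history DataFrame of VIF tables with a
    'removed' marker per round).
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least two predictors")
    cols = list(X.columns)
    history = []
    while True:
        vifs = vif_table(X[cols])
        worst = vifs.idxmax()
        removed = vifs[worst] >= threshold
        history.append(
            pd.DataFrame(
                {"predictor": vifs.index, "vif": vifs.values,
                 "removed": [c == worst and removed for c in vifs.index]}
            )
        )
        if not removed or len(cols) == 1:
            break
        cols.remove(worst)
        if len(cols) == 1:
            break
    return cols, pd.concat(history, keys=range(len(history)), names=["round"]).reset_index(level=0)


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    family: str
    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    term_table: pd.DataFrame  # term, statistic, df, p (+ denom df for LMM)
    scaling: dict
    term_blocks: dict
    resid_var: Optional[float] = None  # sigma^2 (gaussian)
    group_var: Optional[float] = None  # random-intercept variance
    loglik_null: Optional[float] = None
    dispersion: Optional[float] = None
    flags: list = dc_field(default_factory=list)
    fit_stats: dict = dc_field(default_factory=dict)
    converged: bool = True

    @property
    def ci_low(self) -> pd.Series:
        return self.params - 1.96 * self.se

    @property
    def ci_high(self) -> pd.Series:
        return self.params + 1.96 * self.se

    def mcfadden_r2(self) -> Optional[float]:
        if self.loglik_null is None:
            return None
        if self.loglik_null == 0:
            return 0.0
        return 1.0 - self.loglik / self.loglik_null

    def tidy(self) -> pd.DataFrame:
        """Coefficient table mirroring the published layout."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.se.values,
                "ci_low": self.ci_low.values,
                "ci_high": self.ci_high.values,
            }
        )


def _wald_type3(params: np.ndarray, cov: np.ndarray, term_blocks: dict, names: list) -> pd.DataFrame:
    """Wald type-III chi^2 per term block: beta_b' V_bb^{-1} beta_b."""
    rows = []
    for label, idx in term_blocks.items():
        if label == "Intercept":
            continue
        idx = [i for i in idx if i < len(params)]
        if not idx:
            continue
        b = params[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df = len(idx)
        rows.append(
            {"term": label, "statistic": stat, "df": df,
             "p": float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else np.nan}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixed-effect models (statsmodels behind the module surface)
# ---------------------------------------------------------------------------

def fit_lm(spec: ModelSpec, data: pd.DataFrame, standardize_continuous: bool = True) -> FitResult:
    design = build_design(data, spec, standardize_continuous)
    model = sm.OLS(design.y, design.X)
    res = model.fit()
    cov = np.asarray(res.cov_params())
    params = pd.Series(res.params, index=design.columns)
    null_ll = float(sm.OLS(design.y, np.ones((design.n, 1))).fit().llf)
    fr = FitResult(
        family="gaussian",
        params=params,
        se=pd.Series(np.sqrt(np.diag(cov)), index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=float(res.llf),
        loglik_null=null_ll,
        n=design.n,
        term_table=_wald_type3(res.params, cov, design.term_blocks, design.columns),
        scaling=design.scaling,
        term_blocks=design.term_blocks,
        resid_var=float(res.scale),
        flags=[f"aliased:{a}" for a in design.aliased],
    )
    fr.fit_stats["adj_r2"] = float(res.rsquared_adj)
    fr.fit_stats["r2"] = float(res.rsquared)
    return fr


def fit_glm(spec: ModelSpec, data: pd.DataFrame, standardize_continuous: bool = True) -> FitResult:
    design = build_design(data, spec, standardize_continuous)
    fam = {"binomial": sm.families.Binomial(), "poisson": sm.families.Poisson(),
           "gaussian": sm.families.Gaussian()}[spec.family]
    if spec.family == "binomial":
        uniq = np.unique(design.y)
        if len(uniq) < 2:
            raise SeparationError("response has a single class")
    model = sm.GLM(design.y, design.X, family=fam)
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise ConvergenceError(str(exc)) from exc
    if spec.family == "binomial" and np.max(np.abs(res.params)) > 30:
        raise SeparationError(
            "complete separation suspected (|coef| > 30); consider penalized fit"
        )
    cov = np.asarray(res.cov_params())
    null_res = sm.GLM(design.y, np.ones((design.n, 1)), family=fam).fit()
    dispersion = None
    if spec.family == "poisson":
        mu = res.fittedvalues
        dispersion = float(np.sum((design.y - mu) ** 2 / mu) / res.df_resid) if res.df_resid > 0 else np.nan
    fr = FitResult(
        family=spec.family,
        params=pd.Series(res.params, index=design.columns),
        se=pd.Series(np.sqrt(np.diag(cov)), index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=float(res.llf),
        loglik_null=float(null_res.llf),
        n=design.n,
        term_table=_wald_type3(res.params, cov, design.term_blocks, design.columns),
        scaling=design.scaling,
        term_blocks=design.term_blocks,
        dispersion=dispersion,
        flags=[f"aliased:{a}" for a in design.aliased],
    )
    return fr


# ---------------------------------------------------------------------------
# Gaussian random-intercept LMM by profiled REML
# ---------------------------------------------------------------------------

def _group_sums(M: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    out = np.zeros((n_groups,) + M.shape[1:], dtype=float)
    np.add.at(out, groups, M)
    return out


def _lmm_gls(X, y, groups, n_groups, lam):
    """GLS pieces under V = I + lam * Z Z' (per-group compound symmetry)."""
    ng = np.bincount(groups, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * ng)  # per group
    Sx = _group_sums(X, groups, n_groups)  # G x p
    Sy = _group_sums(y[:, None], groups, n_groups)[:, 0]  # G
    XtVX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtVy = X.T @ y - (Sx * c[:, None]).T @ Sy
    ytVy = float(y @ y - c @ (Sy * Sy))
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    logdetV = float(np.sum(np.log1p(lam * ng)))
    return beta, XtVX, rss, logdetV, ng


def _reml_m2ll_profiled(log_lam, X, y, groups, n_groups):
    lam = np.exp(log_lam)
    n, p = X.shape
    beta, XtVX, rss, logdetV, _ = _lmm_gls(X, y, groups, n_groups, lam)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    return (
        (n - p) * np.log(2 * np.pi * sigma2)
        + logdetV
        + logdetXtVX
        - p * 0.0
        + (n - p)
    )


def _reml_m2ll(sigma2, tau2, X, y, groups, n_groups):
    """Unprofiled REML deviance at variance components (sigma2, tau2)."""
    n, p = X.shape
    lam = tau2 / sigma2
    beta, XtVX_l, rss_l, logdetV_l, ng = _lmm_gls(X, y, groups, n_groups, lam)
    # rescale from lambda-parameterization to absolute variances
    logdetV = n * np.log(sigma2) + logdetV_l
    quad = rss_l / sigma2
    sign, logdetXtVX = np.linalg.slogdet(XtVX_l / sigma2)
    return (n - p) * np.log(2 * np.pi) + logdetV + logdetXtVX + quad


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, standardize_continuous: bool = True) -> FitResult:
    """Gaussian random-intercept mixed model by profiled REML.

    The variance ratio lambda = tau^2/sigma^2 is profiled out and optimised
    on the log scale; a boundary solution (lambda -> 0) is reported as
    group_var = 0 with a flag rather than an error.  Per-term tests are
    F statistics with Satterthwaite denominator df.
    """
    if spec.group is None:
        raise ValueError("fit_lmm requires a grouping factor")
    design = build_design(data, spec, standardize_continuous)
    if design.groups is None or len(set(design.groups)) < 2:
        raise ValueError("grouping factor needs >= 2 groups")
    X, y, groups = design.X, design.y, design.groups
    n_groups = len(design.group_labels)
    n, p = X.shape

    res = optimize.minimize_scalar(
        _reml_m2ll_profiled,
        bounds=(-12.0, 12.0),
        method="bounded",
        args=(X, y, groups, n_groups),
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x)
    lam = float(np.exp(log_lam))
    flags = [f"aliased:{a}" for a in design.aliased]
    if log_lam <= -11.5:
        lam = 0.0
        flags.append("boundary:group_var_zero")
    beta, XtVX, rss, logdetV, ng = _lmm_gls(X, y, groups, n_groups, lam)
    sigma2 = rss / (n - p)
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    m2ll = _reml_m2ll(sigma2, max(tau2, 1e-12), X, y, groups, n_groups)

    # Satterthwaite df per coefficient
    sat_df = _satterthwaite_df(X, y, groups, n_groups, sigma2, tau2, flags)

    tt = _wald_type3(beta, cov, design.term_blocks, design.columns)
    if not tt.empty:
        tt["F"] = tt["statistic"] / tt["df"]
        # map single-coefficient blocks onto Satterthwaite denominators
        den = []
        for _, row in tt.iterrows():
            idx = design.term_blocks[row["term"]]
            den.append(float(np.mean([sat_df[i] for i in idx])))
        tt["den_df"] = den
        tt["p_F"] = [
            float(stats.f.sf(f, d1, d2)) if np.isfinite(f) and d2 > 0 else np.nan
            for f, d1, d2 in zip(tt["F"], tt["df"], tt["den_df"])
        ]

    return FitResult(
        family="gaussian",
        params=pd.Series(beta, index=design.columns),
        se=pd.Series(se, index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=-0.5 * float(m2ll),
        n=n,
        term_table=tt,
        scaling=design.scaling,
        term_blocks=design.term_blocks,
        resid_var=float(sigma2),
        group_var=float(tau2),
        flags=flags,
    )


def _satterthwaite_df(X, y, groups, n_groups, sigma2, tau2, flags) -> np.ndarray:
    """Satterthwaite denominator df per coefficient:
    df_k = 2 * C_kk^2 / Var(C_kk), Var via the delta method with the inverse
    observed REML information of (sigma^2, tau^2)."""
    n, p = X.shape

    def ckk(theta):
        s2, t2 = theta
        lam = max(t2, 0.0) / s2
        _, XtVX, _, _, _ = _lmm_gls(X, y, groups, n_groups, lam)
        return np.diag(s2 * np.linalg.inv(XtVX))

    try:
        t2_eval = max(tau2, 1e-8)
        h = np.array([max(sigma2, 1e-8) * 1e-4, t2_eval * 1e-4])
        theta0 = np.array([sigma2, t2_eval])

        def m2ll(theta):
            return _reml_m2ll(theta[0], max(theta[1], 1e-12), X, y, groups, n_groups)

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                H[i, j] = (
                    m2ll(theta0 + ei + ej) - m2ll(theta0 + ei - ej)
                    - m2ll(theta0 - ei + ej) + m2ll(theta0 - ei - ej)
                ) / (4 * h[i] * h[j])
        A = np.linalg.inv(0.5 * H)  # asymptotic cov of (sigma2, tau2)
        grads = np.zeros((p, 2))
        for j in range(2):
            e = np.zeros(2); e[j] = h[j]
            grads[:, j] = (ckk(theta0 + e) - ckk(theta0 - e)) / (2 * h[j])
        c0 = ckk(theta0)
        var_c = np.einsum("pi,ij,pj->p", grads, A, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * c0 ** 2 / var_c
        df = np.where((df > 0) & np.isfinite(df), df, float(n - p))
        return np.minimum(df, n - p)
    except np.linalg.LinAlgError:
        flags.append("satterthwaite_failed:residual_df_used")
        return np.full(p, float(n - p))


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM (Laplace)
# ---------------------------------------------------------------------------

def _glmm_inner_modes(beta, sigma2, X, y, groups, n_groups, u0):
    """Newton solve for the per-group random-intercept modes (concave)."""
    u = u0.copy()
    Xb = X @ beta
    for _ in range(200):
        eta = Xb + u[groups]
        p = special.expit(eta)
        g = np.bincount(groups, weights=y - p, minlength=n_groups) - u / sigma2
        w = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        # clamp the Newton step: the per-group objective is concave but an
        # undamped step can overshoot and oscillate from a far start
        step = np.clip(g / w, -2.0, 2.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return u


def _glmm_laplace_m2ll(params, X, y, groups, n_groups, state):
    beta = params[:-1]
    log_sigma = params[-1]
    sigma2 = float(np.exp(2.0 * log_sigma))
    u = _glmm_inner_modes(beta, sigma2, X, y, groups, n_groups, state["u"])
    state["u"] = u
    eta = X @ beta + u[groups]
    ll_data = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    p = special.expit(eta)
    W = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
    ll = (
        ll_data
        - float(np.sum(u * u)) / (2.0 * sigma2)
        - 0.5 * n_groups * np.log(sigma2)
        - 0.5 * float(np.sum(np.log(W)))
    )
    return -2.0 * ll


def fit_glmm_binomial(
    spec: ModelSpec,
    data: pd.DataFrame,
    standardize_continuous: bool = True,
    fix_sigma_zero: bool = False,
) -> FitResult:
    """Random-intercept logistic GLMM; the marginal likelihood is integrated
    per group with a Laplace approximation and maximised over (beta, log sigma).

    fix_sigma_zero=True collapses the model to a plain ML logistic fit
    (degenerate-variance contract).  Complete separation and non-convergence
    raise explicit diagnostics.
    """
    if spec.group is None and not fix_sigma_zero:
        raise ValueError("fit_glmm_binomial requires a grouping factor")
    design = build_design(data, spec, standardize_continuous)
    y = design.y
    if len(np.unique(y)) < 2:
        raise SeparationError("response has a single class")
    if fix_sigma_zero:
        glm = fit_glm(ModelSpec(spec.response, spec.terms, "binomial", None), data,
                      standardize_continuous)
        glm.group_var = 0.0
        glm.flags.append("boundary:group_var_fixed_zero")
        return glm

    X, groups = design.X, design.groups
    n_groups = len(design.group_labels)
    n, p = X.shape

    # warm start from the fixed-effect logistic fit; a wild starting fit
    # (possible quasi-separation) falls back to a neutral start — separation
    # is only fatal if the GLMM optimum itself is extreme
    try:
        start = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        beta0 = np.asarray(start.params)
    except Exception:
        beta0 = np.zeros(p)
    if np.max(np.abs(beta0)) > 15:
        beta0 = np.zeros(p)
        beta0[0] = special.logit(max(min(y.mean(), 1 - 1e-6), 1e-6))

    state = {"u": np.zeros(n_groups)}
    x0 = np.append(beta0, np.log(0.5))
    obj = lambda prm: _glmm_laplace_m2ll(prm, X, y, groups, n_groups, state)
    res = optimize.minimize(obj, x0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    if not (res.success or res.status == 2):  # status 2: precision loss near optimum
        raise ConvergenceError(f"GLMM optimizer failed: {res.message}")
    prm = res.x
    if np.max(np.abs(prm[:p])) > 30:
        raise SeparationError("complete separation suspected (|coef| > 30)")

    # observed information by central differences on the Laplace deviance
    hstep = 1e-4 * np.maximum(1.0, np.abs(prm))
    k = len(prm)
    H = np.zeros((k, k))
    f0 = obj(prm)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hstep[i]
            ej = np.zeros(k); ej[j] = hstep[j]
            fpp = obj(prm + ei + ej)
            fpm = obj(prm + ei - ej)
            fmp = obj(prm - ei + ej)
            fmm = obj(prm - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hstep[i] * hstep[j])
    try:
        cov_all = np.linalg.inv(0.5 * H)  # cov of (beta, log sigma)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix") from exc
    cov = cov_all[:p, :p]
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        raise ConvergenceError("non-positive-definite information at optimum")
    beta = prm[:p]
    sigma2 = float(np.exp(2.0 * prm[-1]))
    flags = [f"aliased:{a}" for a in design.aliased]
    if sigma2 < 1e-6:
        flags.append("boundary:group_var_zero")

    # null model (intercept + random intercept) for McFadden
    null_state = {"u": np.zeros(n_groups)}
    null_obj = lambda q: _glmm_laplace_m2ll(q, np.ones((n, 1)), y, groups, n_groups, null_state)
    null_res = optimize.minimize(null_obj, np.array([special.logit(max(min(y.mean(), 1 - 1e-6), 1e-6)), np.log(0.5)]),
                                 method="BFGS", options={"gtol": 1e-6})
    ll_null = -0.5 * float(null_res.fun)

    return FitResult(
        family="binomial",
        params=pd.Series(beta, index=design.columns),
        se=pd.Series(np.sqrt(diag), index=design.columns),
        cov=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        loglik=-0.5 * float(res.fun),
        loglik_null=ll_null,
        n=n,
        term_table=_wald_type3(beta, cov, design.term_blocks, design.columns),
        scaling=design.scaling,
        term_blocks=design.term_blocks,
        group_var=sigma2,
        flags=flags,
        converged=bool(res.success or res.status == 2),
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def marginal_r2(fit: FitResult, spec: ModelSpec, data: pd.DataFrame) -> float:
    """Nakagawa-style marginal R^2: variance of the fixed-effect linear
    predictor over the total (fixed + random-intercept + residual) variance.
    The residual variance is sigma^2 for Gaussian models and pi^2/3 on the
    latent scale for binomial-logit models."""
    design = build_design(data, spec, True)
    common = [c for c in fit.params.index if c in design.columns]
    idx = [design.columns.index(c) for c in common]
    eta = design.X[:, idx] @ fit.params[common].to_numpy()
    var_f = float(np.var(eta))
    tau2 = fit.group_var or 0.0
    if fit.family == "binomial":
        resid = np.pi ** 2 / 3.0
    elif fit.family == "poisson":
        resid = float(np.log(1.0 / np.exp(eta).mean() + 1.0))  # lognormal approx
    else:
        resid = fit.resid_var or 0.0
    total = var_f + tau2 + resid
    return var_f / total if total > 0 else np.nan


def semi_partial_r2(
    fit: FitResult, spec: ModelSpec, data: pd.DataFrame, fitter
) -> pd.Series:
    """Leave-one-term-out marginal-R^2 differences (declared estimator)."""
    full = marginal_r2(fit, spec, data)
    out = {}
    for label in fit.term_blocks:
        if label == "Intercept":
            continue
        reduced_spec = spec.without_term(label)
        if len(reduced_spec.terms) == len(spec.terms) and label not in [
            f"{t.name}^2" for t in spec.terms if isinstance(t, Cont) and t.quadratic
        ]:
            continue
        try:
            red = fitter(reduced_spec, data)
            out[label] = full - marginal_r2(red, reduced_spec, data)
        except Exception:
            out[label] = np.nan
    return pd.Series(out, name="semi_partial_r2")


def diagnostics(fit: FitResult, spec: ModelSpec, data: pd.DataFrame, fitter=None) -> dict:
    """Wald type-III table, McFadden R^2, marginal R^2, semi-partial R^2 and
    (Poisson) dispersion, as reported alongside each fitted model."""
    out = {
        "wald_type3": fit.term_table,
        "mcfadden_r2": fit.mcfadden_r2(),
        "marginal_r2": marginal_r2(fit, spec, data),
        "dispersion": fit.dispersion,
    }
    if fitter is not None:
        out["semi_partial_r2"] = semi_partial_r2(fit, spec, data, fitter)
    return out
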
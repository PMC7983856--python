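"""Statistical layer: trait–parameter associations.

Covers the analyses relating mating-system parameters to herkogamy and to
each other: REML variance components of herkogamy (among vs within plants),
beta regression of a proportion (the primary selfing rate) on herkogamy
with AIC link selection, Gaussian GLMs, ANCOVA with population as fixed
factor, and Pearson correlations.

Beta regression uses the mean–precision parametrization: the response is
Beta(mu*phi, (1-mu)*phi) with mu = link^-1(b0 + b1*x) and a single
precision phi fitted on the log scale.  A beta likelihood cannot score
exact 0/1 responses; when boundary values are present the standard
compression y' = (y*(n-1) + 0.5)/n is applied (and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import minimize_scalar
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.families import links as sm_links
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "VarianceComponents",
    "AssociationResult",
    "variance_components",
    "beta_regression",
    "select_link",
    "gaussian_glm",
    "ancova",
    "pearson_correlation",
]

_LINKS = {
    "logit": sm_links.Logit,
    "log": sm_links.Log,
    "cloglog": sm_links.CLogLog,
    "identity": sm_links.Identity,
}


@dataclass
class VarianceComponents:
    """Among- vs within-plant variance of a repeated floral measurement."""

    sigma2_among: float
    sigma2_within: float
    n_plants: int
    n_flowers: int
    method: str = "reml"

    @property
    def proportion_among(self) -> float:
        total = self.sigma2_among + self.sigma2_within
        return self.sigma2_among / total if total > 0 else np.nan


@dataclass
class AssociationResult:
    """One fitted association: family, link, coefficient table, fit stats."""

    response: str
    predictors: list[str]
    model_family: str  # beta | gaussian | ancova | pearson
    link: str
    params: pd.DataFrame  # index: term; columns: estimate, se, p
    log_likelihood: float
    aic: float
    n: int
    df: int
    phi: float | None = None
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        head = (
            f"{self.model_family} model: {self.response} ~ {' + '.join(self.predictors)}"
            f"  (link={self.link}, n={self.n})"
        )
        tab = self.params.to_string(float_format=lambda v: f"{v: .4f}")
        tail = f"log-likelihood {self.log_likelihood:.4f}   AIC {self.aic:.4f}"
        if self.phi is not None:
            tail += f"   phi {self.phi:.4f}"
        return "\n".join([head, "-" * len(head), tab, tail])


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


def variance_components(
    measurements: pd.DataFrame,
    value_col: str = "herkogamy",
    group_col: str = "plant",
) -> VarianceComponents:
    """One-way random-intercept REML fit (plant effect) on unbalanced data.

    Negative variance estimates are impossible under REML's boundary
    constraint; a zero among-plant component is returned as exactly 0.
    """
    df = measurements[[value_col, group_col]].dropna()
    sizes = df.groupby(group_col).size()
    if len(sizes) < 2:
        raise ValueError("need measurements from at least two plants")
    if (sizes < 2).all():
        raise ValueError("within-plant variance unidentifiable: all plants single-flower")

    # profile REML for the one-way random-intercept model.  With
    # theta = sigma2_among / sigma2_within, the within variance and the
    # grand mean profile out in closed form and the criterion reduces to a
    # 1-D minimisation in theta, solved by Brent to machine precision
    # (an iterative mixed-model fitter stalls well short of that).
    y = df[value_col].to_numpy(dtype=float)
    groups, counts = np.unique(df[group_col].to_numpy(), return_counts=True)
    idx = pd.Series(np.arange(len(groups)), index=groups)[df[group_col]].to_numpy()
    n_i = counts.astype(float)
    ybar = np.bincount(idx, weights=y) / n_i
    ss_within = np.bincount(idx, weights=(y - ybar[idx]) ** 2)
    N = y.size

    def criterion(theta: float) -> float:
        d = 1.0 + n_i * theta
        w = n_i / d
        mu = float((w * ybar).sum() / w.sum())
        q = float((ss_within + n_i * (ybar - mu) ** 2 / d).sum())
        return (N - 1) * np.log(q) + float(np.log(d).sum()) + np.log(w.sum())

    # bracket in log-space; theta = 0 boundary handled explicitly
    res = minimize_scalar(
        lambda u: criterion(np.exp(u)), bounds=(-30.0, 30.0), method="bounded",
        options={"xatol": 1e-12},
    )
    theta = float(np.exp(res.x))
    if criterion(0.0) <= criterion(theta):
        theta = 0.0
    d = 1.0 + n_i * theta
    w = n_i / d
    mu = float((w * ybar).sum() / w.sum())
    q = float((ss_within + n_i * (ybar - mu) ** 2 / d).sum())
    s2_within = q / (N - 1)
    return VarianceComponents(
        sigma2_among=theta * s2_within,
        sigma2_within=s2_within,
        n_plants=int(len(groups)),
        n_flowers=int(N),
    )


# ---------------------------------------------------------------------------
# beta regression
# ---------------------------------------------------------------------------


def compress_boundary(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Smithson–Verkuilen compression y' = (y(n-1)+0.5)/n, applied only when
    exact 0/1 responses are present."""
    y = np.asarray(y, dtype=float)
    if np.any((y == 0.0) | (y == 1.0)):
        n = y.size
        return (y * (n - 1) + 0.5) / n, True
    return y, False


def _fit_beta(model: BetaModel, y: np.ndarray, x: np.ndarray, link: str):
    """Fit with the default start, falling back to link-transformed OLS
    starts; non-logit mean links often need the hint."""
    import warnings

    attempts: list[np.ndarray | None] = [None]
    g = _LINKS[link]()
    eta = g(np.clip(y, 1e-6, 1 - 1e-6))
    ols = sm.OLS(eta, sm.add_constant(x)).fit()
    for phi0 in (np.log(10.0), np.log(50.0)):
        attempts.append(np.r_[ols.params, phi0])
    best = None
    for start in attempts:
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                res = model.fit(disp=False, maxiter=500, start_params=start)
                if not np.isfinite(res.llf) or not res.mle_retvals.get("converged", True):
                    continue
                if best is None or res.llf > best.llf:
                    best = res
        except Exception:  # noqa: BLE001 - try the next start
            continue
    return best


def beta_regression(y, x, link: str = "logit", x_name: str = "x", y_name: str = "y") -> AssociationResult:
    """ML beta regression of a proportion on one covariate.

    Returns estimates/SEs/Wald p-values for intercept and slope, the
    precision phi, log-likelihood and AIC (k = 3 parameters).  Raises on
    responses outside [0, 1] or a non-converged optimisation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any((y < 0) | (y > 1) | ~np.isfinite(y)):
        raise ValueError("beta regression response must lie in [0, 1]")
    if link not in _LINKS:
        raise ValueError(f"unknown link {link!r}")
    y_fit, compressed = compress_boundary(y)
    if np.ptp(y_fit) == 0.0:
        # constant response: the mean model is exact (slope 0) and the
        # precision diverges, so report the flat fit explicitly
        g = _LINKS[link]()
        params = pd.DataFrame(
            {"estimate": [float(g(y_fit[0])), 0.0], "se": [np.nan, np.nan], "p": [np.nan, np.nan]},
            index=["intercept", x_name],
        )
        return AssociationResult(
            response=y_name, predictors=[x_name], model_family="beta", link=link,
            params=params, log_likelihood=np.nan, aic=np.nan, n=int(y.size),
            df=int(y.size - 3), phi=None,
            extra={"boundary_compressed": compressed, "degenerate": True},
        )
    exog = sm.add_constant(x)
    model = BetaModel(y_fit, exog, link=_LINKS[link]())
    res = _fit_beta(model, y_fit, x, link)
    if res is None or not res.mle_retvals.get("converged", True) or not np.isfinite(res.llf):
        raise RuntimeError(f"beta regression with {link} link did not converge")
    with np.errstate(all="ignore"):
        est = np.asarray(res.params)
        se = np.asarray(res.bse)
        p = np.asarray(res.pvalues)
    params = pd.DataFrame(
        {"estimate": est[:2], "se": se[:2], "p": p[:2]},
        index=["intercept", x_name],
    )
    k = len(est)
    llf = float(res.llf)
    return AssociationResult(
        response=y_name,
        predictors=[x_name],
        model_family="beta",
        link=link,
        params=params,
        log_likelihood=llf,
        aic=2 * k - 2 * llf,
        n=int(y.size),
        df=int(y.size - k),
        phi=float(np.exp(est[-1])) if model.link_precision.__class__.__name__ == "Log" else float(est[-1]),
        extra={"boundary_compressed": compressed},
    )


def select_link(
    y,
    x,
    links: tuple[str, ...] = ("cloglog", "logit", "log"),
    x_name: str = "x",
    y_name: str = "y",
) -> tuple[AssociationResult, pd.DataFrame]:
    """Fit one beta regression per link and keep the minimum-AIC fit.

    Returns ``(best_fit, aic_table)``; ties break toward the logit link.
    Links that fail to converge are excluded (recorded in the table with
    NaN AIC); if every link fails, the errors are aggregated and raised.
    """
    fits: dict[str, AssociationResult] = {}
    rows = []
    errors = []
    for lk in links:
        try:
            fit = beta_regression(y, x, link=lk, x_name=x_name, y_name=y_name)
            fits[lk] = fit
            rows.append({"link": lk, "aic": fit.aic, "log_likelihood": fit.log_likelihood})
        except Exception as exc:  # noqa: BLE001 - report per-link failure
            errors.append(f"{lk}: {exc}")
            rows.append({"link": lk, "aic": np.nan, "log_likelihood": np.nan})
    if not fits:
        raise RuntimeError("all link fits failed: " + "; ".join(errors))
    table = pd.DataFrame(rows)
    best_aic = min(f.aic for f in fits.values())
    if "logit" in fits and fits["logit"].aic <= best_aic + 1e-9:
        best = fits["logit"]
    else:
        best = min(fits.values(), key=lambda f: f.aic)
    return best, table


# ---------------------------------------------------------------------------
# Gaussian models
# ---------------------------------------------------------------------------


def gaussian_glm(y, x, x_name: str = "x", y_name: str = "y") -> AssociationResult:
    """Gaussian GLM (OLS) of y on one covariate; t-based p-values."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    params = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "p": res.pvalues},
    )
    params.index = ["intercept", x_name]
    k = 3  # intercept, slope, residual variance
    return AssociationResult(
        response=y_name,
        predictors=[x_name],
        model_family="gaussian",
        link="identity",
        params=params,
        log_likelihood=float(res.llf),
        aic=2 * k - 2 * float(res.llf),
        n=int(y.size),
        df=int(res.df_resid),
    )


def ancova(
    y,
    group,
    covariate,
    y_name: str = "y",
    interaction: bool = False,
) -> AssociationResult:
    """Linear model ``y ~ group + covariate`` with Type-II marginal F-tests.

    ``group`` is a categorical fixed factor (e.g., population); the
    covariate is quantitative.  The returned ``params`` table holds the
    coefficient estimates; the per-term F statistics and p-values sit in
    ``extra['anova']``.
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "group": np.asarray(group), "cov": np.asarray(covariate, dtype=float)})
    sizes = df.groupby("group").size()
    if len(sizes) < 2:
        raise ValueError("ANCOVA needs at least two groups")
    if (sizes < 2).any():
        raise ValueError("each group needs at least two observations")
    formula = "y ~ C(group) * cov" if interaction else "y ~ C(group) + cov"
    res = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(res, typ=2)
    params = pd.DataFrame({"estimate": res.params, "se": res.bse, "p": res.pvalues})
    k = len(res.params) + 1
    return AssociationResult(
        response=y_name,
        predictors=["group", "covariate"],
        model_family="ancova",
        link="identity",
        params=params,
        log_likelihood=float(res.llf),
        aic=2 * k - 2 * float(res.llf),
        n=int(len(df)),
        df=int(res.df_resid),
        extra={"anova": anova},
    )


def pearson_correlation(x, y, x_name: str = "x", y_name: str = "y") -> AssociationResult:
    """Pearson correlation with t test on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = scipy.stats.pearsonr(x, y)
    n = x.size
    se = float(np.sqrt((1 - r**2) / (n - 2))) if abs(r) < 1 else 0.0
    params = pd.DataFrame({"estimate": [r], "se": [se], "p": [p]}, index=[f"corr({x_name},{y_name})"])
    return AssociationResult(
        response=y_name,
        predictors=[x_name],
        model_family="pearson",
        link="identity",
        params=params,
        log_likelihood=np.nan,
        aic=np.nan,
        n=int(n),
        df=int(n - 2),
    )
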
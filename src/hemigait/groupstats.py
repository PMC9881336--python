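"""Per-metric mixed-effects models of group, centered speed, and interaction.

Model, one per gait metric:

    y_ij = b0 + bG * group_i + bS * speed~_ij + bGS * group_i * speed~_ij
           + u_i + e_ij,     u_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with group coded stroke = 1 / neurotypical = 0 (a positive group coefficient
means larger in stroke) and speed~ the grand-mean-centered belt speed, so the
group coefficient is the between-group contrast at the average speed.

The classical fit is restricted maximum likelihood with the likelihood
profiled over the variance ratio; fixed-effect tests use Satterthwaite
degrees of freedom computed from the REML information.  The robust fit
iterates Huber downweighting of both scaled residuals and predicted random
intercepts (tuning constant 1.345 by default) around weighted REML; with the
tuning constant at infinity it reproduces the classical fit exactly.
Satterthwaite df for the robust path are borrowed from the classical fit on
the same design — a documented approximation, since no exact robust recipe
exists for this estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

TERMS = ("intercept", "group", "speed_centered", "group_x_speed")
METRICS = ("sla", "dlsta", "slsta", "knee_flex_deg", "tla_deg", "circumduction_m", "hip_hike_deg")
ALPHA = 0.05  # a-priori significance threshold


class ModelError(ValueError):
    pass


@dataclass
class ModelFitResult:
    metric: str
    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    df: np.ndarray
    p_values: np.ndarray
    tau2: float
    sigma2: float
    n_observations: int
    n_participants: int
    estimator: str
    converged: bool = True
    n_iter: int = 0
    singular_random_effect: bool = False

    def __post_init__(self) -> None:
        if np.any(self.se <= 0) or np.any(self.df <= 0):
            raise ModelError("invalid fit: non-positive SE or df")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "term": list(self.terms),
                "estimate": self.coef,
                "se": self.se,
                "df": self.df,
                "p": self.p_values,
            }
        )


def center_speed(speeds: np.ndarray | pd.Series) -> np.ndarray:
    """Subtract the grand mean (not per-group) so centered speeds sum to 0."""
    speeds = np.asarray(speeds, dtype=float)
    if np.unique(speeds).size < 2:
        raise ModelError("need >= 2 distinct speed values to center")
    return speeds - speeds.mean()


# ---------------------------------------------------------------------------
# weighted random-intercept REML core (closed-form Woodbury via group sums)


def _gls(y, X, codes, G, sigma2, tau2, w_e, inv_wb):
    """GLS pieces for V_g = sigma2 * diag(1/w_e) + (tau2 * inv_wb_g) * 11'."""
    n, p = X.shape
    u = tau2 * inv_wb  # per-group random-intercept variance after weighting
    sw = np.bincount(codes, weights=w_e, minlength=G)
    gam = u / (sigma2 + u * sw)
    Xw = X * w_e[:, None]
    Sx = np.zeros((G, p))
    np.add.at(Sx, codes, Xw)
    XtViX = (X.T @ Xw - (Sx.T * gam) @ Sx) / sigma2
    Sy = np.bincount(codes, weights=w_e * y, minlength=G)
    XtViy = (Xw.T @ y - Sx.T @ (gam * Sy)) / sigma2
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    Sr = np.bincount(codes, weights=w_e * r, minlength=G)
    rtVir = (np.sum(w_e * r * r) - np.sum(gam * Sr * Sr)) / sigma2
    logdetV = (
        n * np.log(sigma2) - np.sum(np.log(w_e)) + np.sum(np.log1p(u * sw / sigma2))
    )
    blup = u * Sr * (1.0 - gam * sw) / sigma2
    return beta, XtViX, rtVir, logdetV, blup


def _reml_loglik(y, X, codes, G, sigma2, tau2, w_e, inv_wb):
    _, XtViX, rtVir, logdetV, _ = _gls(y, X, codes, G, sigma2, tau2, w_e, inv_wb)
    sign, logdet_info = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdetV + logdet_info + rtVir)


def _fit_reml(y, X, codes, G, w_e, inv_wb):
    """Profiled REML over the variance ratio rho = tau2/sigma2."""
    n, p = X.shape

    def neg_profiled(log_rho):
        rho = np.exp(log_rho)
        _, XtViX, rtV0ir, logdetV0, _ = _gls(y, X, codes, G, 1.0, rho, w_e, inv_wb)
        sigma2 = rtV0ir / (n - p)
        sign, logdet_info = np.linalg.slogdet(XtViX)
        if sign <= 0 or sigma2 <= 0:
            return np.inf
        return 0.5 * (logdetV0 + logdet_info + (n - p) * (np.log(sigma2) + 1.0))

    res = optimize.minimize_scalar(neg_profiled, bounds=(-13.0, 9.0), method="bounded")
    log_rho = float(res.x)
    rho = np.exp(log_rho)
    beta, XtViX, rtV0ir, _, _ = _gls(y, X, codes, G, 1.0, rho, w_e, inv_wb)
    sigma2 = rtV0ir / (n - p)
    tau2 = rho * sigma2
    singular = log_rho <= -12.5
    beta, XtViX, _, _, blup = _gls(y, X, codes, G, sigma2, tau2, w_e, inv_wb)
    cov_beta = np.linalg.inv(XtViX)
    return beta, cov_beta, sigma2, tau2, blup, singular


def _satterthwaite(y, X, codes, G, sigma2, tau2, w_e, inv_wb):
    """Satterthwaite df per coefficient from the REML information.

    df_k = 2 f_k^2 / (g_k' A g_k) with f_k the k-th diagonal of the
    fixed-effect covariance as a function of (sigma2, tau2), g_k its
    gradient, and A the inverse observed REML information of (sigma2, tau2).
    """
    phi = np.array([sigma2, max(tau2, 1e-10 * sigma2)])
    steps = np.maximum(phi, 1e-8) * 1e-4

    def covdiag(ph):
        _, XtViX, _, _, _ = _gls(y, X, codes, G, ph[0], ph[1], w_e, inv_wb)
        return np.diag(np.linalg.inv(XtViX))

    def ll(ph):
        return _reml_loglik(y, X, codes, G, ph[0], ph[1], w_e, inv_wb)

    p = X.shape[1]
    grad = np.zeros((2, p))
    for i in range(2):
        e = np.zeros(2)
        e[i] = steps[i]
        grad[i] = (covdiag(phi + e) - covdiag(phi - e)) / (2 * steps[i])

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = steps[i], steps[j]
            H[i, j] = H[j, i] = (
                ll(phi + ei + ej) - ll(phi + ei - ej) - ll(phi - ei + ej) + ll(phi - ei - ej)
            ) / (4 * steps[i] * steps[j])
    info = -H
    try:
        A = np.linalg.inv(info)
        if np.any(np.diag(A) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(info)
    f = covdiag(phi)
    denom = np.einsum("ip,ij,jp->p", grad, A, grad)
    n, pdim = X.shape
    df = np.where(denom > 0, 2.0 * f**2 / np.maximum(denom, 1e-300), n - pdim)
    return np.clip(df, 1.0, 1e7)


def _huber_weight(z: np.ndarray, c: float) -> np.ndarray:
    """psi(z)/z for the Huber psi: 1 inside [-c, c], c/|z| outside."""
    if not np.isfinite(c):
        return np.ones_like(z)
    az = np.abs(z)
    return np.where(az <= c, 1.0, c / np.maximum(az, 1e-300))


def _mad_scale(x: np.ndarray, fallback: float) -> float:
    s = 1.4826 * np.median(np.abs(x - np.median(x)))
    return float(s) if s > 0 else fallback


# ---------------------------------------------------------------------------
# public fitting interface


def _design(df: pd.DataFrame, metric: str):
    sub = df[["participant_id", "group", "speed_mps", metric]].dropna(subset=[metric])
    if sub.empty:
        raise ModelError(f"no usable rows for {metric}")
    g = (sub["group"].str.lower() == "stroke").astype(float).to_numpy()
    for label, mask in (("stroke", g == 1), ("neurotypical", g == 0)):
        if sub.loc[mask, "participant_id"].nunique() < 2:
            raise ModelError(f"fewer than 2 {label} participants for {metric}")
    s = center_speed(sub["speed_mps"].to_numpy())
    X = np.column_stack([np.ones(len(sub)), g, s, g * s])
    y = sub[metric].to_numpy(float)
    codes, uniques = pd.factorize(sub["participant_id"])
    return y, X, codes.astype(int), len(uniques)


def fit_metric_model(
    table: pd.DataFrame,
    metric: str,
    estimator: str = "robust",
    *,
    tuning_constant: float = 1.345,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ModelFitResult:
    """Fit the group x centered-speed random-intercept model for one metric.

    ``table`` follows the metrics-table schema (participant_id, group,
    speed_mps, metric columns); rows with the metric missing are dropped
    listwise for this metric only.
    """
    if estimator not in ("robust", "classical"):
        raise ModelError(f"unknown estimator {estimator!r}")
    y, X, codes, G = _design(table, metric)
    n, p = X.shape
    ones = np.ones(n)
    ones_g = np.ones(G)

    beta, cov, sigma2, tau2, blup, singular = _fit_reml(y, X, codes, G, ones, ones_g)
    if singular:
        warnings.warn(
            f"{metric}: random-intercept variance estimated at boundary; "
            "falling back to fixed-effects-only inference",
            stacklevel=2,
        )
        se = np.sqrt(np.diag(cov))
        df = np.full(p, float(n - p))
        t = beta / se
        return ModelFitResult(
            metric=metric, terms=TERMS, coef=beta, se=se, df=df,
            p_values=2 * stats.t.sf(np.abs(t), df), tau2=tau2, sigma2=sigma2,
            n_observations=n, n_participants=G, estimator=estimator,
            singular_random_effect=True,
        )

    df_sat = _satterthwaite(y, X, codes, G, sigma2, tau2, ones, ones_g)
    n_iter, converged = 0, True

    if estimator == "robust":
        # Huber-type downweighting of both scaled residuals and predicted
        # random intercepts (standardized by robust MAD scales, so an outlier
        # cannot inflate its own standardization), iterated around weighted
        # REML.  With the tuning constant at infinity all weights are 1 and
        # the first pass reproduces the classical fit exactly.
        c = tuning_constant
        w_e_prev = None
        for n_iter in range(1, max_iter + 1):
            resid = y - X @ beta - blup[codes]
            s_e = _mad_scale(resid, np.sqrt(sigma2))
            s_b = _mad_scale(blup, np.sqrt(max(tau2, 1e-12)))
            w_e = _huber_weight(resid / s_e, c)
            w_b = _huber_weight(blup / s_b, c)
            if w_e_prev is not None:  # damp weight churn between iterations
                w_e = 0.5 * (w_e + w_e_prev[0])
                w_b = 0.5 * (w_b + w_e_prev[1])
            w_e_prev = (w_e, w_b)
            inv_wb = 1.0 / np.maximum(w_b, 1e-8)
            beta_new, cov, sigma2, tau2, blup, sing = _fit_reml(
                y, X, codes, G, w_e, inv_wb
            )
            delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
            beta = beta_new
            if delta < tol:
                break
        else:
            converged = False
            warnings.warn(
                f"{metric}: robust fit did not converge in {max_iter} iterations "
                f"(last relative change {delta:.2e})",
                stacklevel=2,
            )

    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df_sat)
    return ModelFitResult(
        metric=metric, terms=TERMS, coef=beta, se=se, df=df_sat,
        p_values=np.clip(pvals, np.finfo(float).tiny, 1.0),
        tau2=float(tau2), sigma2=float(sigma2),
        n_observations=n, n_participants=G, estimator=estimator,
        converged=converged, n_iter=n_iter,
    )


def fit_all_metrics(
    table: pd.DataFrame, estimator: str = "robust", min_rows: int = 10
) -> list[ModelFitResult]:
    """One model per outcome metric; metrics with too few usable rows are
    skipped with a warning (per-metric listwise deletion of missing rows)."""
    fits = []
    for metric in METRICS:
        usable = table[metric].notna().sum() if metric in table else 0
        if usable < min_rows:
            warnings.warn(f"{metric}: only {usable} usable rows, skipped", stacklevel=2)
            continue
        fits.append(fit_metric_model(table, metric, estimator=estimator))
    return fits


def results_table(fits: list[ModelFitResult]) -> pd.DataFrame:
    return pd.concat([f.summary_frame() for f in fits], ignore_index=True)
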
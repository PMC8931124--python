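"""Random-intercept (panel) logit fitted by maximum likelihood.

The model for subject i, trial t:

    P(y_it = 1 | x_it, u_i) = logistic(x_it' b + u_i),   u_i ~ N(0, sigma_u^2)

The marginal per-subject likelihood integrates the random intercept out
with Gauss-Hermite quadrature; the variance is parameterized as
lnsig2u = log(sigma_u^2) so the optimization is unconstrained (a hard
floor keeps exp(lnsig2u) finite when the data carry no between-subject
variance, in which case the fit collapses to a plain logit). Standard
errors are cluster-robust (sandwich over subjects). Average marginal
effects are the sample-average derivative of the predicted probability
at the subject-average intercept (u = 0) by default; integrating the
probability over the estimated random-intercept distribution is
available behind a flag.

statsmodels supplies starting values (plain Logit) and the numerical
differentiation utilities; it has no maximum-likelihood random-effects
logit of its own, which is why the estimator lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import logsumexp
from statsmodels.tools import numdiff

__all__ = ["PanelLogitResult", "fit_random_intercept_logit", "panel_logit",
           "SPEC_COLUMNS"]

_LNSIG2U_BOUNDS = (-12.0, 8.0)


@dataclass
class PanelLogitResult:
    """Coefficients, cluster-robust SEs, variance component, and AMEs."""

    params: pd.Series
    bse: pd.Series
    lnsig2u: float
    lnsig2u_se: float
    ame: pd.Series
    loglike: float
    n_obs: int
    n_clusters: int
    converged: bool

    @property
    def sigma_u(self) -> float:
        return float(np.exp(self.lnsig2u / 2.0))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "ame": self.ame})


def _cluster_loglikes(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                      starts: np.ndarray, nodes: np.ndarray,
                      log_wts: np.ndarray) -> np.ndarray:
    """Log marginal likelihood per cluster, GH quadrature over u."""
    beta, lnsig2u = theta[:-1], theta[-1]
    sigma = np.exp(lnsig2u / 2.0)
    xb = X @ beta
    # log Bernoulli likelihood per observation per node:
    #   y*eta - log(1 + exp(eta)),  eta = xb + sqrt(2)*sigma*z
    eta = xb[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    # sum within clusters (clusters are contiguous via `starts`)
    ll_cluster_node = np.add.reduceat(ll_obs, starts, axis=0)
    return logsumexp(ll_cluster_node + log_wts[None, :], axis=1)


def fit_random_intercept_logit(
    X: pd.DataFrame,
    y: Sequence[int],
    groups: Sequence,
    n_quad: int = 21,
    integrate_re_ame: bool = False,
    start_params: Optional[np.ndarray] = None,
) -> PanelLogitResult:
    """Fit the random-intercept logit by GH-quadrature ML.

    ``X`` must already contain a constant column if one is wanted.
    Observations are re-sorted by group internally; ``groups`` defines
    the clustering for both the likelihood and the robust SEs.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    Xv = X.to_numpy(dtype=float)[order]
    yv = y[order]
    gv = groups[order]
    _, starts = np.unique(gv, return_index=True)
    n_clusters = starts.size

    z, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_wts = np.log(wts) - 0.5 * np.log(np.pi)

    def nll(theta):
        return -np.sum(_cluster_loglikes(theta, Xv, yv, starts, z, log_wts))

    if start_params is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                logit0 = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
                b0 = logit0.params
                if not np.all(np.isfinite(b0)) or np.abs(b0).max() > 50:
                    warnings.warn("possible separation in the plain-logit "
                                  "starting fit", stacklevel=2)
                    b0 = np.clip(b0, -50, 50)
            except Exception:
                b0 = np.zeros(Xv.shape[1])
        start_params = np.append(b0, 0.0)

    bounds = [(None, None)] * Xv.shape[1] + [_LNSIG2U_BOUNDS]
    res = optimize.minimize(nll, start_params, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    if not res.success:
        warnings.warn(f"panel logit did not fully converge: {res.message}")
    theta = res.x

    # cluster-robust sandwich: H^{-1} (sum_i g_i g_i') H^{-1}
    def cluster_ll(t):
        return _cluster_loglikes(t, Xv, yv, starts, z, log_wts)

    G = numdiff.approx_fprime(theta, cluster_ll)  # n_clusters x n_params
    H = numdiff.approx_hess1(theta, nll)
    try:
        Hinv = np.linalg.inv(H)
        meat = G.T @ G
        cov = Hinv @ meat @ Hinv
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; standard errors unavailable")
        se = np.full(theta.size, np.nan)

    beta = theta[:-1]
    if integrate_re_ame:
        sigma = np.exp(theta[-1] / 2.0)
        eta = Xv @ beta
        etas = eta[:, None] + np.sqrt(2.0) * sigma * z[None, :]
        p = 1.0 / (1.0 + np.exp(-etas))
        dens = (p * (1 - p)) @ (wts / np.sqrt(np.pi))
    else:
        p = 1.0 / (1.0 + np.exp(-(Xv @ beta)))
        dens = p * (1 - p)
    ame = dens.mean() * beta

    return PanelLogitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se[:-1], index=names),
        lnsig2u=float(theta[-1]),
        lnsig2u_se=float(se[-1]),
        ame=pd.Series(ame, index=names),
        loglike=float(-res.fun),
        n_obs=int(yv.size),
        n_clusters=int(n_clusters),
        converged=bool(res.success),
    )


SPEC_COLUMNS = {
    1: ["const", "cancellation"],
    2: ["const", "cancellation", "t0", "alpha_i", "delta_i", "beta_i"],
    3: ["const", "cancellation", "t0", "alpha_i", "delta_i", "beta_i",
        "cancellation_x_t0", "cancellation_x_alpha"],
}


def panel_logit(trials: pd.DataFrame, estimates: pd.DataFrame,
                spec: int = 3, trial_subset: Optional[str] = None,
                n_quad: int = 21,
                integrate_re_ame: bool = False) -> PanelLogitResult:
    """Random-intercept logit of later-choice on framing and preferences.

    ``trials`` is a trial-level table (trials.csv layout); ``estimates``
    carries the per-subject structural estimates (estimates.csv layout)
    and must already exclude negative-alpha subjects (enforced here).
    ``trial_subset``: None/"all" keeps every trial; "diff1" keeps only
    the pairs whose amounts differ by exactly 1 currency unit.
    Specifications: 1 = condition only; 2 = + immediacy and the three
    preference parameters; 3 = + condition interactions with immediacy
    and curvature.
    """
    if spec not in SPEC_COLUMNS:
        raise ValueError("spec must be 1, 2 or 3")
    if bool(estimates.get("negative_alpha_flag", pd.Series(dtype=bool)).any()):
        raise ValueError("estimates still contain negative-alpha subjects; "
                         "apply the exclusion filter first")
    df = trials.merge(
        estimates[["subject_id", "alpha_hat", "beta_hat", "delta_hat"]],
        on="subject_id", how="inner",
    )
    if trial_subset not in (None, "all", "diff1"):
        raise ValueError(f"unknown trial_subset {trial_subset!r}")
    if trial_subset == "diff1":
        df = df[np.isclose(df["later_amount"] - df["earlier_amount"], 1.0)]
    if df.empty:
        raise ValueError("no trials left after merging/subsetting")
    design = pd.DataFrame({
        "const": 1.0,
        "cancellation": (df["condition"] == "cancellation").astype(float),
        "t0": df["t0"].astype(float),
        "alpha_i": df["alpha_hat"].astype(float),
        "delta_i": df["delta_hat"].astype(float),
        "beta_i": df["beta_hat"].astype(float),
    })
    design["cancellation_x_t0"] = design["cancellation"] * design["t0"]
    design["cancellation_x_alpha"] = design["cancellation"] * design["alpha_i"]
    cols = SPEC_COLUMNS[spec]
    return fit_random_intercept_logit(
        design[cols], df["choice_later"].to_numpy(), df["subject_id"].to_numpy(),
        n_quad=n_quad, integrate_re_ame=integrate_re_ame,
    )
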
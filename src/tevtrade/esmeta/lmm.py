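"""Maximum-likelihood fitting of the random-intercept linear mixed model.

The ES-value meta-analysis uses a single model family throughout:

    y_i = x_i' beta + a_c(i) + e_i,   a_c ~ N(0, s1^2),  e_i ~ N(0, s^2)

with one random intercept per country.  For this family the ML problem
profiles down to a one-dimensional search: given the variance ratio
``rho = s1^2 / s^2`` the GLS estimate of ``beta`` is ordinary least squares
on quasi-demeaned data (each observation shrunk towards its group mean by
``theta_g = 1 - 1/sqrt(1 + n_g rho)``), and ``s^2`` is profiled out in
closed form.  The profile log-likelihood is

    ll(rho) = -n/2 [log(2 pi) + 1 + log(rss(rho)/n)]
              - 1/2 sum_g log(1 + n_g rho)

which we maximize over ``log rho`` with a bounded scalar search, always
comparing against the boundary ``rho = 0`` (the fixed-effects fit).  This
makes a single fit cheap enough to sustain full 2^J model enumeration,
leave-one-out cross-validation, and bootstrap refitting.

ML (not REML) is used deliberately: AICc comparisons across different
fixed-effect sets require full-likelihood values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ..exceptions import FitError

__all__ = ["LMMFit", "fit_random_intercept"]

#: variance-ratio value below which the fit is reported as singular
_SINGULAR_RHO = 1e-7


@dataclass
class LMMFit:
    """ML estimates of the random-intercept model."""

    columns: tuple[str, ...]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_country: float
    sigma_resid: float
    loglik: float
    group_effects: dict[int, float]   # BLUPs of a_c, keyed by group label
    n: int
    k: int                            # fixed effects + 2 variance parameters
    singular: bool = False
    _fitted_rho: float = field(default=0.0, repr=False)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _check_rank(X: np.ndarray, columns: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(X, mode="economic", pivoting=True)
        offenders = [columns[j] for j in piv[rank:]]
        raise FitError(f"design is rank-deficient; collinear terms: {offenders}")


def fit_random_intercept(
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray,
        columns: tuple[str, ...] | None = None,
        group_labels: np.ndarray | None = None,
) -> LMMFit:
    """Fit the model by profiled maximum likelihood.

    Parameters
    ----------
    y, X
        Response vector and design matrix (intercept included as a column).
    groups
        Integer group codes ``0..G-1`` per observation.
    columns
        Design column names (used in error messages and the result).
    group_labels
        Original group labels in code order; defaults to the codes.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if columns is None:
        columns = tuple(f"x{j}" for j in range(p))
    if n <= p + 2:
        raise FitError(f"too few observations (n={n}) for {p} fixed effects")
    _check_rank(X, columns)

    n_groups = int(groups.max()) + 1 if len(groups) else 0
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    present = counts > 0
    # per-group means, precomputed once
    ybar = np.zeros(n_groups)
    np.add.at(ybar, groups, y)
    ybar[present] /= counts[present]
    Xbar = np.zeros((n_groups, p))
    np.add.at(Xbar, groups, X)
    Xbar[present] /= counts[present][:, None]

    log2pi = np.log(2.0 * np.pi)

    def profile(rho: float):
        theta = 1.0 - 1.0 / np.sqrt(1.0 + counts * rho)
        w = theta[groups]
        yt = y - w * ybar[groups]
        Xt = X - w[:, None] * Xbar[groups]
        XtX = Xt.T @ Xt
        Xty = Xt.T @ yt
        try:
            beta = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        resid = yt - Xt @ beta
        rss = float(resid @ resid)
        sigma2 = rss / n
        if sigma2 <= 0:
            sigma2 = 1e-300
        ll = (-0.5 * n * (log2pi + 1.0 + np.log(sigma2))
              - 0.5 * float(np.sum(np.log1p(counts[present] * rho))))
        return ll, beta, sigma2, XtX

    ll0 = profile(0.0)[0]
    best_rho = 0.0
    if n_groups > 1:
        res = minimize_scalar(lambda u: -profile(np.exp(u))[0],
                              bounds=(np.log(1e-8), np.log(1e8)),
                              method="bounded",
                              options={"xatol": 1e-8})
        if -res.fun > ll0:
            best_rho = float(np.exp(res.x))

    ll, beta, sigma2, XtX = profile(best_rho)
    singular = best_rho < _SINGULAR_RHO
    if singular:
        best_rho = 0.0
        ll, beta, sigma2, XtX = profile(0.0)

    cov_beta = sigma2 * np.linalg.inv(XtX)
    sigma_resid = float(np.sqrt(sigma2))
    sigma_country = float(np.sqrt(best_rho * sigma2))

    # BLUPs of the group effects: shrunken group-mean residuals
    marg_resid = y - X @ beta
    rbar = np.zeros(n_groups)
    np.add.at(rbar, groups, marg_resid)
    rbar[present] /= counts[present]
    shrink = counts * best_rho / (1.0 + counts * best_rho)
    effects_vec = shrink * rbar
    if group_labels is None:
        group_labels = np.arange(n_groups)
    group_effects = {int(group_labels[g]): float(effects_vec[g])
                     for g in range(n_groups) if present[g]}

    return LMMFit(
        columns=tuple(columns),
        beta=beta,
        cov_beta=cov_beta,
        sigma_country=sigma_country,
        sigma_resid=sigma_resid,
        loglik=float(ll),
        group_effects=group_effects,
        n=n,
        k=p + 2,
        singular=singular,
        _fitted_rho=best_rho,
    )
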
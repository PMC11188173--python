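"""Thin logistic-regression fitting layer shared by form search, stepwise
selection and weight computation.

Fractional-polynomial bases over narrow covariate supports are nearly
collinear, so the raw Newton Hessian can be numerically singular even
though the model is identified.  :func:`fit_logit` therefore standardizes
the non-intercept columns before fitting and maps coefficients and their
covariance back to the original scale.  AIC, fitted probabilities and
joint Wald tests are invariant to this reparametrization; separation
diagnostics use the standardized coefficients (an effect of 15 on the
log-odds *per standard deviation* is far outside anything plausible
here, whatever the column's units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm


class FitError(RuntimeError):
    """A logistic fit failed (non-convergence, singular design, separation)."""


@dataclass
class LogitFit:
    """A fitted logistic regression on the original column scale.

    ``params``/``bse``/``cov`` are original-scale; ``std_params`` and
    ``std_bse`` refer to the internally standardized columns and are the
    right scale for separation heuristics.
    """

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    std_params: np.ndarray
    std_bse: np.ndarray
    std_cov: np.ndarray
    llf: float
    aic: float
    nobs: int

    def cov_params(self) -> np.ndarray:
        return self.cov


def fit_logit(y: np.ndarray, X: np.ndarray, maxiter: int = 100) -> LogitFit:
    """Fit a logistic regression; ``X`` must carry the intercept as its
    first column.  Raises :class:`FitError` on any failure so callers can
    skip a candidate rather than propagate a half-fitted model."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.min() == y.max():
        raise FitError("outcome is constant; no model possible")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    mean[0], scale[0] = 0.0, 1.0  # leave the intercept column alone
    degenerate = scale == 0
    if degenerate.any():
        raise FitError("design contains a constant non-intercept column")
    Z = (X - mean) / scale

    res = None
    last_error = "fit failed"
    # Newton is fastest when it works; undamped steps can oscillate on
    # ill-conditioned resampled designs, so fall back to line-searched BFGS
    for method, iters in (("newton", maxiter), ("bfgs", 4 * maxiter)):
        try:
            with np.errstate(all="ignore"):
                cand = sm.Logit(y, Z).fit(disp=0, maxiter=iters,
                                          method=method, tol=1e-8)
        except Exception as exc:  # singular matrix, separation blow-ups, ...
            last_error = str(exc)
            continue
        if not cand.mle_retvals.get("converged", False):
            last_error = f"{method} iterations did not converge"
            continue
        if not (np.all(np.isfinite(cand.params))
                and np.all(np.isfinite(cand.bse))):
            last_error = "non-finite coefficients or standard errors"
            continue
        res = cand
        break
    if res is None:
        raise FitError(last_error)

    # back-transform: beta = A @ beta_std with A mapping standardized to
    # original coordinates
    k = X.shape[1]
    A = np.diag(1.0 / scale)
    A[0, :] = -mean / scale
    A[0, 0] = 1.0
    params = A @ res.params
    std_cov = np.asarray(res.cov_params())
    cov = A @ std_cov @ A.T
    return LogitFit(
        params=params,
        bse=np.sqrt(np.diag(cov)),
        cov=cov,
        std_params=np.asarray(res.params),
        std_bse=np.asarray(res.bse),
        std_cov=std_cov,
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
    )


def wald_block_p(res: LogitFit, idx: np.ndarray) -> float:
    """Joint Wald chi-square p-value for the coefficient block ``idx``
    (computed in standardized coordinates, where it is best conditioned;
    the test is invariant to per-column affine rescaling)."""
    idx = np.asarray(idx, dtype=int)
    beta = res.std_params[idx]
    cov = res.std_cov[np.ix_(idx, idx)]
    try:
        stat = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        return 1.0
    if stat < 0:  # numerically indefinite covariance
        return 1.0
    return float(stats.chi2.sf(stat, len(idx)))


def c_statistic(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance statistic (AUC): probability a random case is assigned a
    higher fitted probability than a random non-case, ties counting 0.5."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("C-statistic needs at least one case and one non-case")
    ranks = stats.rankdata(p)  # midranks handle ties as 0.5
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
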
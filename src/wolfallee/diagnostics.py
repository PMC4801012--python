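"""MCMC convergence diagnostics: Gelman–Rubin R-hat and multivariate R-hat.

Implements the classic (non-rank-normalized) potential scale reduction
factor with its sampling-theory upper 97.5% limit, and the Brooks–Gelman
multivariate factor R-hat_p.  Convergence for a fit is declared when the
upper confidence limits of every univariate R-hat and of R-hat_p are all
below a threshold (1.1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["gelman_rubin", "multivariate_psrf", "ConvergenceReport", "diagnose"]


def gelman_rubin(chains: np.ndarray) -> tuple[float, float]:
    """Classic Gelman–Rubin PSRF and its upper 97.5% limit.

    Parameters
    ----------
    chains
        Array of shape (m_chains, n_draws) for one scalar parameter.

    Returns
    -------
    (psrf, upper) — point estimate and upper 97.5% confidence limit.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    m, n = x.shape
    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    w = s2.mean()
    b = n * xbar.var(ddof=1)  # between-chain variance estimate (times n)
    muhat = xbar.mean()
    if w <= 0:
        # all chains constant: degenerate, treat as converged
        return 1.0, 1.0
    var_w = s2.var(ddof=1) / m
    var_b = (2.0 * b**2) / (m - 1)
    cov_wb = (n / m) * (
        _cov(s2, xbar**2) - 2.0 * muhat * _cov(s2, xbar)
    )
    sig2hat = (n - 1) / n * w + b / n
    vhat = sig2hat + b / (m * n)
    var_v = (
        ((n - 1) ** 2) * var_w
        + ((1 + 1 / m) ** 2) * var_b
        + 2 * (n - 1) * (1 + 1 / m) * cov_wb
    ) / n**2
    if var_v <= 0:
        df_v = np.inf
        df_adj = 1.0
    else:
        df_v = 2 * vhat**2 / var_v
        df_adj = (df_v + 3) / (df_v + 1)
    psrf2 = df_adj * vhat / w
    r2_fixed = (n - 1) / n
    r2_random = (1 + 1 / m) * (1 / n) * (b / w)
    if var_w <= 0:
        upper2 = df_adj * (r2_fixed + r2_random)
    else:
        df_w = 2 * w**2 * m / var_w
        q = stats.f.ppf(0.975, m - 1, df_w)
        upper2 = df_adj * (r2_fixed + q * r2_random)
    return float(np.sqrt(max(psrf2, 0.0))), float(np.sqrt(max(upper2, 0.0)))


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1])


def multivariate_psrf(chains: np.ndarray) -> float:
    """Brooks–Gelman multivariate PSRF (R-hat_p).

    Parameters
    ----------
    chains
        Array of shape (m_chains, n_draws, p_params).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need (m, n, p) array with m >= 2")
    m, n, p = x.shape
    xbar = x.mean(axis=1)  # (m, p)
    w = np.zeros((p, p))
    for j in range(m):
        d = x[j] - xbar[j]
        w += d.T @ d / (n - 1)
    w /= m
    gbar = xbar.mean(axis=0)
    db = xbar - gbar
    b_over_n = db.T @ db / (m - 1)  # B/n
    # largest eigenvalue of W^{-1} B/n
    try:
        lam = float(np.max(np.real(
            np.linalg.eigvals(np.linalg.solve(w, b_over_n))
        )))
    except np.linalg.LinAlgError:
        lam = 0.0
    return float(np.sqrt((n - 1) / n + (m + 1) / m * max(lam, 0.0)))


@dataclass(frozen=True)
class ConvergenceReport:
    parameter_names: list
    psrf: np.ndarray
    psrf_upper: np.ndarray
    mpsrf: float
    threshold: float
    converged: bool
    complete: bool = True

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "converged": bool(self.converged),
            "complete": bool(self.complete),
            "mpsrf": self.mpsrf,
            "psrf": {
                name: {"point": float(p), "upper": float(u)}
                for name, p, u in zip(
                    self.parameter_names, self.psrf, self.psrf_upper
                )
            },
        }


def diagnose(
    chains: np.ndarray,
    parameter_names: list | None = None,
    threshold: float = 1.1,
) -> ConvergenceReport:
    """Full convergence report over an (m, n, p) array of draws.

    ``converged`` is True iff the upper 97.5% limits of all univariate
    R-hats and the multivariate R-hat_p are below ``threshold``.  With a
    single chain the diagnostics are undefined and the report is marked
    incomplete (converged=False).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 3:
        raise ValueError("chains must be (m, n, p)")
    m, n, p = x.shape
    if parameter_names is None:
        parameter_names = [f"param[{i}]" for i in range(p)]
    if m < 2:
        nanv = np.full(p, np.nan)
        return ConvergenceReport(
            parameter_names, nanv, nanv, float("nan"), threshold,
            converged=False, complete=False,
        )
    psrf = np.empty(p)
    upper = np.empty(p)
    for i in range(p):
        psrf[i], upper[i] = gelman_rubin(x[:, :, i])
    # drop constant parameters from the multivariate statistic
    keep = x.reshape(m * n, p).std(axis=0) > 0
    mp = multivariate_psrf(x[:, :, keep]) if keep.sum() >= 2 else 1.0
    converged = bool(np.all(upper < threshold) and mp < threshold)
    return ConvergenceReport(
        list(parameter_names), psrf, upper, mp, threshold, converged
    )
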
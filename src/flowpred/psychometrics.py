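"""Cumulative-Gaussian psychometric fitting (PSE and JND).

For each participant x ball speed x motion profile, the two staircases'
2IFC responses are pooled and P(comparison judged faster) is modelled as
Phi((level - mu) / sigma).  The fitted mean is the point of subjective
equality (PSE) and the fitted SD is the just-noticeable difference (JND):
the fitted curve evaluated at PSE + 1 JND is 84.1%.

Fitting maximises the Bernoulli log-likelihood directly (no lapse or guess
parameters) with bounded L-BFGS-B from several deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["PsychFit", "fit_cum_gaussian", "fit_psychometric_table", "cum_gaussian_loglik"]

_P_CLIP = 1e-10


@dataclass(frozen=True)
class PsychFit:
    pse: float  # mu of the cumulative Gaussian, m/s
    jnd: float  # sigma, m/s
    loglik: float
    converged: bool
    n_trials: int = 0

    def predict(self, level: float | np.ndarray) -> np.ndarray:
        """P(comparison judged faster) at the given comparison level(s)."""
        return norm.cdf((np.asarray(level, dtype=float) - self.pse) / self.jnd)


def cum_gaussian_loglik(
    mu: float, sigma: float, levels: np.ndarray, responses: np.ndarray
) -> float:
    """Bernoulli log-likelihood of (mu, sigma) for pooled 2IFC data."""
    p = norm.cdf((levels - mu) / sigma)
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return float(np.sum(np.where(responses, np.log(p), np.log1p(-p))))


def _nll_and_grad(theta, levels, responses):
    """Negative log-likelihood and its analytic gradient in (mu, sigma)."""
    mu, sigma = theta
    z = (levels - mu) / sigma
    p = np.clip(norm.cdf(z), _P_CLIP, 1 - _P_CLIP)
    nll = -np.sum(np.where(responses, np.log(p), np.log1p(-p)))
    phi = norm.pdf(z)
    # d loglik / d z elementwise, then chain rule for mu and sigma
    dz = np.where(responses, phi / p, -phi / (1.0 - p))
    return float(nll), np.array([np.sum(dz) / sigma, np.sum(dz * z) / sigma])


def _probit_start(levels: np.ndarray, responses: np.ndarray) -> tuple[float, float]:
    """Crude start from a probit line through the binned response rates."""
    uniq, inv = np.unique(levels, return_inverse=True)
    k = np.bincount(inv, weights=responses.astype(float))
    n = np.bincount(inv)
    rate = np.clip((k + 0.5) / (n + 1.0), 0.02, 0.98)
    z = norm.ppf(rate)
    if len(uniq) >= 2 and np.ptp(uniq) > 0:
        slope, intercept = np.polyfit(uniq, z, 1)
        if slope > 1e-6:
            return float(-intercept / slope), float(1.0 / slope)
    return float(np.mean(levels)), float(np.std(levels) or 1.0)


def fit_cum_gaussian(
    levels: np.ndarray,
    responses: np.ndarray,
    sigma_bounds: tuple[float, float] | None = None,
    n_starts: int = 5,
) -> PsychFit:
    """Maximum-likelihood cumulative-Gaussian fit of 2IFC data.

    Parameters
    ----------
    levels, responses:
        Comparison levels (m/s) and booleans "comparison judged faster",
        pooled over the condition's two staircases.
    sigma_bounds:
        Bounds on the JND; defaults to [1e-3, 3 * max level].
    n_starts:
        Number of deterministic starts (spread over the level quantiles).

    All-identical responses or fewer than two distinct levels cannot pin
    down both parameters; the fit is returned with ``converged=False`` and
    should be excluded downstream.
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=bool)
    if levels.shape != responses.shape:
        raise ValueError("levels and responses must have the same length")
    n = len(levels)
    degenerate = n < 2 or np.unique(levels).size < 2 or responses.all() or (~responses).all()

    lo = sigma_bounds[0] if sigma_bounds else 1e-3
    hi = sigma_bounds[1] if sigma_bounds else 3.0 * float(np.max(levels, initial=1.0))
    span = max(float(levels.std()), 1e-2) if n else 1.0

    mu0, sigma0 = _probit_start(levels, responses)
    sigma0 = float(np.clip(sigma0, lo, hi))
    q = np.quantile(levels, np.linspace(0.25, 0.75, max(n_starts - 1, 1)))
    starts = [(mu0, sigma0)] + [
        (float(qi), float(np.clip(s * span, lo, hi)))
        for qi, s in zip(q, (1.0, 0.5, 1.5, 0.25))
    ][: max(n_starts - 1, 0)]

    best = None
    mu_lo, mu_hi = float(levels.min()) - 3 * span, float(levels.max()) + 3 * span
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            x0,
            args=(levels, responses),
            jac=True,
            method="L-BFGS-B",
            bounds=[(mu_lo, mu_hi), (lo, hi)],
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    mu, sigma = float(best.x[0]), float(best.x[1])
    return PsychFit(
        pse=mu,
        jnd=sigma,
        loglik=-float(best.fun),
        converged=bool(best.success) and not degenerate,
        n_trials=n,
    )


def fit_psychometric_table(speed_trials: pd.DataFrame, n_starts: int = 5) -> pd.DataFrame:
    """Fit one psychometric function per participant x ball speed x profile.

    ``speed_trials`` is a 2IFC trial log with columns ``participant``,
    ``ball_speed``, ``profile``, ``cloud_speed`` and ``chose_cloud_faster``
    (both staircases of a condition are pooled).  Returns a tidy table with
    ``pse``, ``jnd``, ``loglik``, ``converged`` and ``n_trials``.
    """
    rows = []
    for (pid, v, prof), grp in speed_trials.groupby(
        ["participant", "ball_speed", "profile"], sort=True, observed=True
    ):
        fit = fit_cum_gaussian(
            grp["cloud_speed"].to_numpy(),
            grp["chose_cloud_faster"].to_numpy(),
            sigma_bounds=(1e-3, 3.0 * float(v)),
            n_starts=n_starts,
        )
        rows.append((pid, v, prof, fit.pse, fit.jnd, fit.loglik, fit.converged, fit.n_trials))
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "ball_speed",
            "profile",
            "pse",
            "jnd",
            "loglik",
            "converged",
            "n_trials",
        ],
    )
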
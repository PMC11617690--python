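"""Peaks-over-threshold modelling of the lower tail of a proximity indicator.

The proximity between two road users (minimum distance, metres) has a
multi-modal body, but its lower tail — the near interactions — is monotone and
can be approximated by a Generalized Pareto distribution (GPD) after a
decreasing transform.  The simplest such transform is negation: with
``x_tilde = -x`` the lower tail of proximity becomes the upper tail of the
negated variable, and excesses of ``x_tilde`` over a high threshold
``u = -d0`` follow

    H(x_tilde) = 1 - (1 + gamma * (x_tilde - u) / sigma)^(-1/gamma),

with the exponential limit ``1 - exp(-(x_tilde - u)/sigma)`` as gamma -> 0.
A negative shape ``gamma`` bounds the support at ``u - sigma/gamma``; when that
endpoint exceeds 0 on the negated scale, the event "proximity <= 0" (a
collision) lies inside the extrapolated support even though it was never
observed.

This module provides the GPD itself (CDF, quantile, maximum-likelihood fit),
threshold-selection diagnostics (mean residual life, parameter stability), and
the conditional tail CDF of proximity given a near interaction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    FitError,
    InsufficientDataError,
    NumericalError,
    ParameterDomainError,
)

__all__ = [
    "GPDParams",
    "ThresholdDiagnostics",
    "negate",
    "gpd_cdf",
    "gpd_pdf",
    "gpd_quantile",
    "fit_gpd",
    "mean_residual_life",
    "parameter_stability",
    "tail_cdf_proximity",
    "read_proximity_csv",
]

# Shape below which |gamma| is treated as exactly zero (exponential branch).
_GAMMA_EPS = 1e-9
# Normal quantile for the default 95% diagnostic intervals.
_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class GPDParams:
    """Fitted (or specified) Generalized Pareto tail on the negated scale.

    ``threshold_u`` is on the negated-proximity scale, i.e. ``u = -d0`` where
    ``d0`` is the proximity threshold in metres.
    """

    threshold_u: float
    scale_sigma: float
    shape_gamma: float
    n_exceed: int | None = None
    loglik: float | None = None
    se_sigma: float | None = None
    se_gamma: float | None = None
    shape_unstable: bool = False  # gamma_hat <= -0.5: MLE regularity fails

    def __post_init__(self) -> None:
        if not self.scale_sigma > 0:
            raise ParameterDomainError(
                f"GPD scale must be positive, got {self.scale_sigma}"
            )
        if self.n_exceed is not None and self.n_exceed < 2:
            raise ParameterDomainError("n_exceed must be at least 2")

    @property
    def endpoint(self) -> float:
        """Upper support endpoint on the negated scale (inf if gamma >= 0)."""
        if self.shape_gamma < -_GAMMA_EPS:
            return self.threshold_u - self.scale_sigma / self.shape_gamma
        return np.inf

    @property
    def d0(self) -> float:
        """Proximity threshold in metres (positive)."""
        return -self.threshold_u

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GPDParams":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class ThresholdDiagnostics:
    """Threshold-selection diagnostics over a candidate grid.

    Mean-residual-life part: ``mean_excess`` with normal-approximation CIs.
    Stability part: shape estimates ``gamma_hat`` and modified scale
    ``sigma_star = sigma_hat - gamma_hat * u`` (threshold-invariant under a
    correct GPD model), with delta-method CIs.  Entries are NaN where a grid
    threshold leaves no (or too few) exceedances.
    """

    grid: np.ndarray
    n_exceed: np.ndarray
    mean_excess: np.ndarray | None = None
    mean_excess_ci: np.ndarray | None = None  # (len(grid), 2)
    gamma_hat: np.ndarray | None = None
    gamma_ci: np.ndarray | None = None
    sigma_star: np.ndarray | None = None
    sigma_star_ci: np.ndarray | None = None
    fits: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per (threshold, quantity)."""
        rows = []
        for name, est, ci in (
            ("mean_excess", self.mean_excess, self.mean_excess_ci),
            ("gamma", self.gamma_hat, self.gamma_ci),
            ("sigma_star", self.sigma_star, self.sigma_star_ci),
        ):
            if est is None:
                continue
            for i, u in enumerate(self.grid):
                rows.append(
                    {
                        "threshold": float(u),
                        "quantity": name,
                        "estimate": float(est[i]),
                        "lo": float(ci[i, 0]),
                        "hi": float(ci[i, 1]),
                        "n_exceed": int(self.n_exceed[i]),
                    }
                )
        return pd.DataFrame(rows)


def negate(values: Sequence[float]) -> np.ndarray:
    """Decreasing transform of a margin by negation (an involution)."""
    return -np.asarray(values, dtype=float)


def _check_params(params: GPDParams) -> None:
    if not params.scale_sigma > 0:
        raise ParameterDomainError("GPD scale must be positive")


def gpd_cdf(params: GPDParams, x) -> np.ndarray | float:
    """GPD CDF H(x) of threshold excesses, on the negated-proximity scale.

    Below the threshold the value is 0 by convention: the object models
    exceedances only, and callers needing the unconditional scale multiply by
    the exceedance fraction P(Omega0).
    """
    _check_params(params)
    x = np.asarray(x, dtype=float)
    z = (x - params.threshold_u) / params.scale_sigma
    g = params.shape_gamma
    with np.errstate(invalid="ignore", divide="ignore"):
        if abs(g) < _GAMMA_EPS:
            h = 1.0 - np.exp(-z)
        else:
            arg = 1.0 + g * z
            h = np.where(arg > 0, 1.0 - np.maximum(arg, 0.0) ** (-1.0 / g), 1.0)
    h = np.where(z < 0, 0.0, h)
    # gamma > 0 with arg <= 0 cannot occur for z >= 0; gamma < 0 beyond the
    # endpoint yields 1 via the np.where above.
    return h if h.ndim else float(h)


def gpd_pdf(params: GPDParams, x) -> np.ndarray | float:
    """GPD density; zero below the threshold and beyond a finite endpoint."""
    _check_params(params)
    x = np.asarray(x, dtype=float)
    s, g = params.scale_sigma, params.shape_gamma
    z = (x - params.threshold_u) / s
    with np.errstate(invalid="ignore"):
        if abs(g) < _GAMMA_EPS:
            d = np.exp(-z) / s
        else:
            arg = 1.0 + g * z
            d = np.where(arg > 0, np.maximum(arg, 1e-300) ** (-1.0 / g - 1.0) / s, 0.0)
    d = np.where(z < 0, 0.0, d)
    return d if d.ndim else float(d)


def gpd_quantile(params: GPDParams, p) -> np.ndarray | float:
    """Inverse of :func:`gpd_cdf` on [0, 1) (p=1 allowed iff gamma < 0)."""
    _check_params(params)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise NumericalError("quantile level must be in [0, 1]")
    g = params.shape_gamma
    if np.any(p == 1) and g >= -_GAMMA_EPS:
        raise NumericalError("p=1 only attainable for a bounded tail (gamma < 0)")
    with np.errstate(divide="ignore"):
        if abs(g) < _GAMMA_EPS:
            q = params.threshold_u - params.scale_sigma * np.log1p(-p)
        else:
            q = params.threshold_u + params.scale_sigma / g * ((1.0 - p) ** (-g) - 1.0)
    return q if q.ndim else float(q)


def _pwm_start(excesses: np.ndarray) -> tuple[float, float]:
    """Probability-weighted-moment starting values (Hosking & Wallis)."""
    x = np.sort(excesses)
    n = x.size
    b0 = x.mean()
    # a1 estimates E[X (1 - F(X))]: descending weights on the ascending sort
    j = np.arange(n)
    b1 = np.sum((n - 1 - j) / (n - 1) * x) / n
    denom = b0 - 2.0 * b1
    if denom <= 0:
        return float(b0), 0.1
    sigma = 2.0 * b0 * b1 / denom
    gamma = 2.0 - b0 / denom
    # PWM is derived for gamma < 1; clamp to the optimizer box.
    return float(max(sigma, 1e-8)), float(np.clip(gamma, -0.95, 5.0))


def _gpd_nll(log_sigma: float, gamma: float, excesses: np.ndarray) -> float:
    sigma = np.exp(log_sigma)
    if abs(gamma) < _GAMMA_EPS:
        return excesses.size * log_sigma + excesses.sum() / sigma
    arg = 1.0 + gamma * excesses / sigma
    if np.any(arg <= 0):
        return np.inf
    return excesses.size * log_sigma + (1.0 + 1.0 / gamma) * np.sum(np.log(arg))


def fit_gpd(
    values: Sequence[float],
    threshold: float,
    min_exceed: int = 10,
) -> GPDParams:
    """Maximum-likelihood GPD fit to excesses of ``values`` over ``threshold``.

    Optimizes the profile in ``(log sigma, gamma)`` with a box-constrained
    quasi-Newton method started from probability-weighted moments — robust for
    shapes near -0.5, where plain ML is known to be unstable.  Standard errors
    come from the observed information and are reported only when
    ``gamma_hat > -0.5`` (the regular regime); below that the fit carries a
    ``shape_unstable`` flag and a warning, since extrapolation from such a
    tail is unreliable.
    """
    values = np.asarray(values, dtype=float)
    exc = values[values > threshold] - threshold
    if exc.size < min_exceed:
        raise InsufficientDataError(
            f"{exc.size} exceedances above {threshold}; need at least {min_exceed}"
        )
    if np.ptp(exc) == 0:
        raise FitError("all exceedances equal; GPD fit is degenerate")

    sigma0, gamma0 = _pwm_start(exc)
    # project the start into the feasible region: for gamma < 0 the support
    # endpoint sigma/|gamma| must exceed the largest excess
    if gamma0 < 0 and sigma0 / -gamma0 <= exc.max():
        gamma0 = -0.9 * sigma0 / exc.max()

    def nll_vec(p):
        if not (-20.0 <= p[0] <= 20.0 and -0.999 <= p[1] <= 10.0):
            return np.inf
        return _gpd_nll(p[0], p[1], exc)

    # Nelder-Mead copes with the hard feasibility barrier (1 + gamma*z/sigma
    # > 0), where gradient-based steps stall on infinite trial values.
    opts = {"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000}
    res = optimize.minimize(
        nll_vec,
        x0=np.array([np.log(sigma0), gamma0]),
        method="Nelder-Mead",
        options=opts,
    )
    if not res.success or not np.isfinite(res.fun):
        # restart from the (always feasible) exponential-model point
        res = optimize.minimize(
            nll_vec,
            x0=np.array([np.log(exc.mean()), 0.0]),
            method="Nelder-Mead",
            options=opts,
        )
    if not res.success or not np.isfinite(res.fun):
        raise FitError(f"GPD optimizer did not converge: {res.message}")
    sigma_hat = float(np.exp(res.x[0]))
    gamma_hat = float(res.x[1])

    se_sigma = se_gamma = None
    if gamma_hat > -0.5:
        se_sigma, se_gamma = _gpd_se(sigma_hat, gamma_hat, exc)

    unstable = gamma_hat <= -0.5
    if unstable:
        warnings.warn(
            "fitted GPD shape <= -0.5: the MLE is irregular and extrapolated "
            "extreme events should not be used as a basis for conditioning",
            RuntimeWarning,
            stacklevel=2,
        )
    return GPDParams(
        threshold_u=float(threshold),
        scale_sigma=sigma_hat,
        shape_gamma=gamma_hat,
        n_exceed=int(exc.size),
        loglik=float(-res.fun),
        se_sigma=se_sigma,
        se_gamma=se_gamma,
        shape_unstable=unstable,
    )


def _gpd_obs_info(sigma: float, gamma: float, exc: np.ndarray) -> np.ndarray:
    """Observed information in (sigma, gamma) by central finite differences."""

    def nll(p):
        return _gpd_nll(np.log(p[0]), p[1], exc)

    h = np.array([max(1e-5 * sigma, 1e-8), 1e-5])
    H = np.empty((2, 2))
    p0 = np.array([sigma, gamma])
    f0 = nll(p0)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            if i == j:
                H[i, i] = (nll(p0 + ei) - 2 * f0 + nll(p0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(p0 + ei + ej)
                    - nll(p0 + ei - ej)
                    - nll(p0 - ei + ej)
                    + nll(p0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _gpd_se(
    sigma: float, gamma: float, exc: np.ndarray
) -> tuple[float | None, float | None]:
    H = _gpd_obs_info(sigma, gamma, exc)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, None
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return None, None
    return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


def mean_residual_life(
    values: Sequence[float],
    grid: Sequence[float],
    ci_level: float = 0.95,
) -> ThresholdDiagnostics:
    """Mean-excess estimates over a threshold grid.

    Under a correct GPD model with shape < 1 the mean excess is linear in the
    threshold, so the practitioner picks the largest threshold from which the
    plot is (approximately) linear.  Thresholds above the sample maximum yield
    NaN entries rather than an exception.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterDomainError("threshold grid must be strictly increasing")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    me = np.full(grid.size, np.nan)
    ci = np.full((grid.size, 2), np.nan)
    n_exc = np.zeros(grid.size, dtype=int)
    for i, u in enumerate(grid):
        exc = values[values > u] - u
        n_exc[i] = exc.size
        if exc.size == 0:
            continue
        me[i] = exc.mean()
        half = z * exc.std(ddof=1) / np.sqrt(exc.size) if exc.size > 1 else np.nan
        ci[i] = (me[i] - half, me[i] + half)
    return ThresholdDiagnostics(grid=grid, n_exceed=n_exc, mean_excess=me, mean_excess_ci=ci)


def parameter_stability(
    values: Sequence[float],
    grid: Sequence[float],
    min_exceed: int = 10,
    ci_level: float = 0.95,
) -> ThresholdDiagnostics:
    """GPD shape and modified-scale estimates over a threshold grid.

    The modified scale ``sigma* = sigma_hat - gamma_hat * u`` is invariant to
    the threshold under a correct GPD model, so flat curves (within CI)
    support the chosen threshold.  CIs use the delta method with the observed
    information; they are NaN where the shape estimate is irregular.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterDomainError("threshold grid must be strictly increasing")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    gam = np.full(grid.size, np.nan)
    gam_ci = np.full((grid.size, 2), np.nan)
    sstar = np.full(grid.size, np.nan)
    sstar_ci = np.full((grid.size, 2), np.nan)
    n_exc = np.zeros(grid.size, dtype=int)
    fits: list[GPDParams | None] = []
    for i, u in enumerate(grid):
        exc_n = int(np.sum(values > u))
        n_exc[i] = exc_n
        if exc_n < min_exceed:
            fits.append(None)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gpd(values, u, min_exceed=min_exceed)
        fits.append(fit)
        gam[i] = fit.shape_gamma
        sstar[i] = fit.scale_sigma - fit.shape_gamma * u
        if fit.se_sigma is not None and fit.se_gamma is not None:
            exc = values[values > u] - u
            H = _gpd_obs_info(fit.scale_sigma, fit.shape_gamma, exc)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                continue
            gam_ci[i] = (gam[i] - z * np.sqrt(cov[1, 1]), gam[i] + z * np.sqrt(cov[1, 1]))
            # var(sigma - gamma*u) by the delta method
            var_ss = cov[0, 0] + u * u * cov[1, 1] - 2 * u * cov[0, 1]
            if var_ss > 0:
                half = z * np.sqrt(var_ss)
                sstar_ci[i] = (sstar[i] - half, sstar[i] + half)
    return ThresholdDiagnostics(
        grid=grid,
        n_exceed=n_exc,
        gamma_hat=gam,
        gamma_ci=gam_ci,
        sigma_star=sstar,
        sigma_star_ci=sstar_ci,
        fits=fits,
    )


def tail_cdf_proximity(params: GPDParams, x) -> np.ndarray | float:
    """Conditional CDF of proximity given a near interaction.

    Computes P(X <= x | X < d0) on the original proximity scale, where
    ``d0 = -params.threshold_u``: the lower tail of proximity maps to the
    upper tail of the negated variable, so the value is the GPD survival
    function at ``-x``, i.e. ``1 - H(-x)``.  At ``x = d0`` this is 1; it is
    strictly positive down to the support endpoint (which can lie below 0 for
    gamma < 0, putting the never-observed collision event inside the model's
    support).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x > -params.threshold_u + 1e-12):
        raise NumericalError(
            "x above the proximity threshold d0: outside the modelled near-interaction region"
        )
    out = 1.0 - np.asarray(gpd_cdf(params, -x))
    return out if out.ndim else float(out)


def read_proximity_csv(path, column: str | None = None) -> np.ndarray:
    """Read proximity values from a one-column or named-column CSV."""
    df = pd.read_csv(path)
    if column is None:
        column = "md" if "md" in df.columns else df.columns[0]
    return df[column].to_numpy(dtype=float)


def diagnostics_to_json(diag: ThresholdDiagnostics) -> str:
    return json.dumps(diag.to_frame().to_dict(orient="records"), indent=1)
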
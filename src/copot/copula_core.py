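"""Copula families, pseudo-observations, and rank-based estimation.

Three single-parameter families cover the dependence shapes of interest for
(proximity, severity) pairs: Gumbel (upper-tail dependence), Clayton
(lower-tail dependence) and Gaussian (symmetric).  Estimation is primarily by
Kendall-tau inversion — the closed-form map tau = g(theta) is inverted at the
tie-corrected sample tau — with maximum likelihood on pseudo-observations
available as a refinement.  Rotation (180-degree survival rotation) and
single-margin flips implement the identities needed when a margin has been
transformed decreasingly.

Parameter domains:
    gumbel   theta in [1, inf)    tau = 1 - 1/theta        (tau >= 0)
    clayton  theta in (0, inf)    tau = theta/(theta + 2)  (tau > 0)
    gaussian rho   in [-1, 1]     tau = (2/pi) arcsin(rho)
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import roots_legendre

from .evt_margin import GPDParams, gpd_cdf
from .exceptions import (
    DataError,
    FitError,
    InsufficientDataError,
    ParameterDomainError,
    UnsupportedDependenceError,
)

__all__ = [
    "FAMILIES",
    "CopulaModel",
    "PseudoObservations",
    "RotatedCopula",
    "FlippedVCopula",
    "copula_cdf",
    "copula_pdf",
    "pseudo_observations",
    "empirical_copula",
    "sample_kendall_tau",
    "tau_from_param",
    "param_from_tau",
    "rotate_copula",
    "flip_v",
    "simulate_copula",
    "fit_tau",
    "fit_ml",
    "bvn_cdf",
]

FAMILIES = ("gumbel", "clayton", "gaussian")

_DOMAINS = {
    "gumbel": (1.0, np.inf, "[1, inf)"),
    "clayton": (0.0, np.inf, "(0, inf)"),
    "gaussian": (-1.0, 1.0, "[-1, 1]"),
}

# 64-node Gauss-Legendre rule for the Drezner single-integral reduction of the
# bivariate normal CDF; fixed order gives ~1e-14 accuracy for |rho| <= 0.999.
_GL_NODES, _GL_WEIGHTS = roots_legendre(64)


def _check_param(family: str, param: float) -> None:
    if family not in _DOMAINS:
        raise ParameterDomainError(f"unknown copula family {family!r}")
    lo, hi, desc = _DOMAINS[family]
    ok = (param >= lo if family != "clayton" else param > lo) and param <= hi
    if not ok:
        raise ParameterDomainError(f"{family} parameter {param} outside {desc}")


@dataclass(frozen=True)
class CopulaModel:
    """A one-parameter copula: family tag plus parameter in its domain."""

    family: str
    param: float

    def __post_init__(self) -> None:
        _check_param(self.family, self.param)

    def cdf(self, u, v):
        return copula_cdf(self, u, v)

    def pdf(self, u, v):
        return copula_pdf(self, u, v)

    @property
    def tau(self) -> float:
        return tau_from_param(self.family, self.param)

    def to_dict(self) -> dict:
        return {"family": self.family, "param": self.param, "tau": self.tau}


@dataclass(frozen=True)
class PseudoObservations:
    """Pairs (u_i, v_i) strictly inside the unit square, with provenance."""

    u: np.ndarray
    v: np.ndarray
    margin_x: str = "empirical-rank"  # or "parametric-gp"
    margin_y: str = "empirical-rank"

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        if u.shape != v.shape:
            raise DataError("u and v must have the same length")
        if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
            raise DataError("pseudo-observations must lie strictly inside (0,1)")

    def __len__(self) -> int:
        return self.u.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"u": self.u, "v": self.v})


# ---------------------------------------------------------------------------
# CDFs and densities


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(Z1 <= h, Z2 <= k) with correlation rho.

    Drezner-style reduction to a single integral over the correlation,
    evaluated with a fixed-order Gauss-Legendre rule:

        Phi2(h,k;rho) = Phi(h)Phi(k)
                        + (1/2pi) * int_0^rho phi2(h,k;r) dr.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base
    # map nodes from [-1,1] to [0, rho]
    r = 0.5 * rho * (_GL_NODES + 1.0)
    w = 0.5 * abs(rho) * _GL_WEIGHTS * np.sign(rho)
    hh = h[..., None]
    kk = k[..., None]
    omr2 = 1.0 - r**2
    dens = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * omr2)) / np.sqrt(omr2)
    corr = np.sum(w * dens, axis=-1) / (2.0 * np.pi)
    out = base + corr
    return out


def copula_cdf(model, u, v):
    """Copula CDF C(u, v); accepts scalars or arrays on [0, 1]^2."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1) | (v < 0) | (v > 1)):
        raise ParameterDomainError("copula arguments must lie in [0, 1]")
    fam, th = model.family, model.param
    _check_param(fam, th)
    # interior formula, with boundary handling applied afterwards
    ui = np.clip(u, 1e-300, 1.0)
    vi = np.clip(v, 1e-300, 1.0)
    if fam == "gumbel":
        if th == 1.0:
            c = ui * vi
        else:
            s = (-np.log(ui)) ** th + (-np.log(vi)) ** th
            c = np.exp(-(s ** (1.0 / th)))
    elif fam == "clayton":
        with np.errstate(over="ignore"):  # u -> 0 overflows then collapses to 0
            c = (ui ** (-th) + vi ** (-th) - 1.0) ** (-1.0 / th)
    else:  # gaussian
        if th == 0.0:
            c = ui * vi
        elif th == 1.0:
            c = np.minimum(ui, vi)
        elif th == -1.0:
            c = np.maximum(ui + vi - 1.0, 0.0)
        else:
            # clip away exact 0/1 before the probit: the boundary cases are
            # overwritten below, and +-inf would poison the quadrature
            c = bvn_cdf(
                stats.norm.ppf(np.clip(ui, 1e-16, 1 - 1e-16)),
                stats.norm.ppf(np.clip(vi, 1e-16, 1 - 1e-16)),
                th,
            )
    c = np.where((u == 0) | (v == 0), 0.0, c)
    c = np.where(u == 1, v, c)
    c = np.where(v == 1, np.where(u == 1, 1.0, u), c)
    c = np.clip(c, 0.0, 1.0)
    return c if c.ndim else float(c)


def copula_pdf(model, u, v):
    """Copula density c(u, v) on the open unit square."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise ParameterDomainError("copula density requires arguments in (0, 1)")
    fam, th = model.family, model.param
    _check_param(fam, th)
    if fam == "gumbel":
        if th == 1.0:
            d = np.ones_like(u)
        else:
            lu = -np.log(u)
            lv = -np.log(v)
            s = lu**th + lv**th
            s1t = s ** (1.0 / th)
            C = np.exp(-s1t)
            d = (
                C
                * (lu * lv) ** (th - 1.0)
                / (u * v)
                * s ** (1.0 / th - 2.0)
                * (s1t + th - 1.0)
            )
    elif fam == "clayton":
        d = (
            (1.0 + th)
            * (u * v) ** (-th - 1.0)
            * (u ** (-th) + v ** (-th) - 1.0) ** (-1.0 / th - 2.0)
        )
    else:
        if abs(th) == 1.0:
            raise ParameterDomainError("gaussian density undefined at |rho| = 1")
        z1 = stats.norm.ppf(u)
        z2 = stats.norm.ppf(v)
        omr2 = 1.0 - th**2
        d = np.exp(
            -(th**2 * (z1**2 + z2**2) - 2.0 * th * z1 * z2) / (2.0 * omr2)
        ) / np.sqrt(omr2)
    d = np.asarray(d)
    return d if d.ndim else float(d)


# ---------------------------------------------------------------------------
# Pseudo-observations and empirical quantities


def pseudo_observations(
    x_tail,
    y,
    margin_x: GPDParams | str = "empirical",
    margin_y=None,
) -> PseudoObservations:
    """Map (x_tail, y) pairs to the unit square for copula fitting.

    ``x_tail`` is on the negated-proximity scale.  With a fitted GPD as
    ``margin_x`` the u-coordinates come from the parametric tail CDF; the
    string ``"empirical"`` uses scaled ranks instead.  ``margin_y`` may be
    ``None``/``"empirical"`` (scaled ranks) or any object with a ``cdf``
    method (a scipy frozen distribution, for example).

    Ranks are scaled by (m + 1), with average ranks for ties, so all
    coordinates are strictly interior; parametric coordinates are clamped to
    [0.5/(m+1), 1 - 0.5/(m+1)] for the same reason.
    """
    x_tail = np.asarray(x_tail, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_tail.shape != y.shape:
        raise DataError("x and y must have the same length")
    m = x_tail.size
    eps = 0.5 / (m + 1)

    if isinstance(margin_x, GPDParams):
        if np.any(x_tail < margin_x.threshold_u):
            raise DataError("x values below the GP threshold on the negated scale")
        u = np.clip(np.asarray(gpd_cdf(margin_x, x_tail)), eps, 1 - eps)
        tag_x = "parametric-gp"
    else:
        u = stats.rankdata(x_tail, method="average") / (m + 1)
        tag_x = "empirical-rank"

    if margin_y is None or (isinstance(margin_y, str) and margin_y == "empirical"):
        v = stats.rankdata(y, method="average") / (m + 1)
        tag_y = "empirical-rank"
    else:
        v = np.clip(np.asarray(margin_y.cdf(y), dtype=float), eps, 1 - eps)
        tag_y = "parametric"
    return PseudoObservations(u=u, v=v, margin_x=tag_x, margin_y=tag_y)


def empirical_copula(pobs: PseudoObservations, u, v):
    """Empirical copula C_n(u, v) = mean of I{U_i <= u, V_i <= v}."""
    u, v = np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
    scalar = u.ndim == 0
    uq = np.atleast_1d(u)
    vq = np.atleast_1d(v)
    out = np.mean(
        (pobs.u[None, :] <= uq.reshape(-1, 1)) & (pobs.v[None, :] <= vq.reshape(-1, 1)),
        axis=1,
    ).reshape(uq.shape)
    return float(out[0]) if scalar else out


def sample_kendall_tau(pobs: PseudoObservations) -> float:
    """Tie-corrected sample Kendall tau (tau-b) of the pseudo-observations."""
    if len(pobs) < 2:
        raise InsufficientDataError("Kendall tau requires at least 2 observations")
    return float(stats.kendalltau(pobs.u, pobs.v).statistic)


# ---------------------------------------------------------------------------
# Tau <-> parameter mappings


def tau_from_param(family: str, param: float) -> float:
    """Population Kendall tau g(theta) = 4 E[C(U,V)] - 1, in closed form."""
    _check_param(family, param)
    if family == "gumbel":
        return 1.0 - 1.0 / param
    if family == "clayton":
        return param / (param + 2.0)
    return 2.0 / np.pi * np.arcsin(param)


def param_from_tau(family: str, tau: float) -> float:
    """Invert g: the rank-inversion estimator theta_hat = g^{-1}(tau_hat)."""
    if not -1.0 <= tau <= 1.0:
        raise ParameterDomainError("tau must lie in [-1, 1]")
    if family == "gumbel":
        if tau < 0:
            raise UnsupportedDependenceError(
                "gumbel supports only non-negative tau; apply the decreasing-"
                "transform adjustment (negate the severity margin) first"
            )
        if tau >= 1:
            raise ParameterDomainError("tau = 1 maps to an unbounded gumbel parameter")
        return 1.0 / (1.0 - tau)
    if family == "clayton":
        if tau <= 0:
            raise UnsupportedDependenceError(
                "clayton supports only positive tau; apply the decreasing-"
                "transform adjustment (negate the severity margin) first"
            )
        if tau >= 1:
            raise ParameterDomainError("tau = 1 maps to an unbounded clayton parameter")
        return 2.0 * tau / (1.0 - tau)
    if family == "gaussian":
        return float(np.sin(np.pi * tau / 2.0))
    raise ParameterDomainError(f"unknown copula family {family!r}")


# ---------------------------------------------------------------------------
# Rotations and flips


@dataclass(frozen=True)
class RotatedCopula:
    """180-degree rotation C_rot(u,v) = u + v - 1 + C(1-u, 1-v).

    This is the copula of the pair after decreasing transforms of *both*
    margins; it preserves Kendall tau (rotation preserves concordance).
    """

    base: CopulaModel

    def cdf(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        out = u + v - 1.0 + np.asarray(copula_cdf(self.base, 1.0 - u, 1.0 - v))
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def pdf(self, u, v):
        return copula_pdf(self.base, 1.0 - np.asarray(u), 1.0 - np.asarray(v))


@dataclass(frozen=True)
class FlippedVCopula:
    """Flip of the second margin: C_flip(u,v) = u - C(u, 1-v).

    The copula of (U, 1-V); used to move between a copula fitted on the
    transformed severity and the equivalent direct representation.
    """

    base: CopulaModel

    def cdf(self, u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        out = u - np.asarray(copula_cdf(self.base, u, 1.0 - v))
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def pdf(self, u, v):
        return copula_pdf(self.base, np.asarray(u), 1.0 - np.asarray(v))


def rotate_copula(model: CopulaModel) -> RotatedCopula:
    """Survival (180-degree) rotation of a fitted copula."""
    return RotatedCopula(base=model)


def flip_v(model: CopulaModel) -> FlippedVCopula:
    """Copula of (U, 1-V) for a fitted model."""
    return FlippedVCopula(base=model)


# ---------------------------------------------------------------------------
# Simulation


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_copula(model: CopulaModel, n: int, seed) -> PseudoObservations:
    """Draw n pairs with uniform margins and the model's dependence.

    Exact (rejection-free) samplers: positive-stable frailty for Gumbel,
    gamma frailty for Clayton, correlated normals for Gaussian.
    """
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rng = _as_rng(seed)
    fam, th = model.family, model.param
    if fam == "gumbel":
        if th == 1.0:
            u, v = rng.random(n), rng.random(n)
        else:
            alpha = 1.0 / th
            # Chambers-Mallows-Stuck positive alpha-stable draw
            theta_ang = rng.uniform(0.0, np.pi, n)
            w = rng.standard_exponential(n)
            s = (
                np.sin(alpha * theta_ang)
                / np.sin(theta_ang) ** (1.0 / alpha)
                * (np.sin((1.0 - alpha) * theta_ang) / w) ** ((1.0 - alpha) / alpha)
            )
            e1 = rng.standard_exponential(n)
            e2 = rng.standard_exponential(n)
            u = np.exp(-((e1 / s) ** alpha))
            v = np.exp(-((e2 / s) ** alpha))
    elif fam == "clayton":
        g = rng.gamma(1.0 / th, size=n)
        e1 = rng.standard_exponential(n)
        e2 = rng.standard_exponential(n)
        u = (1.0 + e1 / g) ** (-1.0 / th)
        v = (1.0 + e2 / g) ** (-1.0 / th)
    else:
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        x1 = z1
        x2 = th * z1 + np.sqrt(max(1.0 - th**2, 0.0)) * z2
        u = stats.norm.cdf(x1)
        v = stats.norm.cdf(x2)
    tiny = 1e-15
    u = np.clip(u, tiny, 1 - tiny)
    v = np.clip(v, tiny, 1 - tiny)
    return PseudoObservations(u=u, v=v, margin_x="simulated", margin_y="simulated")


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class CopulaFit:
    model: CopulaModel
    loglik: float | None
    method: str
    tau: float
    boundary: bool = False

    def to_json(self) -> str:
        d = {
            "family": self.model.family,
            "param": self.model.param,
            "tau": self.tau,
            "loglik": self.loglik,
            "method": self.method,
            "boundary": self.boundary,
        }
        return json.dumps(d, indent=1)


def fit_tau(pobs: PseudoObservations, family: str) -> CopulaFit:
    """Rank-inversion fit: theta_hat = g^{-1}(sample tau)."""
    tau = sample_kendall_tau(pobs)
    param = param_from_tau(family, tau)
    model = CopulaModel(family, param)
    return CopulaFit(model=model, loglik=None, method="tau-inversion", tau=tau)


_ML_BOUNDS = {
    "gumbel": (1.0 + 1e-8, 60.0),
    "clayton": (1e-8, 60.0),
    "gaussian": (-0.9999, 0.9999),
}


def fit_ml(pobs: PseudoObservations, family: str) -> CopulaFit:
    """Maximum-likelihood fit on pseudo-observations.

    Started from the tau-inversion estimate (clamped into the domain): copula
    likelihoods can be badly behaved far from the optimum, so a consistent
    starting value matters.  Solutions at the search boundary are flagged.
    """
    if len(pobs) < 10:
        raise InsufficientDataError("ML copula fit requires at least 10 pairs")
    tau = sample_kendall_tau(pobs)
    lo, hi = _ML_BOUNDS[family]
    try:
        start = param_from_tau(family, tau)
    except UnsupportedDependenceError:
        start = lo  # independence-edge start for gumbel/clayton with tau < 0
    start = float(np.clip(start, lo, hi))

    u, v = pobs.u, pobs.v

    def nll(p: float) -> float:
        try:
            d = copula_pdf(CopulaModel(family, float(p)), u, v)
        except ParameterDomainError:
            return np.inf
        d = np.asarray(d)
        if np.any(~np.isfinite(d)) or np.any(d <= 0):
            return np.inf
        return -float(np.sum(np.log(d)))

    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    if not res.success or not np.isfinite(res.fun):
        raise FitError(f"copula ML did not converge for {family}: {res}")
    param = float(res.x)
    boundary = bool(param - lo < 1e-6 * max(1.0, abs(lo)) or hi - param < 1e-6)
    return CopulaFit(
        model=CopulaModel(family, param),
        loglik=float(-res.fun),
        method="ml",
        tau=tau,
        boundary=boundary,
    )
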
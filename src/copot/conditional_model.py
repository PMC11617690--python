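"""Restricted-measure model: margin + copula + exceedance fraction.

The interaction space is partitioned at a proximity threshold ``d0``; the
near-interaction region Omega0 = {X < d0} carries its own probability measure
Q(.) = P(. | Omega0), and all modelling happens there: the transformed
proximity ``X_tilde = -X`` follows the fitted GPD above ``u = -d0``, the
severity Y has margin F2 (empirical or parametric) on Omega0, and a copula C
couples them.  The only computational trace of the measure construction is
the normalizing constant P(Omega0) — the fraction of interactions that are
near interactions — which converts Q-probabilities back to the full space:

    P(X <= x, Y > y) = Q(X <= x, Y > y) * P(Omega0),   x <= d0.

Because the GPD tail can extend beyond every observed proximity (negative
shape with endpoint below 0), the conditional severity law given
{X <= x0} is well defined even for events absent from the data — e.g. the
collision event x0 = 0.

When the sample rank correlation of (X_tilde, Y) is negative, Gumbel and
Clayton cannot represent it; the severity margin is then transformed
decreasingly (negated) and the copula C_T is fitted on the transformed pair.
All probabilities are invariant to this adjustment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .copula_core import (
    CopulaModel,
    PseudoObservations,
    param_from_tau,
    pseudo_observations,
    sample_kendall_tau,
)
from .evt_margin import GPDParams, fit_gpd, gpd_cdf
from .exceptions import (
    ConfigError,
    EmptyRegionError,
    ExtrapolationError,
    OutOfRegionError,
    ParameterDomainError,
)

__all__ = [
    "ACCIDENT_PROXIMITY",
    "EmpiricalMargin",
    "NegatedMargin",
    "RestrictedMeasureModel",
    "p_omega0",
    "joint_prob",
    "conditional_cdf",
    "injury_probability",
    "fit_restricted_model",
    "model_to_json",
    "model_from_json",
]

# Proximity 0 means the two road users' positions coincide: the (extrapolated)
# accident event is {X <= ACCIDENT_PROXIMITY}.
ACCIDENT_PROXIMITY = 0.0


class EmpiricalMargin:
    """Empirical CDF F_n(y) = (1/m) * #{Y_i <= y} on the restricted sample."""

    def __init__(self, values: Sequence[float]):
        v = np.sort(np.asarray(values, dtype=float))
        if v.size < 1:
            raise EmptyRegionError("empirical margin needs at least one value")
        self.values = v

    @property
    def m(self) -> int:
        return self.values.size

    def cdf(self, y):
        y = np.asarray(y, dtype=float)
        out = np.searchsorted(self.values, y, side="right") / self.m
        return out if out.ndim else float(out)

    def cdf_left(self, y):
        """Strict version P(Y < y); differs from cdf only at atoms."""
        y = np.asarray(y, dtype=float)
        out = np.searchsorted(self.values, y, side="left") / self.m
        return out if out.ndim else float(out)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        idx = np.clip(np.ceil(q * self.m).astype(int) - 1, 0, self.m - 1)
        out = self.values[idx]
        return out if out.ndim else float(out)


class NegatedMargin:
    """Margin of -Y given the margin of Y (a continuous decreasing transform).

    ``cdf(t) = P(-Y <= t) = P(Y >= -t)``, via the base survival function.
    """

    def __init__(self, base):
        self.base = base

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.asarray(self.base.sf(-t))
        return out if out.ndim else float(out)

    cdf_left = cdf  # continuous base: no atoms

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = -np.asarray(self.base.ppf(1.0 - q))
        return out if out.ndim else float(out)


@dataclass
class RestrictedMeasureModel:
    """Assembled model on the near-interaction region.

    ``severity_margin`` is the margin actually coupled by ``copula``: F2 of Y
    when ``y_transformed`` is False, or F_T2 of -Y when True (the
    negative-dependence adjustment).  ``copula`` is any object with a
    ``cdf(u, v)`` method on the unit square.
    """

    gpd: GPDParams
    severity_margin: object
    copula: object
    p_omega0: float
    y_transformed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_omega0 <= 1.0:
            raise ParameterDomainError("p_omega0 must lie in (0, 1]")
        if not -self.gpd.threshold_u > 0:
            raise ParameterDomainError("proximity threshold d0 = -u must be positive")

    @property
    def d0(self) -> float:
        return -self.gpd.threshold_u

    def f1_tail(self, x):
        """Q(X <= x): conditional proximity CDF given Omega0, x <= d0."""
        x = np.asarray(x, dtype=float)
        out = 1.0 - np.asarray(gpd_cdf(self.gpd, -x))
        return out if out.ndim else float(out)


def p_omega0(proximities: Sequence[float], d0: float) -> float:
    """Exceedance fraction P(X < d0): share of near interactions."""
    if not d0 > 0:
        raise ParameterDomainError("d0 must be positive")
    x = np.asarray(proximities, dtype=float)
    n_below = int(np.sum(x < d0))
    if n_below == 0:
        raise EmptyRegionError(f"no observation below d0={d0}")
    return n_below / x.size


def _q_joint(model: RestrictedMeasureModel, x, y):
    """Q(X <= x, Y <= y) and Q(X <= x, Y > y), vectorized over y."""
    a = np.asarray(gpd_cdf(model.gpd, -np.asarray(x, dtype=float)))  # H(x_tilde)
    if not model.y_transformed:
        b = np.asarray(model.severity_margin.cdf(y))
        c = np.asarray(model.copula.cdf(np.broadcast_to(a, b.shape) if b.ndim else a, b))
        q_le = b - c
        q_gt = (1.0 - a) - q_le
    else:
        # severity_margin is the margin of -Y; use the strict-left CDF so that
        # {Y <= y} maps exactly to the complement of {-Y <= -y} at atoms
        m = model.severity_margin
        bt = np.asarray(m.cdf_left(-np.asarray(y, dtype=float)))
        ct = np.asarray(model.copula.cdf(np.broadcast_to(a, bt.shape) if bt.ndim else a, bt))
        q_gt = bt - ct
        q_le = (1.0 - a) - q_gt
    return q_le, q_gt


def joint_prob(
    model: RestrictedMeasureModel,
    x: float,
    y,
    y_side: str = "greater",
):
    """Unconditional P(X <= x, Y > y) or P(X <= x, Y <= y), for x <= d0.

    The model covers only the near-interaction region, so ``x`` must not
    exceed ``d0``; the Q-probability is scaled back to the full interaction
    space by P(Omega0).
    """
    if y_side not in ("greater", "at_most"):
        raise ConfigError("y_side must be 'greater' or 'at_most'")
    if x > model.d0 + 1e-12:
        raise OutOfRegionError(f"x={x} above d0={model.d0}: outside Omega0")
    q_le, q_gt = _q_joint(model, x, y)
    q = q_gt if y_side == "greater" else q_le
    out = np.clip(q, 0.0, 1.0) * model.p_omega0
    return out if np.ndim(out) else float(out)


def conditional_cdf(model: RestrictedMeasureModel, y, x0: float):
    """Conditional severity CDF F_{Y | X <= x0}(y).

    ``x0`` may index an extrapolated event: any proximity with positive mass
    under the fitted tail qualifies, including values never observed (for the
    bounded tail, down to the support endpoint).  Raises
    ``ExtrapolationError`` when the conditioning event has probability zero;
    warns when the fitted shape is in the irregular regime (gamma <= -0.5),
    where extrapolation is unreliable.
    """
    if x0 > model.d0 + 1e-12:
        raise OutOfRegionError(f"x0={x0} above d0={model.d0}: outside Omega0")
    denom = model.f1_tail(x0)
    if not denom > 0:
        raise ExtrapolationError(
            f"conditioning event X <= {x0} has probability 0 under the fitted tail"
        )
    if model.gpd.shape_unstable:
        warnings.warn(
            "conditioning on an extrapolated event with fitted shape <= -0.5",
            RuntimeWarning,
            stacklevel=2,
        )
    q_le, _ = _q_joint(model, x0, y)
    out = np.clip(np.asarray(q_le) / denom, 0.0, 1.0)
    return out if out.ndim else float(out)


def injury_probability(
    model: RestrictedMeasureModel,
    risk_curve: Callable,
    x0: float,
    grid_points: int = 4001,
) -> float:
    """Expected injury risk E[risk_curve(Y) | X <= x0].

    Integrates a user-supplied risk curve (severity -> probability, e.g. a
    logistic dose-response in delta-v) against the conditional severity law.
    With an empirical severity margin the Lebesgue–Stieltjes sum over the
    support atoms is exact; with a parametric margin a dense-grid Stieltjes
    sum over the quantile range is used.
    """
    margin = model.severity_margin
    emp = isinstance(margin, EmpiricalMargin)
    if emp:
        vals = margin.values
        ys = np.unique(-vals[::-1]) if model.y_transformed else np.unique(vals)
        F = np.asarray(conditional_cdf(model, ys, x0))
        masses = np.diff(F, prepend=0.0)
        return float(np.sum(np.asarray(risk_curve(ys)) * masses))
    base = margin.base if isinstance(margin, NegatedMargin) else margin
    lo = float(base.ppf(1e-7))
    hi = float(base.ppf(1.0 - 1e-7))
    ys = np.linspace(lo, hi, grid_points)
    F = np.asarray(conditional_cdf(model, ys, x0))
    mids = 0.5 * (ys[:-1] + ys[1:])
    total = float(np.sum(np.asarray(risk_curve(mids)) * np.diff(F)))
    total += float(risk_curve(lo)) * float(F[0])
    total += float(risk_curve(hi)) * float(1.0 - F[-1])
    return total


def fit_restricted_model(
    md: Sequence[float],
    dv: Sequence[float],
    d0: float,
    family: str = "gumbel",
    min_exceed: int = 10,
    transform_if_negative: bool = True,
) -> tuple[RestrictedMeasureModel, PseudoObservations]:
    """Fit the full pipeline on (minimum distance, delta-v) pairs.

    Steps: exceedance fraction below ``d0``; GPD fit to the negated proximity
    above ``-d0``; pseudo-observations (parametric GP margin for proximity,
    scaled ranks for severity); sample Kendall tau; tau-inversion copula fit —
    with the decreasing-transform (negated severity) branch engaged
    automatically when the sample tau is negative.
    """
    md = np.asarray(md, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if md.shape != dv.shape:
        raise ConfigError("md and dv must have the same length")
    p0 = p_omega0(md, d0)
    gpd = fit_gpd(-md, -d0, min_exceed=min_exceed)
    mask = md < d0
    x_tail = -md[mask]
    y_near = dv[mask]

    pobs = pseudo_observations(x_tail, y_near, margin_x=gpd)
    tau = sample_kendall_tau(pobs)
    y_transformed = bool(transform_if_negative and tau < 0)
    if y_transformed:
        pobs = pseudo_observations(x_tail, -y_near, margin_x=gpd)
        tau_fit = sample_kendall_tau(pobs)
        margin = EmpiricalMargin(-y_near)
    else:
        tau_fit = tau
        margin = EmpiricalMargin(y_near)
    copula = CopulaModel(family, param_from_tau(family, tau_fit))
    model = RestrictedMeasureModel(
        gpd=gpd,
        severity_margin=margin,
        copula=copula,
        p_omega0=p0,
        y_transformed=y_transformed,
        meta={
            "family": family,
            "tau_raw": tau,
            "tau_fitted": tau_fit,
            "m": int(mask.sum()),
            "n": int(md.size),
        },
    )
    return model, pobs


# ---------------------------------------------------------------------------
# Serialization (CLI model bundles)


def model_to_json(model: RestrictedMeasureModel) -> str:
    if not isinstance(model.severity_margin, EmpiricalMargin):
        raise ConfigError("only empirical severity margins serialize to JSON")
    if not isinstance(model.copula, CopulaModel):
        raise ConfigError("only plain family copulas serialize to JSON")
    return json.dumps(
        {
            "gpd": model.gpd.to_dict(),
            "copula": model.copula.to_dict(),
            "p_omega0": model.p_omega0,
            "y_transformed": model.y_transformed,
            "severity_values": model.severity_margin.values.tolist(),
            "meta": model.meta,
        },
        indent=1,
    )


def model_from_json(text: str) -> RestrictedMeasureModel:
    d = json.loads(text)
    return RestrictedMeasureModel(
        gpd=GPDParams.from_dict(d["gpd"]),
        severity_margin=EmpiricalMargin(d["severity_values"]),
        copula=CopulaModel(d["copula"]["family"], d["copula"]["param"]),
        p_omega0=d["p_omega0"],
        y_transformed=d["y_transformed"],
        meta=d.get("meta", {}),
    )
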
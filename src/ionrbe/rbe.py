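"""RBE from LQ iso-effect: dose/survival dependence and LET-RBE curve families.

The relative biological effectiveness at a high-LET dose d_H is obtained by
solving the iso-effect equation

    alpha_L d_L + beta_L d_L^2  =  alpha_H d_H + beta_H d_H^2

for the low-LET dose d_L producing the same LQ effect, and taking
RBE = d_L / d_H.  RBE is bracketed by two closed-form limits:
RBE -> alpha_H/alpha_L (RBE_max) as dose -> 0 and
RBE -> sqrt(beta_H/beta_L) (RBE_min) as dose -> infinity, and moves
monotonically between them as dose rises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .saturation import (
    AlphaSaturationParams,
    BetaSaturationParams,
    ZSaturationParams,
    alpha_u_from_alpha_l,
    beta_u_from_beta_l,
    let_u_from_z,
)
from .scaling import DEFAULT_LET_C, LetResponse, LQParams, alpha_h, beta_h

__all__ = [
    "RBEResult",
    "RBELimits",
    "solve_lq_dose",
    "rbe_at_dose",
    "rbe_at_sf",
    "rbe_limits",
    "rbe_curve",
    "build_let_response",
]


@dataclass(frozen=True)
class RBEResult:
    """One iso-effect solution: the high-LET dose, its low-LET equivalent,
    their ratio, and the shared effect level."""

    d_h: float  # high-LET dose (Gy)
    d_l: float  # iso-effective low-LET dose (Gy)
    rbe: float  # d_l / d_h
    effect: float  # E = alpha d + beta d^2
    sf: float  # exp(-E)
    limit: bool = False  # True when reported as the analytic zero-dose limit


@dataclass(frozen=True)
class RBELimits:
    """Dose-limit RBE values: rbe_max = alpha_H/alpha_L (dose -> 0),
    rbe_min = sqrt(beta_H/beta_L) (dose -> infinity)."""

    rbe_max: float
    rbe_min: float


def solve_lq_dose(effect: float, lq: LQParams) -> float:
    """Unique positive dose (Gy) with LQ effect ``effect``.

    For beta > 0 the positive quadratic root
    d = (-alpha + sqrt(alpha^2 + 4 beta E)) / (2 beta); for beta = 0, E/alpha.
    """
    if not (effect > 0):
        raise ValueError(f"effect must be positive, got {effect}")
    a, b = lq.alpha, lq.beta
    if a == 0 and b == 0:
        raise ValueError("alpha and beta cannot both be zero")
    if b == 0:
        return effect / a
    return (-a + math.sqrt(a * a + 4.0 * b * effect)) / (2.0 * b)


def rbe_at_dose(d_h: float, lq_low: LQParams, lq_high: LQParams) -> RBEResult:
    """RBE at high-LET dose ``d_h`` (Gy) by iso-effect against the low-LET LQ."""
    if not (d_h > 0):
        raise ValueError(f"d_h must be positive, got {d_h}")
    effect = lq_high.effect(d_h)
    d_l = solve_lq_dose(effect, lq_low)
    return RBEResult(
        d_h=d_h, d_l=d_l, rbe=d_l / d_h, effect=effect, sf=math.exp(-effect)
    )


def rbe_at_sf(sf: float, lq_low: LQParams, lq_high: LQParams) -> RBEResult:
    """RBE at surviving fraction ``sf``; both doses solved at E = -ln(sf).

    sf = 1 (zero dose) is reported as the analytic limit RBE_max with
    ``limit=True`` rather than an error, since curve families need the
    low-dose envelope.
    """
    if not (0 < sf <= 1):
        raise ValueError(f"sf must lie in (0, 1], got {sf}")
    if sf == 1.0:
        limits = rbe_limits(lq_low, lq_high)
        return RBEResult(d_h=0.0, d_l=0.0, rbe=limits.rbe_max, effect=0.0, sf=1.0,
                         limit=True)
    effect = -math.log(sf)
    d_h = solve_lq_dose(effect, lq_high)
    d_l = solve_lq_dose(effect, lq_low)
    return RBEResult(d_h=d_h, d_l=d_l, rbe=d_l / d_h, effect=effect, sf=sf)


def rbe_limits(lq_low: LQParams, lq_high: LQParams) -> RBELimits:
    """Closed-form dose limits of the RBE.

    Neither ordering of the limits is assumed; both are simply computed.
    """
    if lq_low.alpha <= 0:
        raise ValueError("rbe_max undefined: alpha_L must be positive")
    if lq_low.beta <= 0:
        raise ValueError("rbe_min undefined: beta_L must be positive")
    return RBELimits(
        rbe_max=lq_high.alpha / lq_low.alpha,
        rbe_min=math.sqrt(lq_high.beta / lq_low.beta),
    )


def build_let_response(
    lq_low: LQParams,
    z: float | None = None,
    let_u: float | None = None,
    alpha_u: float | None = None,
    beta_u: float | None = None,
    z_params: ZSaturationParams | None = None,
    alpha_params: AlphaSaturationParams | None = None,
    beta_params: BetaSaturationParams | None = None,
    let_c: float = DEFAULT_LET_C,
    post_turnover: str = "reciprocal",
) -> LetResponse:
    """Assemble a :class:`LetResponse` from either pinned turnover values or
    the saturation relations.

    Pipeline when values are not pinned: ``let_u`` from the charge relation
    (needs ``z`` and fitted ``z_params``); ``alpha_u``/``beta_u`` from the
    alpha/beta saturation relations (linear c = 6.47 and nonlinear
    R = 2.5, u = 25 defaults respectively).
    """
    if let_u is None:
        if z is None or z_params is None:
            raise ValueError("need let_u, or z together with fitted z_params")
        let_u = let_u_from_z(z, z_params)
    if alpha_u is None:
        alpha_u = alpha_u_from_alpha_l(lq_low.alpha, alpha_params or AlphaSaturationParams())
    if beta_u is None:
        beta_u = beta_u_from_beta_l(lq_low.beta, beta_params or BetaSaturationParams())
    return LetResponse(
        let_u=float(let_u),
        lq_low=lq_low,
        lq_turn=LQParams(alpha=float(alpha_u), beta=float(beta_u)),
        let_c=let_c,
        z=z,
        post_turnover=post_turnover,
    )


def rbe_curve(
    let_grid,
    resp: LetResponse,
    dose: float | None = None,
    sf: float | None = None,
) -> pd.DataFrame:
    """LET-RBE curve at a fixed high-LET dose (Gy) or surviving fraction.

    One of ``dose`` and ``sf`` must be given.  Returns a DataFrame with
    columns ``let, alpha_h, beta_h, rbe``; the RBE peaks at the grid point
    nearest the turnover LET, at every dose/SF level.
    """
    if (dose is None) == (sf is None):
        raise ValueError("give exactly one of dose or sf")
    grid = np.asarray(let_grid, dtype=float)
    a_h = np.atleast_1d(alpha_h(grid, resp))
    b_h = np.atleast_1d(beta_h(grid, resp))
    rbe = np.empty_like(a_h)
    for i in range(a_h.size):
        lq_high = LQParams(alpha=float(a_h[i]), beta=float(b_h[i]))
        if dose is not None:
            rbe[i] = rbe_at_dose(dose, resp.lq_low, lq_high).rbe
        else:
            rbe[i] = rbe_at_sf(sf, resp.lq_low, lq_high).rbe
    return pd.DataFrame({"let": grid, "alpha_h": a_h, "beta_h": b_h, "rbe": rbe})
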
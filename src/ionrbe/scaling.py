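"""Piecewise LET efficiency scaling of the LQ radiosensitivities.

Between the low-LET control quality (LET_C, where the cell line shows its
intrinsic alpha_L, beta_L) and the turnover point (LET_U, where it shows its
maximal alpha_U, beta_U) the killing efficiency per unit dose rises linearly:

    efficiency(LET_x) = (LET_x - LET_C) / (LET_U - LET_C),   LET_C <= LET_x <= LET_U

Beyond the turnover point additional deposited energy is wasted ("overkill")
and the efficiency declines reciprocally:

    efficiency(LET_x) = LET_U / LET_x,                        LET_x > LET_U

so that efficiency is exactly 1 at LET_U and continuous everywhere.  Both
alpha and beta are scaled by the SAME efficiency with the SAME turnover LET —
this symmetry is what keeps the position of the RBE peak independent of dose:

    alpha_H = alpha_L + efficiency * (alpha_U - alpha_L)
    beta_H  = beta_L  + efficiency * (beta_U  - beta_L)

The post-turnover branch admits a second reading in which the inefficiency is
normalised by LET_U rather than LET_x, i.e. efficiency = 1 - (LET_x-LET_U)/LET_U.
That form goes negative past 2*LET_U, so it is offered only behind
``post_turnover="strict"`` with the efficiency clamped at zero; the default
``"reciprocal"`` form is the one the model's own worked arithmetic uses and
decays asymptotically to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LQParams", "LetResponse", "efficiency", "alpha_h", "beta_h", "scaling_table",
           "DEFAULT_LET_C"]

#: Default control (low-LET reference) LET in keV/um, representative of
#: megavoltage photons.
DEFAULT_LET_C = 1.2


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity pair: SF(d) = exp(-alpha d - beta d^2).

    alpha in Gy^-1, beta in Gy^-2.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha) or not math.isfinite(self.beta):
            raise ValueError("alpha and beta must be finite")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")

    @property
    def ab_ratio(self) -> float:
        """alpha/beta ratio (Gy); inf when beta = 0."""
        return self.alpha / self.beta if self.beta > 0 else math.inf

    def effect(self, dose) -> float:
        """LQ effect E = alpha d + beta d^2 (natural-log scale)."""
        d = np.asarray(dose, dtype=float)
        out = self.alpha * d + self.beta * d * d
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LetResponse:
    """Assembled per-ion LET response: turnover position plus the LQ endpoints.

    Attributes
    ----------
    let_u : float
        Turnover LET (keV/um) at which alpha and beta peak.
    lq_low : LQParams
        Intrinsic (alpha_L, beta_L) at the low-LET control quality.
    lq_turn : LQParams
        Maximal (alpha_U, beta_U) at the turnover point.
    let_c : float
        Control LET (keV/um); the model is undefined below it.
    z : float or None
        Ion charge, if the turnover LET came from the charge relation.
    post_turnover : str
        "reciprocal" (default) or "strict" — see module docstring.
    """

    let_u: float
    lq_low: LQParams
    lq_turn: LQParams
    let_c: float = DEFAULT_LET_C
    z: float | None = None
    post_turnover: str = "reciprocal"

    def __post_init__(self) -> None:
        if not (0 < self.let_c < self.let_u):
            raise ValueError(
                f"need 0 < let_c < let_u, got let_c={self.let_c}, let_u={self.let_u}"
            )
        if self.lq_low.alpha <= 0:
            raise ValueError("control alpha_L must be positive")
        if self.lq_turn.alpha < self.lq_low.alpha:
            raise ValueError("turnover alpha_U must be >= control alpha_L")
        if self.lq_turn.beta < self.lq_low.beta:
            raise ValueError("turnover beta_U must be >= control beta_L")
        if self.post_turnover not in ("reciprocal", "strict"):
            raise ValueError(
                f"post_turnover must be 'reciprocal' or 'strict', got {self.post_turnover!r}"
            )


def efficiency(let_x, resp: LetResponse):
    """Relative killing efficiency in (0, 1] at LET ``let_x`` (keV/um).

    Linear rise from 0 at the control LET to 1 at the turnover LET, then
    reciprocal (or clamped strict) decline.  Raises below the control LET,
    where the model is undefined.
    """
    let_x = np.asarray(let_x, dtype=float)
    if np.any(let_x < resp.let_c):
        raise ValueError(f"let_x below the control LET {resp.let_c} keV/um is undefined")
    pre = (let_x - resp.let_c) / (resp.let_u - resp.let_c)
    if resp.post_turnover == "reciprocal":
        with np.errstate(divide="ignore"):
            post = resp.let_u / let_x
    else:
        post = np.maximum(1.0 - (let_x - resp.let_u) / resp.let_u, 0.0)
    out = np.where(let_x <= resp.let_u, pre, post)
    return float(out) if out.ndim == 0 else out


def alpha_h(let_x, resp: LetResponse):
    """alpha at LET ``let_x``: alpha_L + efficiency * (alpha_U - alpha_L), in Gy^-1."""
    eff = efficiency(let_x, resp)
    return resp.lq_low.alpha + eff * (resp.lq_turn.alpha - resp.lq_low.alpha)


def beta_h(let_x, resp: LetResponse):
    """beta at LET ``let_x``: beta_L + efficiency * (beta_U - beta_L), in Gy^-2.

    Uses the same efficiency (hence the same turnover LET) as alpha — the
    symmetry that keeps the RBE-peak position dose-invariant.
    """
    eff = efficiency(let_x, resp)
    return resp.lq_low.beta + eff * (resp.lq_turn.beta - resp.lq_low.beta)


def lq_at(let_x: float, resp: LetResponse) -> LQParams:
    """LQParams (alpha_H, beta_H) at a single LET value."""
    return LQParams(alpha=float(alpha_h(let_x, resp)), beta=float(beta_h(let_x, resp)))


def scaling_table(let_grid, resp: LetResponse) -> pd.DataFrame:
    """Vectorised evaluation over an LET grid.

    Returns a DataFrame with columns ``let, efficiency, alpha_h, beta_h``.
    """
    grid = np.asarray(let_grid, dtype=float)
    eff = efficiency(grid, resp)
    return pd.DataFrame(
        {
            "let": grid,
            "efficiency": eff,
            "alpha_h": resp.lq_low.alpha + eff * (resp.lq_turn.alpha - resp.lq_low.alpha),
            "beta_h": resp.lq_low.beta + eff * (resp.lq_turn.beta - resp.lq_low.beta),
        }
    )
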
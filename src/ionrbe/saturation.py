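"""Closed-form saturation relations of the LET efficiency model.

Three exponential-saturation laws underpin the model:

* turnover LET versus ion charge:  LET_U(Z) = anchor + (S/k)(1 - exp(-k(Z-1))),
  anchored at the proton value LET_U(1) = 30.5 keV/um;
* maximum alpha versus low-LET alpha:  alpha_U = (A/j)(1 - exp(-j alpha_L)),
  or the linear no-intercept form alpha_U = c * alpha_L;
* maximum beta versus low-LET beta:  beta_U = (R/u)(1 - exp(-u beta_L)),
  with defaults R = 2.5, u = 25 giving a ceiling of 0.1 Gy^-2.

Each law is the closed-form solution of a first-order saturation ODE
(dy/dx = slope - rate * y): the response rises with its stated initial slope
and levels off at the finite asymptote slope/rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZSaturationParams",
    "AlphaSaturationParams",
    "BetaSaturationParams",
    "let_u_from_z",
    "alpha_u_from_alpha_l",
    "beta_u_from_beta_l",
    "NEUTRON_PRESETS",
    "DEFAULT_ANCHOR_LET",
    "DEFAULT_ALPHA_C",
    "DEFAULT_BETA_R",
    "DEFAULT_BETA_U_RATE",
]

#: Proton (Z = 1) turnover LET in keV/um used to anchor the Z relation.
DEFAULT_ANCHOR_LET = 30.5
#: Linear no-intercept coefficient alpha_U = c * alpha_L for ion beams
#: (valid for alpha_L below ~0.35 Gy^-1).
DEFAULT_ALPHA_C = 6.47
#: Default beta saturation initial slope (dimensionless).
DEFAULT_BETA_R = 2.5
#: Default beta saturation rate constant (Gy^2); ceiling R/u = 0.1 Gy^-2.
DEFAULT_BETA_U_RATE = 25.0


@dataclass(frozen=True)
class ZSaturationParams:
    """Parameters of the charge -> turnover-LET saturation relation.

    Attributes
    ----------
    S : float
        Initial slope of LET_U with Z (keV/um per unit charge).
    k : float
        Saturation rate constant (per unit charge).
    anchor_let : float
        LET_U at Z = 1 (keV/um).  Default 30.5, the proton turnover LET.
    """

    S: float
    k: float
    anchor_let: float = DEFAULT_ANCHOR_LET

    def __post_init__(self) -> None:
        if not (self.S > 0 and math.isfinite(self.S)):
            raise ValueError(f"S must be positive and finite, got {self.S}")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"k must be positive and finite, got {self.k}")
        if not (self.anchor_let > 0 and math.isfinite(self.anchor_let)):
            raise ValueError(
                f"anchor_let must be positive and finite, got {self.anchor_let}"
            )

    @property
    def amplitude(self) -> float:
        """S/k, the maximum rise of LET_U above the proton anchor (keV/um)."""
        return self.S / self.k

    @property
    def asymptote(self) -> float:
        """Limiting LET_U as Z grows without bound (keV/um)."""
        return self.anchor_let + self.S / self.k

    @classmethod
    def from_amplitude(
        cls, amplitude: float, k: float, anchor_let: float = DEFAULT_ANCHOR_LET
    ) -> "ZSaturationParams":
        """Build from (S/k, k) — the parametrisation the fit works in."""
        return cls(S=amplitude * k, k=k, anchor_let=anchor_let)


@dataclass(frozen=True)
class AlphaSaturationParams:
    """Parameters mapping the low-LET alpha_L to the turnover alpha_U.

    ``mode="linear"`` uses alpha_U = c * alpha_L (the published ion-beam
    coefficient c = 6.47); ``mode="nonlinear"`` uses the saturation form
    (A/j)(1 - exp(-j alpha_L)) and requires A and j, which are not published
    for ion beams and must be supplied (e.g. from a fit).
    """

    mode: str = "linear"
    c: float = DEFAULT_ALPHA_C
    A: float | None = None
    j: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be 'linear' or 'nonlinear', got {self.mode!r}")
        if self.mode == "linear":
            if not (self.c > 1):
                raise ValueError(f"linear coefficient c must exceed 1, got {self.c}")
        else:
            if self.A is None or self.j is None:
                raise ValueError("nonlinear mode requires both A and j")
            if not (self.A > 0 and self.j > 0):
                raise ValueError(f"A and j must be positive, got A={self.A}, j={self.j}")

    @property
    def ceiling(self) -> float:
        """Limiting alpha_U (Gy^-1); infinite in linear mode."""
        if self.mode == "nonlinear":
            return self.A / self.j  # type: ignore[operator]
        return math.inf


@dataclass(frozen=True)
class BetaSaturationParams:
    """Parameters mapping the low-LET beta_L to the turnover beta_U.

    Modes: ``nonlinear`` (default, (R/u)(1 - exp(-u beta_L)) with R = 2.5,
    u = 25), ``linear`` (beta_U = c * beta_L), or ``constant`` (beta taken
    as LET-invariant, beta_U = beta_L).
    """

    mode: str = "nonlinear"
    R: float = DEFAULT_BETA_R
    u: float = DEFAULT_BETA_U_RATE
    c: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("nonlinear", "linear", "constant"):
            raise ValueError(
                f"mode must be 'nonlinear', 'linear' or 'constant', got {self.mode!r}"
            )
        if self.mode == "nonlinear":
            if not (self.R > 0 and self.u > 0):
                raise ValueError(f"R and u must be positive, got R={self.R}, u={self.u}")
            if not math.isfinite(self.R / self.u):
                raise ValueError("ceiling R/u must be finite")
        if self.mode == "linear":
            if self.c is None or not (self.c > 0):
                raise ValueError("linear mode requires a positive coefficient c")

    @property
    def ceiling(self) -> float:
        """Limiting beta_U (Gy^-2); infinite in linear/constant modes."""
        if self.mode == "nonlinear":
            return self.R / self.u
        return math.inf


def let_u_from_z(z, params: ZSaturationParams):
    """Turnover LET (keV/um) for ion charge ``z``.

    LET_U = anchor + (S/k)(1 - exp(-k (z - 1))).  ``z`` may be a scalar or
    array; the relation treats charge as continuous but is only physical for
    z >= 1.  Strictly increasing and concave in z, bounded by the asymptote.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 1):
        raise ValueError("ion charge z must be >= 1")
    out = params.anchor_let + (params.S / params.k) * (
        1.0 - np.exp(-params.k * (z - 1.0))
    )
    return float(out) if out.ndim == 0 else out


def alpha_u_from_alpha_l(alpha_l, params: AlphaSaturationParams):
    """Turnover alpha_U (Gy^-1) from the low-LET alpha_L.

    Returns the raw formula value; callers wanting a genuine high-LET
    enhancement should validate alpha_U > alpha_L themselves (the linear
    form guarantees it for c > 1, the nonlinear form does not everywhere).
    """
    alpha_l = np.asarray(alpha_l, dtype=float)
    if np.any(alpha_l < 0):
        raise ValueError("alpha_l must be non-negative")
    if params.mode == "linear":
        out = params.c * alpha_l
    else:
        out = (params.A / params.j) * (1.0 - np.exp(-params.j * alpha_l))
    return float(out) if out.ndim == 0 else out


def beta_u_from_beta_l(beta_l, params: BetaSaturationParams):
    """Turnover beta_U (Gy^-2) from the low-LET beta_L."""
    beta_l = np.asarray(beta_l, dtype=float)
    if np.any(beta_l < 0):
        raise ValueError("beta_l must be non-negative")
    if params.mode == "constant":
        out = beta_l.copy()
    elif params.mode == "linear":
        out = params.c * beta_l
    else:
        out = (params.R / params.u) * (1.0 - np.exp(-params.u * beta_l))
    return float(out) if out.ndim == 0 else out


# Fast-neutron (64 MV) regression presets.  These describe neutron, not ion,
# radiation quality: neutron LET spectra sit below the ionic turnover point,
# so these coefficients underestimate alpha_U/beta_U and must not be used for
# ion-beam RBE prediction.
NEUTRON_PRESETS: dict[str, AlphaSaturationParams | BetaSaturationParams] = {
    "neutron_alpha_linear": AlphaSaturationParams(mode="linear", c=2.72),
    "neutron_alpha_nonlinear": AlphaSaturationParams(mode="nonlinear", A=5.37, j=3.68),
    "neutron_beta_linear": BetaSaturationParams(mode="linear", c=1.57),
    "neutron_beta_nonlinear": BetaSaturationParams(mode="nonlinear", R=2.29, u=23.57),
}
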
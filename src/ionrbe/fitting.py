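"""Least-squares calibration of the saturation relations and LQ survival.

Model classes follow the familiar pattern of statistical modelling packages:
construct a model object from data, call :meth:`fit`, and receive a results
object carrying the point estimates, their standard errors, residuals and a
``summary()`` table.

All nonlinear fits share one deterministic strategy: the saturation forms
``y = a0 + amp * (1 - exp(-rate * (x - x0)))`` are linear in the amplitude
``amp`` for a fixed rate constant, so the rate is profiled over a log-spaced
grid with the conditionally optimal amplitude solved in closed form at each
grid point, and the best candidate is then polished by Levenberg-Marquardt.
No stochastic search is involved; identical data always yield identical fits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear

from .saturation import (
    DEFAULT_ANCHOR_LET,
    AlphaSaturationParams,
    BetaSaturationParams,
    ZSaturationParams,
)
from .scaling import LQParams

__all__ = [
    "SaturationFitResults",
    "ZSaturationModel",
    "AlphaSaturationModel",
    "BetaSaturationModel",
    "LQSurvivalModel",
    "LQFitResults",
    "generate_synthetic_survival",
]

# Log-spaced profile grid for the rate constant (k, j or u).  The upper end
# is generous (1e2) so that steep relations such as the beta saturation
# (u = 25 Gy^2) start within the grid rather than relying on the polish alone.
_RATE_GRID = np.logspace(-3.0, 2.0, 400)
_RSS_TOL = 1e-10


def _check_xyw(x, y, weights):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite, non-negative, same length as x")
    return x, y, w


@dataclass
class SaturationFitResults:
    """Results of a saturation-curve fit.

    Attributes
    ----------
    params : dict
        Named point estimates (e.g. ``amplitude`` and ``rate``, plus the
        derived initial ``slope`` = amplitude * rate).
    bse : dict
        Approximate standard errors from the Gauss-Newton covariance
        s^2 (J'J)^-1; NaN when there are no residual degrees of freedom.
    resid : numpy.ndarray
        Per-point residuals y_i - yhat_i at the estimates.
    rss : float
        Residual sum of squares.
    converged : bool
    n_iter : int
        Function evaluations used by the local refinement.
    """

    model: object
    params: dict
    bse: dict
    resid: np.ndarray
    rss: float
    converged: bool
    n_iter: int
    extra: dict = field(default_factory=dict)

    @property
    def nobs(self) -> int:
        return self.resid.size

    def predict(self, x):
        return self.model.predict(self.params, x)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit results",
            "=" * 46,
            f"{'n obs':<14}{self.nobs:>10}",
            f"{'RSS':<14}{self.rss:>16.8g}",
            f"{'converged':<14}{str(self.converged):>10}",
            f"{'n iterations':<14}{self.n_iter:>10}",
            "-" * 46,
            f"{'param':<12}{'estimate':>16}{'std err':>16}",
        ]
        for name, val in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<12}{val:>16.6g}{se:>16.6g}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": type(self.model).__name__,
                "params": self.params,
                "bse": {k: (None if math.isnan(v) else v) for k, v in self.bse.items()},
                "rss": self.rss,
                "resid": self.resid.tolist(),
                "converged": self.converged,
                "n_iter": self.n_iter,
                **self.extra,
            },
            indent=2,
        )


def _profile_polish(residual_of, amp_given_rate, rate_grid=_RATE_GRID):
    """Deterministic profile-then-polish driver.

    ``amp_given_rate(rate)`` returns the conditionally optimal linear
    amplitude(s); ``residual_of(theta)`` the weighted residual vector for the
    full parameter vector ``theta = [*amps, rate]``.
    """
    best = None
    for rate in rate_grid:
        amps = amp_given_rate(rate)
        r = residual_of([*amps, rate])
        rss = float(r @ r)
        if best is None or rss < best[0] - _RSS_TOL:
            best = (rss, [*amps, rate])
    sol = least_squares(
        residual_of, x0=best[1], method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    r0 = residual_of(best[1])
    # keep whichever of grid-best / polished has lower RSS (LM can stall on
    # pathological flat valleys)
    if float(r0 @ r0) < 2 * sol.cost:
        theta, rss, nfev, ok = best[1], float(r0 @ r0), len(rate_grid), True
    else:
        theta, rss, nfev, ok = sol.x, 2 * sol.cost, sol.nfev, sol.success
    return np.asarray(theta, dtype=float), rss, nfev, ok, sol


def _gauss_newton_bse(jac, rss, nobs, nparams):
    dof = nobs - nparams
    if dof <= 0:
        return np.full(nparams, np.nan)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(nparams, np.nan)


class ZSaturationModel:
    """Fit the charge -> turnover-LET relation to (Z, LET_U) calibration data.

    The proton anchor LET_U(1) = 30.5 keV/um is held fixed by default
    (``fix_anchor=True``); the free parameters are the amplitude S/k and the
    rate constant k.  With ``fix_anchor=False`` the anchor is estimated too.

    Parameters
    ----------
    z, let_u : array-like
        Calibration points (ion charge, observed turnover LET in keV/um).
    weights : array-like, optional
        Non-negative least-squares weights.
    anchor_let : float
        The fixed (or initial) Z = 1 turnover LET.
    """

    def __init__(self, z, let_u, weights=None, anchor_let=DEFAULT_ANCHOR_LET,
                 fix_anchor=True):
        self.z, self.let_u, self.weights = _check_xyw(z, let_u, weights)
        if np.any(self.z < 1):
            raise ValueError("ion charge must be >= 1")
        if np.unique(self.z).size != self.z.size:
            raise ValueError("Z values must be distinct")
        n_free = np.count_nonzero(self.z > 1)
        if n_free < 2:
            raise ValueError("need at least 2 non-anchor calibration points")
        self.anchor_let = anchor_let
        self.fix_anchor = fix_anchor

    def predict(self, params: dict, z):
        z = np.asarray(z, dtype=float)
        a0 = params.get("anchor_let", self.anchor_let)
        return a0 + params["amplitude"] * (1.0 - np.exp(-params["rate"] * (z - 1.0)))

    def _basis(self, rate):
        return 1.0 - np.exp(-rate * (self.z - 1.0))

    def fit(self) -> SaturationFitResults:
        sw = np.sqrt(self.weights)
        y = self.let_u

        if self.fix_anchor:
            yc = y - self.anchor_let

            def amp_given_rate(rate):
                b = self._basis(rate) * sw
                denom = b @ b
                return [(b @ (yc * sw)) / denom if denom > 0 else 0.0]

            def residual_of(theta):
                amp, rate = theta
                return sw * (yc - amp * self._basis(rate))

            theta, rss, nfev, ok, sol = _profile_polish(residual_of, amp_given_rate)
            amp, rate = theta
            params = {"amplitude": amp, "rate": rate, "slope": amp * rate}
            jac = np.column_stack(
                [-sw * self._basis(rate),
                 -sw * amp * (self.z - 1.0) * np.exp(-rate * (self.z - 1.0))]
            )
            bse_v = _gauss_newton_bse(jac, rss, y.size, 2)
            bse = {"amplitude": bse_v[0], "rate": bse_v[1], "slope": float("nan")}
            resid = yc - amp * self._basis(rate)
        else:
            def amp_given_rate(rate):
                X = np.column_stack([np.ones_like(self.z), self._basis(rate)]) * sw[:, None]
                coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
                return [coef[0], coef[1]]

            def residual_of(theta):
                a0, amp, rate = theta
                return sw * (y - a0 - amp * self._basis(rate))

            theta, rss, nfev, ok, sol = _profile_polish(residual_of, amp_given_rate)
            a0, amp, rate = theta
            params = {"anchor_let": a0, "amplitude": amp, "rate": rate,
                      "slope": amp * rate}
            jac = np.column_stack(
                [-sw,
                 -sw * self._basis(rate),
                 -sw * amp * (self.z - 1.0) * np.exp(-rate * (self.z - 1.0))]
            )
            bse_v = _gauss_newton_bse(jac, rss, y.size, 3)
            bse = {"anchor_let": bse_v[0], "amplitude": bse_v[1], "rate": bse_v[2],
                   "slope": float("nan")}
            resid = y - a0 - amp * self._basis(rate)

        return SaturationFitResults(
            model=self, params=params, bse=bse, resid=resid, rss=rss,
            converged=ok, n_iter=nfev,
        )

    @staticmethod
    def results_to_params(res: SaturationFitResults) -> ZSaturationParams:
        """Convert fit results to a :class:`ZSaturationParams`."""
        return ZSaturationParams.from_amplitude(
            amplitude=res.params["amplitude"],
            k=res.params["rate"],
            anchor_let=res.params.get("anchor_let", res.model.anchor_let),
        )


class _RadiosensitivitySaturationModel:
    """Shared machinery for the alpha and beta saturation fits.

    Fits either ``y = slope * x`` (linear no-intercept, closed form) or the
    saturation law ``y = amp (1 - exp(-rate x))`` with amp = slope/rate.
    """

    def __init__(self, x, y, weights=None, mode="nonlinear"):
        self.x, self.y, self.weights = _check_xyw(x, y, weights)
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("radiosensitivities must be non-negative")
        if mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be 'linear' or 'nonlinear', got {mode!r}")
        if mode == "linear" and self.x.size < 1:
            raise ValueError("linear mode needs at least 1 point")
        if mode == "nonlinear" and self.x.size < 2:
            raise ValueError("nonlinear mode needs at least 2 points")
        self.mode = mode

    def predict(self, params: dict, x):
        x = np.asarray(x, dtype=float)
        if self.mode == "linear":
            return params["slope"] * x
        return params["amplitude"] * (1.0 - np.exp(-params["rate"] * x))

    def fit(self) -> SaturationFitResults:
        sw = np.sqrt(self.weights)
        if self.mode == "linear":
            denom = float((sw * self.x) @ (sw * self.x))
            if denom == 0:
                raise ValueError("degenerate data: all x are zero")
            slope = float((sw * self.x) @ (sw * self.y)) / denom
            resid = self.y - slope * self.x
            rss = float((sw * resid) @ (sw * resid))
            bse_v = _gauss_newton_bse((sw * self.x)[:, None], rss, self.x.size, 1)
            return SaturationFitResults(
                model=self, params={"slope": slope}, bse={"slope": bse_v[0]},
                resid=resid, rss=rss, converged=True, n_iter=0,
            )

        def amp_given_rate(rate):
            b = (1.0 - np.exp(-rate * self.x)) * sw
            denom = b @ b
            return [(b @ (self.y * sw)) / denom if denom > 0 else 0.0]

        def residual_of(theta):
            amp, rate = theta
            return sw * (self.y - amp * (1.0 - np.exp(-rate * self.x)))

        theta, rss, nfev, ok, sol = _profile_polish(residual_of, amp_given_rate)
        amp, rate = theta
        params = {"amplitude": amp, "rate": rate, "slope": amp * rate}
        jac = np.column_stack(
            [-sw * (1.0 - np.exp(-rate * self.x)),
             -sw * amp * self.x * np.exp(-rate * self.x)]
        )
        bse_v = _gauss_newton_bse(jac, rss, self.x.size, 2)
        return SaturationFitResults(
            model=self, params=params,
            bse={"amplitude": bse_v[0], "rate": bse_v[1], "slope": float("nan")},
            resid=self.y - amp * (1.0 - np.exp(-rate * self.x)),
            rss=rss, converged=ok, n_iter=nfev,
        )


class AlphaSaturationModel(_RadiosensitivitySaturationModel):
    """Fit alpha_U (or alpha_H) against the low-LET alpha_L.

    Linear mode recovers the no-intercept coefficient c (published ion value
    6.47); nonlinear mode recovers (A, j) of the saturation law with
    A = slope = amplitude * rate.
    """

    @staticmethod
    def results_to_params(res: SaturationFitResults) -> AlphaSaturationParams:
        if res.model.mode == "linear":
            return AlphaSaturationParams(mode="linear", c=res.params["slope"])
        return AlphaSaturationParams(
            mode="nonlinear", A=res.params["slope"], j=res.params["rate"]
        )


class BetaSaturationModel(_RadiosensitivitySaturationModel):
    """Fit beta_U (or beta_H) against the low-LET beta_L; (R, u) analogue of
    the alpha fit."""

    @staticmethod
    def results_to_params(res: SaturationFitResults) -> BetaSaturationParams:
        if res.model.mode == "linear":
            return BetaSaturationParams(mode="linear", c=res.params["slope"])
        return BetaSaturationParams(
            mode="nonlinear", R=res.params["slope"], u=res.params["rate"]
        )


@dataclass
class LQFitResults(SaturationFitResults):
    """LQ survival fit results; adds the fitted :class:`LQParams`."""

    @property
    def lq(self) -> LQParams:
        return LQParams(alpha=self.params["alpha"], beta=self.params["beta"])


class LQSurvivalModel:
    """Fit LQ radiosensitivities (alpha, beta) to clonogenic survival data.

    The fit is linear least squares of -ln(SF) on dose and dose^2 with no
    intercept (survival is 1 at zero dose by construction), with alpha and
    beta constrained non-negative.  Fitting on the log scale is standard
    practice for clonogenic assays, where errors are roughly multiplicative.
    """

    def __init__(self, dose, sf, weights=None):
        self.dose, self.sf, self.weights = _check_xyw(dose, sf, weights)
        if self.dose.size < 3:
            raise ValueError("need at least 3 survival points")
        if np.unique(self.dose).size != self.dose.size:
            raise ValueError("doses must be distinct")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if np.any((self.sf <= 0) | (self.sf > 1)):
            raise ValueError("surviving fractions must lie in (0, 1]")
        if np.all(self.sf == 1.0):
            raise ValueError("degenerate data: all surviving fractions are 1")

    def predict(self, params: dict, dose):
        d = np.asarray(dose, dtype=float)
        return np.exp(-(params["alpha"] * d + params["beta"] * d * d))

    def fit(self) -> LQFitResults:
        y = -np.log(self.sf)
        sw = np.sqrt(self.weights)
        X = np.column_stack([self.dose, self.dose**2])
        sol = lsq_linear(X * sw[:, None], y * sw, bounds=(0.0, np.inf),
                         tol=1e-14)
        alpha, beta = sol.x
        resid = y - X @ sol.x
        rss = float((sw * resid) @ (sw * resid))
        bse_v = _gauss_newton_bse(X * sw[:, None], rss, y.size, 2)
        return LQFitResults(
            model=self,
            params={"alpha": float(alpha), "beta": float(beta)},
            bse={"alpha": bse_v[0], "beta": bse_v[1]},
            resid=resid, rss=rss, converged=bool(sol.success),
            n_iter=int(getattr(sol, "nit", 0) or 0),
            extra={"scale": "log-survival"},
        )


def generate_synthetic_survival(
    lq: LQParams, doses, noise_cv: float = 0.0, n_reps: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate clonogenic LQ survival data with multiplicative noise.

    Surviving fraction at dose d is exp(-alpha d - beta d^2) times a
    lognormal factor of mean 1 and coefficient of variation ``noise_cv`` —
    the standard error structure of colony-count assays, where variability
    scales with the measured fraction.  ``seed`` is required whenever
    ``noise_cv > 0`` so every synthetic table is reproducible.

    Returns a DataFrame with columns ``dose, sf, rep``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if noise_cv > 0 and seed is None:
        raise ValueError("a seed is required when noise_cv > 0")
    doses = np.asarray(doses, dtype=float)
    clean = np.exp(-(lq.alpha * doses + lq.beta * doses**2))
    frames = []
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        sf = clean.copy()
        if noise_cv > 0:
            sigma = math.sqrt(math.log1p(noise_cv**2))
            factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=doses.size)
            sf = sf * factor
        frames.append(pd.DataFrame({"dose": doses, "sf": sf, "rep": rep}))
    return pd.concat(frames, ignore_index=True)
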
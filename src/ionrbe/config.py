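"""Model configuration: every tunable constant in one validated block.

A config file (YAML or JSON — YAML is a superset) may override any subset of
the model constants; absent keys take the published defaults and unknown
keys are rejected outright so that typos cannot silently fall back to
defaults in what may be a clinical sanity-check calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import yaml

from .saturation import (
    DEFAULT_ALPHA_C,
    DEFAULT_ANCHOR_LET,
    DEFAULT_BETA_R,
    DEFAULT_BETA_U_RATE,
    AlphaSaturationParams,
    BetaSaturationParams,
    ZSaturationParams,
)
from .scaling import DEFAULT_LET_C

__all__ = ["ModelConfig", "load_config"]

logger = logging.getLogger("ionrbe")


@dataclass(frozen=True)
class ModelConfig:
    """All model constants, with published defaults.

    ``S`` and ``k`` of the charge relation have no published values — they
    are calibrated from the packaged four-point table; leave them ``None``
    to have :meth:`z_params` fit them on demand.
    """

    anchor_let: float = DEFAULT_ANCHOR_LET
    S: float | None = None
    k: float | None = None
    alpha_mode: str = "linear"
    alpha_c: float = DEFAULT_ALPHA_C
    A: float | None = None
    j: float | None = None
    beta_mode: str = "nonlinear"
    R: float = DEFAULT_BETA_R
    u: float = DEFAULT_BETA_U_RATE
    let_c: float = DEFAULT_LET_C
    post_turnover: str = "reciprocal"

    def __post_init__(self) -> None:
        # delegate validation to the parameter types themselves
        if (self.S is None) != (self.k is None):
            raise ValueError("S and k must be given together (or both omitted)")
        if self.S is not None:
            ZSaturationParams(S=self.S, k=self.k, anchor_let=self.anchor_let)
        elif not (self.anchor_let > 0):
            raise ValueError(f"anchor_let must be positive, got {self.anchor_let}")
        self.alpha_params()
        self.beta_params()
        if not (self.let_c > 0):
            raise ValueError(f"let_c must be positive, got {self.let_c}")
        if self.post_turnover not in ("reciprocal", "strict"):
            raise ValueError(
                f"post_turnover must be 'reciprocal' or 'strict', got {self.post_turnover!r}"
            )

    def z_params(self) -> ZSaturationParams:
        """Charge-relation parameters; calibrated from the packaged table
        when S, k are not configured."""
        if self.S is not None:
            return ZSaturationParams(S=self.S, k=self.k, anchor_let=self.anchor_let)
        from .datasets import load_z_letu_calibration
        from .fitting import ZSaturationModel

        cal = load_z_letu_calibration()
        model = ZSaturationModel(cal["z"], cal["let_u"], anchor_let=self.anchor_let)
        res = model.fit()
        return ZSaturationModel.results_to_params(res)

    def alpha_params(self) -> AlphaSaturationParams:
        if self.alpha_mode == "linear":
            return AlphaSaturationParams(mode="linear", c=self.alpha_c)
        return AlphaSaturationParams(mode="nonlinear", A=self.A, j=self.j)

    def beta_params(self) -> BetaSaturationParams:
        if self.beta_mode == "linear":
            # a linear beta mode mirrors the alpha linear form; reuse R as slope
            return BetaSaturationParams(mode="linear", c=self.R)
        return BetaSaturationParams(mode=self.beta_mode, R=self.R, u=self.u)

    def log_constants(self) -> None:
        """Echo every constant actually in use, once, for auditability."""
        items = ", ".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        logger.info("model constants: %s", items)


def load_config(path=None, overrides: dict | None = None) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML/JSON file, applying defaults.

    Unknown keys raise a ``ValueError`` naming every offending key; invalid
    values raise with the offending field named by the parameter type.
    """
    data: dict = {}
    source = "defaults"
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
        source = str(path)
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(ModelConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    cfg = ModelConfig(**data)
    logger.info("config loaded from %s (absent keys defaulted)", source)
    return cfg
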
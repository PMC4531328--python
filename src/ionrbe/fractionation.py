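"""Iso-effective fractionation via biologically effective dose (BED).

A low-LET schedule of n fractions of d_L Gy has BED = n d_L (1 + d_L/(a/b)_L).
The iso-effective high-LET dose per fraction d_H over m fractions solves

    n d_L (1 + d_L/(a/b)_L)  =  m d_H [RBE_max + RBE_min^2 d_H / (a/b)_L]

— the standard high-LET BED form, in which RBE_max = alpha_H/alpha_L scales
the linear (alpha) term and RBE_min^2 = beta_H/beta_L the quadratic (beta)
term of the reference tissue.  Because high-LET radiation raises alpha far
more than beta, high-LET treatments show much less fractionation sparing:
total iso-effective dose varies only weakly with the number of fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .rbe import RBELimits

__all__ = ["Schedule", "bed_low", "solve_high_let_dose", "isoeffect_table"]


@dataclass(frozen=True)
class Schedule:
    """A fractionation schedule against a low-LET reference tissue.

    n fractions of d Gy; ab_ratio is the tissue's low-LET alpha/beta (Gy).
    """

    n: int
    d: float
    ab_ratio: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not (self.d > 0):
            raise ValueError(f"dose per fraction must be positive, got {self.d}")
        if not (self.ab_ratio > 0):
            raise ValueError(f"alpha/beta ratio must be positive, got {self.ab_ratio}")

    @property
    def total_dose(self) -> float:
        return self.n * self.d


def bed_low(s: Schedule) -> float:
    """BED (Gy) of a low-LET schedule: n d (1 + d/(a/b))."""
    return s.n * s.d * (1.0 + s.d / s.ab_ratio)


def solve_high_let_dose(
    bed: float, m: int, limits: RBELimits, ab_ratio: float
) -> float:
    """High-LET dose per fraction (Gy) delivering ``bed`` in ``m`` fractions.

    Positive root of (m RBE_min^2 / (a/b)) d^2 + m RBE_max d - bed = 0.
    """
    if not (bed > 0):
        raise ValueError(f"bed must be positive, got {bed}")
    if not (m >= 1):
        raise ValueError(f"m must be >= 1, got {m}")
    if not (ab_ratio > 0):
        raise ValueError(f"alpha/beta ratio must be positive, got {ab_ratio}")
    a = m * limits.rbe_min**2 / ab_ratio
    b = m * limits.rbe_max
    if a == 0 and b == 0:
        raise ValueError("no solution: rbe_max and rbe_min both zero")
    if a == 0:
        return bed / b
    return (-b + math.sqrt(b * b + 4.0 * a * bed)) / (2.0 * a)


def isoeffect_table(
    reference: Schedule, m_values: Iterable[int], limits: RBELimits
) -> pd.DataFrame:
    """Iso-effective high-LET schedules matching a low-LET reference.

    For each fraction number m, solves for the dose per fraction d_h giving
    the reference BED.  Columns: ``m, d_h, total_dose``.
    """
    bed = bed_low(reference)
    rows = []
    for m in m_values:
        d_h = solve_high_let_dose(bed, m, limits, reference.ab_ratio)
        rows.append({"m": m, "d_h": d_h, "total_dose": m * d_h})
    return pd.DataFrame(rows)
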
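"""Packaged calibration data.

The (Z, LET_U) calibration table holds the four turnover-LET estimates with
unequivocal experimental support — protons (30.5 keV/um), helium (103.4),
carbon (208) and neon (233) — pooled from the classic clonogenic-survival
datasets.  These four points calibrate the charge -> turnover-LET relation;
heavier ions (silicon, argon) are excluded because their published turnover
positions are not accurate enough.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_z_letu_calibration"]


def load_z_letu_calibration() -> pd.DataFrame:
    """The packaged four-point (z, let_u) calibration table."""
    with resources.files("ionrbe.data").joinpath("z_letu_calibration.csv").open() as fh:
        return pd.read_csv(fh)
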
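"""Chlorella biomass from optical density and growth-series summaries.

OD at 680 nm tracks chlorophyll and hence Chlorella biomass; a wet-weight
calibration line converts readings to mg/L.  The default line
(slope 4021.9 mg/L per OD unit, intercept -8.6817 mg/L) can be overridden
for other strains or instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cld import tukey_letters

__all__ = ["BiomassCalibration", "od_to_biomass", "biomass_series"]


@dataclass(frozen=True)
class BiomassCalibration:
    """Linear OD680 -> biomass (mg/L) calibration; fit_r2 is metadata."""

    slope: float = 4021.9
    intercept: float = -8.6817
    fit_r2: float = 0.9995

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


DEFAULT_CALIBRATION = BiomassCalibration()


def od_to_biomass(od, cal: BiomassCalibration = DEFAULT_CALIBRATION):
    """Convert OD680 to biomass (mg/L): slope * od + intercept.

    Negative OD is a domain error.  Predictions below zero (OD below the
    calibration's valid range, where the fitted intercept dips negative)
    are clipped to 0 with a warning.
    """
    arr = np.asarray(od, dtype=float)
    if (arr < 0).any():
        raise ValueError("OD680 must be >= 0")
    biomass = cal.slope * arr + cal.intercept
    if (biomass < 0).any():
        warnings.warn(
            "OD below calibration range; negative biomass clipped to 0",
            stacklevel=2,
        )
        biomass = np.clip(biomass, 0.0, None)
    return float(biomass) if np.isscalar(od) else biomass


def biomass_series(
    od_series: pd.DataFrame,
    cal: BiomassCalibration = DEFAULT_CALIBRATION,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Convert an OD series and compare systems on the final day.

    Returns ``(biomass_table, letters)`` where the table has columns
    (system, day, replicate, biomass_mg_per_L) and ``letters`` is the
    compact letter display of a one-way ANOVA + Tukey HSD on the final-day
    biomass (empty when any system has fewer than 2 replicates).
    """
    out = od_series[["system", "day", "replicate"]].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["biomass_mg_per_L"] = od_to_biomass(
            od_series["od680"].to_numpy(), cal
        )
    final = out[out["day"] == out["day"].max()]
    sizes = final.groupby("system").size()
    letters: dict = {}
    if len(sizes) >= 2 and (sizes >= 2).all():
        letters = tukey_letters(
            final["biomass_mg_per_L"].to_numpy(),
            final["system"].to_numpy(),
            alpha=alpha,
        )
    return out, letters
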
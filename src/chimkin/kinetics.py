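"""Kinetic predictors over consecutive chimerism measurements.

Relapse after transplantation announces itself as growth of the recipient
fraction over time, so the change between two consecutive measurements
``Ct1`` (at ``t1`` days post-transplant) and ``Ct2`` (at ``t2``) is more
informative than either absolute value. Four predictors are computed:

* ``delta_c = Ct2 - Ct1`` — absolute change in percentage points;
* ``rate = delta_c / delta_t`` — change per day;
* ``ratio = Ct2 / Ct1`` — fold change;
* ``icf = (Ct2/Ct1) ** (1/delta_t)`` — the increment factor, the per-day
  geometric growth factor implied by the fold change.

Censored measurements enter the arithmetic at their reporting floor (0.8%
for STR, 0.36% for SNP-NGS), which also keeps ``Ct1 > 0`` so the ratio and
increment factor are defined.

Pairs are classified into the groups used for relapse prediction:
``CH`` (change in chimerism: negative at t1, positive at t2), ``NC`` (no
change: negative at both), and excluded categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = ["PairRecord", "KineticPredictors", "PairClass",
           "compute_predictors", "classify_pair", "predictors_table"]


@dataclass(frozen=True)
class PairRecord:
    """Two consecutive chimerism measurements of one patient."""

    ct1: float
    ct2: float
    t1: int
    t2: int
    relapse: bool = False

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError("t2 must be after t1")
        if self.ct1 < 0 or self.ct2 < 0:
            raise ValueError("chimerism values cannot be negative")


@dataclass(frozen=True)
class KineticPredictors:
    delta_c: float   # percentage points
    delta_t: float   # days
    rate: float      # percentage points per day
    ratio: float     # fold change, dimensionless
    icf: float       # per-day geometric increment factor


class PairClass(str, Enum):
    CH = "CH"                 # negative -> positive: change in chimerism
    NC = "NC"                 # negative -> negative: no change
    EXCLUDED_DECREASING = "excluded_decreasing"
    EXCLUDED_OTHER = "excluded_other"  # established positive chimerism at t1


def compute_predictors(pair: PairRecord) -> KineticPredictors:
    """All four kinetic predictors for one consecutive pair.

    ``Ct1`` must be positive for the ratio and increment factor; censored
    values should be supplied at their reporting floor.
    """
    delta_t = pair.t2 - pair.t1
    delta_c = pair.ct2 - pair.ct1
    if pair.ct1 <= 0:
        raise ValueError(
            "Ct1 must be positive for ratio/ICF; substitute the assay floor "
            "for censored values"
        )
    ratio = pair.ct2 / pair.ct1
    icf = ratio ** (1.0 / delta_t)
    return KineticPredictors(
        delta_c=delta_c,
        delta_t=float(delta_t),
        rate=delta_c / delta_t,
        ratio=ratio,
        icf=icf,
    )


def classify_pair(ct1: float, ct2: float, str_floor: float = 0.8) -> PairClass:
    """Assign a consecutive pair to the CH/NC relapse-prediction groups.

    Values are on the STR scale: at or below the floor means complete
    chimerism (negative). Decreasing pairs that start positive are excluded
    from the groups, as are pairs positive at both time points.
    """
    neg1, neg2 = ct1 <= str_floor, ct2 <= str_floor
    if neg1 and not neg2:
        return PairClass.CH
    if neg1 and neg2:
        return PairClass.NC
    if ct2 < ct1:
        return PairClass.EXCLUDED_DECREASING
    return PairClass.EXCLUDED_OTHER


def predictors_table(
    pairs: pd.DataFrame,
    ct1_col: str,
    ct2_col: str,
    interval_col: str = "interval_days",
) -> pd.DataFrame:
    """Vectorized predictors for a table of consecutive pairs.

    Returns a copy of *pairs* with ``delta_c, delta_t, rate, ratio, icf``
    columns appended, computed from the named value columns.
    """
    out = pairs.copy()
    ct1, ct2 = out[ct1_col], out[ct2_col]
    dt = out[interval_col].astype(float)
    if (dt <= 0).any():
        raise ValueError("all intervals must be positive")
    if (ct1 <= 0).any():
        raise ValueError("Ct1 must be positive (use assay floors for censored values)")
    out["delta_c"] = ct2 - ct1
    out["delta_t"] = dt
    out["rate"] = out["delta_c"] / dt
    out["ratio"] = ct2 / ct1
    out["icf"] = out["ratio"] ** (1.0 / dt)
    return out
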
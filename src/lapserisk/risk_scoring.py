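"""Dichotomized risk indicators, the 0-6 count score, and the weighted
linear lapse-risk score.

Six momentary risk factors are dichotomized from each EMA: agreeing or
strongly agreeing to urge and stress (response ≥ 4), disagreeing or strongly
disagreeing with commitment to staying smoke free (motivation ≤ 2),
cigarettes fairly easily / easily available (≥ 4), and the two binary items
pass through.  The unweighted estimator is the count of factors present
(0-6).  The weighted estimator centers each ordinal at 3 (neutral / "with
difficulty") and applies fixed coefficients:

    risk = 0.2·(urge−3) + 0.2·(stress−3) + 0.7·(availability−3)
           + 1·[interacting with a smoker] + 1·[alcohol past hour]
           − 0.2·(motivation−3)

Over all 5⁴·2² = 2,500 response profiles the default weighted score spans
[−2.6, 4.6].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .ema_model import EmaRecord

__all__ = ["RiskIndicators", "RiskWeights", "dichotomize",
           "unweighted_score", "weighted_score", "score_analysis_set",
           "feature_matrix", "indicator_matrix", "enumerate_profiles",
           "score_extrema"]


@dataclass(frozen=True)
class RiskIndicators:
    """The six dichotomized lapse-risk factors for one EMA."""

    urge_high: bool
    stress_high: bool
    motivation_low: bool
    cigs_available: bool
    interacting_smoker: bool
    alcohol_recent: bool

    def as_tuple(self) -> tuple[bool, ...]:
        return (self.urge_high, self.stress_high, self.motivation_low,
                self.cigs_available, self.interacting_smoker,
                self.alcohol_recent)


@dataclass(frozen=True)
class RiskWeights:
    """Centering offset and coefficients of the weighted linear score.

    Defaults reproduce the published formula exactly; ``motivation`` is
    protective and always enters with a minus sign, so its coefficient is
    kept non-negative.
    """

    offset: float = 3.0
    urge: float = 0.2
    stress: float = 0.2
    motivation: float = 0.2
    availability: float = 0.7
    smoker_present: float = 1.0
    alcohol: float = 1.0

    def __post_init__(self):
        vec = (self.offset, self.urge, self.stress, self.motivation,
               self.availability, self.smoker_present, self.alcohol)
        if not all(np.isfinite(vec)):
            raise ValueError("weights must be finite")
        if self.motivation < 0:
            raise ValueError("motivation coefficient must be non-negative "
                             "(it always enters with a minus sign)")

    def as_vector(self) -> np.ndarray:
        """Coefficients in feature-matrix order (see :func:`feature_matrix`)."""
        return np.array([self.urge, self.stress, self.availability,
                         self.smoker_present, self.alcohol, self.motivation])


def dichotomize(record: EmaRecord) -> RiskIndicators:
    """Dichotomize one EMA's items into the six risk indicators."""
    return RiskIndicators(
        urge_high=record.urge >= 4,
        stress_high=record.stress >= 4,
        motivation_low=record.motivation <= 2,
        cigs_available=record.availability >= 4,
        interacting_smoker=record.interacting_smoker,
        alcohol_recent=record.alcohol_past_hour,
    )


def unweighted_score(ind: RiskIndicators) -> int:
    """Count of risk factors present, 0-6."""
    return int(sum(ind.as_tuple()))


def weighted_score(record: EmaRecord,
                   weights: RiskWeights = RiskWeights()) -> float:
    """Weighted linear lapse-risk score of one EMA."""
    w = weights
    return (w.urge * (record.urge - w.offset)
            + w.stress * (record.stress - w.offset)
            + w.availability * (record.availability - w.offset)
            + w.smoker_present * record.interacting_smoker
            + w.alcohol * record.alcohol_past_hour
            - w.motivation * (record.motivation - w.offset))


# -- vectorized scoring -----------------------------------------------------

def feature_matrix(df: pd.DataFrame, offset: float = 3.0) -> np.ndarray:
    """(n, 6) signed design matrix of the weighted score.

    Columns: urge−offset, stress−offset, availability−offset,
    interacting_smoker, alcohol_past_hour, −(motivation−offset) — so any
    non-negative coefficient vector yields a risk-increasing score via a
    plain dot product.
    """
    return np.column_stack([
        df["urge"].to_numpy(float) - offset,
        df["stress"].to_numpy(float) - offset,
        df["availability"].to_numpy(float) - offset,
        df["interacting_smoker"].to_numpy(float),
        df["alcohol_past_hour"].to_numpy(float),
        -(df["motivation"].to_numpy(float) - offset),
    ])


def indicator_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 6) boolean indicator matrix in RiskIndicators field order."""
    return np.column_stack([
        df["urge"].to_numpy() >= 4,
        df["stress"].to_numpy() >= 4,
        df["motivation"].to_numpy() <= 2,
        df["availability"].to_numpy() >= 4,
        df["interacting_smoker"].to_numpy(bool),
        df["alcohol_past_hour"].to_numpy(bool),
    ])


def score_analysis_set(records: pd.DataFrame,
                       weights: Optional[RiskWeights] = RiskWeights()
                       ) -> pd.DataFrame:
    """Append ``n_risk_factors`` and (if weights given)
    ``weighted_risk_score`` columns to a labeled record table.

    Rows with any of the six items missing are dropped with a logged count
    (item-level missingness cannot be scored); order is otherwise preserved.
    """
    out = records.copy()
    item_cols = ["urge", "stress", "motivation", "availability",
                 "interacting_smoker", "alcohol_past_hour"]
    missing = out[item_cols].isna().any(axis=1)
    if missing.any():
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d record(s) with missing items", int(missing.sum()))
        out = out.loc[~missing]
    if out.empty:
        out["n_risk_factors"] = pd.Series(dtype="int64")
        if weights is not None:
            out["weighted_risk_score"] = pd.Series(dtype=float)
        return out
    out["n_risk_factors"] = indicator_matrix(out).sum(axis=1).astype("int64")
    if weights is not None:
        out["weighted_risk_score"] = (
            feature_matrix(out, weights.offset) @ weights.as_vector())
    return out


# -- exhaustive enumeration -------------------------------------------------

def enumerate_profiles() -> pd.DataFrame:
    """All 5⁴·2² = 2,500 response profiles as an item table."""
    rows = list(product(range(1, 6), range(1, 6), range(1, 6), range(1, 6),
                        (False, True), (False, True)))
    return pd.DataFrame(rows, columns=["urge", "stress", "motivation",
                                       "availability", "interacting_smoker",
                                       "alcohol_past_hour"])


def score_extrema(weights: RiskWeights = RiskWeights()
                  ) -> tuple[float, float]:
    """(min, max) of the weighted score over every response profile."""
    scores = feature_matrix(enumerate_profiles(),
                            weights.offset) @ weights.as_vector()
    return float(scores.min()), float(scores.max())
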
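"""Lapse-proximity windowing: mark the first lapse, keep pre-lapse EMAs,
and label each retained EMA by proximity class.

Every post-quit EMA gets exactly one label: for lapsers, records within the
look-ahead window before the first lapse (default 4 h, closed at both ends)
are ``WITHIN_4H``, earlier ones ``PRE_LAPSE_OVER_4H``, and records at or
after the lapse instant are excluded (the lapse-report EMA itself is not a
predictor observation).  All records of participants who never lapsed are
``ABSTAINER``; participants flagged as inconsistent reporters are excluded
wholesale.  Only the first three labels enter analyses.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ema_model import CohortTable, EmaRecord, Participant

__all__ = ["ProximityLabel", "WindowConfig", "label_proximity",
           "build_analysis_set", "RETAINED_LABELS"]

logger = logging.getLogger(__name__)


class ProximityLabel(str, enum.Enum):
    WITHIN_4H = "WITHIN_4H"
    PRE_LAPSE_OVER_4H = "PRE_LAPSE_OVER_4H"
    ABSTAINER = "ABSTAINER"
    EXCLUDED_POST_LAPSE = "EXCLUDED_POST_LAPSE"
    EXCLUDED_INCONSISTENT = "EXCLUDED_INCONSISTENT"


RETAINED_LABELS = (ProximityLabel.WITHIN_4H, ProximityLabel.PRE_LAPSE_OVER_4H,
                   ProximityLabel.ABSTAINER)


@dataclass(frozen=True)
class WindowConfig:
    """Look-ahead window defining an imminent lapse (default 4 hours)."""

    window_hours: float = 4.0

    def __post_init__(self):
        if not self.window_hours > 0:
            raise ValueError("window_hours must be positive")

    @property
    def window(self) -> pd.Timedelta:
        return pd.Timedelta(hours=self.window_hours)


def label_proximity(record: EmaRecord, participant: Participant,
                    config: WindowConfig = WindowConfig()) -> ProximityLabel:
    """Proximity label for a single EMA.

    The boundary ``lapse − t == window`` counts as WITHIN_4H; an EMA
    time-stamped exactly at the lapse instant counts as post-lapse.
    """
    if record.participant_id != participant.participant_id:
        raise ValueError("record does not belong to participant")
    if pd.isna(record.timestamp) or pd.isna(participant.quit_time):
        raise ValueError("missing timestamp")
    if not participant.consistent_reporting:
        return ProximityLabel.EXCLUDED_INCONSISTENT
    if not participant.lapsed:
        return ProximityLabel.ABSTAINER
    lapse = participant.first_lapse_time
    if record.timestamp >= lapse:
        return ProximityLabel.EXCLUDED_POST_LAPSE
    if lapse - record.timestamp <= config.window:
        return ProximityLabel.WITHIN_4H
    return ProximityLabel.PRE_LAPSE_OVER_4H


def build_analysis_set(cohort: CohortTable,
                       config: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Label every EMA and return only the retained (analyzable) records.

    Returns the EMA table restricted to WITHIN_4H / PRE_LAPSE_OVER_4H /
    ABSTAINER records with a ``proximity_label`` column appended; original
    row order is preserved.  Records time-stamped before the quit time are
    dropped with a logged warning (a pre-quit observation week is outside
    this analysis).  Per-label counts are logged and attached as
    ``df.attrs["label_counts"]`` (the retained + excluded counts sum to the
    input record count).
    """
    ema = cohort.ema.copy()
    roster = cohort.roster.set_index("participant_id")
    if ema.empty:
        out = ema.assign(proximity_label=pd.Series(dtype=object))
        out.attrs["label_counts"] = {}
        return out

    quit_time = roster["quit_time"].reindex(ema["participant_id"]).to_numpy()
    lapse_time = roster["first_lapse_time"].reindex(
        ema["participant_id"]).to_numpy()
    consistent = roster["consistent_reporting"].reindex(
        ema["participant_id"]).to_numpy().astype(bool)
    t = ema["timestamp"].to_numpy()
    if pd.isna(t).any() or pd.isna(quit_time).any():
        raise ValueError("missing timestamp in EMA table or roster")

    prequit = t < quit_time
    lapsed = ~pd.isna(lapse_time)
    window = config.window.to_timedelta64()

    labels = np.empty(len(ema), dtype=object)
    labels[:] = ProximityLabel.ABSTAINER.value
    labels[lapsed & (t >= lapse_time)] = \
        ProximityLabel.EXCLUDED_POST_LAPSE.value
    within = lapsed & (t < lapse_time) & ((lapse_time - t) <= window)
    over = lapsed & (t < lapse_time) & ((lapse_time - t) > window)
    labels[within] = ProximityLabel.WITHIN_4H.value
    labels[over] = ProximityLabel.PRE_LAPSE_OVER_4H.value
    labels[~consistent] = ProximityLabel.EXCLUDED_INCONSISTENT.value

    n_prequit = int(prequit.sum())
    if n_prequit:
        logger.warning("dropping %d pre-quit EMA record(s)", n_prequit)

    keep = ~prequit
    counts = {"input": len(ema), "pre_quit_dropped": n_prequit}
    for lab in ProximityLabel:
        counts[lab.value] = int((labels[keep] == lab.value).sum())
    logger.info("proximity label counts: %s", counts)

    retained = keep & np.isin(labels.astype(str),
                              [lab.value for lab in RETAINED_LABELS])
    out = ema.loc[retained].copy()
    out["proximity_label"] = labels[retained].astype(str)
    out.attrs["label_counts"] = counts
    return out
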
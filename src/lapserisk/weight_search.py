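"""Exhaustive grid search over risk-factor weights.

The weighted estimator's coefficients were found by iterating over candidate
weights per factor and keeping the combination that best separates
imminent-lapse EMAs (within the look-ahead window) from all other retained
EMAs.  This module reproduces that procedure as a deterministic Cartesian
grid search: for each candidate weight vector the score is evaluated on
every record, and the objective is either the best Youden index J =
sensitivity + specificity − 1 over a cut-off grid (default: all midpoints
between adjacent observed scores) or the AUC.

Flagging convention is strict: a record is flagged when score > cutoff.  A
reported "cut-off of c" under the ≥ convention therefore corresponds to a
strict threshold just below c (see :func:`ge_cutoff`).

Ties on the objective are broken deterministically: smallest L1 norm of the
coefficient vector, then lexicographic order of the coefficient tuple.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lapse_windowing import ProximityLabel
from .risk_scoring import RiskWeights, feature_matrix

__all__ = ["SearchConfig", "SearchResult", "Objective", "grid_search",
           "evaluate_weights", "positive_mask", "ge_cutoff"]

#: Tolerance below which two objective values count as tied.
_TIE_TOL = 1e-9

#: Offset used to express a ">= c" cut-off as a strict threshold.
_GE_EPS = 1e-9


class Objective(str, enum.Enum):
    YOUDEN_MAX_OVER_CUTOFFS = "youden_max_over_cutoffs"
    AUC = "auc"


@dataclass(frozen=True)
class SearchConfig:
    """Grids and objective of the weight search.

    ``weight_grid_ordinal`` applies to urge, stress, motivation and
    availability; ``weight_grid_binary`` to the two binary items.  With
    ``cutoff_grid=None`` the Youden objective scans all midpoints between
    adjacent observed scores (plus one cut-off below and above everything).
    """

    weight_grid_ordinal: tuple[float, ...] = tuple(
        round(0.1 * k, 1) for k in range(11))
    weight_grid_binary: tuple[float, ...] = (0.0, 0.5, 1.0)
    objective: Objective = Objective.YOUDEN_MAX_OVER_CUTOFFS
    cutoff_grid: Optional[tuple[float, ...]] = None
    offset: float = 3.0

    def __post_init__(self):
        if not self.weight_grid_ordinal or not self.weight_grid_binary:
            raise ValueError("weight grids must be non-empty")
        if self.cutoff_grid is not None and len(self.cutoff_grid) == 0:
            raise ValueError("cutoff grid must be non-empty when given")


@dataclass(frozen=True)
class SearchResult:
    best_weights: RiskWeights
    best_cutoff: float
    objective_value: float
    n_evaluated: int


def ge_cutoff(c: float) -> float:
    """Strict threshold equivalent to flagging scores ≥ c (for reporting
    against cut-offs stated in the ≥ convention, e.g. "3 or more factors")."""
    return c - _GE_EPS


def positive_mask(records: pd.DataFrame) -> np.ndarray:
    """True for imminent-lapse (within-window) records, False for the other
    retained records."""
    return (records["proximity_label"].to_numpy()
            == ProximityLabel.WITHIN_4H.value)


def evaluate_weights(records: pd.DataFrame, weights: RiskWeights,
                     cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) of a weight vector at a strict cut-off.

    Sensitivity = fraction of within-window records with score > cutoff;
    specificity = fraction of other retained records with score ≤ cutoff.
    """
    y = positive_mask(records)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    s = feature_matrix(records, weights.offset) @ weights.as_vector()
    flagged = s > cutoff
    sens = float(flagged[y].mean())
    spec = float((~flagged[~y]).mean())
    return sens, spec


def _youden_scan(scores: np.ndarray, y: np.ndarray,
                 cutoffs: Optional[Sequence[float]]
                 ) -> tuple[float, float]:
    """(best J, best cutoff) over the cut-off grid for one score vector."""
    if cutoffs is None:
        u = np.unique(scores)
        mids = (u[:-1] + u[1:]) / 2.0
        cutoffs = np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])
    cutoffs = np.asarray(cutoffs, float)
    flagged = scores[:, None] > cutoffs[None, :]
    sens = flagged[y].mean(axis=0)
    spec = (~flagged[~y]).mean(axis=0)
    j = sens + spec - 1.0
    k = int(np.argmax(j))
    return float(j[k]), float(cutoffs[k])


def _youden_batch(S: np.ndarray, pos_w: np.ndarray,
                  neg_w: np.ndarray) -> np.ndarray:
    """Best Youden J per column of the (m, B) score matrix, scanning all
    midpoints between adjacent observed scores (vectorized sort/cumsum).

    Rows are distinct observations (e.g. unique response profiles) carrying
    ``pos_w``/``neg_w`` counts of positive and negative records."""
    n_pos = pos_w.sum()
    n_neg = neg_w.sum()
    order = np.argsort(S, axis=0, kind="stable")
    s_sorted = np.take_along_axis(S, order, axis=0)
    cpos = np.cumsum(pos_w[order], axis=0)
    cneg = np.cumsum(neg_w[order], axis=0)
    # cutting between rows i and i+1: flag rows above i
    sens = (n_pos - cpos) / n_pos
    spec = cneg / n_neg
    j = sens + spec - 1.0
    # a cut inside a run of tied scores is not a realizable threshold
    tied = s_sorted[:-1] == s_sorted[1:]
    j[:-1][tied] = -np.inf
    # cut below all scores gives J = 0
    return np.maximum(j.max(axis=0), 0.0)


def _auc_column(scores: np.ndarray, y: np.ndarray) -> float:
    from .evaluation import auc_rank
    return auc_rank(scores, y)


def _weights_from_tuple(t: Sequence[float], offset: float) -> RiskWeights:
    wu, ws, wm, wa, wsm, wal = t
    return RiskWeights(offset=offset, urge=wu, stress=ws, motivation=wm,
                       availability=wa, smoker_present=wsm, alcohol=wal)


def grid_search(records: pd.DataFrame,
                config: SearchConfig = SearchConfig(),
                return_trace: bool = False):
    """Exhaustively evaluate the Cartesian weight grid and return the
    maximizer of the configured objective.

    Deterministic: identical input and config always yield the same
    :class:`SearchResult`, including under objective ties (smallest L1 norm,
    then lexicographically smallest coefficient tuple, wins).  With
    ``return_trace=True`` also returns the full grid trace as a DataFrame
    (one row per weight vector with its objective value).
    """
    y = positive_mask(records)
    if y.all() or not y.any():
        raise ValueError("grid search needs both classes present")

    go = list(config.weight_grid_ordinal)
    gb = list(config.weight_grid_binary)
    # coefficient tuple order: urge, stress, motivation, availability,
    # smoker_present, alcohol
    combos = list(itertools.product(go, go, go, go, gb, gb))
    n_eval = len(combos)
    # feature-matrix column order: urge, stress, availability, smoker,
    # alcohol, motivation
    W = np.array([(wu, ws, wa, wsm, wal, wm)
                  for (wu, ws, wm, wa, wsm, wal) in combos])
    X = feature_matrix(records, config.offset)

    # records collapse onto at most 5^4·2^2 distinct response profiles, so
    # the scan runs on unique profiles weighted by class counts
    Xu, inverse = np.unique(X, axis=0, return_inverse=True)
    pos_w = np.bincount(inverse[y], minlength=len(Xu)).astype(float)
    neg_w = np.bincount(inverse[~y], minlength=len(Xu)).astype(float)

    batch = max(1, int(5_000_000 // max(len(Xu), 1)))
    use_youden = config.objective is Objective.YOUDEN_MAX_OVER_CUTOFFS
    all_vals = np.empty(n_eval)
    for start in range(0, n_eval, batch):
        Wb = W[start:start + batch]
        if use_youden and config.cutoff_grid is None:
            vals = _youden_batch(Xu @ Wb.T, pos_w, neg_w)
        elif use_youden:
            S = X @ Wb.T
            vals = np.array([_youden_scan(S[:, k], y, config.cutoff_grid)[0]
                             for k in range(S.shape[1])])
        else:
            S = X @ Wb.T
            vals = np.array([_auc_column(S[:, k], y)
                             for k in range(S.shape[1])])
        all_vals[start:start + len(vals)] = vals

    # ties on the objective: smallest L1 norm of the coefficient tuple wins,
    # then the lexicographically smallest tuple
    tied = np.flatnonzero(all_vals >= all_vals.max() - _TIE_TOL)
    best_idx = min(tied, key=lambda i: (sum(abs(c) for c in combos[i]),
                                        combos[i]))
    weights = _weights_from_tuple(combos[best_idx], config.offset)
    scores = X @ W[best_idx]
    if use_youden:
        obj, cutoff = _youden_scan(scores, y, config.cutoff_grid)
        obj = max(obj, 0.0) if config.cutoff_grid is None else obj
    else:
        obj = _auc_column(scores, y)
        # operating cut-off reported at the best Youden point for reference
        _, cutoff = _youden_scan(scores, y, None)
    result = SearchResult(best_weights=weights, best_cutoff=float(cutoff),
                          objective_value=float(obj), n_evaluated=n_eval)
    if return_trace:
        trace = pd.DataFrame(combos, columns=["urge", "stress", "motivation",
                                              "availability",
                                              "smoker_present", "alcohol"])
        trace["objective"] = all_vals
        return result, trace
    return result
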
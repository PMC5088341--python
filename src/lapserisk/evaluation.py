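"""Evaluation of lapse-risk estimators.

Covers the full reporting battery: class-conditional risk-factor prevalence
tables, mixed-model group comparisons with a seeded permutation fallback,
operating points (sensitivity/specificity at a cut-off), ROC curves, AUC
with a 95% CI from the asymptotic variance of the rank statistic (DeLong
placements), a paired correlated-ROC comparison of two estimators scored on
the same records (structural-components test, with a seeded paired
bootstrap as an alternative), and participant-level detection (fraction of
lapsers with at least one flagged EMA inside the look-ahead window).

The AUC is the rank (Mann-Whitney) statistic with ties counted 1/2, which
equals the trapezoidal area under the empirical ROC curve.  Records are
treated as independent observations, ignoring within-participant
clustering; :func:`cluster_bootstrap_auc_ci` resamples participants instead
as a sensitivity option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .lapse_windowing import ProximityLabel
from .risk_scoring import indicator_matrix
from .weight_search import ge_cutoff, positive_mask

__all__ = [
    "RocCurve", "EvalReport", "auc_rank", "delong_variance", "roc_and_auc",
    "compare_auc", "prevalence_table", "group_compare",
    "participant_detection", "operating_point", "evaluate",
    "cluster_bootstrap_auc_ci", "FACTOR_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Indicator column names in the canonical reporting order.
FACTOR_COLUMNS = ("urge_high", "stress_high", "motivation_low",
                  "cigs_available", "alcohol_recent", "interacting_smoker")

_CLASS_ORDER = (ProximityLabel.WITHIN_4H.value,
                ProximityLabel.PRE_LAPSE_OVER_4H.value,
                ProximityLabel.ABSTAINER.value)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: thresholds (decreasing) with the corresponding
    cumulative true- and false-positive rates (both non-decreasing)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpr, self.fpr))


# -- AUC --------------------------------------------------------------------

def _check_two_class(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation, ties counted 1/2."""
    y = _check_two_class(labels)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(scores: np.ndarray, y: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: for each positive, the fraction of
    negatives it beats (ties 1/2), and symmetrically for each negative."""
    pos = np.asarray(scores, float)[y]
    neg = np.asarray(scores, float)[~y]
    order = np.argsort(neg, kind="stable")
    neg_sorted = neg[order]
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    order_p = np.argsort(pos, kind="stable")
    pos_sorted = pos[order_p]
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / len(pos)
    return v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """Asymptotic variance of the rank AUC (DeLong)."""
    y = _check_two_class(labels)
    v10, v01 = _placements(scores, y)
    n1, n0 = len(v10), len(v01)
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def roc_and_auc(scores: np.ndarray, labels: np.ndarray,
                alpha: float = 0.05
                ) -> tuple[RocCurve, float, tuple[float, float]]:
    """ROC curve, rank AUC, and its 95% (or 1−alpha) asymptotic CI."""
    y = _check_two_class(labels)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), np.asarray(scores, float),
                                  drop_intermediate=False)
    curve = RocCurve(thresholds=thr, tpr=tpr, fpr=fpr)
    auc = auc_rank(scores, y)
    se = float(np.sqrt(delong_variance(scores, y)))
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return curve, auc, (lo, hi)


def compare_auc(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray, method: str = "delong",
                n_boot: int = 2000, seed: int = 0) -> dict:
    """Paired comparison of two estimators' AUCs on the same records.

    ``method='delong'`` uses the correlated-ROC structural-components test;
    ``method='bootstrap'`` uses a seeded paired bootstrap over records.
    Returns ``{'auc_a', 'auc_b', 'diff', 'p_value', 'method'}``.
    """
    y = _check_two_class(labels)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("score vectors must cover the same records")
    auc_a = auc_rank(a, y)
    auc_b = auc_rank(b, y)
    diff = auc_a - auc_b

    if method == "delong":
        va10, va01 = _placements(a, y)
        vb10, vb01 = _placements(b, y)
        n1, n0 = len(va10), len(va01)
        if n1 > 1 and n0 > 1:
            cov10 = np.cov(va10, vb10, ddof=1)
            cov01 = np.cov(va01, vb01, ddof=1)
            var = (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / n1 \
                + (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n0
        else:
            var = 0.0
        if var <= 0:
            p = 1.0 if abs(diff) < 1e-12 else 0.0
        else:
            z = diff / np.sqrt(var)
            p = float(2 * (1 - ndtr(abs(z))))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(y)
        diffs = np.empty(n_boot)
        k = 0
        while k < n_boot:
            idx = rng.integers(0, n, n)
            yk = y[idx]
            if yk.all() or not yk.any():
                continue  # degenerate resample: redraw
            diffs[k] = auc_rank(a[idx], yk) - auc_rank(b[idx], yk)
            k += 1
        p_lo = (1 + np.sum(diffs <= 0)) / (n_boot + 1)
        p_hi = (1 + np.sum(diffs >= 0)) / (n_boot + 1)
        p = float(min(1.0, 2 * min(p_lo, p_hi)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff,
            "p_value": p, "method": method}


def cluster_bootstrap_auc_ci(scored: pd.DataFrame, score_col: str,
                             n_boot: int = 2000, seed: int = 0,
                             alpha: float = 0.05) -> tuple[float, float]:
    """Percentile CI for the AUC resampling participants (clusters) rather
    than records — a sensitivity analysis for within-person clustering."""
    rng = np.random.default_rng(seed)
    pids = scored["participant_id"].unique()
    groups = {p: g for p, g in scored.groupby("participant_id")}
    aucs = []
    while len(aucs) < n_boot:
        take = rng.choice(pids, size=len(pids), replace=True)
        df = pd.concat([groups[p] for p in take], ignore_index=True)
        y = positive_mask(df)
        if y.all() or not y.any():
            continue
        aucs.append(auc_rank(df[score_col].to_numpy(), y))
    return (float(np.quantile(aucs, alpha / 2)),
            float(np.quantile(aucs, 1 - alpha / 2)))


# -- tables and operating points -------------------------------------------

def _with_indicators(scored: pd.DataFrame) -> pd.DataFrame:
    df = scored.copy()
    ind = indicator_matrix(df)
    # indicator_matrix order: urge, stress, motivation, availability,
    # smoker, alcohol
    df["urge_high"] = ind[:, 0]
    df["stress_high"] = ind[:, 1]
    df["motivation_low"] = ind[:, 2]
    df["cigs_available"] = ind[:, 3]
    df["interacting_smoker_ind"] = ind[:, 4]
    df["alcohol_recent"] = ind[:, 5]
    return df


def prevalence_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Risk-factor prevalence (%) and mean factor count by proximity class.

    One row per proximity class actually present (an empty class is absent,
    not reported as zero), with per-factor percentages, the mean and SD of
    the factor count, and the record count.
    """
    df = _with_indicators(scored)
    if "n_risk_factors" not in df.columns:
        df["n_risk_factors"] = indicator_matrix(df).sum(axis=1)
    rows = []
    for cls in _CLASS_ORDER:
        sub = df[df["proximity_label"] == cls]
        if sub.empty:
            continue
        row = {"proximity_label": cls, "n_records": len(sub)}
        for name, col in (("urge", "urge_high"), ("stress", "stress_high"),
                          ("low_motivation", "motivation_low"),
                          ("availability", "cigs_available"),
                          ("alcohol", "alcohol_recent"),
                          ("smoker_interaction", "interacting_smoker_ind")):
            row[name + "_pct"] = 100.0 * float(sub[col].mean())
        row["mean_risk_factors"] = float(sub["n_risk_factors"].mean())
        row["sd_risk_factors"] = float(sub["n_risk_factors"].std(ddof=1)) \
            if len(sub) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def operating_point(scored: pd.DataFrame, score_col: str, cutoff: float,
                    ge: bool = False) -> dict:
    """Sensitivity/specificity of one score column at a cut-off.

    ``ge=True`` flags scores ≥ cutoff (the convention in which an integer
    count cut-off of 3 means "3 or more factors"); otherwise strictly >.
    """
    y = _check_two_class(positive_mask(scored))
    thr = ge_cutoff(cutoff) if ge else cutoff
    s = scored[score_col].to_numpy(float)
    flagged = s > thr
    return {"score": score_col, "cutoff": float(cutoff),
            "convention": "ge" if ge else "gt",
            "sensitivity": float(flagged[y].mean()),
            "specificity": float((~flagged[~y]).mean())}


def participant_detection(scored: pd.DataFrame, roster: pd.DataFrame,
                          cutoff: float, score_col: str = "n_risk_factors",
                          ge: bool = False) -> float:
    """Fraction of lapsers with ≥1 flagged EMA inside the look-ahead window.

    The denominator is every consistent-reporting lapser in the roster,
    whether or not they completed an EMA inside the window.
    """
    lapsers = roster[roster["first_lapse_time"].notna()
                     & roster["consistent_reporting"].astype(bool)]
    if lapsers.empty:
        raise ValueError("zero lapsers in roster")
    thr = ge_cutoff(cutoff) if ge else cutoff
    win = scored[(scored["proximity_label"]
                  == ProximityLabel.WITHIN_4H.value)
                 & (scored[score_col] > thr)]
    detected = win["participant_id"].unique()
    return float(len(set(detected) & set(lapsers["participant_id"]))
                 / len(lapsers))


# -- group comparisons ------------------------------------------------------

_CONTRASTS = (
    (ProximityLabel.WITHIN_4H.value, ProximityLabel.PRE_LAPSE_OVER_4H.value),
    (ProximityLabel.WITHIN_4H.value, ProximityLabel.ABSTAINER.value),
    (ProximityLabel.PRE_LAPSE_OVER_4H.value, ProximityLabel.ABSTAINER.value),
)


def _permutation_test(sub: pd.DataFrame, outcome: str, class_a: str,
                      n_permutations: int, rng: np.random.Generator
                      ) -> tuple[float, float]:
    """Seeded permutation contrast of record-level means between two classes.

    Participants appearing in both classes (the within-lapser contrast) have
    their record labels permuted within participant; otherwise the
    participant→class assignment is permuted wholesale.
    """
    y = sub[outcome].to_numpy(float)
    in_a = (sub["proximity_label"] == class_a).to_numpy()
    obs = y[in_a].mean() - y[~in_a].mean()

    by_pid = sub.groupby("participant_id", sort=True)
    pid_classes = by_pid["proximity_label"].nunique()
    within = bool((pid_classes > 1).any())

    count = 0
    if within:
        # shuffle labels within each participant's records
        groups = [idx.to_numpy() for _, idx in
                  sub.groupby("participant_id", sort=True).groups.items()]
        pos = {ix: k for k, ix in enumerate(sub.index)}
        group_pos = [np.array([pos[i] for i in g]) for g in groups]
        for _ in range(n_permutations):
            lab = in_a.copy()
            for g in group_pos:
                lab[g] = lab[g[rng.permutation(len(g))]]
            if lab.all() or not lab.any():
                stat = 0.0
            else:
                stat = y[lab].mean() - y[~lab].mean()
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
    else:
        pids = sub["participant_id"].to_numpy()
        uniq = np.unique(pids)
        pid_is_a = {p: bool(in_a[pids == p][0]) for p in uniq}
        base = np.array([pid_is_a[p] for p in uniq])
        pid_index = {p: k for k, p in enumerate(uniq)}
        rec_pid_idx = np.array([pid_index[p] for p in pids])
        for _ in range(n_permutations):
            perm = base[rng.permutation(len(base))]
            lab = perm[rec_pid_idx]
            if lab.all() or not lab.any():
                stat = 0.0
            else:
                stat = y[lab].mean() - y[~lab].mean()
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
    p = (1 + count) / (n_permutations + 1)
    return float(obs), float(p)


def _model_test(sub: pd.DataFrame, outcome: str, class_a: str,
                binary: bool) -> tuple[float, float]:
    """Participant random-intercept model contrast: mixed logit (variational
    Bayes) for binary factors, linear mixed model for the count score.
    Raises on non-convergence or degeneracy; callers fall back."""
    import statsmodels.api as sm
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    data = pd.DataFrame({
        "y": sub[outcome].to_numpy(float),
        "cls": (sub["proximity_label"] == class_a).astype(float).to_numpy(),
        "arm_cm": (sub["arm"] == "CM").astype(float).to_numpy(),
        "pid": sub["participant_id"].to_numpy(),
    })
    if data["y"].nunique() < 2:
        raise ValueError("degenerate outcome")
    rhs = "cls + arm_cm" if data["arm_cm"].nunique() > 1 else "cls"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if binary:
            model = BinomialBayesMixedGLM.from_formula(
                f"y ~ {rhs}", {"pid": "0 + C(pid)"}, data)
            fit = model.fit_vb()
            names = list(fit.model.exog_names)
            k = names.index("cls")
            est = float(fit.fe_mean[k])
            sd = float(fit.fe_sd[k])
            if not np.isfinite(est) or not np.isfinite(sd) or sd <= 0:
                raise ValueError("mixed logit did not converge")
            p = float(2 * (1 - ndtr(abs(est / sd))))
        else:
            model = sm.MixedLM.from_formula(f"y ~ {rhs}", groups=data["pid"],
                                            data=data)
            fit = model.fit(reml=True)
            est = float(fit.params["cls"])
            p = float(fit.pvalues["cls"])
            if not np.isfinite(p):
                raise ValueError("mixed model did not converge")
    return est, p


def group_compare(scored: pd.DataFrame, roster: pd.DataFrame,
                  method: str = "model",
                  factors: Optional[Sequence[str]] = None,
                  contrasts: Optional[Sequence[tuple[str, str]]] = None,
                  n_permutations: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Pairwise proximity-class contrasts for each risk factor and the count
    score, adjusted for treatment arm.

    The default ``method='model'`` fits a participant random-intercept model
    per factor and contrast (logit link for the six binary indicators,
    identity link for the count score), falling back — with a logged warning
    — to a seeded participant-level permutation test whenever the model is
    degenerate or fails to converge.  ``method='permutation'`` uses the
    permutation test throughout (the treatment-arm adjustment does not apply
    there).

    Returns a tidy frame: factor, class_a, class_b, estimate, p_value,
    method.
    """
    if method not in ("model", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    df = _with_indicators(scored)
    if "n_risk_factors" not in df.columns:
        df["n_risk_factors"] = indicator_matrix(df).sum(axis=1)
    df = df.merge(roster[["participant_id", "arm"]], on="participant_id",
                  how="left")
    present = [c for c in _CLASS_ORDER
               if (df["proximity_label"] == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two proximity classes")

    all_factors = {
        "urge": "urge_high", "stress": "stress_high",
        "low_motivation": "motivation_low", "availability": "cigs_available",
        "alcohol": "alcohol_recent",
        "smoker_interaction": "interacting_smoker_ind",
        "n_risk_factors": "n_risk_factors",
    }
    if factors is None:
        factors = list(all_factors)
    use_contrasts = [c for c in (contrasts or _CONTRASTS)
                     if c[0] in present and c[1] in present]
    rng = np.random.default_rng(seed)

    rows = []
    for fac in factors:
        col = all_factors[fac]
        binary = col != "n_risk_factors"
        for class_a, class_b in use_contrasts:
            sub = df[df["proximity_label"].isin((class_a, class_b))]
            n_pid_a = sub.loc[sub["proximity_label"] == class_a,
                              "participant_id"].nunique()
            n_pid_b = sub.loc[sub["proximity_label"] == class_b,
                              "participant_id"].nunique()
            used = method
            if method == "model" and min(n_pid_a, n_pid_b) >= 2:
                try:
                    est, p = _model_test(sub, col, class_a, binary)
                except Exception as exc:  # degenerate fit → permutation
                    logger.warning(
                        "model contrast %s %s vs %s failed (%s); "
                        "permutation fallback", fac, class_a, class_b, exc)
                    est, p = _permutation_test(sub, col, class_a,
                                               n_permutations, rng)
                    used = "permutation_fallback"
            else:
                if method == "model":
                    logger.warning(
                        "contrast %s %s vs %s has <2 participants in a "
                        "class; permutation fallback", fac, class_a, class_b)
                    used = "permutation_fallback"
                est, p = _permutation_test(sub, col, class_a,
                                           n_permutations, rng)
            rows.append({"factor": fac, "class_a": class_a,
                         "class_b": class_b, "estimate": est,
                         "p_value": p, "method": used})
    return pd.DataFrame(rows)


# -- full report ------------------------------------------------------------

@dataclass
class EvalReport:
    """Everything the evaluation stage reports, JSON-serializable."""

    class_counts: dict
    prevalence: pd.DataFrame
    operating_points: list
    participant_detection: dict
    auc_unweighted: float
    auc_unweighted_ci: tuple[float, float]
    auc_weighted: float
    auc_weighted_ci: tuple[float, float]
    auc_comparison_p: float
    auc_comparison_method: str
    group_tests: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        prev = self.prevalence.copy()
        for c in prev.columns:
            if c.endswith("_pct"):
                prev[c] = prev[c].round(1)
        for c in ("mean_risk_factors", "sd_risk_factors"):
            if c in prev.columns:
                prev[c] = prev[c].round(2)
        out = {
            "class_counts": self.class_counts,
            "prevalence_table": prev.to_dict(orient="records"),
            "operating_points": [
                {**op, "sensitivity": round(op["sensitivity"], 4),
                 "specificity": round(op["specificity"], 4)}
                for op in self.operating_points],
            "participant_detection": {
                k: round(v, 4) for k, v in self.participant_detection.items()},
            "auc_unweighted": round(self.auc_unweighted, 4),
            "auc_unweighted_ci": [round(v, 4) for v in self.auc_unweighted_ci],
            "auc_weighted": round(self.auc_weighted, 4),
            "auc_weighted_ci": [round(v, 4) for v in self.auc_weighted_ci],
            "auc_comparison_p": self.auc_comparison_p,
            "auc_comparison_method": self.auc_comparison_method,
        }
        if self.group_tests is not None:
            out["group_tests"] = self.group_tests.to_dict(orient="records")
        return out


def evaluate(scored: pd.DataFrame, roster: pd.DataFrame, *,
             unweighted_cutoff: float = 3.0, weighted_cutoff: float = 1.0,
             unweighted_ge: bool = True, weighted_ge: bool = False,
             run_group_tests: bool = False, group_method: str = "model",
             seed: int = 0) -> EvalReport:
    """Full evaluation of the scored analysis set.

    By default the unweighted count estimator is reported at its integer
    cut-off in the ≥ convention ("3 or more factors") and the weighted
    estimator at a strict cut-off (score above 1.0); both conventions are
    switchable.  AUCs treat within-window records as positives and all
    other retained records as negatives.
    """
    y = _check_two_class(positive_mask(scored))
    counts = scored["proximity_label"].value_counts().to_dict()

    s_unw = scored["n_risk_factors"].to_numpy(float)
    s_w = scored["weighted_risk_score"].to_numpy(float)
    _, auc_u, ci_u = roc_and_auc(s_unw, y)
    _, auc_w, ci_w = roc_and_auc(s_w, y)
    comp = compare_auc(s_w, s_unw, y, method="delong", seed=seed)

    ops = [operating_point(scored, "n_risk_factors", unweighted_cutoff,
                           ge=unweighted_ge),
           operating_point(scored, "weighted_risk_score", weighted_cutoff,
                           ge=weighted_ge)]
    detection = {
        "unweighted": participant_detection(
            scored, roster, unweighted_cutoff, "n_risk_factors",
            ge=unweighted_ge),
        "weighted": participant_detection(
            scored, roster, weighted_cutoff, "weighted_risk_score",
            ge=weighted_ge),
    }
    group = None
    if run_group_tests:
        group = group_compare(scored, roster, method=group_method, seed=seed)

    return EvalReport(
        class_counts={str(k): int(v) for k, v in counts.items()},
        prevalence=prevalence_table(scored),
        operating_points=ops,
        participant_detection=detection,
        auc_unweighted=auc_u, auc_unweighted_ci=ci_u,
        auc_weighted=auc_w, auc_weighted_ci=ci_w,
        auc_comparison_p=comp["p_value"],
        auc_comparison_method=comp["method"],
        group_tests=group)
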
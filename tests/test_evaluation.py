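"""ROC/AUC machinery, prevalence tables, group contrasts and
participant-level detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lapserisk import (SimConfig, build_analysis_set, generate_cohort,
                       prevalence_table, score_analysis_set)
from lapserisk.evaluation import (auc_rank, compare_auc, group_compare,
                                  operating_point, participant_detection,
                                  roc_and_auc)
from lapserisk.synthetic_cohort import (PREVALENCE_ABSTAINER,
                                        PREVALENCE_WITHIN4H,
                                        draw_item_matrix)
from lapserisk.weight_search import evaluate_weights, positive_mask
from lapserisk import RiskWeights
from conftest import auc_pairwise_oracle, make_random_records


def test_auc_trivial_cases():
    assert auc_rank([1, 2, 3], [0, 0, 1]) == 1.0
    assert auc_rank([3, 2, 1], [0, 0, 1]) == 0.0
    assert auc_rank([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5  # ties only


def test_auc_matches_pairwise_oracle_and_libraries():
    rng = np.random.default_rng(11)
    scores = rng.integers(0, 7, 500).astype(float)  # heavy ties
    labels = rng.random(500) < 0.3
    ours = auc_rank(scores, labels)
    assert ours == pytest.approx(auc_pairwise_oracle(scores, labels),
                                 abs=1e-12)
    assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_equals_trapezoidal_roc_area():
    rng = np.random.default_rng(12)
    scores = np.round(rng.normal(size=800), 1)
    labels = rng.random(800) < 0.4
    curve, auc, _ = roc_and_auc(scores, labels)
    assert auc == pytest.approx(curve.area(), abs=1e-9)
    assert curve.fpr[0] == 0 and curve.tpr[0] == 0
    assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
    assert np.all(np.diff(curve.tpr) >= 0) and np.all(np.diff(curve.fpr) >= 0)


def test_auc_ci_contains_point_estimate():
    rng = np.random.default_rng(13)
    scores = rng.normal(size=300) + np.where(rng.random(300) < 0.5, 1.0, 0.0)
    labels = scores > np.median(scores)  # crude separation
    scores = scores + rng.normal(scale=0.5, size=300)
    _, auc, (lo, hi) = roc_and_auc(scores, labels)
    assert 0.0 <= lo <= auc <= hi <= 1.0
    assert hi - lo > 0


def test_roc_operating_point_matches_evaluate_weights(study_scored):
    """Sensitivity/specificity read off the ROC at a threshold equal the
    direct confusion tally at that threshold."""
    y = positive_mask(study_scored)
    s = study_scored["weighted_risk_score"].to_numpy(float)
    curve, _, _ = roc_and_auc(s, y)
    sens, spec = evaluate_weights(study_scored, RiskWeights(), 1.0)
    # the ROC vertex flagging exactly the scores above 1.0 is the one whose
    # threshold is the smallest observed score exceeding 1.0
    mask = curve.thresholds > 1.0
    assert mask.any()
    idx = np.where(mask)[0][-1]
    assert curve.tpr[idx] == pytest.approx(sens)
    assert 1 - curve.fpr[idx] == pytest.approx(spec)


def test_compare_auc_identical_and_shifted():
    rng = np.random.default_rng(14)
    s = rng.normal(size=200)
    y = rng.random(200) < 0.5
    same = compare_auc(s, s.copy(), y)
    assert same["p_value"] == 1.0 and same["diff"] == 0.0
    shifted = compare_auc(s, s + 3.14, y)  # rank-preserving shift
    assert shifted["p_value"] == 1.0 and shifted["diff"] == 0.0


def test_compare_auc_methods_agree():
    """Structural-components p agrees with the paired bootstrap within 0.02
    on 500-record synthetic data."""
    rng = np.random.default_rng(15)
    n = 500
    signal = rng.normal(size=n)
    y = rng.random(n) < 1 / (1 + np.exp(-signal))
    a = signal + rng.normal(scale=1.0, size=n)
    b = signal + rng.normal(scale=1.3, size=n)
    p_delong = compare_auc(a, b, y, method="delong")["p_value"]
    p_boot = compare_auc(a, b, y, method="bootstrap", n_boot=2000,
                         seed=7)["p_value"]
    assert abs(p_delong - p_boot) <= 0.02


def test_prevalence_table_trivial_classes():
    df = pd.DataFrame({
        "urge": [1, 5], "stress": [1, 1], "motivation": [5, 5],
        "availability": [1, 4], "interacting_smoker": [False, False],
        "alcohol_past_hour": [False, False],
        "proximity_label": ["ABSTAINER", "WITHIN_4H"],
    })
    tab = prevalence_table(df).set_index("proximity_label")
    assert tab.loc["ABSTAINER", "mean_risk_factors"] == 0.0
    assert tab.loc["ABSTAINER", "urge_pct"] == 0.0
    assert tab.loc["WITHIN_4H", "mean_risk_factors"] == 2.0  # urge + avail
    # empty class absent, not zero
    assert "PRE_LAPSE_OVER_4H" not in tab.index


def test_prevalence_table_on_study_cohort(study_scored):
    tab = prevalence_table(study_scored).set_index("proximity_label")
    # class means sit near the configured-prevalence expectations
    assert tab.loc["WITHIN_4H", "mean_risk_factors"] == pytest.approx(
        2.452, abs=0.45)
    assert tab.loc["PRE_LAPSE_OVER_4H", "mean_risk_factors"] == pytest.approx(
        1.852, abs=0.15)
    assert tab.loc["ABSTAINER", "mean_risk_factors"] == pytest.approx(
        1.278, abs=0.12)


def test_participant_detection_trivial():
    scored = pd.DataFrame({
        "participant_id": ["L1", "L1", "L2"],
        "proximity_label": ["WITHIN_4H", "WITHIN_4H", "WITHIN_4H"],
        "n_risk_factors": [4, 1, 2],
    })
    roster = pd.DataFrame({
        "participant_id": ["L1", "L2", "A1"],
        "first_lapse_time": [pd.Timestamp("2012-03-06")] * 2 + [pd.NaT],
        "consistent_reporting": [True, True, True],
    })
    assert participant_detection(scored, roster, 3, ge=True) == 0.5
    # cut-off below everything detects every lapser with a within-window EMA
    assert participant_detection(scored, roster, 0, ge=True) == 1.0
    with pytest.raises(ValueError):
        participant_detection(scored, roster.iloc[2:3], 3)


def test_participant_detection_matches_per_participant_scan():
    """Agreement with a direct per-participant oracle over 50 random small
    cohorts."""
    for seed in range(50):
        cohort = generate_cohort(SimConfig(
            n_lapsers=4, n_abstainers=2, days_postquit=2, master_seed=seed))
        scored = score_analysis_set(build_analysis_set(cohort))
        got = participant_detection(scored, cohort.roster, 3,
                                    "n_risk_factors", ge=True)
        lapsers = cohort.roster[cohort.roster["first_lapse_time"].notna()]
        hits = 0
        for pid in lapsers["participant_id"]:
            sub = scored[(scored["participant_id"] == pid)
                         & (scored["proximity_label"] == "WITHIN_4H")]
            hits += bool((sub["n_risk_factors"] >= 3).any())
        assert got == pytest.approx(hits / len(lapsers))


def test_operating_point_conventions(study_scored):
    ge = operating_point(study_scored, "n_risk_factors", 3, ge=True)
    gt = operating_point(study_scored, "n_risk_factors", 3, ge=False)
    assert ge["sensitivity"] >= gt["sensitivity"]
    assert ge["specificity"] <= gt["specificity"]


def test_group_compare_detects_planted_contrast(study_scored, study_cohort):
    res = group_compare(study_scored, study_cohort.roster,
                        method="permutation", factors=["urge", "alcohol"],
                        contrasts=[("WITHIN_4H", "ABSTAINER")],
                        n_permutations=500, seed=4)
    assert (res["p_value"] < 0.05).all()
    assert (res["estimate"] > 0).all()


def test_group_compare_single_participant_falls_back():
    """A class with a single participant never gets a silent model fit."""
    rng = np.random.default_rng(5)
    df = make_random_records(rng, 30)
    df["participant_id"] = ["solo"] * 10 + [f"A{i}" for i in range(20)]
    df["proximity_label"] = ["WITHIN_4H"] * 10 + ["ABSTAINER"] * 20
    roster = pd.DataFrame({
        "participant_id": df["participant_id"].unique(),
        "arm": "UC",
    })
    res = group_compare(df, roster, method="model", factors=["urge"],
                        contrasts=[("WITHIN_4H", "ABSTAINER")], seed=1,
                        n_permutations=200)
    assert res["method"].iloc[0] == "permutation_fallback"


def test_group_compare_requires_two_classes():
    rng = np.random.default_rng(6)
    df = make_random_records(rng, 10)
    df["participant_id"] = "P1"
    df["proximity_label"] = "ABSTAINER"
    roster = pd.DataFrame({"participant_id": ["P1"], "arm": ["UC"]})
    with pytest.raises(ValueError):
        group_compare(df, roster)


def test_group_compare_power_for_urge_contrast():
    """At study-sized classes (108 vs 1722 records) the within-window vs
    abstainer urge contrast is significant in ≥90% of replicates."""
    rng = np.random.default_rng(99)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        w4 = draw_item_matrix(PREVALENCE_WITHIN4H, 108, rng)
        ab = draw_item_matrix(PREVALENCE_ABSTAINER, 1722, rng)
        w4["participant_id"] = [f"L{i % 40}" for i in range(len(w4))]
        ab["participant_id"] = [f"A{i % 40}" for i in range(len(ab))]
        w4["proximity_label"] = "WITHIN_4H"
        ab["proximity_label"] = "ABSTAINER"
        df = pd.concat([w4, ab], ignore_index=True)
        roster = pd.DataFrame({
            "participant_id": df["participant_id"].unique(), "arm": "UC"})
        res = group_compare(df, roster, method="permutation",
                            factors=["urge"],
                            contrasts=[("WITHIN_4H", "ABSTAINER")],
                            n_permutations=300, seed=0)
        hits += res["p_value"].iloc[0] < 0.05
    assert hits / n_rep >= 0.9
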
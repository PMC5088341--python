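"""Weight grid search: exhaustiveness, determinism, invariances, and
recovery of planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lapserisk import (RiskWeights, SearchConfig, SimConfig, Objective,
                       build_analysis_set, generate_cohort, grid_search,
                       score_analysis_set)
from lapserisk.weight_search import evaluate_weights, ge_cutoff
from conftest import make_random_records

SMALL_GRID = SearchConfig(weight_grid_ordinal=(0.0, 0.5, 1.0),
                          weight_grid_binary=(0.0, 1.0))


@pytest.fixture(scope="module")
def labeled(study_scored):
    return study_scored


def _noise_records(rng, n, p_positive=0.5):
    df = make_random_records(rng, n)
    lab = np.array(["WITHIN_4H"] * int(n * p_positive)
                   + ["ABSTAINER"] * (n - int(n * p_positive)))
    rng.shuffle(lab)
    df["proximity_label"] = lab
    return df


def test_singleton_grid_returns_those_weights(labeled):
    cfg = SearchConfig(weight_grid_ordinal=(0.2,), weight_grid_binary=(1.0,))
    res = grid_search(labeled, cfg)
    # only one candidate: urge=stress=motivation=availability=0.2,
    # binaries=1
    assert res.n_evaluated == 1
    assert res.best_weights == RiskWeights(availability=0.2)
    sens, spec = evaluate_weights(labeled, res.best_weights, res.best_cutoff)
    assert sens + spec - 1 == pytest.approx(res.objective_value, abs=1e-9)


def test_exhaustiveness(labeled):
    res = grid_search(labeled, SMALL_GRID)
    assert res.n_evaluated == 3 ** 4 * 2 ** 2


def test_determinism(labeled):
    a = grid_search(labeled, SMALL_GRID)
    b = grid_search(labeled, SMALL_GRID)
    assert a == b


def test_objective_attained_by_reported_weights(labeled):
    res = grid_search(labeled, SMALL_GRID)
    sens, spec = evaluate_weights(labeled, res.best_weights, res.best_cutoff)
    assert sens + spec - 1 == pytest.approx(res.objective_value, abs=1e-9)


def test_scale_invariance(labeled):
    res = grid_search(labeled, SMALL_GRID)
    w = res.best_weights
    doubled = dataclasses.replace(
        w, urge=2 * w.urge, stress=2 * w.stress, motivation=2 * w.motivation,
        availability=2 * w.availability, smoker_present=2 * w.smoker_present,
        alcohol=2 * w.alcohol)
    s1 = evaluate_weights(labeled, w, res.best_cutoff)
    s2 = evaluate_weights(labeled, doubled, 2 * res.best_cutoff)
    assert s1 == pytest.approx(s2)


def test_evaluate_weights_trivial_cutoffs(labeled):
    w = RiskWeights()
    assert evaluate_weights(labeled, w, -100.0) == (1.0, 0.0)
    assert evaluate_weights(labeled, w, 100.0) == (0.0, 1.0)


def test_evaluate_weights_matches_direct_tally():
    rng = np.random.default_rng(3)
    df = _noise_records(rng, 1000, p_positive=0.3)
    w = RiskWeights()
    cutoff = 0.65  # between attainable score values (multiples of 0.1)
    sens, spec = evaluate_weights(df, w, cutoff)
    # independent tally
    from lapserisk import weighted_score, EmaRecord, PromptType
    tp = fn = tn = fp = 0
    for _, row in df.iterrows():
        rec = EmaRecord("P", pd.Timestamp("2012-03-05"), PromptType.RANDOM,
                        int(row.urge), int(row.stress), int(row.motivation),
                        int(row.availability), bool(row.interacting_smoker),
                        bool(row.alcohol_past_hour), False)
        s = weighted_score(rec, w)
        if row.proximity_label == "WITHIN_4H":
            tp += s > cutoff
            fn += s <= cutoff
        else:
            fp += s > cutoff
            tn += s <= cutoff
    assert sens == pytest.approx(tp / (tp + fn))
    assert spec == pytest.approx(tn / (tn + fp))


def test_ge_cutoff_flags_at_threshold():
    assert 3 > ge_cutoff(3)
    assert not (2.999999 > ge_cutoff(3))


def test_single_class_and_empty_grid_errors(labeled):
    df = labeled[labeled["proximity_label"] == "ABSTAINER"]
    with pytest.raises(ValueError):
        grid_search(df, SMALL_GRID)
    with pytest.raises(ValueError):
        SearchConfig(weight_grid_ordinal=())


def test_label_permutation_gives_null_objective():
    """With labels carrying no signal, the maximized Youden index stays
    near zero (|J| < 0.1 at n = 5,000)."""
    rng = np.random.default_rng(17)
    df = _noise_records(rng, 5000)
    res = grid_search(df, SMALL_GRID)
    assert 0.0 <= res.objective_value < 0.1


def test_planted_availability_weight_recovered():
    """When the true signal is availability alone, the searched weights put
    their (weakly) largest coefficient on availability in ≥18/20 seeds."""
    successes = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        df = make_random_records(rng, 5000)
        latent = (df["availability"] - 3).to_numpy(float)
        p = 1.0 / (1.0 + np.exp(-1.5 * latent))
        df["proximity_label"] = np.where(rng.random(5000) < p,
                                         "WITHIN_4H", "ABSTAINER")
        w = grid_search(df, SMALL_GRID).best_weights
        others = max(w.urge, w.stress, w.motivation, w.smoker_present,
                     w.alcohol)
        successes += (w.availability >= others) and (w.availability > 0)
    assert successes >= 18


def test_auc_objective_supported(labeled):
    cfg = SearchConfig(weight_grid_ordinal=(0.2, 0.7),
                       weight_grid_binary=(1.0,),
                       objective=Objective.AUC)
    res = grid_search(labeled, cfg)
    assert 0.5 < res.objective_value <= 1.0
    assert res.n_evaluated == 2 ** 4


def test_explicit_cutoff_grid(labeled):
    cfg = SearchConfig(weight_grid_ordinal=(0.2,), weight_grid_binary=(1.0,),
                       cutoff_grid=(0.5, 1.0, 1.5))
    res = grid_search(labeled, cfg)
    assert res.best_cutoff in (0.5, 1.0, 1.5)
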
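"""Synthetic cohort generator: seeded determinism, prevalence recovery,
copula correlation, and sampling-design guarantees."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from lapserisk import (SimConfig, generate_cohort, map_prevalence_to_ordinal,
                       draw_item_matrix, write_cohort,
                       PREVALENCE_WITHIN4H, PREVALENCE_OVER4H,
                       PREVALENCE_ABSTAINER)
from lapserisk.risk_scoring import indicator_matrix

# indicator_matrix column order: urge, stress, motivation_low, availability,
# smoker, alcohol — prevalence vectors use table order (alcohol before
# smoker), hence this permutation
_IND_TO_FACTOR = (0, 1, 2, 3, 5, 4)


def _empirical_prevalences(items: pd.DataFrame) -> np.ndarray:
    ind = indicator_matrix(items).mean(axis=0)
    return ind[list(_IND_TO_FACTOR)]


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(n_lapsers=8, n_abstainers=6, days_postquit=3,
                    master_seed=99)
    for tag in ("a", "b"):
        write_cohort(generate_cohort(cfg), tmp_path / f"e{tag}.csv",
                     tmp_path / f"r{tag}.csv")
    assert (tmp_path / "ea.csv").read_bytes() == (tmp_path / "eb.csv").read_bytes()
    assert (tmp_path / "ra.csv").read_bytes() == (tmp_path / "rb.csv").read_bytes()


def test_different_seed_differs():
    a = generate_cohort(SimConfig(n_lapsers=4, n_abstainers=3,
                                  days_postquit=2, master_seed=1))
    b = generate_cohort(SimConfig(n_lapsers=4, n_abstainers=3,
                                  days_postquit=2, master_seed=2))
    assert not a.equals(b)


def test_mean_completed_emas_per_participant(study_cohort):
    """Study design target: ≈ 43.5 completed EMAs per participant over the
    7-day post-quit week (before post-lapse exclusion), within ±10%."""
    mean = len(study_cohort.ema) / len(study_cohort.roster)
    assert abs(mean - 43.5) <= 4.35


@pytest.mark.parametrize("prevs", [PREVALENCE_WITHIN4H, PREVALENCE_OVER4H,
                                   PREVALENCE_ABSTAINER])
def test_prevalence_recovery_at_large_n(prevs):
    """Dichotomized empirical prevalences match the configured class
    prevalences to ±1% absolute at n = 100,000."""
    rng = np.random.default_rng(314159)
    items = draw_item_matrix(prevs, 100_000, rng)
    emp = _empirical_prevalences(items)
    assert np.all(np.abs(emp - np.asarray(prevs)) <= 0.01)


def test_ordinal_map_masses():
    m = map_prevalence_to_ordinal(0.593, "urge")
    assert abs(sum(m.masses) - 1.0) < 1e-12
    by_cat = dict(zip(m.category_order, m.masses))
    assert abs(by_cat[4] + by_cat[5] - 0.593) < 1e-12
    # motivation is mirrored: the indicator is the low end of the scale
    mm = map_prevalence_to_ordinal(0.173, "motivation")
    by_cat = dict(zip(mm.category_order, mm.masses))
    assert abs(by_cat[1] + by_cat[2] - 0.173) < 1e-12


@pytest.mark.parametrize("p,expect", [(0.0, 0.0), (1.0, 1.0), (0.593, 0.593)])
def test_ordinal_map_prevalence_edge_cases(p, expect):
    m = map_prevalence_to_ordinal(p, "urge")
    pos_mass = sum(mass for cat, mass in zip(m.category_order, m.masses)
                   if cat in (4, 5))
    assert abs(pos_mass - expect) < 1e-12


def test_indicators_independent_without_copula():
    rng = np.random.default_rng(7)
    ind = indicator_matrix(draw_item_matrix(PREVALENCE_WITHIN4H, 50_000, rng))
    corr = np.corrcoef(ind.astype(float).T)
    off = corr[~np.eye(6, dtype=bool)]
    assert np.all(np.abs(off) < 0.02)


def test_copula_induces_positive_correlation_preserving_marginals():
    rng = np.random.default_rng(8)
    items = draw_item_matrix(PREVALENCE_WITHIN4H, 50_000, rng,
                             latent_correlation=0.5)
    ind = indicator_matrix(items)
    corr = np.corrcoef(ind.astype(float).T)
    off = corr[~np.eye(6, dtype=bool)]
    assert np.all(off > 0.05)
    emp = _empirical_prevalences(items)
    assert np.all(np.abs(emp - np.asarray(PREVALENCE_WITHIN4H)) <= 0.01)


def test_every_lapser_has_prelapse_ema_at_full_compliance():
    cohort = generate_cohort(SimConfig(n_lapsers=30, n_abstainers=0,
                                       compliance_prob=1.0, master_seed=5))
    roster = cohort.roster.set_index("participant_id")
    for pid, grp in cohort.ema.groupby("participant_id"):
        lapse = roster.loc[pid, "first_lapse_time"]
        assert (grp["timestamp"] < lapse).any()


def test_smoking_report_flips_at_lapse(small_cohort):
    roster = small_cohort.roster.set_index("participant_id")
    ema = small_cohort.ema
    lapse = roster["first_lapse_time"].reindex(ema["participant_id"]).to_numpy()
    post = ~pd.isna(lapse) & (ema["timestamp"].to_numpy() >= lapse)
    assert (ema["smoked_since_last"].to_numpy() == post).all()


@pytest.mark.parametrize("bad", [
    {"waking_window_hours": 0.0},
    {"prevalence_within4h": (0.5, 0.5)},
    {"prevalence_abstainer": (0.1, 0.1, 0.1, 0.1, 0.1, 1.3)},
    {"latent_correlation": 1.0},
    {"compliance_prob": 1.5},
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValidationError):
        SimConfig(**bad)


def test_generator_meta_counts_cover_all_records(small_cohort):
    meta = small_cohort.meta
    assert (meta["n_within4h"] + meta["n_over4h"] + meta["n_abstainer"]
            + meta["n_post_lapse"] + meta["n_inconsistent_records"]
            == meta["n_records"] == len(small_cohort.ema))
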
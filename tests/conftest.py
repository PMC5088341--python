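import numpy as np
import pandas as pd
import pytest

from lapserisk import (SimConfig, build_analysis_set, generate_cohort,
                       score_analysis_set)


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic cohort at the study design defaults (92 participants)."""
    return generate_cohort(SimConfig(master_seed=20240917))


@pytest.fixture(scope="session")
def study_scored(study_cohort):
    return score_analysis_set(build_analysis_set(study_cohort))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimConfig(n_lapsers=6, n_abstainers=5,
                                     days_postquit=3, master_seed=7))


def make_random_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Uniform-random EMA item table (no class structure)."""
    return pd.DataFrame({
        "urge": rng.integers(1, 6, n),
        "stress": rng.integers(1, 6, n),
        "motivation": rng.integers(1, 6, n),
        "availability": rng.integers(1, 6, n),
        "interacting_smoker": rng.random(n) < 0.3,
        "alcohol_past_hour": rng.random(n) < 0.2,
    })


def poisson_binomial_pmf(ps) -> np.ndarray:
    """Exact distribution of a sum of independent Bernoulli(p_i) variables
    (dynamic-programming convolution); independent oracle for count-score
    tail probabilities."""
    pmf = np.zeros(len(ps) + 1)
    pmf[0] = 1.0
    for p in ps:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= (1 - p)
    return pmf


def auc_pairwise_oracle(scores, labels) -> float:
    """O(n^2) mean over positive-negative pairs of [s_p > s_n] + 1/2[s_p == s_n]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        total += np.sum(sp > neg) + 0.5 * np.sum(sp == neg)
    return total / (len(pos) * len(neg))
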
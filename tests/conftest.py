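import numpy as np
import pytest

from chant.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient cohort at the development-cohort prevalence."""
    return generate_cohort(CohortConfig(n_patients=300, prevalence=0.42, seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """A 5000-patient cohort for Monte-Carlo calibration checks."""
    return generate_cohort(CohortConfig(n_patients=5000, prevalence=0.42, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles (used by several test modules)
# ---------------------------------------------------------------------------

def pair_counting_auc(scores, labels):
    """Concordance probability by explicit pair counting, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    conc = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1.0
            elif p == q:
                conc += 0.5
    return conc / (len(pos) * len(neg))


def midrank(values):
    """Midranks computed from scratch (1-based)."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    """Spearman correlation as the Pearson correlation of midranks."""
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
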
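import numpy as np
import pytest

from dualcap import ObserverParams, simulate_experiment
from dualcap.observer import ExperimentDesign


@pytest.fixture(scope="session")
def serial_experiment():
    """One 11-subject serial experiment at the study's operating point."""
    return simulate_experiment(
        ObserverParams(regime="serial"), n_subjects=11, seed=99
    )


@pytest.fixture(scope="session")
def independent_experiment():
    return simulate_experiment(
        ObserverParams(regime="independent"), n_subjects=11, seed=101
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_concordance(present_counts, absent_counts) -> float:
    """Exhaustive pairwise concordance P(Rp > Ra) + 0.5 P(tie), the
    independent oracle for the rating-ROC area."""
    total = 0.0
    n_pairs = sum(present_counts) * sum(absent_counts)
    for i, p in enumerate(present_counts):
        for j, a in enumerate(absent_counts):
            if i > j:
                total += p * a
            elif i == j:
                total += 0.5 * p * a
    return total / n_pairs
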
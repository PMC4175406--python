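import numpy as np
import pytest

from molci import LabeledScores


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def four_point_scores():
    """Actives score {3, 1}, inactives {2, 0}: AUC 3/4 by enumeration."""
    return LabeledScores(
        scores=np.array([3.0, 1.0, 2.0, 0.0]),
        labels=np.array([True, True, False, False]),
    )


def brute_force_auc(actives, inactives) -> float:
    """Pairwise counting oracle: wins + half-ties over all pairs."""
    wins = 0.0
    for a in actives:
        for i in inactives:
            if a > i:
                wins += 1.0
            elif a == i:
                wins += 0.5
    return wins / (len(actives) * len(inactives))
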
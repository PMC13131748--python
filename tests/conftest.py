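import numpy as np
import pandas as pd
import pytest

from icudca.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """~12k patient-day cohort used by several structural checks."""
    return generate_cohort(CohortSpec(n_admissions=10_000, seed=7))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(n_admissions=400, seed=11))


def brute_force_confusion(y, p, t):
    """Independent oracle: count the confusion cells one row at a time."""
    tp = fp = tn = fn = 0
    for yi, pi in zip(y, p):
        flagged = pi >= t
        if flagged and yi == 1:
            tp += 1
        elif flagged and yi == 0:
            fp += 1
        elif not flagged and yi == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_force_roc_auc(y, p):
    """Pairwise oracle: P(random positive outscores random negative), ties 1/2."""
    y = np.asarray(y)
    p = np.asarray(p)
    pos = p[y == 1]
    neg = p[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))
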
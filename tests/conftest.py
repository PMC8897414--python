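import numpy as np
import pandas as pd
import pytest

import varprio as v
from varprio.scores import LABEL_BENIGN, LABEL_PATHOGENIC, LabeledScores


@pytest.fixture(scope="session")
def registry():
    return v.default_registry()


def make_table(pos_scores, neg_scores, predictor="score", splicing=False):
    """Small LabeledScores table from two score lists (NaN = missing)."""
    n = len(pos_scores) + len(neg_scores)
    frame = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "label": [LABEL_PATHOGENIC] * len(pos_scores) + [LABEL_BENIGN] * len(neg_scores),
        "splicing_subset": splicing,
        predictor: list(pos_scores) + list(neg_scores),
    })
    return LabeledScores(frame, predictors=[predictor])


@pytest.fixture
def simple_spec():
    return v.PredictorSpec(
        name="score", family=v.Family.NON_SPLICING,
        direction=v.Direction.HIGHER, optimal_cutoff=0.0,
    )


def brute_force_auc(pos, neg):
    """Exhaustive concordant-pair count with half credit for ties."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_cutoff(pos, neg, objective):
    """Exhaustive scan over observed thresholds (higher-is-risk scores).

    objective(sens, spec) -> value to maximize; ties broken toward higher
    sensitivity, then the stricter (larger) threshold.
    """
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    best = None
    for t in np.unique(np.concatenate([pos, neg])):
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        key = (objective(sens, spec), sens, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]
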
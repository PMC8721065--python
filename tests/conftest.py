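import numpy as np
import pandas as pd
import pytest

import rankagree as ra


@pytest.fixture(scope="session")
def fma():
    return ra.load_scale("fma_le")


def make_ratings(scores, scale):
    """Build a validated dataset from {(subject, rater, occasion): {item: score}}
    or, when the inner value is an int, that score on every item."""
    rows = []
    for (subj, rater, occ), val in scores.items():
        per_item = val if isinstance(val, dict) else {i: val for i in scale.item_ids}
        for item, score in per_item.items():
            rows.append({"subject_id": subj, "rater_id": rater, "occasion": occ,
                         "item_id": item, "score": score})
    return ra.load_ratings(pd.DataFrame(rows), scale)


@pytest.fixture
def perfect_study(fma):
    """3 subjects, 2 raters, 2 occasions, identical scores everywhere."""
    scores = {}
    per_subject = {"S1": 2, "S2": 1, "S3": 0}
    for subj, val in per_subject.items():
        for rater in ("A", "B"):
            for occ in (1, 2):
                scores[(subj, rater, occ)] = val
    return make_ratings(scores, fma)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241015)
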
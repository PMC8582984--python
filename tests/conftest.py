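import numpy as np
import pandas as pd
import pytest

import perceptrisk as pr
from perceptrisk.codebook import Codebook, ItemCoding


@pytest.fixture
def toy_codebook():
    """3 items with sign patterns +1/-1, +1/0, -1/0 (hand-enumerable)."""
    return Codebook(items=[
        ItemCoding("K01", "knowledge", ("cat1", "cat2"), {"cat1": 1, "cat2": -1}),
        ItemCoding("P01", "perception_severity", ("cat1", "cat2"), {"cat1": 1, "cat2": 0}),
        ItemCoding("B01", "preventive_practice", ("cat1", "cat2"), {"cat1": -1, "cat2": 0}),
    ])


def make_response_frame(codebook, answers, **overrides):
    """One-row respondent frame with valid defaults for every column."""
    from perceptrisk.responses import DEMOGRAPHICS, EMOTIONS, MEDIA

    n = len(next(iter(answers.values()))) if answers else overrides.get("n", 1)
    base = {
        "respondent_id": [f"R{i}" for i in range(n)],
        "age": [30] * n,
        "gender": ["female"] * n,
        "civil_status": ["partner"] * n,
        "education": ["undergraduate"] * n,
        "position": ["student"] * n,
    }
    for item in codebook.item_ids:
        base[item] = answers.get(item, [None] * n)
    for flag in (*EMOTIONS, *MEDIA):
        base[flag] = [0] * n
    base.update({k: v for k, v in overrides.items() if k != "n"})
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def small_survey():
    """Session-wide synthetic survey (n=300) reused across read-only tests."""
    return pr.generate(pr.GeneratorConfig(n=300, seed=11))
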
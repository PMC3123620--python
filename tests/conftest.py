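from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def make_paired(diffs: np.ndarray, baseline: float = 25.0):
    """Build (ct, annotation) whose per-feature paired differences equal ``diffs``.

    ``diffs`` is features x cases; normal samples sit at ``baseline`` and the
    malignant partner at ``baseline + diff``.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_feat, n_cases = diffs.shape
    samples, cols = [], []
    for c in range(1, n_cases + 1):
        samples += [f"{c}N", f"{c}M"]
        cols += [np.full(n_feat, baseline), baseline + diffs[:, c - 1]]
    ct = pd.DataFrame(
        np.column_stack(cols),
        index=[f"f{i}" for i in range(1, n_feat + 1)],
        columns=samples,
    )
    annot = pd.DataFrame(
        {
            "case_id": [s[:-1] for s in samples],
            "tissue_class": ["normal" if s.endswith("N") else "malignant" for s in samples],
            "gleason_score": np.nan,
            "tumor_pct": np.nan,
            "who_grade": np.nan,
            "paired": True,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ct, annot


@pytest.fixture
def paired_builder():
    return make_paired


@pytest.fixture
def rng():
    return np.random.default_rng(20110527)
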
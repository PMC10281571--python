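"""Shared fixtures: the two published rules and a default synthetic study."""

import numpy as np
import pandas as pd
import pytest

from garules import (
    CourseLabel,
    FeatureMatrix,
    RULE1_TEXT,
    RULE2_TEXT,
    SimConfig,
    parse_rule_text,
    simulate_discovery,
)


@pytest.fixture(scope="session")
def rule1():
    return parse_rule_text(RULE1_TEXT)


@pytest.fixture(scope="session")
def rule2():
    return parse_rule_text(RULE2_TEXT)


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study: 20/43 discovery cohort with the
    high-specificity rule planted at its published coverage."""
    return simulate_discovery(SimConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_labels(default_bundle):
    return {p: CourseLabel(v) for p, v in default_bundle.truth["labels"].items()}


def make_matrix(values, patient_ids=None, protein_ids=None) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    patient_ids = patient_ids or [f"P{i + 1:02d}" for i in range(n)]
    protein_ids = protein_ids or [f"G{j + 1:02d}" for j in range(p)]
    return FeatureMatrix(
        pd.DataFrame(values, index=pd.Index(patient_ids, name="patient_id"), columns=protein_ids)
    )


@pytest.fixture
def tiny_separable():
    """8-patient cohort where G01 <= 1.0 holds exactly for the favourable
    patients; G02 is uninformative."""
    values = [
        [0.5, 1.0],
        [0.8, 2.0],
        [0.9, 0.5],
        [0.7, 1.5],
        [1.5, 1.0],
        [2.0, 2.0],
        [1.8, 0.5],
        [2.5, 1.5],
    ]
    labels = [CourseLabel.FAVOURABLE] * 4 + [CourseLabel.UNFAVOURABLE] * 4
    return make_matrix(values), labels
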
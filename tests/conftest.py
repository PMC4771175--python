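"""Shared fixtures: small synthetic studies and discovery-set builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rppanet.consensus import DiscoverySet
from rppanet.synth import GroundTruth, generate_ground_truth, sample_cohorts


@pytest.fixture(scope="session")
def small_study():
    """8-antibody, 2-cohort study used across unit tests."""
    gt = generate_ground_truth(8, density=0.25, seed=11)
    return sample_cohorts(gt, {"C1": 300, "C2": 250}, noise_sd=0.05, seed=12)


@pytest.fixture(scope="session")
def chain_truth() -> GroundTruth:
    """3-variable chain A-B, B-C (no A-C): the canonical transitive motif."""
    antibodies = ["A", "B", "C"]
    P = np.array(
        [
            [1.8, -0.8, 0.0],
            [-0.8, 2.6, -0.8],
            [0.0, -0.8, 1.8],
        ]
    )
    from rppanet.data import make_annotation

    ann = make_annotation(antibodies, {a: [f"G_{a}"] for a in antibodies})
    return GroundTruth(
        antibodies=antibodies,
        edges=frozenset({("A", "B"), ("B", "C")}),
        precision=P,
        annotation=ann,
    )


def make_discovery(weights: dict, cohorts: list[str], significant: dict | None = None) -> DiscoverySet:
    """Build a DiscoverySet from {pair: [w_per_cohort]} dictionaries."""
    pairs = sorted(weights)
    index = pd.MultiIndex.from_tuples(pairs, names=["antibody1", "antibody2"])
    W = pd.DataFrame([weights[p] for p in pairs], index=index, columns=cohorts, dtype=float)
    if significant is None:
        S = pd.DataFrame(True, index=index, columns=cohorts)
    else:
        S = pd.DataFrame([significant[p] for p in pairs], index=index, columns=cohorts, dtype=bool)
    return DiscoverySet(weights=W, significant=S, threshold=len(pairs) + 1)
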
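"""Shared fixtures: a small cheap cohort for unit tests and one full-scale
study-condition analysis (computed once per session) for recovery checks."""

from __future__ import annotations

import numpy as np
import pytest

from stemfc import generate_cohort
from stemfc.pipeline import PipelineConfig, analyze_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort: 4 subjects, 60+20 nodes, 3 communities, 210 timepoints."""
    return generate_cohort(n_subjects=4, n_cortex=60, n_brainstem=20,
                           k_communities=3, n_timepoints=210, seed=11,
                           n_receptors=8, n_terms=20)


@pytest.fixture(scope="session")
def study_cohort():
    """Full study-condition cohort: 20 subjects x (400 + 58) nodes, K = 5."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def study_config():
    return PipelineConfig(seed=1, louvain_runs=50, n_rotations=1000)


@pytest.fixture(scope="session")
def study_result(study_cohort, study_config):
    """Full analysis chain on the study cohort (community sweep, association,
    gradients, spin test), shared across recovery and conservation tests."""
    return analyze_cohort(study_cohort, study_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
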
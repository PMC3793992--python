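"""Shared fixtures: short synthetic recordings for fast unit testing.

The short catalog keeps the native 204.8 Hz rate and all 13 activities but
shrinks bout durations so a subject takes well under a second to generate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from dlahar import Activity, default_profiles, generate_subject
from dlahar.pipeline import RunConfig, cohort_features
from dlahar.synthetic import generate_cohort


def short_profiles(duration_s: float = 20.0, bc_amplitude_ratio: float = 1.6):
    """Default archetypes with every bout cut to ``duration_s`` seconds."""
    return {
        act: dataclasses.replace(profile, duration_s=duration_s)
        for act, profile in default_profiles(bc_amplitude_ratio).items()
    }


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_subject():
    """One subject with 20 s bouts: (recording, segments)."""
    return generate_subject(0, profiles=short_profiles(), seed=42)


@pytest.fixture(scope="session")
def small_cohort_features():
    """(generic, rest) feature matrices of a 3-subject short cohort."""
    cohort = generate_cohort(3, seed=7, profiles=short_profiles())
    return cohort_features(cohort, RunConfig(n_subjects=3, seed=7))
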
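"""Shared fixtures: small seeded cohorts and recordings.

Everything is generated programmatically; the heavier multi-cohort study
used by the recovery tests is session-scoped so it is simulated once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import tovaqeeg as tq
from tovaqeeg.apen import apen_score
from tovaqeeg.covimg import covariance_image
from tovaqeeg.epochs import resting_segment, segment
from tovaqeeg.spectral import CONDITION_CLASSES


@pytest.fixture(scope="session")
def clean_profiles():
    """Paper-like crossover preset without blink/drift/line artifacts."""
    return tq.study_profiles(artifacts=False)


@pytest.fixture(scope="session")
def small_spec(clean_profiles):
    """Scaled-down cohort: 6+6 subjects, 48 s rest, 120 task trials."""
    return tq.CohortSpec(n_control=6, n_patient=6, rest_duration=48.0,
                         n_trials=120, n_targets=60, seed=7,
                         group_profiles=clean_profiles)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return tq.generate_cohort(small_spec)


def cohort_apen_scores(spec: tq.CohortSpec) -> pd.DataFrame:
    """Per-subject, per-condition entropy scores for one cohort."""
    cohort = tq.generate_cohort(spec)
    rows = []
    for s in cohort.subjects:
        trialsets = {"resting": resting_segment(s.resting),
                     "target": None, "nontarget": None}
        task = segment(s.tova, s.session)
        trialsets["target"] = trialsets["nontarget"] = task
        for cond in ("resting", "target", "nontarget"):
            img = covariance_image(trialsets[cond], CONDITION_CLASSES[cond],
                                   condition=cond)
            rows.append({"subject_id": s.subject_id, "group": s.group,
                         "condition": cond, "apen": apen_score(img).value,
                         "bdi": s.bdi})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def crossover_study(small_spec):
    """Entropy scores for 100 seeded cohorts with the crossover preset."""
    frames = []
    for k in range(100):
        spec = dataclasses.replace(small_spec, seed=10_000 + k)
        df = cohort_apen_scores(spec)
        df["cohort"] = k
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
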
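"""Shared fixtures: synthetic cohorts at the study's group-mean parameters.

Cohorts are generated once per test session (they are deterministic) and
reused by the per-module and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pfrkit import pipeline
from pfrkit.gaze_synth import OculomotorProfile

INTACT = dict(
    open_loop_gain=0.157,
    foveal_gain=0.186,
    misselect_prob=1.0 - 0.968,
    latency_mean_ms=360.0,
    latency_sd_ms=45.0,
)
BLIND = dict(
    open_loop_gain=0.0045,
    foveal_gain=0.150,
    misselect_prob=1.0 - 0.894,
    latency_mean_ms=382.0,
    latency_sd_ms=57.0,
)


def simulate_field_cohort(
    profile_kwargs: dict,
    seed: int,
    n_subjects: int = 11,
    n_trials: int = 150,
) -> pd.DataFrame:
    """Per-subject summaries for a single-field cohort (all apertures one field)."""
    prof = OculomotorProfile(**profile_kwargs)
    profiles = {"intact": prof, "blind": prof}
    rows = []
    for s, child in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        trials = pipeline.simulate_participant(profiles, n_trials, child)
        df = pipeline.measure_trials(trials)
        rows.append(
            {
                "participant": s,
                "open_loop_gain": df["open_loop_gain"].mean(),
                "foveal_gain": df.loc[df["stimulus_present"], "foveal_gain"].mean(),
                "correct_rate": df["correct"].mean(),
                "gt_correct_rate": np.mean([t.ground_truth["correct"] for t in trials]),
                "latency_ms": df["latency_ms"].mean(),
                "landing_mae_deg": df.loc[df["correct"], "landing_error_deg"].mean(),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def intact_cohort() -> pd.DataFrame:
    return simulate_field_cohort(INTACT, seed=101)


@pytest.fixture(scope="session")
def blind_cohort() -> pd.DataFrame:
    return simulate_field_cohort(BLIND, seed=202)
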
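"""Shared fixtures: programmatic builders of valid test sessions and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from speedcog.records import FIGID_N_ITEMS
from speedcog.simulate import _SGST_SEQUENCE, SimConfig, simulate_cohort

SGST_SEQUENCE = list(_SGST_SEQUENCE)


def build_sgst_session(
    latencies_ms,
    correct=None,
    respondent_id: str = "R000001",
    session_index: int = 1,
    device: str = "keyboard",
) -> pd.DataFrame:
    """A structurally valid 49-trial SGST session DataFrame."""
    n = len(SGST_SEQUENCE)
    latencies_ms = np.asarray(latencies_ms, dtype=float)
    assert len(latencies_ms) == n
    correct = np.ones(n, dtype=int) if correct is None else np.asarray(correct, int)
    return pd.DataFrame(
        {
            "respondent_id": respondent_id,
            "test": "SGST",
            "session_index": session_index,
            "device_type": device,
            "trial_index": np.arange(1, n + 1),
            "trial_type": SGST_SEQUENCE,
            "item_id": "",
            "block_id": "",
            "latency_ms": latencies_ms,
            "correct": correct,
        }
    )


def build_figid_session(
    latencies_ms,
    correct=None,
    item_order=None,
    respondent_id: str = "R000001",
    session_index: int = 1,
    device: str = "keyboard",
) -> pd.DataFrame:
    """A structurally valid 60-item figure-identification session DataFrame."""
    n = FIGID_N_ITEMS
    latencies_ms = np.asarray(latencies_ms, dtype=float)
    assert len(latencies_ms) == n
    correct = np.ones(n, dtype=int) if correct is None else np.asarray(correct, int)
    items = np.arange(1, n + 1) if item_order is None else np.asarray(item_order)
    return pd.DataFrame(
        {
            "respondent_id": respondent_id,
            "test": "FIGID",
            "session_index": session_index,
            "device_type": device,
            "trial_index": np.arange(1, n + 1),
            "trial_type": "",
            "item_id": items,
            "block_id": (items - 1) % 6 + 1,
            "latency_ms": latencies_ms,
            "correct": correct,
        }
    )


def random_sgst_session(rng: np.random.Generator, **kwargs) -> pd.DataFrame:
    """Random session with lognormal latencies and mixed correctness."""
    lat = np.exp(rng.normal(0.0, 0.4, 49)) * 1000
    correct = rng.random(49) < rng.uniform(0.5, 1.0)
    return build_sgst_session(np.round(lat, 1), correct.astype(int), **kwargs)


def random_figid_session(rng: np.random.Generator, **kwargs) -> pd.DataFrame:
    """Random figure session with occasional >30 s outliers."""
    lat = np.exp(rng.normal(1.5, 0.5, 60)) * 1000
    outlier = rng.random(60) < 0.05
    lat[outlier] = rng.uniform(30_001, 80_000, outlier.sum())
    correct = rng.random(60) < rng.uniform(0.5, 1.0)
    return build_figid_session(np.round(lat, 1), correct.astype(int), **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-respondent cohort with both tests, reused across tests."""
    config = SimConfig(n_respondents=300, seed=42)
    return config, simulate_cohort(config)
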
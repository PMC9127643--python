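"""Scoring of Stop and Go Switching Task (SGST) sessions.

Each session yields four scores: the median response time (seconds) over
the normal-baseline, reverse-baseline, nonswitch, and switch trials.
Medians damp the influence of stray slow responses, so no latency trimming
is applied.  Sessions with accuracy below 70% over the 49 scorable trials
are flagged invalid and receive no medians: the items are easy enough that
low accuracy indicates careless or inattentive responding, which also makes
the latencies untrustworthy.

By default medians are computed over correct trials only; pass
``include_incorrect_trials=True`` to include every trial of a type.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import trials_to_frame, validate_session
from .records import (
    ACCURACY_THRESHOLD,
    SGST_N_TRIALS,
    DeviceType,
    IntegrityError,
    SGSTScore,
    Test,
    TrialRecord,
    TrialType,
)

logger = logging.getLogger(__name__)

_MS_PER_S = 1000.0


def score_sgst_session(
    session: pd.DataFrame | Sequence[TrialRecord],
    include_incorrect_trials: bool = False,
) -> SGSTScore:
    """Score one validated SGST session.

    Accuracy is (# correct)/49 over all trials.  If accuracy < 0.70 the
    session is returned unscored (no medians).  Otherwise each trial type's
    median latency is computed in seconds; the median of an even number of
    latencies is the mean of the two central order statistics.
    """
    frame = (
        session
        if isinstance(session, pd.DataFrame)
        else trials_to_frame(list(session))
    )
    report = validate_session(frame)
    if report.test is not Test.SGST:
        raise IntegrityError(f"expected an SGST session, got {report.test.value}")
    if not report.valid:
        raise IntegrityError(
            f"session failed validation: {'; '.join(report.problems)}"
        )

    correct = frame["correct"].astype(int).to_numpy()
    accuracy = float(correct.sum()) / SGST_N_TRIALS
    base = SGSTScore(
        respondent_id=report.respondent_id,
        session_index=report.session_index,
        device_type=DeviceType(frame["device_type"].iloc[0]),
        accuracy=accuracy,
        scored=accuracy >= ACCURACY_THRESHOLD,
    )
    if not base.scored:
        return base

    latency_s = frame["latency_ms"].astype(float).to_numpy() / _MS_PER_S
    ttype = frame["trial_type"].astype(str).to_numpy()
    # a trial type with no correct responses has no defined median
    medians: dict[str, float | None] = {}
    for t in TrialType:
        mask = ttype == t.value
        if not include_incorrect_trials:
            mask = mask & (correct == 1)
        medians[t.value] = float(np.median(latency_s[mask])) if mask.any() else None
    return SGSTScore(
        respondent_id=base.respondent_id,
        session_index=base.session_index,
        device_type=base.device_type,
        accuracy=accuracy,
        scored=True,
        median_normal_s=medians["normal"],
        median_reverse_s=medians["reverse"],
        median_nonswitch_s=medians["nonswitch"],
        median_switch_s=medians["switch"],
    )


def score_sgst_log(
    trials: pd.DataFrame, include_incorrect_trials: bool = False
) -> pd.DataFrame:
    """Score every SGST session in a trial log.

    Returns one row per (respondent_id, session_index) with the SGSTScore
    fields as columns, in sorted key order.
    """
    frame = trials.loc[trials["test"] == Test.SGST.value]
    rows = []
    for _, group in frame.groupby(["respondent_id", "session_index"], sort=True):
        s = score_sgst_session(group, include_incorrect_trials)
        rows.append(
            {
                "respondent_id": s.respondent_id,
                "session_index": s.session_index,
                "device_type": s.device_type.value,
                "median_normal_s": s.median_normal_s,
                "median_reverse_s": s.median_reverse_s,
                "median_nonswitch_s": s.median_nonswitch_s,
                "median_switch_s": s.median_switch_s,
                "accuracy": s.accuracy,
                "scored": s.scored,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "respondent_id",
            "session_index",
            "device_type",
            "median_normal_s",
            "median_reverse_s",
            "median_nonswitch_s",
            "median_switch_s",
            "accuracy",
            "scored",
        ],
    )


def filter_scored(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a score table into (retained, excluded) by the ``scored`` flag."""
    retained = scores.loc[scores["scored"].astype(bool)]
    excluded = scores.loc[~scores["scored"].astype(bool)]
    logger.info(
        "validity filter: %d retained, %d excluded of %d sessions",
        len(retained),
        len(excluded),
        len(scores),
    )
    return retained, excluded
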
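"""Scoring of Figure Identification (perceptual speed) sessions.

All 60 figures are administered without a live timer; speed pressure is
reintroduced at scoring time by a *posterior time limit*: per-item latencies
are accumulated in administration order within each 30-item set, and a
figure counts toward the primary score only if it is correct and its
cumulative time through its own response is within 90 s.  Extreme latencies
above 30 s (rare pauses or walk-aways) are removed outright first: they
contribute neither time nor correctness anywhere downstream.

Secondary measures deliberately ignore the time limit: percent incorrect
and the median response time of accurate figures are computed over all
non-outlier figures, separating the accuracy and speed components of the
combined primary score.

The module also houses the item-to-block balancing randomization used to
build the 6 administration blocks from pilot item statistics.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import trials_to_frame, validate_session
from .records import (
    ACCURACY_THRESHOLD,
    FIGID_N_ITEMS,
    BlockAssignment,
    ConfigurationError,
    DeviceType,
    FigIDScore,
    IntegrityError,
    ItemStats,
    ScoringLimits,
    Test,
    TrialRecord,
)

_MS_PER_S = 1000.0


def remove_outlier_trials(
    session: pd.DataFrame, limits: ScoringLimits = ScoringLimits()
) -> tuple[pd.DataFrame, int]:
    """Drop trials with latency strictly above the outlier cut (default 30 s).

    Removed trials count toward nothing downstream.  The comparison is done
    in milliseconds (> 30000 ms) so a latency of exactly 30 s is retained.
    Administration order of the remainder is preserved.
    """
    lat_ms = session["latency_ms"].astype(float)
    keep = lat_ms <= limits.outlier_cut_s * _MS_PER_S
    return session.loc[keep], int((~keep).sum())


def apply_posterior_time_limit(
    trials: pd.DataFrame, limits: ScoringLimits = ScoringLimits()
) -> int:
    """Count correct figures answered within the per-set posterior time limit.

    ``trials`` is an outlier-free session in administration order whose
    ``trial_index`` still reflects the original administered positions:
    set 1 is positions 1-30, set 2 positions 31-60 (fixed before outlier
    removal).  Within each set the retained latencies are accumulated in
    order; a figure scores iff it is correct and its cumulative time through
    its own response is <= the set limit (inclusive at exactly 90.000 s).
    """
    if trials.empty:
        return 0
    set_size = FIGID_N_ITEMS // limits.n_sets
    pos = trials["trial_index"].astype(int).to_numpy()
    set_id = (pos - 1) // set_size
    lat_ms = trials["latency_ms"].astype(float).to_numpy()
    correct = trials["correct"].astype(int).to_numpy()
    limit_ms = limits.set_limit_s * _MS_PER_S
    score = 0
    for s in np.unique(set_id):
        in_set = set_id == s
        cum = np.cumsum(lat_ms[in_set])
        score += int(((cum <= limit_ms) & (correct[in_set] == 1)).sum())
    return score


def score_figid_session(
    session: pd.DataFrame | Sequence[TrialRecord],
    limits: ScoringLimits = ScoringLimits(),
) -> FigIDScore:
    """Score one validated figure-identification session.

    Primary score: correct figures within the posterior time limits, after
    outlier removal.  Accuracy = correct / non-outlier figures; the session
    is scored only if accuracy >= 0.70.  ``pct_incorrect`` and the median
    response time of correct figures use all non-outlier figures with no
    time limit.  A session whose figures are all outliers is unscored.
    """
    frame = (
        session
        if isinstance(session, pd.DataFrame)
        else trials_to_frame(list(session))
    )
    report = validate_session(frame)
    if report.test is not Test.FIGID:
        raise IntegrityError(f"expected a FIGID session, got {report.test.value}")
    if not report.valid:
        raise IntegrityError(f"session failed validation: {'; '.join(report.problems)}")

    retained, n_removed = remove_outlier_trials(frame, limits)
    n_kept = len(retained)
    if n_kept == 0:
        return FigIDScore(
            respondent_id=report.respondent_id,
            session_index=report.session_index,
            device_type=DeviceType(frame["device_type"].iloc[0]),
            score=0,
            accuracy=float("nan"),
            pct_incorrect=float("nan"),
            median_rt_correct_s=None,
            n_outliers_removed=n_removed,
            scored=False,
        )
    correct = retained["correct"].astype(int).to_numpy()
    accuracy = float(correct.sum()) / n_kept
    lat_s = retained["latency_ms"].astype(float).to_numpy() / _MS_PER_S
    median_rt = float(np.median(lat_s[correct == 1])) if correct.any() else None
    return FigIDScore(
        respondent_id=report.respondent_id,
        session_index=report.session_index,
        device_type=DeviceType(frame["device_type"].iloc[0]),
        score=apply_posterior_time_limit(retained, limits),
        accuracy=accuracy,
        pct_incorrect=100.0 * (1.0 - accuracy),
        median_rt_correct_s=median_rt,
        n_outliers_removed=n_removed,
        scored=accuracy >= ACCURACY_THRESHOLD,
    )


def score_figid_log(
    trials: pd.DataFrame, limits: ScoringLimits = ScoringLimits()
) -> pd.DataFrame:
    """Score every figure-identification session in a trial log."""
    frame = trials.loc[trials["test"] == Test.FIGID.value]
    rows = []
    for _, group in frame.groupby(["respondent_id", "session_index"], sort=True):
        s = score_figid_session(group, limits)
        rows.append(
            {
                "respondent_id": s.respondent_id,
                "session_index": s.session_index,
                "device_type": s.device_type.value,
                "score": s.score,
                "pct_incorrect": s.pct_incorrect,
                "median_rt_correct_s": s.median_rt_correct_s,
                "accuracy": s.accuracy,
                "n_outliers_removed": s.n_outliers_removed,
                "scored": s.scored,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "respondent_id",
            "session_index",
            "device_type",
            "score",
            "pct_incorrect",
            "median_rt_correct_s",
            "accuracy",
            "n_outliers_removed",
            "scored",
        ],
    )


def _block_balance_objective(
    medians_by_block: list[np.ndarray], var_median: float, var_iqr: float
) -> float:
    # Dispersion of per-block summaries (median and IQR of the item medians),
    # each standardized by the corresponding across-item dispersion so the
    # two terms are unit-free and comparable.
    block_medians = np.array([np.median(m) for m in medians_by_block])
    block_iqrs = np.array(
        [np.percentile(m, 75) - np.percentile(m, 25) for m in medians_by_block]
    )
    t1 = block_medians.var() / var_median if var_median > 0 else 0.0
    t2 = block_iqrs.var() / var_iqr if var_iqr > 0 else block_iqrs.var()
    return float(t1 + t2)


def design_item_blocks(
    items: Sequence[ItemStats],
    n_blocks: int = 6,
    n_iter: int = 500,
    seed: int | np.random.Generator = 0,
    return_objectives: bool = False,
) -> BlockAssignment | tuple[BlockAssignment, list[float]]:
    """Assign items to blocks, balancing difficulty, by constrained resampling.

    Items are ranked by pilot median response time (ascending, ties broken
    by item_id).  Each consecutive rank-group of ``n_blocks`` items is
    randomly permuted across the blocks, so every block receives exactly one
    item per difficulty stratum.  The randomization is repeated ``n_iter``
    times and the assignment with the most similar block-level median and
    IQR (smallest standardized across-block variance, ties to the earliest
    iteration) is returned.
    """
    items = list(items)
    if n_blocks < 1 or len(items) % n_blocks != 0:
        raise ConfigurationError(
            f"item count {len(items)} not divisible by n_blocks={n_blocks}"
        )
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ranked = sorted(items, key=lambda it: (it.median_rt, it.item_id))
    medians = np.array([it.median_rt for it in ranked])
    iqrs = np.array([it.iqr_rt for it in ranked])
    var_median = float(medians.var())
    var_iqr = float(iqrs.var())
    n_groups = len(ranked) // n_blocks

    best: tuple[float, int, np.ndarray] | None = None
    history: list[float] = []
    for it_index in range(1, n_iter + 1):
        # blocks[k] = block (0-based) of the k-th ranked item
        blocks = np.concatenate(
            [rng.permutation(n_blocks) for _ in range(n_groups)]
        )
        per_block = [medians[blocks == b] for b in range(n_blocks)]
        obj = _block_balance_objective(per_block, var_median, var_iqr)
        history.append(obj)
        if best is None or obj < best[0]:
            best = (obj, it_index, blocks)
    assert best is not None
    obj, chosen, blocks = best
    mapping = {it.item_id: int(b) + 1 for it, b in zip(ranked, blocks)}
    assignment = BlockAssignment(
        mapping=mapping, objective_value=obj, chosen_iteration=chosen
    )
    return (assignment, history) if return_objectives else assignment
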
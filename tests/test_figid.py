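"""Figure-identification scoring: outliers, posterior time limit, block design."""

import itertools

import numpy as np
import pytest

from speedcog.figid import (
    apply_posterior_time_limit,
    design_item_blocks,
    remove_outlier_trials,
    score_figid_session,
)
from speedcog.records import ConfigurationError, ItemStats, ScoringLimits
from conftest import build_figid_session, random_figid_session

LIMITS = ScoringLimits()


def oracle_figid_score(frame, limits=LIMITS):
    """Independent cumulative-clock walk over the administered trial list."""
    set_size = 60 // limits.n_sets
    clocks = {}
    score = 0
    for row in frame.itertuples():
        if row.latency_ms > limits.outlier_cut_s * 1000:
            continue  # outlier: no time, no credit
        s = (row.trial_index - 1) // set_size
        clocks[s] = clocks.get(s, 0.0) + row.latency_ms
        if row.correct == 1 and clocks[s] <= limits.set_limit_s * 1000:
            score += 1
    return score


class TestOutlierRemoval:
    def test_no_outliers_unchanged(self):
        frame = build_figid_session(np.full(60, 2000.0))
        kept, n = remove_outlier_trials(frame)
        assert n == 0 and len(kept) == 60

    def test_31s_trial_removed(self):
        lat = np.full(60, 2000.0)
        lat[7] = 31_000.0
        kept, n = remove_outlier_trials(build_figid_session(lat))
        assert n == 1 and len(kept) == 59

    def test_exactly_30s_retained(self):
        lat = np.full(60, 2000.0)
        lat[7] = 30_000.0
        kept, n = remove_outlier_trials(build_figid_session(lat))
        assert n == 0 and len(kept) == 60


class TestPosteriorTimeLimit:
    def test_boundary_inclusive_score_60(self):
        # 30 items x 3.0 s hits 90.000 s exactly at the last item of each set
        score = apply_posterior_time_limit(build_figid_session(np.full(60, 3000.0)))
        assert score == 60

    def test_3p1_seconds_gives_58(self):
        # 29 x 3.1 = 89.9 <= 90; the 30th exceeds the limit in each set
        score = apply_posterior_time_limit(build_figid_session(np.full(60, 3100.0)))
        assert score == 58

    def test_outlier_excluded_from_clock_and_credit(self):
        lat = np.full(60, 3000.0)
        lat[4] = 31_000.0  # administered position 5, set 1
        s = score_figid_session(build_figid_session(lat))
        # set 1: 29 retained x 3 s = 87 s, all within limit -> 29; set 2 -> 30
        assert s.score == 59 and s.n_outliers_removed == 1

    def test_matches_cumulative_clock_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            frame = random_figid_session(rng)
            s = score_figid_session(frame)
            assert s.score == oracle_figid_score(frame)

    def test_monotone_in_limit_and_unbounded_limit(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            frame = random_figid_session(rng)
            kept, _ = remove_outlier_trials(frame)
            s90 = apply_posterior_time_limit(kept, ScoringLimits(set_limit_s=90))
            s120 = apply_posterior_time_limit(kept, ScoringLimits(set_limit_s=120))
            s_inf = apply_posterior_time_limit(kept, ScoringLimits(set_limit_s=1e9))
            assert s90 <= s120 <= s_inf
            assert s_inf == int((kept["correct"] == 1).sum())


class TestSessionScore:
    def test_perfect_fast_session(self):
        s = score_figid_session(build_figid_session(np.full(60, 2000.0)))
        assert s.score == 60
        assert s.pct_incorrect == 0.0
        assert s.median_rt_correct_s == pytest.approx(2.0)
        assert s.scored

    @pytest.mark.parametrize("n_correct,expected", [(41, False), (42, True)])
    def test_70_percent_threshold_boundary(self, n_correct, expected):
        correct = np.zeros(60, dtype=int)
        correct[:n_correct] = 1
        s = score_figid_session(build_figid_session(np.full(60, 2000.0), correct))
        assert s.scored is expected

    def test_secondary_measures_ignore_time_limit(self):
        # slow but accurate: time limit caps the score, not the secondaries
        s = score_figid_session(build_figid_session(np.full(60, 10_000.0)))
        assert s.score == 18  # 9 items x 10 s fit per 90 s set
        assert s.accuracy == 1.0
        assert s.median_rt_correct_s == pytest.approx(10.0)


class TestBlockDesign:
    @staticmethod
    def _items(medians, iqrs=None):
        iqrs = iqrs if iqrs is not None else [0.5] * len(medians)
        return [
            ItemStats(item_id=i + 1, median_rt=m, iqr_rt=q)
            for i, (m, q) in enumerate(zip(medians, iqrs))
        ]

    def test_degenerate_identical_items_choose_iteration_1(self):
        items = self._items([2.0] * 60)
        a = design_item_blocks(items, seed=5)
        assert a.objective_value == 0.0 and a.chosen_iteration == 1

    def test_rank_group_constraint_holds_every_iteration(self):
        rng = np.random.default_rng(17)
        items = self._items(sorted(rng.uniform(2, 8, 60)), rng.uniform(0.2, 2, 60))
        for seed in range(5):
            a = design_item_blocks(items, n_blocks=6, n_iter=20, seed=seed)
            ranked = sorted(items, key=lambda it: (it.median_rt, it.item_id))
            for g in range(10):
                group = ranked[g * 6 : (g + 1) * 6]
                blocks = {a.mapping[it.item_id] for it in group}
                assert blocks == {1, 2, 3, 4, 5, 6}

    def test_sampler_finds_exhaustive_optimum_12_items_2_blocks(self):
        rng = np.random.default_rng(31)
        medians = sorted(rng.uniform(2, 8, 12))
        iqrs = rng.uniform(0.2, 2, 12)
        items = self._items(medians, iqrs)
        a = design_item_blocks(items, n_blocks=2, n_iter=500, seed=1)

        # brute force: each of the 6 rank pairs contributes one item per block
        from speedcog.figid import _block_balance_objective

        med = np.array([it.median_rt for it in sorted(items, key=lambda x: x.median_rt)])
        var_m = float(med.var())
        var_q = float(np.array(iqrs).var())
        best = np.inf
        for choice in itertools.product([0, 1], repeat=6):
            blocks = np.array([[c, 1 - c] for c in choice]).ravel()
            per_block = [med[blocks == b] for b in (0, 1)]
            best = min(best, _block_balance_objective(per_block, var_m, var_q))
        assert a.objective_value == pytest.approx(best)

    def test_returned_objective_not_worse_than_any_sampled(self):
        rng = np.random.default_rng(37)
        items = self._items(sorted(rng.uniform(2, 8, 60)), rng.uniform(0.2, 2, 60))
        a, history = design_item_blocks(items, n_iter=100, seed=3, return_objectives=True)
        assert len(history) == 100
        assert all(a.objective_value <= h for h in history)

    def test_indivisible_item_count_rejected(self):
        with pytest.raises(ConfigurationError):
            design_item_blocks(self._items([2.0] * 59), n_blocks=6)
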
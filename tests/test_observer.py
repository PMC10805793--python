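"""Generative checks on the simulated dual-task observers."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dualcap import ObserverParams, ag, rating_counts, simulate_observer
from dualcap.observer import ExperimentDesign, dprime_for_pc, matched_guess_dist
from dualcap.tradeoff import response_correct


def single_pc(trials, side):
    cue = f"single_{side}"
    sub = trials[trials["cue"] == cue]
    return response_correct(sub[f"resp_{side}"], sub[f"cat_{side}"]).mean()


class TestDesign:
    def test_block_mix_one_one_two(self):
        trials = simulate_observer(ObserverParams(), ExperimentDesign(n_blocks=60), seed=0)
        per_block = trials.groupby("block")["cue"].first()
        assert len(trials) == 1200
        assert (per_block == "dual").sum() == 30
        assert (per_block == "single_top").sum() == 15
        assert (per_block == "single_bottom").sum() == 15

    def test_single_trials_have_one_response_dual_have_two(self):
        trials = simulate_observer(ObserverParams(), seed=1)
        dual = trials[trials["cue"] == "dual"]
        assert dual["resp_top"].notna().all() and dual["resp_bottom"].notna().all()
        assert dual["first_response_side"].isin(["top", "bottom"]).all()
        st = trials[trials["cue"] == "single_top"]
        assert st["resp_top"].notna().all() and st["resp_bottom"].isna().all()
        sb = trials[trials["cue"] == "single_bottom"]
        assert sb["resp_bottom"].notna().all() and sb["resp_top"].isna().all()

    def test_seeded_runs_bit_reproducible(self):
        a = simulate_observer(ObserverParams(), seed=7)
        b = simulate_observer(ObserverParams(), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_categories_independent(self):
        trials = simulate_observer(
            ObserverParams(), ExperimentDesign.dual_only(20_000), seed=2
        )
        top = (trials["cat_top"] == "present").astype(int)
        bottom = (trials["cat_bottom"] == "present").astype(int)
        assert abs(np.corrcoef(top, bottom)[0, 1]) < 0.02


class TestRegimes:
    def test_single_task_pc_matches_phi_of_half_dprime(self):
        d = 1.19
        params = ObserverParams(dprime_top=d, dprime_bottom=d, fixation_break_rate=0.0)
        trials = simulate_observer(
            params, ExperimentDesign(n_blocks=400), seed=3
        )
        expected = norm.cdf(d / 2)
        assert single_pc(trials, "top") == pytest.approx(expected, abs=0.02)
        assert single_pc(trials, "bottom") == pytest.approx(expected, abs=0.02)

    def test_serial_p_top_one_leaves_bottom_at_chance(self):
        params = ObserverParams(regime="serial", p_top=1.0, fixation_break_rate=0.0)
        trials = simulate_observer(params, ExperimentDesign.dual_only(20_000), seed=4)
        pc_bottom = response_correct(trials["resp_bottom"], trials["cat_bottom"]).mean()
        assert pc_bottom == pytest.approx(0.5, abs=0.01)
        assert ag(rating_counts(trials, "bottom", "dual")) == pytest.approx(0.5, abs=0.01)

    def test_independent_dual_matches_single_ag(self):
        params = ObserverParams(regime="independent", fixation_break_rate=0.0)
        trials = simulate_observer(params, ExperimentDesign(n_blocks=400), seed=5)
        for side in ("top", "bottom"):
            a_single = ag(rating_counts(trials, side, f"single_{side}"))
            a_dual = ag(rating_counts(trials, side, "dual"))
            assert a_dual == pytest.approx(a_single, abs=0.02)

    def test_fixed_capacity_scales_sensitivity(self):
        params = ObserverParams(regime="fixed_capacity", w_top=1.0,
                                fixation_break_rate=0.0)
        trials = simulate_observer(params, ExperimentDesign.dual_only(20_000), seed=6)
        # w_top = 1: top at full sensitivity, bottom has none left.
        pc_top = response_correct(trials["resp_top"], trials["cat_top"]).mean()
        pc_bottom = response_correct(trials["resp_bottom"], trials["cat_bottom"]).mean()
        assert pc_top == pytest.approx(0.8, abs=0.01)
        assert pc_bottom == pytest.approx(0.5, abs=0.01)

    def test_symmetric_guesses_carry_no_signal(self):
        params = ObserverParams(
            regime="serial", p_top=1.0, guess_dist=(0.0, 0.5, 0.5, 0.0),
            fixation_break_rate=0.0,
        )
        trials = simulate_observer(params, ExperimentDesign.dual_only(20_000), seed=8)
        pc = response_correct(trials["resp_bottom"], trials["cat_bottom"]).mean()
        assert pc == pytest.approx(0.5, abs=0.01)


class TestParams:
    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            ObserverParams(regime="telepathic")

    def test_non_normalized_guess_dist_rejected(self):
        with pytest.raises(ValueError, match="guess_dist"):
            ObserverParams(guess_dist=(0.5, 0.5, 0.5, 0.5))

    def test_criteria_must_increase(self):
        with pytest.raises(ValueError, match="criteria"):
            ObserverParams(criteria=(1.0, 0.0, -1.0))

    def test_matched_guess_dist_is_rating_symmetric(self):
        g = matched_guess_dist(dprime_for_pc(0.8), (-1.0, 0.0, 1.0))
        assert g.sum() == pytest.approx(1.0)
        assert g[0] + g[1] == pytest.approx(g[2] + g[3])

    def test_selection_errors_swap_dual_reports(self):
        base = ObserverParams(regime="independent", fixation_break_rate=0.0)
        swapped = ObserverParams(
            regime="independent", selection_error_rate=1.0, fixation_break_rate=0.0
        )
        a = simulate_observer(base, ExperimentDesign.dual_only(200), seed=9)
        b = simulate_observer(swapped, ExperimentDesign.dual_only(200), seed=9)
        pd.testing.assert_series_equal(
            a["resp_top"], b["resp_bottom"], check_names=False
        )
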
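"""Bootstrap CIs, t tests, JZS Bayes factors, repeated-measures interaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from dualcap import bootstrap_ci, describe_effect, jzs_bf, one_sample_t, rm_interaction_test


class TestBootstrapCI:
    def test_constant_vector_collapses(self):
        lo, hi = bootstrap_ci([3.0, 3.0, 3.0], seed=0)
        assert lo == hi == 3.0

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(1).normal(size=20)
        assert bootstrap_ci(x, seed=42) == bootstrap_ci(x, seed=42)

    def test_coverage_near_nominal(self):
        # 500 replicate standard-normal datasets of n = 30: the 95% CI
        # should cover the true mean 0 about 95% of the time.
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 4000  # Monte Carlo se ~0.004 on a ~0.93 coverage rate
        for i in range(n_rep):
            x = rng.normal(size=30)
            lo, hi = bootstrap_ci(x, n_boot=1000, seed=100_000 + i)
            covered += lo <= 0.0 <= hi
        assert 0.92 <= covered / n_rep <= 0.98

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        widths = []
        for n in (25, 100, 400):
            ws = []
            for i in range(40):
                x = rng.normal(size=n)
                lo, hi = bootstrap_ci(x, seed=i)
                ws.append(hi - lo)
            widths.append(np.mean(ws))
        # ~1/sqrt(n): each 4x increase in n should halve the width.
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.2)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.2)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])


class TestOneSampleT:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            one_sample_t([1.0, 1.0, 1.0])

    def test_symmetric_data_give_t_zero(self):
        res = one_sample_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.df == 4

    def test_matches_longhand_formula(self):
        x = np.random.default_rng(3).normal(0.5, 1.0, size=11)
        res = one_sample_t(x)
        expected_t = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        assert res.df == 10
        assert res.sem == pytest.approx(x.std(ddof=1) / np.sqrt(11), abs=1e-12)


class TestJZSBayesFactor:
    def test_no_effect_favors_null(self):
        assert jzs_bf(0.0, 11) < 1.0
        assert jzs_bf(0.0, 50) < jzs_bf(0.0, 5)

    @pytest.mark.parametrize("n", [5, 11, 40])
    def test_strictly_increasing_in_abs_t(self, n):
        ts = np.linspace(0.0, 8.0, 17)
        bfs = [jzs_bf(t, n) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    @given(t=st.floats(-6.0, 6.0), n=st.integers(3, 60))
    @settings(max_examples=60, deadline=None)
    def test_matches_independent_implementation(self, t, n):
        pingouin = pytest.importorskip("pingouin")
        theirs = float(pingouin.bayesfactor_ttest(t, n, paired=True))
        assert jzs_bf(t, n) == pytest.approx(theirs, rel=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf(np.inf, 11)
        with pytest.raises(ValueError):
            jzs_bf(2.0, 1)


class TestDescribeEffect:
    def test_bundle_is_internally_consistent(self):
        x = np.random.default_rng(9).normal(0.3, 1.0, size=15)
        res = describe_effect(x, seed=1)
        assert res.ci_low <= res.mean_diff <= res.ci_high
        assert res.bf == pytest.approx(jzs_bf(res.t, 15), rel=1e-9)


def make_table(values_by_cell, subjects):
    rows = []
    for s, subject in enumerate(subjects):
        for (side, cue), vals in values_by_cell.items():
            rows.append(
                {"subject": subject, "side": side, "cue_condition": cue,
                 "value": vals[s]}
            )
    return pd.DataFrame(rows)


class TestRMInteraction:
    def test_additive_table_has_no_interaction(self):
        rng = np.random.default_rng(5)
        n = 12
        subject_effect = rng.normal(size=n)
        cells = {}
        for i, side in enumerate(("top", "bottom")):
            for j, cue in enumerate(("single", "dual")):
                cells[(side, cue)] = (
                    0.7 + 0.05 * i + 0.08 * j + subject_effect * 0.01
                    + rng.normal(scale=1e-6, size=n)
                )
        f, df1, df2, p = rm_interaction_test(make_table(cells, range(n)))
        # With purely additive structure the interaction F is null-distributed.
        assert p > 0.05
        assert (df1, df2) == (1, n - 1)

    def test_crossover_detected(self):
        rng = np.random.default_rng(6)
        n = 11
        cells = {
            ("top", "single"): 0.70 + rng.normal(scale=0.02, size=n),
            ("bottom", "single"): 0.80 + rng.normal(scale=0.02, size=n),
            ("top", "dual"): 0.80 + rng.normal(scale=0.02, size=n),
            ("bottom", "dual"): 0.70 + rng.normal(scale=0.02, size=n),
        }
        f, _, _, p = rm_interaction_test(make_table(cells, range(n)))
        assert p < 0.05
        assert f > 10

    def test_incomplete_table_rejected(self):
        rng = np.random.default_rng(7)
        cells = {
            (s, c): rng.normal(size=4)
            for s in ("top", "bottom") for c in ("single", "dual")
        }
        table = make_table(cells, range(4))
        table = table[~((table["subject"] == 2) & (table["side"] == "top")
                        & (table["cue_condition"] == "dual"))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_interaction_test(table)

    def test_null_p_values_roughly_uniform(self):
        # Independent null datasets: the interaction p-value should be
        # uniform on [0, 1].
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(300):
            cells = {
                (s, c): rng.normal(size=8)
                for s in ("top", "bottom") for c in ("single", "dual")
            }
            _, _, _, p = rm_interaction_test(make_table(cells, range(8)))
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01
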
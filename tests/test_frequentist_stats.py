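"""t-test and repeated-measures ANOVA against brute-force formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dreadchoice import CohortSpec, block_aggregate, generate_binomial_cohort, one_sample_t, rm_anova


def brute_force_t(values, chance):
    x = np.asarray(values, dtype=float)
    n = len(x)
    t = (x.mean() - chance) / (x.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p


def tidy_cells(y):
    """subjects x a-levels x b-levels cube -> tidy frame."""
    n, p, q = y.shape
    rows = [
        {"subject_id": f"s{s}", "a": i + 1, "b": j + 1, "percent": y[s, i, j]}
        for s in range(n)
        for i in range(p)
        for j in range(q)
    ]
    return pd.DataFrame(rows)


class TestOneSampleT:
    def test_null_case(self):
        r = one_sample_t([40.0, 60.0, 45.0, 55.0])
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_hand_oracle(self):
        r = one_sample_t([55.0, 60.0, 50.0, 45.0, 65.0])
        assert r.df == 4
        assert r.mean == pytest.approx(55.0)
        assert r.t == pytest.approx(5.0 / (7.905694 / np.sqrt(5)), abs=1e-5)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(20):
            values = rng.normal(52, 8, size=rng.integers(3, 30))
            t, p = brute_force_t(values, 50.0)
            r = one_sample_t(values)
            assert r.t == pytest.approx(t, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)

    def test_shift_invariance(self, rng):
        values = rng.normal(55, 5, 12)
        r1 = one_sample_t(values, chance=50.0)
        r2 = one_sample_t(values + 17.0, chance=67.0)
        assert r1.t == pytest.approx(r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([55.0])
        with pytest.raises(ValueError):
            one_sample_t([55.0, 55.0, 55.0])


class TestBlockAggregate:
    def test_uniform_chooser_fills_all_cells(self, design1):
        table = generate_binomial_cohort(
            CohortSpec(n_subjects=2, n_sessions=4, p_choice=1.0, seed=1), design1
        )
        for blocking in ("trial_block", "session_block"):
            cells = block_aggregate(table, blocking)
            assert (cells["percent"] == 100.0).all()

    def test_trial_block_cut_at_free_trial_eight(self, handmade_table):
        """The fixture's 16 free trials are 7 EL, 7 LL, 2 omissions in order
        EL*7, LL*7, omission*2: block 1 (free trials 1-8) = 7 EL + 1 LL."""
        cells = block_aggregate(handmade_table, "trial_block")
        b1 = cells[(cells["a"] == 1) & (cells["b"] == 1)]["percent"].item()
        b2 = cells[(cells["a"] == 2) & (cells["b"] == 1)]["percent"].item()
        assert b1 == pytest.approx(100.0 * 7 / 8)
        assert b2 == pytest.approx(0.0)  # 6 LL choices + 2 omissions

    def test_session_block_layout(self, design1):
        table = generate_binomial_cohort(
            CohortSpec(n_subjects=1, n_sessions=10, p_choice=0.5, seed=3), design1
        )
        cells = block_aggregate(table, "session_block")
        assert set(cells["a"]) == {1, 2}
        assert set(cells["b"]) == {1, 2, 3, 4, 5}
        assert len(cells) == 10

    def test_empty_cell_is_nan(self, design1):
        table = generate_binomial_cohort(
            CohortSpec(n_subjects=1, n_sessions=2, p_choice=0.5, omission_rate=1.0, seed=4),
            design1,
        )
        cells = block_aggregate(table, "trial_block")
        assert cells["percent"].isna().all()


class TestRmAnova:
    def test_no_effect_when_levels_identical(self, rng):
        base = rng.normal(50, 10, size=(8, 1, 4))
        y = np.repeat(base, 2, axis=1)  # factor a has identical levels
        res = rm_anova(tidy_cells(y))
        assert res.effects["a"].F == pytest.approx(0.0, abs=1e-20)

    def test_two_level_factor_equals_squared_paired_t(self, rng):
        """For a 2-level within factor, F = t^2 of the paired t on level differences."""
        y = rng.normal(50, 10, size=(12, 2, 5))
        res = rm_anova(tidy_cells(y))
        diffs = y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)
        t = stats.ttest_1samp(diffs, 0.0)
        assert res.effects["a"].F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.effects["a"].p == pytest.approx(t.pvalue, rel=1e-8)

    def test_ss_partition_identity(self, rng):
        """Sum of all effect, error and subject strata equals total SS computed
        independently from the raw data."""
        y = rng.normal(50, 10, size=(10, 2, 6))
        res = rm_anova(tidy_cells(y))
        ss_total_oracle = float(((y - y.mean()) ** 2).sum())
        parts = res.ss_subjects + sum(e.ss + e.ss_err for e in res.effects.values())
        assert parts == pytest.approx(ss_total_oracle, rel=1e-8)
        assert res.ss_total == pytest.approx(ss_total_oracle, rel=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(50, 8, size=(9, 2, 4))
        cells = tidy_cells(y)
        ours = rm_anova(cells)
        theirs = pg.rm_anova(
            data=cells, dv="percent", within=["a", "b"], subject="subject_id", effsize="np2"
        ).set_index("Source")
        for name, key in [("a", "a"), ("b", "b"), ("a*b", "a * b")]:
            assert ours.effects[name].F == pytest.approx(theirs.loc[key, "F"], rel=1e-6)
            assert ours.effects[name].p == pytest.approx(
                theirs.loc[key, "p_unc"], rel=1e-6
            )
            assert ours.effects[name].eta_sq == pytest.approx(
                theirs.loc[key, "np2"], rel=1e-6
            )

    def test_gg_corrected_p_never_smaller(self, rng):
        y = rng.normal(50, 10, size=(10, 2, 6))
        # induce a sphericity violation by scaling one level of b
        y[:, :, 0] *= 3.0
        res = rm_anova(tidy_cells(y))
        e = res.effects["b"]
        assert e.gg_epsilon is not None and e.gg_epsilon <= 1.0
        assert e.p_gg >= e.p
        assert e.df_num_gg <= e.df_num and e.df_den_gg <= e.df_den

    def test_listwise_deletion_reduces_df(self, rng):
        y = rng.normal(50, 10, size=(8, 2, 3))
        cells = tidy_cells(y)
        cells.loc[(cells["subject_id"] == "s0") & (cells["a"] == 1) & (cells["b"] == 1), "percent"] = np.nan
        res = rm_anova(cells)
        assert res.n_subjects == 7
        assert res.n_dropped == 1
        assert res.effects["a"].df_den == 6  # (n-1)*(p-1) with n=7

    def test_too_few_complete_subjects_rejected(self, rng):
        y = rng.normal(50, 10, size=(2, 2, 2))
        cells = tidy_cells(y)
        cells.loc[cells["subject_id"] == "s0", "percent"] = np.nan
        with pytest.raises(ValueError):
            rm_anova(cells)
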
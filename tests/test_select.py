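"""Selection calibration: null retention rates, power, and regime nesting."""

import numpy as np
import pandas as pd
import pytest

from emodecode import FeatureMatrix, phase1_baseline_ttest, phase2_anova, run_selection

CONDITIONS = ("distressed", "excited", "depressed", "relaxed", "neutral")


def _fm(values, conditions, family="msc", band="alpha", names=None, is_baseline=False):
    n, d = values.shape
    names = names or [f"{family}.{band}.c{j}" for j in range(d)]
    return FeatureMatrix(
        data=pd.DataFrame(values, columns=names),
        labels=pd.DataFrame(
            {
                "condition": conditions,
                "participant": np.ones(n, dtype=int),
                "session": np.ones(n, dtype=int),
                "trial": np.arange(n),
            }
        ),
        family=family,
        is_baseline=is_baseline,
    )


def _balanced_conditions(n_per):
    return np.repeat(CONDITIONS, n_per)


class TestPhase1:
    def test_null_columns_essentially_never_survive_all_four_tests(self):
        rng = np.random.default_rng(0)
        n_per, d = 100, 2000
        conds = _balanced_conditions(n_per)
        emo = _fm(rng.standard_normal((len(conds), d)), conds)
        base = _fm(rng.standard_normal((len(conds), d)), conds, is_baseline=True)
        mask, p = phase1_baseline_ttest(emo, base)
        assert p.shape == (d, 4)
        assert mask.sum() <= 1  # expected survivors ~ d * 0.05**4 ~ 0.01

    def test_strong_shared_shift_is_retained(self):
        rng = np.random.default_rng(1)
        n_per = 300
        conds = _balanced_conditions(n_per)
        base_vals = rng.standard_normal((len(conds), 3))
        emo_vals = base_vals + rng.standard_normal(base_vals.shape)
        emo_vals[conds != "neutral", 0] += 3.0  # 3 pooled-sd shift, all conditions
        mask, _ = phase1_baseline_ttest(_fm(emo_vals, conds), _fm(base_vals, conds, is_baseline=True))
        assert bool(mask.iloc[0])

    def test_shift_in_single_condition_fails_intersection(self):
        rng = np.random.default_rng(2)
        conds = _balanced_conditions(200)
        base_vals = rng.standard_normal((len(conds), 2))
        emo_vals = rng.standard_normal((len(conds), 2))
        emo_vals[conds == "excited", 0] += 3.0
        mask, p = phase1_baseline_ttest(_fm(emo_vals, conds), _fm(base_vals, conds, is_baseline=True))
        assert not mask.any()
        assert p.loc[p.index[0], "excited"] < 0.05  # it does pass its own test

    def test_neutral_rows_are_not_tested(self):
        rng = np.random.default_rng(3)
        conds = _balanced_conditions(150)
        base_vals = rng.standard_normal((len(conds), 1))
        emo_vals = rng.standard_normal((len(conds), 1))
        emo_vals[conds == "neutral", 0] += 10.0  # only neutral differs
        mask, p = phase1_baseline_ttest(_fm(emo_vals, conds), _fm(base_vals, conds, is_baseline=True))
        assert "neutral" not in p.columns
        assert not mask.any()


class TestPhase2:
    def test_null_retention_rate_is_about_alpha(self):
        """Under a global null the per-column retention rate must sit inside
        the binomial band around the 1% ANOVA level."""
        rng = np.random.default_rng(4)
        d = 10_000
        conds = _balanced_conditions(60)
        fm = _fm(rng.standard_normal((len(conds), d)), conds)
        mask, _ = phase2_anova(fm)
        rate = mask.mean()
        se = np.sqrt(0.01 * 0.99 / d)
        assert abs(rate - 0.01) < 4 * se

    def test_one_sd_shift_detected_with_high_power(self):
        rng = np.random.default_rng(5)
        d = 200
        conds = _balanced_conditions(300)
        vals = rng.standard_normal((len(conds), d))
        vals[conds == "excited"] += 1.0  # 1 sd on every column
        mask, _ = phase2_anova(_fm(vals, conds))
        assert mask.mean() > 0.99

    def test_any_pairwise_difference_suffices(self):
        conds = _balanced_conditions(30)
        vals = np.where(np.isin(conds, ["distressed", "excited"]), 1.0, 0.0)[:, None]
        vals = vals + np.random.default_rng(6).normal(0, 0.1, vals.shape)
        mask, _ = phase2_anova(_fm(vals, conds))
        assert bool(mask.iloc[0])


class TestRunSelection:
    def _planted_dataset(
        self, rng, n_per=200, d_null=400, d_true=20, effect=1.0, all_conditions=False
    ):
        """Null columns plus planted ones; planted columns shift either one
        condition (ANOVA-detectable only) or all four non-neutral conditions
        with graded magnitudes (also baseline-contrast detectable)."""
        conds = _balanced_conditions(n_per)
        null = rng.standard_normal((len(conds), d_null))
        true = rng.standard_normal((len(conds), d_true))
        for j in range(d_true):
            if all_conditions:
                for i, cond in enumerate(CONDITIONS[:4]):
                    true[conds == cond, j] += effect * (1.0 + 0.5 * i)
            else:
                true[conds == CONDITIONS[j % 4], j] += effect
        names = [f"msc.alpha.n{j}" for j in range(d_null)] + [
            f"msc.beta.t{j}" for j in range(d_true)
        ]
        emo = _fm(np.hstack([null, true]), conds, names=names)
        base = _fm(rng.standard_normal(emo.data.shape), conds, names=names, is_baseline=True)
        return emo, base, [f"msc.beta.t{j}" for j in range(d_true)]

    def test_planted_one_sd_effects_recovered(self):
        """Non-normalized selection must recover planted 1-sd contrasts at
        200 observations per condition."""
        rng = np.random.default_rng(7)
        recovered = []
        for _ in range(5):
            emo, base, truth = self._planted_dataset(rng)
            res, _ = run_selection(emo, base, mode="non_normalized")
            kept = set(res.retained_columns)
            recovered.append(np.mean([t in kept for t in truth]))
        assert np.mean(recovered) >= 0.90

    def test_normalized_retained_is_subset_of_non_normalized(self):
        rng = np.random.default_rng(8)
        conds = _balanced_conditions(150)
        base_vals = rng.standard_normal((len(conds), 50))
        emo_vals = base_vals + rng.standard_normal(base_vals.shape)
        emo_vals[conds != "neutral", :10] += 1.5
        emo_vals[conds == "excited", :25] += 1.0
        emo, base = _fm(emo_vals, conds), _fm(base_vals, conds, is_baseline=True)
        res_nn, _ = run_selection(emo, base, mode="non_normalized")
        res_n, _ = run_selection(emo, base, mode="normalized")
        assert set(res_n.retained_columns) <= set(res_nn.retained_columns)

    def test_selection_is_row_order_invariant(self):
        rng = np.random.default_rng(9)
        emo, base, _ = self._planted_dataset(
            rng, n_per=50, d_null=60, d_true=5, effect=2.0, all_conditions=True
        )
        res1, _ = run_selection(emo, base, mode="normalized")
        perm = rng.permutation(len(emo.data))
        emo_p = _fm(emo.data.to_numpy()[perm], emo.labels["condition"].to_numpy()[perm],
                    names=list(emo.data.columns))
        base_p = _fm(base.data.to_numpy()[perm], base.labels["condition"].to_numpy()[perm],
                     names=list(base.data.columns), is_baseline=True)
        res2, _ = run_selection(emo_p, base_p, mode="normalized")
        assert set(res1.retained_columns) == set(res2.retained_columns)

    def test_constant_columns_dropped_and_logged(self):
        rng = np.random.default_rng(10)
        conds = _balanced_conditions(30)
        vals = rng.standard_normal((len(conds), 3))
        vals[:, 1] = 0.0  # e.g. a GC diagonal column
        vals[conds == "excited", 0] += 3.0
        emo = _fm(vals, conds)
        res, red = run_selection(emo, mode="non_normalized")
        name = emo.data.columns[1]
        assert name in res.dropped_undefined
        assert name not in red.data.columns

    def test_zero_retained_raises_actionable_error(self):
        rng = np.random.default_rng(11)
        conds = _balanced_conditions(20)
        emo = _fm(rng.standard_normal((len(conds), 5)), conds)
        with pytest.raises(ValueError, match="retained no features"):
            run_selection(emo, mode="non_normalized")

    def test_counts_table_has_band_columns_and_total(self):
        rng = np.random.default_rng(12)
        emo, base, _ = self._planted_dataset(
            rng, n_per=100, d_null=50, d_true=10, effect=2.0, all_conditions=True
        )
        res, _ = run_selection(emo, base, mode="normalized")
        table = res.counts()
        assert list(table.columns) == ["alpha", "beta", "Total"]
        assert list(table.index) == ["t-test", "ANOVA"]
        assert (table["Total"] == table[["alpha", "beta"]].sum(axis=1)).all()

    def test_reduced_matrix_preserves_column_order_and_rows(self):
        rng = np.random.default_rng(13)
        emo, base, _ = self._planted_dataset(rng, n_per=100, d_null=50, d_true=10, effect=2.0)
        _, red = run_selection(emo, base, mode="non_normalized")
        original_order = [c for c in emo.data.columns if c in set(red.data.columns)]
        assert list(red.data.columns) == original_order
        assert len(red.data) == len(emo.data)


class TestScaleInvariance:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**31 - 1), scale=st.floats(1e-3, 1e3))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_anova_retention_invariant_to_positive_column_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        conds = _balanced_conditions(20)
        vals = rng.standard_normal((len(conds), 8))
        vals[conds == "excited", :2] += 2.0
        m1, _ = phase2_anova(_fm(vals, conds))
        m2, _ = phase2_anova(_fm(vals * scale, conds))
        assert m1.equals(m2)
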
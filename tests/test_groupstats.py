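"""Statistical machinery against hand-computed and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperdifc import (WindowSpec, anova_map, cubic_trend, fdr_bh,
                       interaction_power, mixed_anova_interaction,
                       reliability, required_sample_size, roi_ttest,
                       score_scale, score_table, voltage_magnitude)
from hyperdifc.difc import DIFCTensor
from hyperdifc.groupstats import magnitude_table

from conftest import make_recording

RNG = np.random.default_rng(123)


# ---------------------------------------------------------------------------
# voltage magnitude and ROI t-test
# ---------------------------------------------------------------------------

class TestVoltageMagnitude:
    def test_zero_channel(self):
        rec = make_recording(np.zeros((6, 100)),
                             ["Fp1", "Fp2", "Cz", "Pz", "TP9", "TP10"])
        assert voltage_magnitude(rec)["Cz"] == 0.0

    def test_unit_sinusoid_mean_abs(self):
        # mean |sin| over whole periods = 2/pi
        t = np.arange(10000) / 1000.0
        x = np.vstack([np.sin(2 * np.pi * 5 * t)] * 6)
        rec = make_recording(x, ["Fp1", "Fp2", "Cz", "Pz", "TP9", "TP10"],
                             fs=1000.0)
        assert voltage_magnitude(rec)["Cz"] == pytest.approx(2 / np.pi,
                                                             abs=1e-3)

    def test_homogeneity(self):
        x = RNG.standard_normal((6, 500))
        names = ["Fp1", "Fp2", "Cz", "Pz", "TP9", "TP10"]
        m1 = voltage_magnitude(make_recording(x, names))
        m2 = voltage_magnitude(make_recording(2 * x, names))
        np.testing.assert_allclose(m2.values, 2 * m1.values)


class TestRoiTtest:
    def test_hand_computed_pooled_t(self):
        # groups [1,2,3] vs [2,3,4]: sp^2 = 1, t = -1/sqrt(2/3) = -1.2247
        mags = pd.DataFrame({"Cz": [1.0, 2, 3, 2, 3, 4]},
                            index=list("abcdef"))
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        res = roi_ttest(mags, labels)[0]
        assert res.t == pytest.approx(-1.2247, abs=1e-4)

    def test_identical_groups_null(self):
        mags = pd.DataFrame({"Cz": [1.0, 2, 3, 1, 2, 3]},
                            index=list("abcdef"))
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        res = roi_ttest(mags, labels)[0]
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_effect_channel_recovered_across_seeds(self):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 20
            mags = pd.DataFrame(rng.standard_normal((2 * n, 4)),
                                columns=list("ABCD"))
            labels = pd.Series([0] * n + [1] * n)
            mags.loc[labels == 1, "C"] += 1.5  # large channel-specific effect
            res = {r.channel: r for r in roi_ttest(mags, labels)}
            if res["C"].significant:
                hits += 1
        assert hits >= 9


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def anova_ss_oracle(y, groups):
    """Independent sums-of-squares oracle written from the textbook
    decomposition (plain loops, no shared code with the implementation)."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    n, m = y.shape
    gs = np.unique(groups)
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    grand = y.mean()
    ss_int, ss_err = 0.0, 0.0
    for g in gs:
        rows = y[groups == g]
        cell = rows.mean(axis=0)
        gmean = rows.mean()
        for k in range(m):
            ss_int += len(rows) * (cell[k] - gmean - cond_mean[k] + grand) ** 2
        for r, srow in zip(rows, subj_mean[groups == g]):
            for k in range(m):
                ss_err += (r[k] - srow - cell[k] + gmean) ** 2
    df1 = (len(gs) - 1) * (m - 1)
    df2 = (n - len(gs)) * (m - 1)
    return ss_int, ss_err, df1, df2


class TestMixedAnova:
    def test_parallel_profiles_no_interaction(self):
        # group cell-mean hand effects identical (0.75 each, dyadic exact)
        # while individual dyads still vary around them
        y = np.array([[0.0, 0.5], [2.0, 3.0], [1.0, 1.25], [3.0, 4.25]])
        F, p, eta = mixed_anova_interaction(y, [0, 0, 1, 1])
        assert F == 0.0
        assert eta == 0.0
        assert p == 1.0

    def test_four_pair_hand_oracle(self):
        y = np.array([[1.0, 2.0], [2.0, 2.5], [3.0, 2.0], [2.5, 1.0]])
        groups = np.array([0, 0, 1, 1])
        ss_int, ss_err, df1, df2 = anova_ss_oracle(y, groups)
        F_oracle = (ss_int / df1) / (ss_err / df2)
        F, p, eta = mixed_anova_interaction(y, groups)
        assert F == pytest.approx(F_oracle, abs=1e-10)
        assert eta == pytest.approx(ss_int / (ss_int + ss_err), abs=1e-10)

    def test_matches_pingouin_unbalanced(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        n1, n2 = 5, 8
        y = rng.standard_normal((n1 + n2, 2))
        groups = np.array([0] * n1 + [1] * n2)
        F, p, eta = mixed_anova_interaction(y, groups)
        df = pd.DataFrame({
            "value": y.ravel(),
            "hand": ["off", "on"] * (n1 + n2),
            "pair": np.repeat(np.arange(n1 + n2), 2),
            "group": np.repeat(groups, 2),
        })
        aov = pg.mixed_anova(df, dv="value", within="hand", subject="pair",
                             between="group").set_index("Source")
        assert F == pytest.approx(float(aov.loc["Interaction", "F"]),
                                  rel=1e-6)
        assert p == pytest.approx(float(aov.loc["Interaction", "p_unc"]),
                                  rel=1e-6)

    def test_equals_squared_pooled_t_on_differences(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        y = rng.standard_normal((12, 2))
        groups = np.array([0] * 5 + [1] * 7)
        F, p, _ = mixed_anova_interaction(y, groups)
        d = y[:, 1] - y[:, 0]
        t, pt = stats.ttest_ind(d[groups == 0], d[groups == 1])
        assert F == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_invariances(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal((10, 2))
        groups = np.array([0] * 5 + [1] * 5)
        F0, _, _ = mixed_anova_interaction(y, groups)
        F_shift, _, _ = mixed_anova_interaction(y + 3.7, groups)
        F_swap, _, _ = mixed_anova_interaction(y[:, ::-1], groups)
        assert F0 == pytest.approx(F_shift, rel=1e-10)
        assert F0 == pytest.approx(F_swap, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova_interaction(RNG.standard_normal((6, 2)), [0] * 6)

    def test_missing_condition_pair_excluded(self):
        y = RNG.standard_normal((8, 2))
        y[3, 1] = np.nan
        groups = np.array([0] * 4 + [1] * 4)
        with pytest.warns(UserWarning):
            F, p, eta = mixed_anova_interaction(y, groups)
        F2, _, _ = mixed_anova_interaction(np.delete(y, 3, axis=0),
                                           np.delete(groups, 3))
        assert F == pytest.approx(F2, rel=1e-12)


# ---------------------------------------------------------------------------
# ANOVA map over tensors
# ---------------------------------------------------------------------------

def _toy_tensors(effect=0.0, n_pairs=12, n_win=6, seed=0):
    """Direct tensor construction: lover hand-on r raised by ``effect`` in the
    second half of the window axis."""
    rng = np.random.default_rng(seed)
    tensors = []
    chans = ["Cz", "Pz"]
    for k in range(n_pairs):
        rel = 1 if k < n_pairs // 2 else 0
        pair_noise = 0.1 * rng.standard_normal()
        for hand in ("off", "on"):
            vals = 0.2 + pair_noise + 0.05 * rng.standard_normal((2, 2, n_win))
            if rel == 1 and hand == "on" and effect:
                vals[:, :, n_win // 2:] += effect
            tensors.append(DIFCTensor(
                pair_id=f"P{k:02d}", relationship=rel, hand=hand,
                male_channels=chans, female_channels=chans,
                values=np.clip(vals, -1, 1), window=WindowSpec(120, 80)))
    return tensors


class TestAnovaMap:
    def test_designed_effect_found_in_second_half(self):
        amap = anova_map(_toy_tensors(effect=0.3))
        first = amap.reject[:, :, :3].sum()
        second = amap.reject[:, :, 3:].sum()
        assert second > first
        assert second >= 0.8 * amap.reject.sum()

    def test_alpha_zero_empty(self):
        amap = anova_map(_toy_tensors(effect=0.5), alpha=0.0)
        assert amap.reject.sum() == 0

    def test_matches_scalar_op_cellwise(self):
        tensors = _toy_tensors(effect=0.2, n_pairs=8, n_win=4)
        amap = anova_map(tensors)
        # recompute one cell by hand through the scalar operation
        by_pair: dict = {}
        for t in tensors:
            by_pair.setdefault(t.pair_id, {})[t.hand] = t
        pids = sorted(by_pair)
        y = np.array([[by_pair[p]["off"].values[1, 0, 2],
                       by_pair[p]["on"].values[1, 0, 2]] for p in pids])
        groups = np.array([by_pair[p]["off"].relationship for p in pids])
        F, _, _ = mixed_anova_interaction(y, groups)
        assert amap.F[1, 0, 2] == pytest.approx(F, rel=1e-9)
        assert amap.df == (1, len(y) - 2)

    def test_sig_count_shape(self):
        amap = anova_map(_toy_tensors(effect=0.3))
        assert amap.sig_count.shape == (2, 2)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

class TestFdrBh:
    def test_step_up_hand_example(self):
        q, rej = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        np.testing.assert_allclose(q, 0.04)
        assert rej.all()

    def test_two_value_example(self):
        q, rej = fdr_bh(np.array([0.001, 0.8]), 0.05)
        np.testing.assert_allclose(q, [0.002, 0.8])
        assert list(rej) == [True, False]

    def test_all_ones(self):
        q, rej = fdr_bh(np.ones(5), 0.05)
        np.testing.assert_allclose(q, 1.0)
        assert not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]), 0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(3).uniform(size=200)
        q, rej = fdr_bh(p, 0.05)
        rej_sm, q_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        assert (rej == rej_sm).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_superset_of_bonferroni(self, ps):
        p = np.array(ps)
        q, rej = fdr_bh(p, 0.05)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # q monotone in p
        bonf = p * p.size <= 0.05
        assert (rej | ~bonf).all()  # BH rejects whatever Bonferroni rejects


# ---------------------------------------------------------------------------
# cubic trend
# ---------------------------------------------------------------------------

class TestCubicTrend:
    def test_reproduces_cubic_polynomial(self):
        t = np.arange(1.0, 11.0)
        spline = cubic_trend(t, t ** 3)
        dense = np.linspace(1, 10, 200)
        np.testing.assert_allclose(spline(dense), dense ** 3, atol=1e-8)

    def test_knot_exact(self):
        t = np.array([1.0, 2, 4, 7, 9])
        v = RNG.standard_normal(5)
        spline = cubic_trend(t, v)
        np.testing.assert_allclose(spline(t), v, atol=1e-12)

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            cubic_trend([1, 2, 3], [1, 2, 3])

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(ValueError):
            cubic_trend([1, 2, 2, 3], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# questionnaire scoring and reliability
# ---------------------------------------------------------------------------

class TestScoreScale:
    def test_sds_all_ones(self):
        assert score_scale([1] * 20, "SDS") == 50  # 10 forward + 10*(5-1)

    def test_sas_all_ones(self):
        assert score_scale([1] * 20, "SAS") == 35  # 15 forward + 5*(5-1)

    def test_reversed_item_direction(self):
        items = [1] * 20
        items[1] = 4  # item 2 is reverse-keyed: contributes 1 instead of 4
        assert score_scale(items, "SDS") == 47

    @pytest.mark.parametrize("v", [1, 2, 3, 4])
    def test_sds_uniform_symmetry(self, v):
        # 10 forward/10 reversed items: uniform responses always total 50
        assert score_scale([v] * 20, "SDS") == 50

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_scale([5] + [1] * 19, "SDS")

    def test_score_table_vectorizes(self):
        df = pd.DataFrame([[1] * 20, [2] * 20],
                          columns=[f"item_{i}" for i in range(1, 21)])
        assert list(score_table(df, "SAS")) == [35, score_scale([2] * 20,
                                                                "SAS")]


class TestReliability:
    def test_parallel_items_alpha_one(self):
        col = RNG.standard_normal(50)
        X = np.column_stack([col] * 5)
        alpha, omega = reliability(X)
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert omega > 0.99

    def test_independent_items_alpha_near_zero(self):
        X = np.random.default_rng(0).standard_normal((5000, 10))
        alpha, _ = reliability(X)
        assert abs(alpha) < 0.1

    def test_two_item_hand_formula(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 5.0], [5.0, 9.0]])
        var_items = X.var(axis=0, ddof=1).sum()
        var_total = X.sum(axis=1).var(ddof=1)
        expected = 2 * (1 - var_items / var_total)
        alpha, _ = reliability(X)
        assert alpha == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reliability(np.ones((10, 4)))


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

class TestPower:
    def test_reference_benchmark(self):
        # classic repeated-measures within-between interaction benchmark:
        # f=0.25, alpha=0.05, power=0.80, 2 groups x 2 measures, corr 0.5
        # -> total N = 34
        assert required_sample_size(0.25, power=0.80) == 34

    def test_monotone_in_effect_size(self):
        n1 = required_sample_size(0.1)
        n2 = required_sample_size(0.2)
        n4 = required_sample_size(0.4)
        assert n1 > n2 > n4

    def test_tiny_power_target_returns_minimum(self):
        assert required_sample_size(0.5, power=1e-6) == 4

    def test_power_increases_with_n(self):
        p = [interaction_power(n, 0.25) for n in (10, 20, 40, 80)]
        assert all(np.diff(p) > 0)

    def test_invalid_arguments(self):
        for bad in [dict(f=0), dict(f=0.2, alpha=0), dict(f=0.2, power=1.0)]:
            with pytest.raises(ValueError):
                required_sample_size(**bad)


def test_magnitude_table_averages_hand_blocks(lover_session):
    off, on = lover_session
    table, labels = magnitude_table([off, on])
    direct = (voltage_magnitude(off.male) + voltage_magnitude(on.male)) / 2
    np.testing.assert_allclose(table.loc[off.male.subject_id].values,
                               direct.values)
    assert labels[off.male.subject_id] == 1
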
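"""Classical and Bayesian ANOVA on crossing tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from fprt.crossing import DesignError
from fprt.inference import (
    _make_log_integrand,
    _orthonormal_contrasts,
    _pivot,
    _within_blocks,
    fixed_point_test,
    jzs_bf,
    mixed_anova,
    rm_anova,
)
from fprt.mixtures import normal
from fprt.simulation import SimulationConfig, generate


def brute_force_rm_f(values):
    """Independent sums-of-squares oracle by explicit loops."""
    values = np.asarray(values, dtype=float)
    s, k = values.shape
    grand = values.mean()
    ss_pair = sum(s * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (values[i, :].mean() - grand) ** 2 for i in range(s))
    ss_total = sum((values[i, j] - grand) ** 2 for i in range(s) for j in range(k))
    ss_err = ss_total - ss_pair - ss_subj
    return (ss_pair / (k - 1)) / (ss_err / ((k - 1) * (s - 1)))


class TestRmAnova:
    def test_constant_within_subject_gives_zero_f(self, crossing_table_factory):
        values = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))  # rows constant
        res = rm_anova(crossing_table_factory(values))
        assert res.F == pytest.approx(0.0, abs=1e-24)
        assert res.p == pytest.approx(1.0)

    def test_degrees_of_freedom(self, crossing_table_factory, rng):
        res = rm_anova(crossing_table_factory(rng.normal(size=(12, 4))))
        assert (res.df1, res.df2) == (3.0, 33.0)

    @given(
        values=arrays(
            np.float64,
            shape=st.tuples(st.integers(3, 8), st.integers(3, 5)),
            elements=st.floats(-5, 5, allow_nan=False),
        )
    )
    @settings(max_examples=40)
    def test_matches_brute_force_sums_of_squares(self, crossing_table_factory, values):
        s, k = values.shape
        grand = values.mean()
        resid = (values - values.mean(axis=1, keepdims=True)
                 - values.mean(axis=0, keepdims=True) + grand)
        if (resid**2).sum() < 1e-12 * max(1.0, (values - grand).var()):
            return  # (near-)zero error variance; F undefined
        res = rm_anova(crossing_table_factory(values))
        assert res.F == pytest.approx(brute_force_rm_f(values), abs=1e-10, rel=1e-10)

    def test_null_p_values_are_uniform(self, crossing_table_factory, rng):
        """Type-I calibration: i.i.d. normal crossings give uniform p."""
        pvals = [rm_anova(crossing_table_factory(rng.normal(size=(8, 3)))).p for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_incomplete_table_rejected(self, crossing_table_factory):
        table = crossing_table_factory(np.ones((4, 3)) + np.arange(12).reshape(4, 3))
        table = table.drop(index=0)
        with pytest.raises(ValueError):
            rm_anova(table)

    def test_agrees_with_pingouin(self, crossing_table_factory, rng):
        pingouin = pytest.importorskip("pingouin")
        table = crossing_table_factory(rng.normal(size=(9, 3)))
        res = rm_anova(table)
        ref = pingouin.rm_anova(data=table, dv="crossing", within="pair", subject="subject")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)


class TestMixedAnova:
    def _groups(self, table, n_per_group):
        subjects = sorted(table["subject"].unique())
        return {s: ("A" if i < n_per_group else "B") for i, s in enumerate(subjects)}

    def test_df_shapes_for_two_groups_of_ten(self, crossing_table_factory, rng):
        # 20 subjects, 2 groups, 3 pairs: between df (1, 18), within df (2, 36)
        table = crossing_table_factory(rng.normal(size=(20, 3)))
        res = mixed_anova(table, self._groups(table, 10))
        assert (res["between"].df1, res["between"].df2) == (1.0, 18.0)
        assert (res["within"].df1, res["within"].df2) == (2.0, 36.0)
        assert (res["interaction"].df1, res["interaction"].df2) == (2.0, 36.0)

    def test_single_group_reduces_to_rm_anova(self, crossing_table_factory, rng):
        table = crossing_table_factory(rng.normal(size=(8, 3)))
        groups = {s: "only" for s in table["subject"].unique()}
        res = mixed_anova(table, groups)
        base = rm_anova(table)
        assert res["within"] == base

    def test_between_effect_p_uniform_under_null(self, crossing_table_factory, rng):
        pvals = []
        for _ in range(300):
            table = crossing_table_factory(rng.normal(size=(10, 3)))
            res = mixed_anova(table, self._groups(table, 5))
            pvals.append(res["between"].p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_unequal_group_sizes_rejected(self, crossing_table_factory, rng):
        table = crossing_table_factory(rng.normal(size=(9, 3)))
        with pytest.raises(ValueError):
            mixed_anova(table, self._groups(table, 2))

    def test_agrees_with_pingouin(self, crossing_table_factory, rng):
        pingouin = pytest.importorskip("pingouin")
        table = crossing_table_factory(rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)))
        groups = self._groups(table, 6)
        table2 = table.assign(group=table["subject"].map(groups))
        res = mixed_anova(table, groups)
        ref = pingouin.mixed_anova(data=table2, dv="crossing", within="pair",
                                   subject="subject", between="group")
        ref = ref.set_index("Source")
        assert res["between"].F == pytest.approx(float(ref.loc["group", "F"]), rel=1e-9)
        assert res["within"].F == pytest.approx(float(ref.loc["pair", "F"]), rel=1e-9)
        assert res["interaction"].F == pytest.approx(float(ref.loc["Interaction", "F"]), rel=1e-9)


def mc_bf01(table, n_draws=10**6, seed=7, r_fixed=0.5, r_random=1.0):
    """Monte-Carlo prior-integration oracle for the within-design BF01.

    Draws the g's from their scaled inverse-chi-square priors and averages
    the closed-form conditional marginal-likelihood ratio, independently for
    the subject-only and the pair+subject model.
    """
    from scipy.special import gammaln, logsumexp

    wide = _pivot(table)
    y, bp, bs = _within_blocks(wide, r_fixed, r_random)

    def model_evidence(blocks, seed):
        rng = np.random.default_rng(seed)
        logf = _make_log_integrand(y, blocks)
        U = np.column_stack([
            np.log(stats.invgamma(0.5, scale=b.r**2 / 2).rvs(n_draws, random_state=rng))
            for b in blocks
        ])
        a = 0.5
        lp = sum(
            a * np.log(b.r**2 / 2) - gammaln(a) - a * U[:, i]
            - (b.r**2 / 2) * np.exp(-U[:, i])
            for i, b in enumerate(blocks)
        )
        return logsumexp(logf(U) - lp) - np.log(n_draws)

    return float(np.exp(model_evidence([bs], seed) - model_evidence([bp, bs], seed + 1)))


class TestJzsBf:
    def test_bf01_bf10_product_is_one(self, crossing_table_factory, rng):
        table = crossing_table_factory(rng.normal(size=(10, 3)))
        bf01 = jzs_bf(table)["pair"]
        assert bf01 > 0
        assert bf01 * (1.0 / bf01) == 1.0

    def test_quadrature_matches_monte_carlo_oracle(self, crossing_table_factory, rng):
        values = 0.75 + rng.normal(0, 0.3, (10, 1)) + rng.normal(0, 0.2, (10, 3))
        table = crossing_table_factory(values)
        bf = jzs_bf(table)["pair"]
        oracle = mc_bf01(table)
        assert bf == pytest.approx(oracle, rel=0.02)

    def test_null_data_mostly_favors_the_null(self, crossing_table_factory, rng):
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            table = crossing_table_factory(rng.normal(0, 0.2, (50, 3)) + rng.normal(size=(50, 1)))
            if jzs_bf(table)["pair"] > 1:
                wins += 1
        assert wins / n_rep >= 0.7

    def test_strong_pair_effects_are_detected(self, crossing_table_factory, rng):
        effect = np.array([-1.0, 0.0, 1.0])
        hits = 0
        for _ in range(20):
            table = crossing_table_factory(effect[None, :] + rng.normal(0, 1, (20, 3)))
            if jzs_bf(table)["pair"] < 1:
                hits += 1
        assert hits >= 19

    def test_evidence_for_the_null_grows_with_sample_size(self, crossing_table_factory, rng):
        logs = {}
        for s in (10, 100):
            vals = [
                np.log(jzs_bf(crossing_table_factory(rng.normal(size=(s, 3))))["pair"])
                for _ in range(60)
            ]
            logs[s] = np.mean(vals)
        assert logs[100] > logs[10]

    def test_contrasts_are_orthonormal(self):
        for k in (2, 3, 5, 8):
            C = _orthonormal_contrasts(k)
            np.testing.assert_allclose(C.T @ C, np.eye(k - 1), atol=1e-12)
            np.testing.assert_allclose(C.sum(axis=0), 0.0, atol=1e-12)

    def test_mixed_design_interaction_bf_consistency(self, crossing_table_factory, rng):
        # no real effects: every per-effect BF01 should exceed 1 more often than not,
        # and reciprocals must multiply to 1
        table = crossing_table_factory(rng.normal(0, 0.3, (10, 3)) + rng.normal(size=(10, 1)))
        groups = {s: ("A" if i < 5 else "B") for i, s in enumerate(sorted(table["subject"].unique()))}
        bf = jzs_bf(table, between=groups)
        assert set(bf) == {"between", "within", "interaction"}
        for v in bf.values():
            assert v > 0


class TestFixedPointTest:
    def _sim_data(self, rng, subjects=8, trials=120):
        cfg = SimulationConfig(
            scenario="mixture", first=normal(0, 1), second=normal(1.5, 1),
            proportions=(0.1, 0.5, 0.9), subjects=subjects, trials=trials,
            bandwidth=1.0, label="t",
        )
        return generate(cfg, rng)

    def test_end_to_end_pipeline_returns_consistent_result(self, rng):
        data = self._sim_data(rng)
        res = fixed_point_test(data, h=1.0, seed=1)
        assert res.bf01["pair"] * res.bf10["pair"] == pytest.approx(1.0, rel=1e-12)
        assert res.anova["pair"].df1 == 2.0
        assert 0.0 <= res.anova["pair"].p <= 1.0
        assert res.settings["h"] == 1.0
        assert res.settings["seed"] == 1
        assert len(res.settings["condition_order"]) == 3

    def test_two_condition_design_rejected(self, rng):
        frames = []
        for p in (0.2, 0.8):
            frames.append(pd.DataFrame({
                "subject": "s1", "condition": f"p{p}", "rt": rng.normal(p, 1, 100)}))
        data = pd.concat(frames, ignore_index=True)
        from fprt.io import RTDataset

        with pytest.raises(DesignError):
            fixed_point_test(RTDataset(frame=data, unit="arbitrary"), h=1.0)

    def test_determinism_given_seed(self):
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        r1 = fixed_point_test(self._sim_data(rng1), h=1.0)
        r2 = fixed_point_test(self._sim_data(rng2), h=1.0)
        assert r1.bf01["pair"] == r2.bf01["pair"]
        assert r1.anova["pair"] == r2.anova["pair"]

    def test_between_factor_switches_to_mixed_design(self, rng):
        data = self._sim_data(rng, subjects=8)
        frame = data.frame.copy()
        subs = sorted(frame["subject"].unique())
        frame["block"] = frame["subject"].map({s: ("short" if i < 4 else "long") for i, s in enumerate(subs)})
        from fprt.io import RTDataset

        res = fixed_point_test(RTDataset(frame=frame, unit="arbitrary"), h=1.0, between="block")
        assert set(res.anova) == {"between", "within", "interaction"}
        assert set(res.bf01) == {"between", "within", "interaction"}
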
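"""Within-subject inference: means, rmANOVA, planned tests, Bayes factors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from reachgrasp.errors import InsufficientDataError
from reachgrasp.stats import (
    DEFAULT_COMPARISONS,
    condition_means,
    eta_p2_from_f,
    jzs_bf_anova,
    planned_ttests,
    rm_anova,
    round_half_up,
    summarize_means,
    _design_blocks,
    _cell_array,
    _log_marginal_ratios,
    _log_mean_and_relse,
)
from reachgrasp.stimuli import CELLS, PRONOUNS, VERB_TYPES

from .conftest import EXP1_TABLE
from .oracles import oracle_rm_anova


def _means_frame(y, parameter="pct_t_vpeak"):
    """(n, 3, 2) array -> long means table."""
    rows = []
    for s in range(y.shape[0]):
        for i, p in enumerate(PRONOUNS):
            for j, v in enumerate(VERB_TYPES):
                rows.append({"subject_id": f"s{s:02d}", "pronoun": p,
                             "verb_type": v, parameter: y[s, i, j]})
    return pd.DataFrame(rows)


def _simulated_means(rng, n=12, effects=None, subject_sd=1.5, cell_sd=2.0):
    y = np.empty((n, 3, 2))
    for s in range(n):
        off = rng.normal(0, subject_sd)
        for i, p in enumerate(PRONOUNS):
            for j, v in enumerate(VERB_TYPES):
                base = effects[(p, v)] if effects else 49.77
                y[s, i, j] = base + off + rng.normal(0, cell_sd)
    return y


class TestConditionMeans:
    def test_single_trial_per_cell_identity(self):
        rows = []
        for i, (p, v) in enumerate(CELLS):
            rows.append({"subject_id": "s01", "pronoun": p, "verb_type": v,
                         "is_catch": False, "valid": True,
                         "pct_t_vpeak": 40.0 + i})
        means, report = condition_means(pd.DataFrame(rows))
        assert report.empty
        assert sorted(means["pct_t_vpeak"]) == [40.0 + i for i in range(6)]

    def test_permutation_invariance(self, exp1_noiseless_params):
        params = exp1_noiseless_params
        shuffled = params.sample(frac=1.0, random_state=1)
        m1, _ = condition_means(params)
        m2, _ = condition_means(shuffled)
        pd.testing.assert_frame_equal(
            m1.reset_index(drop=True), m2.reset_index(drop=True)
        )

    def test_subject_with_empty_cell_dropped_with_report(self):
        rows = []
        for subject in ("s01", "s02"):
            for p, v in CELLS:
                if subject == "s02" and (p, v) == ("HE", "IV"):
                    continue
                rows.append({"subject_id": subject, "pronoun": p, "verb_type": v,
                             "is_catch": False, "valid": True, "pct_t_vpeak": 50.0})
        means, report = condition_means(pd.DataFrame(rows))
        assert set(means.subject_id) == {"s01"}
        assert list(report.subject_id) == ["s02"]
        assert "HE_IV" in report.missing_cells.iloc[0]


class TestRmAnova:
    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        for n, df2 in ((12, 22), (13, 24)):
            res = rm_anova(_means_frame(_simulated_means(rng, n)), "pct_t_vpeak")
            interaction = [r for r in res if r.effect == "verb_type:pronoun"][0]
            assert (interaction.df1, interaction.df2) == (2, df2)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 6))
            y = _simulated_means(rng, n)
            res = {r.effect: r for r in rm_anova(_means_frame(y), "pct_t_vpeak")}
            oracle = oracle_rm_anova(np.transpose(y, (0, 2, 1)))  # A=verb, B=pronoun
            for effect, key in (("verb_type", "A"), ("pronoun", "B"),
                                ("verb_type:pronoun", "AB")):
                F, df1, df2, mse, p, eta = oracle[key]
                r = res[effect]
                assert r.F == pytest.approx(F, abs=1e-10)
                assert (r.df1, r.df2) == (df1, df2)
                assert r.MSE == pytest.approx(mse, abs=1e-10)
                assert r.p == pytest.approx(p, abs=1e-10)
                assert r.eta_p2 == pytest.approx(eta, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        frame = _means_frame(_simulated_means(rng, 10))
        res = {r.effect: r for r in rm_anova(frame, "pct_t_vpeak")}
        table = AnovaRM(frame.rename(columns={"subject_id": "subj"}),
                        "pct_t_vpeak", "subj",
                        within=["pronoun", "verb_type"]).fit().anova_table
        assert res["pronoun"].F == pytest.approx(table.loc["pronoun", "F Value"],
                                                 rel=1e-9)
        assert res["verb_type"].F == pytest.approx(table.loc["verb_type", "F Value"],
                                                   rel=1e-9)
        assert res["verb_type:pronoun"].F == pytest.approx(
            table.loc["pronoun:verb_type", "F Value"], rel=1e-9)

    def test_eta_identity(self, rng):
        res = rm_anova(_means_frame(_simulated_means(rng, 8)), "pct_t_vpeak")
        for r in res:
            assert r.eta_p2 == pytest.approx(eta_p2_from_f(r.F, r.df1, r.df2),
                                             abs=1e-12)

    def test_insufficient_subjects(self):
        frame = _means_frame(np.zeros((1, 3, 2)))
        with pytest.raises(InsufficientDataError):
            rm_anova(frame, "pct_t_vpeak")

    def test_power_at_calibrated_effect_size(self):
        # cell-level SD 3.42 pp makes the expected interaction eta_p^2 ~ 0.4;
        # the interaction should then be detected in > 80% of experiments
        rng = np.random.default_rng(2026)
        effects = {cell: EXP1_TABLE[cell][1] for cell in CELLS}
        hits = 0
        for _ in range(500):
            y = _simulated_means(rng, 12, effects=effects, cell_sd=3.42)
            res = rm_anova(_means_frame(y), "pct_t_vpeak")
            inter = [r for r in res if r.effect == "verb_type:pronoun"][0]
            hits += inter.p < 0.05
        assert hits / 500 > 0.80


class TestPlannedTTests:
    def test_antisymmetry(self, rng):
        frame = _means_frame(_simulated_means(rng, 12))
        fwd = planned_ttests(frame, "pct_t_vpeak",
                             [(("YOU", "AV"), ("YOU", "IV"), "greater")])[0]
        rev = planned_ttests(frame, "pct_t_vpeak",
                             [(("YOU", "IV"), ("YOU", "AV"), "greater")])[0]
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)

    def test_all_zero_differences(self):
        frame = _means_frame(np.tile(np.arange(6.0).reshape(3, 2), (5, 1, 1)))
        res = planned_ttests(frame, "pct_t_vpeak",
                             [(("I", "AV"), ("I", "AV"), "greater")])[0]
        assert res.degenerate and res.t == 0.0 and res.p == pytest.approx(0.5)

    def test_one_sided_p_example(self):
        # t = 0.56 on 11 df, one-sided -> p ~ 0.29
        assert float(sps.t.sf(0.56, 11)) == pytest.approx(0.29, abs=0.01)
        rng = np.random.default_rng(0)
        for _ in range(200):
            y = _simulated_means(rng, 12)
            res = planned_ttests(_means_frame(y), "pct_t_vpeak",
                                 [(("I", "AV"), ("I", "IV"), "greater")])[0]
            if abs(res.t - 0.56) < 0.02:
                assert res.p == pytest.approx(float(sps.t.sf(res.t, 11)), abs=1e-12)
                break
        assert res.df == 11

    def test_alpha_corrections(self, rng):
        frame = _means_frame(_simulated_means(rng, 12))
        bonf = planned_ttests(frame, "pct_t_vpeak", correction="bonferroni")
        paper = planned_ttests(frame, "pct_t_vpeak", correction="paper")
        assert bonf[0].alpha_corrected == pytest.approx(0.05 / 3)
        assert paper[0].alpha_corrected == 0.01
        assert len(bonf) == len(DEFAULT_COMPARISONS) == 3


class TestJzsBayesFactor:
    def test_reciprocal_identity_and_reproducibility(self, rng):
        frame = _means_frame(_simulated_means(rng, 12))
        a = jzs_bf_anova(frame, "pct_t_vpeak", n_mc_samples=4000, seed=7)
        b = jzs_bf_anova(frame, "pct_t_vpeak", n_mc_samples=4000, seed=7)
        assert a.BF10 == b.BF10
        assert a.BF10 * a.BF01 == pytest.approx(1.0, rel=1e-12)
        assert a.BF10 > 0 and a.mc_error > 0

    def test_mc_error_shrinks_with_samples(self, rng):
        frame = _means_frame(_simulated_means(rng, 12))
        coarse = jzs_bf_anova(frame, "pct_t_vpeak", n_mc_samples=10_000, seed=1)
        fine = jzs_bf_anova(frame, "pct_t_vpeak", n_mc_samples=160_000, seed=2)
        assert fine.mc_error < coarse.mc_error / 2

    def test_single_block_matches_quadrature(self, rng):
        y = _simulated_means(rng, 10, effects={c: EXP1_TABLE[c][1] for c in CELLS})
        frame = _means_frame(y)
        y_arr, _ = _cell_array(frame, "pct_t_vpeak")
        yvec, fixed, _ = _design_blocks(y_arr)
        X = fixed[0]  # verb block only
        yc = yvec - yvec.mean()
        Xc = X - X.mean(axis=0)
        yty = float(yc @ yc)
        XtX = Xc.T @ Xc
        Xty = Xc.T @ yc
        N = yvec.size
        r = 0.5

        def ratio(g):
            A = XtX + np.eye(1) / g
            R = yty - Xty @ np.linalg.solve(A, Xty)
            return math.exp(-0.5 * (math.log(g) + np.linalg.slogdet(A)[1])
                            - 0.5 * (N - 1) * (math.log(R) - math.log(yty)))

        prior = sps.invgamma(0.5, scale=r * r / 2)
        quad, _ = integrate.quad(lambda g: ratio(g) * prior.pdf(g), 0, np.inf,
                                 limit=200)
        lr = _log_marginal_ratios(yvec, [X], [r],
                                  np.random.default_rng(3), 200_000)
        log_mean, rel_se = _log_mean_and_relse(lr)
        assert math.exp(log_mean) == pytest.approx(quad, rel=max(4 * rel_se, 5e-3))

    def test_direction_under_null_and_effect(self):
        rng = np.random.default_rng(5)
        effects = {c: EXP1_TABLE[c][1] for c in CELLS}
        null_bfs, eff_bfs = [], []
        for i in range(25):
            null_bfs.append(jzs_bf_anova(
                _means_frame(_simulated_means(rng, 12, cell_sd=3.42)),
                "pct_t_vpeak", n_mc_samples=4000, seed=i).BF10)
            eff_bfs.append(jzs_bf_anova(
                _means_frame(_simulated_means(rng, 12, effects=effects, cell_sd=3.42)),
                "pct_t_vpeak", n_mc_samples=4000, seed=i).BF10)
        assert np.median(null_bfs) < 1.0
        assert np.median(eff_bfs) > 1.0


class TestReporting:
    def test_half_up_rounding(self):
        assert round_half_up(47.38) == 47.4
        assert round_half_up(47.35) == 47.4
        assert round_half_up(47.34) == 47.3

    def test_means_table_layout(self, exp1_noiseless_params):
        means, _ = condition_means(exp1_noiseless_params)
        table = summarize_means(means)
        assert list(table.columns) == [
            "parameter", "I_Action", "You_Action", "He_Action",
            "I_Interaction", "You_Interaction", "He_Interaction",
        ]
        row = table[table.parameter == "pct_t_vpeak"].iloc[0]
        assert row["You_Action"] == pytest.approx(52.2, abs=0.5)

    def test_empty_means_headers_only(self):
        empty = pd.DataFrame(columns=["subject_id", "pronoun", "verb_type",
                                      "pct_t_vpeak"])
        table = summarize_means(empty)
        assert list(table.parameter) == ["pct_t_vpeak"]
        assert table.drop(columns="parameter").isna().all().all()
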
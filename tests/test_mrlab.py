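import numpy as np
import pandas as pd
import pytest

from _oracles import brute_clump, egger_closed_form, ivw_closed_form
from conftest import make_genotypes

from onsetprs.exceptions import InsufficientInstrumentsError, ValidationError
from onsetprs.mrlab import (MRDataset, MRResult, TwoSampleMR, harmonize,
                            harmonize_tables, heterogeneity_q,
                            high_confidence_filter, ivw, mr_egger,
                            select_instruments, weighted_median)
from onsetprs.prslab import ld_r2
from onsetprs.syndata import MRSimConfig, simulate_mr_sumstats


def dataset(beta_exp, se_exp, beta_out, se_out):
    k = len(beta_exp)
    return MRDataset(pd.DataFrame({
        "variant_id": [f"iv{i}" for i in range(k)],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
    }))


def sumrow(variant_id="iv0", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01):
    return pd.Series({"variant_id": variant_id, "ea": ea, "oa": oa,
                      "eaf": eaf, "beta": beta, "se": se})


class TestSelectInstruments:
    def test_none_significant_gives_empty(self):
        g = make_genotypes(np.random.default_rng(0)
                           .binomial(2, 0.4, (50, 3)).astype(float))
        stats = pd.DataFrame({
            "variant_id": g.variants["variant_id"],
            "chr": g.variants["chr"], "pos": g.variants["pos"],
            "p": [1e-6, 1e-7, 1e-5]})
        assert select_instruments(stats, g) == []

    def test_correlated_pair_keeps_lower_p(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0.0]])
        g = make_genotypes(d)
        stats = pd.DataFrame({
            "variant_id": ["v0", "v1"], "chr": [1, 1],
            "pos": [1000, 2000], "p": [1e-9, 1e-12]})
        assert select_instruments(stats, g) == ["v1"]

    def test_matches_bruteforce_oracle_on_panel(self):
        rng = np.random.default_rng(5)
        n, m = 300, 12
        base = rng.binomial(1, 0.5, (n, 4)).astype(float)
        cols = [np.clip(base[:, j % 4] + rng.binomial(1, 0.15, n)
                        + rng.binomial(1, 0.35, n), 0, 2) for j in range(m)]
        g = make_genotypes(np.column_stack(cols))
        stats = pd.DataFrame({
            "variant_id": g.variants["variant_id"],
            "chr": g.variants["chr"], "pos": g.variants["pos"],
            "p": 10.0 ** -rng.uniform(6, 20, m)})
        got = select_instruments(stats, g, p_max=5e-8, r2_max=0.3,
                                 window_kb=10_000)
        expected = [c[0] for c in brute_clump(
            stats.to_dict("records"), lambda a, b: ld_r2(g, a, b),
            5e-8, 0.3, 10_000_000)]
        assert got == expected


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        h = harmonize(sumrow(), sumrow(beta=0.05))
        assert h["beta_out"] == 0.05 and h["action"] == "kept"

    def test_swapped_alleles_flip_sign(self):
        h = harmonize(sumrow(), sumrow(ea="G", oa="A", beta=0.05, eaf=0.7))
        assert h["beta_out"] == -0.05
        assert h["eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_resolved(self):
        h = harmonize(sumrow(), sumrow(ea="T", oa="C", beta=0.05))
        assert h is not None and h["beta_out"] == 0.05

    def test_palindromic_near_half_dropped(self):
        exp = sumrow(ea="A", oa="T", eaf=0.50)
        out = sumrow(ea="A", oa="T", eaf=0.50, beta=0.05)
        assert harmonize(exp, out) is None

    def test_palindromic_clear_frequency_aligned(self):
        exp = sumrow(ea="A", oa="T", eaf=0.10)
        out = sumrow(ea="A", oa="T", eaf=0.88, beta=0.05)
        h = harmonize(exp, out)
        assert h["beta_out"] == -0.05  # opposite frequency side: flipped

    def test_irreconcilable_dropped(self):
        assert harmonize(sumrow(), sumrow(ea="C", oa="A")) is None


class TestIVW:
    def test_single_iv_equals_wald_ratio(self):
        d = dataset([0.2], [0.01], [0.08], [0.02])
        est, se, p, per = ivw(d)
        assert est == pytest.approx(0.08 / 0.2, rel=1e-12)

    def test_noiseless_shared_ratio(self):
        be = np.array([0.1, 0.2, 0.05])
        d = dataset(be, [0.01] * 3, 0.5 * be, [0.01] * 3)
        est, se, p, _ = ivw(d)
        q, df, qp = heterogeneity_q(d)
        assert est == pytest.approx(0.5, rel=1e-12)
        assert q == pytest.approx(0.0, abs=1e-20)

    def test_matches_closed_form_oracle(self):
        be = [0.12, -0.25, 0.08]
        se_e = [0.01, 0.02, 0.015]
        bo = [0.03, -0.11, 0.05]
        so = [0.02, 0.03, 0.025]
        est, se, p, _ = ivw(dataset(be, se_e, bo, so))
        oest, ose = ivw_closed_form(be, se_e, bo, so)
        assert est == pytest.approx(oest, rel=1e-12)
        assert se == pytest.approx(ose, rel=1e-12)

    def test_zero_exposure_beta_dropped(self):
        d = dataset([0.0, 0.2], [0.01, 0.01], [0.05, 0.08], [0.02, 0.02])
        est, _, _, per = ivw(d)
        assert len(per) == 1
        assert est == pytest.approx(0.4)

    def test_rescaling_exposure_rescales_estimate(self):
        be = np.array([0.12, -0.25, 0.08])
        d1 = dataset(be, [0.01] * 3, [0.03, -0.11, 0.05], [0.02] * 3)
        d2 = dataset(3 * be, [0.03] * 3, [0.03, -0.11, 0.05], [0.02] * 3)
        assert ivw(d2)[0] == pytest.approx(ivw(d1)[0] / 3, rel=1e-12)
        # Q is invariant under the rescaling
        assert heterogeneity_q(d2)[0] == pytest.approx(
            heterogeneity_q(d1)[0], rel=1e-12)


class TestWeightedMedian:
    def test_odd_equal_weights_is_sample_median(self):
        d = dataset([0.1, 0.1, 0.1], [0.01] * 3,
                    [0.01, 0.05, 0.02], [0.01] * 3)
        est, _, _ = weighted_median(d, n_boot=50, seed=0)
        assert est == pytest.approx(0.2, rel=1e-12)  # median of 0.1,0.5,0.2

    def test_breakdown_robustness_to_one_outlier(self):
        rng = np.random.default_rng(3)
        be = rng.uniform(0.05, 0.15, 10)
        bo = 0.3 * be
        bo[0] = 5.0 * be[0]  # wildly pleiotropic instrument
        d = dataset(be, [0.005] * 10, bo, [0.005] * 10)
        est, _, _ = weighted_median(d, n_boot=200, seed=1)
        assert abs(est - 0.3) < 0.05

    def test_seeded_bootstrap_deterministic(self):
        d = dataset([0.1, 0.12, 0.2, 0.15], [0.01] * 4,
                    [0.03, 0.05, 0.07, 0.04], [0.02] * 4)
        a = weighted_median(d, n_boot=100, seed=7)
        b = weighted_median(d, n_boot=100, seed=7)
        assert a == b

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(dataset([0.1, 0.2], [0.01] * 2,
                                    [0.02, 0.05], [0.01] * 2))


class TestEgger:
    def test_line_through_origin(self):
        be = np.array([0.05, 0.1, 0.2, 0.15])
        d = dataset(be, [0.01] * 4, 0.7 * be, [0.01] * 4)
        res = mr_egger(d)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["slope"] == pytest.approx(0.7, rel=1e-12)

    def test_matches_closed_form_oracle(self):
        be = [0.12, -0.25, 0.08, 0.3]
        so = [0.02, 0.03, 0.025, 0.01]
        bo = [0.05, -0.04, 0.02, 0.12]
        res = mr_egger(dataset(be, [0.01] * 4, bo, so))
        oi, os_, oise, osse = egger_closed_form(be, [0.01] * 4, bo, so)
        assert res["intercept"] == pytest.approx(oi, rel=1e-10)
        assert res["slope"] == pytest.approx(os_, rel=1e-10)
        assert res["intercept_se"] == pytest.approx(oise, rel=1e-8)
        assert res["slope_se"] == pytest.approx(osse, rel=1e-8)

    def test_recovers_pleiotropy_intercept_over_seeds(self):
        # every instrument invalid with directional pleiotropy 0.1: the
        # Egger intercept is consistent for it (mean over seeds)
        ests = []
        for seed in range(50):
            cfg = MRSimConfig(n_instruments=20, true_causal_effect=0.2,
                              pleiotropy_intercept=0.1, invalid_fraction=1.0,
                              exposure_n=10**6, outcome_n=10**6, seed=seed)
            e, o = simulate_mr_sumstats(cfg)
            d = harmonize_tables(e, o)
            ests.append(mr_egger(d)["intercept"])
        assert np.mean(ests) == pytest.approx(0.1, abs=0.01)


class TestHeterogeneityQ:
    def test_three_iv_hand_computed(self):
        be = np.array([0.1, 0.2, 0.4])
        bo = np.array([0.05, 0.04, 0.08])
        so = np.array([0.02, 0.02, 0.04])
        r = bo / be
        s = so / np.abs(be)
        w = 1 / s ** 2
        pooled = (w * r).sum() / w.sum()
        q_hand = (w * (r - pooled) ** 2).sum()
        q, df, p = heterogeneity_q(dataset(be, [0.01] * 3, bo, so))
        assert q == pytest.approx(q_hand, rel=1e-12)
        assert df == 2

    def test_null_q_has_mean_df(self):
        # under valid instruments and large samples Q ~ chi2(k-1)
        qs = []
        for seed in range(120):
            cfg = MRSimConfig(n_instruments=8, true_causal_effect=0.2,
                              exposure_n=10**6, outcome_n=10**6, seed=seed)
            e, o = simulate_mr_sumstats(cfg)
            d = harmonize_tables(e, o)
            qs.append(heterogeneity_q(d)[0])
        # tolerance from a pilot of the chi-square mean at these reps
        assert np.mean(qs) == pytest.approx(7.0, abs=1.0)


class TestHighConfidenceFilter:
    def result(self, ivw_p=0.01, wm_p=0.03, ivw_b=0.2, wm_b=0.25,
               q_p=0.2, egger_p=0.5):
        return MRResult(
            exposure_id="x", outcome_id="y", n_iv=5,
            ivw=(ivw_b, 0.05, ivw_p), weighted_median=(wm_b, 0.06, wm_p),
            egger={"slope": 0.2, "slope_se": 0.05, "slope_p": 0.01,
                   "intercept": 0.0, "intercept_se": 0.01,
                   "intercept_p": egger_p, "df": 3},
            q=(2.0, 4, q_p))

    def test_all_criteria_met(self):
        flag, reasons = high_confidence_filter(self.result())
        assert flag and reasons == []

    def test_directional_discordance(self):
        flag, reasons = high_confidence_filter(self.result(wm_b=-0.1))
        assert not flag and "directional discordance" in reasons

    def test_heterogeneity_boundary_is_ge(self):
        flag, reasons = high_confidence_filter(self.result(q_p=0.049))
        assert not flag and "heterogeneity" in reasons
        flag, _ = high_confidence_filter(self.result(q_p=0.05))
        assert flag  # exactly 0.05 passes the >= convention

    def test_egger_boundary_is_ge(self):
        flag, reasons = high_confidence_filter(self.result(egger_p=0.0499))
        assert not flag and "pleiotropy" in reasons
        assert high_confidence_filter(self.result(egger_p=0.05))[0]

    def test_significance_boundary_is_strict(self):
        flag, reasons = high_confidence_filter(self.result(ivw_p=0.05))
        assert not flag and "ivw not significant" in reasons


class TestTwoSampleMRModel:
    def test_fit_recovers_effect_and_summary(self):
        cfg = MRSimConfig(n_instruments=30, true_causal_effect=0.3,
                          invalid_fraction=0.0, seed=5)
        e, o = simulate_mr_sumstats(cfg)
        res = TwoSampleMR(harmonize_tables(e, o)).fit(seed=1)
        assert res.ivw[0] == pytest.approx(0.3, abs=0.03)
        assert res.weighted_median[0] == pytest.approx(0.3, abs=0.05)
        assert res.high_confidence
        assert "IVW" in res.summary()

    def test_single_iv_refusals(self):
        d = dataset([0.1], [0.01], [0.03], [0.02])
        assert ivw(d)[0] == pytest.approx(0.3)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(d)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(d)
        with pytest.raises(InsufficientInstrumentsError):
            heterogeneity_q(d)
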
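"""MR estimators, pleiotropy screen, colocalization, fine-mapping, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pgnet import causal
from tests.conftest import make_sumstats


def make_instruments(beta_exp, se_exp, beta_out, se_out):
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(beta_exp))],
            "beta_exposure": beta_exp,
            "se_exposure": se_exp,
            "beta_outcome": beta_out,
            "se_outcome": se_out,
        }
    )


class TestClump:
    def _R(self, ids, mat):
        return pd.DataFrame(mat, index=ids, columns=ids)

    def test_correlated_pair_keeps_lower_p(self):
        recs = pd.DataFrame({"variant_id": ["v1", "v2"], "p": [1e-8, 1e-4]})
        R = self._R(["v1", "v2"], [[1, 0.7], [0.7, 1]])
        out = causal.ld_clump(recs, R, r2_max=0.001)
        assert list(out["variant_id"]) == ["v1"]

    def test_uncorrelated_all_kept(self):
        recs = pd.DataFrame({"variant_id": ["v1", "v2", "v3"], "p": [1e-8, 1e-6, 1e-4]})
        R = self._R(["v1", "v2", "v3"], np.eye(3))
        out = causal.ld_clump(recs, R)
        assert set(out["variant_id"]) == {"v1", "v2", "v3"}

    def test_chain_hand_trace(self):
        """r2(v1,v2)=0.81, r2(v2,v3)=0.81, r2(v1,v3)=0 -> keep {v1, v3}."""
        recs = pd.DataFrame({"variant_id": ["v1", "v2", "v3"],
                             "p": [1e-9, 1e-7, 1e-5]})
        R = self._R(["v1", "v2", "v3"],
                    [[1, 0.9, 0], [0.9, 1, 0.9], [0, 0.9, 1]])
        out = causal.ld_clump(recs, R, r2_max=0.5)
        assert set(out["variant_id"]) == {"v1", "v3"}

    def test_variant_missing_from_R_dropped(self):
        recs = pd.DataFrame({"variant_id": ["v1", "vX"], "p": [1e-8, 1e-9]})
        R = self._R(["v1"], [[1.0]])
        out = causal.ld_clump(recs, R)
        assert list(out["variant_id"]) == ["v1"]


class TestHarmonize:
    def test_swapped_alleles_flip(self):
        exp = make_sumstats(["v1"], [0.3], [0.05], effect_allele="A", other_allele="G")
        out = make_sumstats(["v1"], [-0.3], [0.05], effect_allele="G", other_allele="A")
        h = causal.harmonize(exp, out)
        assert h["beta_outcome"].iloc[0] == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        exp = make_sumstats(["v1"], [0.3], [0.05], eaf=[0.5],
                            effect_allele="A", other_allele="T")
        out = make_sumstats(["v1"], [0.3], [0.05], eaf=[0.5],
                            effect_allele="A", other_allele="T")
        assert len(causal.harmonize(exp, out)) == 0

    def test_irreconcilable_pair_dropped(self):
        exp = make_sumstats(["v1"], [0.3], [0.05], effect_allele="A", other_allele="G")
        out = make_sumstats(["v1"], [0.3], [0.05], effect_allele="A", other_allele="C")
        assert len(causal.harmonize(exp, out)) == 0


class TestWald:
    def test_algebra(self):
        inst = make_instruments([0.1], [0.01], [0.2], [0.05])
        res = causal.mr_wald(inst)
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        inst = make_instruments([0.1], [0.01], [0.0], [0.05])
        res = causal.mr_wald(inst)
        assert res.beta == 0.0 and res.p == 1.0

    def test_zero_exposure_rejected(self):
        inst = make_instruments([0.0], [0.01], [0.2], [0.05])
        with pytest.raises(ZeroDivisionError):
            causal.mr_wald(inst)

    def test_null_type_i_error_calibrated(self):
        """Protein with no disease effect: Wald ratio rejects at ~5%."""
        rng = np.random.default_rng(19)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            be = 0.3 + rng.normal(0, 0.01)
            bo = rng.normal(0, 0.05)
            inst = make_instruments([be], [0.01], [bo], [0.05])
            hits += causal.mr_wald(inst).p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


class TestIVW:
    def test_duplicated_instrument_equals_wald_half_variance(self):
        one = make_instruments([0.1], [0.01], [0.2], [0.05])
        two = make_instruments([0.1, 0.1], [0.01, 0.01], [0.2, 0.2], [0.05, 0.05])
        w = causal.mr_wald(one)
        iv = causal.mr_ivw(two)
        assert iv.beta == pytest.approx(w.beta)
        assert iv.se == pytest.approx(w.se / math.sqrt(2))

    def test_identical_ratios_recovered(self):
        inst = make_instruments([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.03, 0.03])
        assert causal.mr_ivw(inst).beta == pytest.approx(0.5)

    def test_equals_meta_of_wald_ratios_first_order(self):
        rng = np.random.default_rng(23)
        be = rng.uniform(0.1, 0.4, 8)
        bo = rng.normal(0.3 * be, 0.05)
        so = rng.uniform(0.02, 0.08, 8)
        inst = make_instruments(be, np.full(8, 0.01), bo, so)
        iv = causal.mr_ivw(inst)
        ratios = bo / be
        w = (be / so) ** 2  # inverse of the first-order Wald-ratio variance
        oracle = np.sum(w * ratios) / np.sum(w)
        assert iv.beta == pytest.approx(oracle, rel=1e-10)
        assert iv.se == pytest.approx(1 / math.sqrt(np.sum(w)), rel=1e-10)

    def test_cross_check_against_wls_through_origin(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(29)
        be = rng.uniform(0.1, 0.4, 10)
        bo = rng.normal(0.3 * be, 0.05)
        so = rng.uniform(0.02, 0.08, 10)
        inst = make_instruments(be, np.full(10, 0.01), bo, so)
        iv = causal.mr_ivw(inst)
        wls = sm.WLS(bo, be, weights=1 / so**2).fit()
        assert iv.beta == pytest.approx(wls.params[0], rel=1e-10)

    def test_planted_effect_recovered(self):
        """True causal effect 0.3, 10 strong instruments: within +-0.1."""
        rng = np.random.default_rng(31)
        ok = 0
        for _ in range(100):
            be_true = rng.uniform(0.1, 0.4, 10)
            be = rng.normal(be_true, 0.01)
            bo = rng.normal(0.3 * be_true, 0.04)
            inst = make_instruments(be, np.full(10, 0.01), bo, np.full(10, 0.04))
            ok += abs(causal.mr_ivw(inst).beta - 0.3) < 0.1
        assert ok >= 90


class TestWeightedMedian:
    def test_equal_weight_median(self):
        inst = make_instruments([1, 1, 1.0], [0.1] * 3, [1, 2, 9.0], [1.0] * 3)
        res = causal.mr_weighted_median(inst, n_boot=200, seed=0)
        assert res.beta == pytest.approx(2.0)

    def test_identical_ratios_small_bootstrap_se(self):
        inst = make_instruments([0.2] * 3, [0.001] * 3, [0.1] * 3, [0.001] * 3)
        res = causal.mr_weighted_median(inst, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.5, abs=1e-9)
        assert res.se < 0.05

    def test_equal_weights_match_plain_median(self):
        rng = np.random.default_rng(37)
        vals = rng.normal(0.3, 0.2, 9)
        est = causal.weighted_median(vals, np.ones(9))
        assert est == pytest.approx(np.median(vals), abs=1e-9)

    def test_robust_to_pleiotropic_outliers(self):
        """3 of 10 instruments pleiotropic: median beats IVW most runs."""
        rng = np.random.default_rng(41)
        wins = 0
        for _ in range(100):
            be_true = rng.uniform(0.15, 0.4, 10)
            be = rng.normal(be_true, 0.01)
            bo_true = 0.3 * be_true
            bo_true[:3] += 0.25  # directional pleiotropy
            bo = rng.normal(bo_true, 0.03)
            inst = make_instruments(be, np.full(10, 0.01), bo, np.full(10, 0.03))
            wm = causal.mr_weighted_median(inst, n_boot=50, seed=2)
            iv = causal.mr_ivw(inst)
            wins += abs(wm.beta - 0.3) < abs(iv.beta - 0.3)
        assert wins >= 80


class TestPleiotropy:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(43)
        pvals = []
        for rep in range(200):
            be_true = rng.uniform(0.15, 0.4, 8)
            be = rng.normal(be_true, 0.01)
            bo = rng.normal(0.3 * be_true, 0.05)
            inst = make_instruments(be, np.full(8, 0.01), bo, np.full(8, 0.05))
            pvals.append(causal.pleiotropy_global_test(inst, n_sim=300, seed=rep))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_outlier_detected(self):
        rng = np.random.default_rng(47)
        hits = 0
        for rep in range(100):
            be_true = rng.uniform(0.15, 0.4, 8)
            be = rng.normal(be_true, 0.01)
            bo_true = 0.3 * be_true
            bo_true[0] += 10 * 0.05  # outcome effect inflated 10 SE
            bo = rng.normal(bo_true, 0.05)
            inst = make_instruments(be, np.full(8, 0.01), bo, np.full(8, 0.05))
            hits += causal.pleiotropy_global_test(inst, n_sim=300, seed=rep) < 0.05
        assert hits >= 90

    def test_too_few_instruments_not_applicable(self):
        inst = make_instruments([0.1], [0.01], [0.2], [0.05])
        assert causal.pleiotropy_global_test(inst) is None


def naive_coloc_oracle(df1, df2, p1=1e-4, p2=1e-4, p12=1e-5, w1=causal.W_QT,
                       w2=causal.W_CC):
    """Direct-summation colocalization oracle in plain floats."""
    b1 = np.exp(causal.wakefield_labf(df1["beta"].to_numpy(), df1["se"].to_numpy(), w1))
    b2 = np.exp(causal.wakefield_labf(df2["beta"].to_numpy(), df2["se"].to_numpy(), w2))
    h0 = 1.0
    h1 = p1 * b1.sum()
    h2 = p2 * b2.sum()
    h4 = p12 * (b1 * b2).sum()
    h3 = p1 * p2 * (b1.sum() * b2.sum() - (b1 * b2).sum())
    tot = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / tot


class TestColoc:
    def test_single_shared_variant_h3_exactly_zero(self):
        df = pd.DataFrame({"variant_id": ["v1"], "beta": [0.3], "se": [0.05]})
        res = causal.coloc_abf(df, df.copy())
        assert res.pp_h3 == 0.0

    def test_no_signal_mass_on_h0(self):
        m = 100
        df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(m)],
                           "beta": np.zeros(m), "se": np.full(m, 0.02)})
        res = causal.coloc_abf(df, df.copy())
        assert res.pp_h0 > 0.99

    def test_shared_causal_high_h4(self):
        m = 100
        beta = np.zeros(m)
        beta[40] = 12 * 0.05  # z = 12 at the causal variant
        df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(m)],
                           "beta": beta, "se": np.full(m, 0.05)})
        res = causal.coloc_abf(df, df.copy())
        assert res.pp_h4 > 0.9

    def test_distinct_causals_high_h3(self):
        m = 80
        b1, b2 = np.zeros(m), np.zeros(m)
        b1[10], b2[60] = 0.5, 0.5
        df1 = pd.DataFrame({"variant_id": [f"v{i}" for i in range(m)],
                            "beta": b1, "se": np.full(m, 0.04)})
        df2 = df1.assign(beta=b2)
        res = causal.coloc_abf(df1, df2)
        assert res.pp_h3 > 0.9

    def test_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            m = int(rng.integers(2, 30))
            ids = [f"v{i}" for i in range(m)]
            df1 = pd.DataFrame({"variant_id": ids,
                                "beta": rng.normal(0, 0.1, m),
                                "se": rng.uniform(0.02, 0.1, m)})
            df2 = pd.DataFrame({"variant_id": ids,
                                "beta": rng.normal(0, 0.1, m),
                                "se": rng.uniform(0.02, 0.1, m)})
            res = causal.coloc_abf(df1, df2)
            oracle = naive_coloc_oracle(df1, df2)
            got = np.array([res.pp_h0, res.pp_h1, res.pp_h2, res.pp_h3, res.pp_h4])
            assert np.allclose(got, oracle, atol=1e-9)

    @given(st.integers(min_value=1, max_value=60), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_posteriors_sum_to_one_fuzzed(self, m, seed):
        rng = np.random.default_rng(seed)
        ids = [f"v{i}" for i in range(m)]
        df1 = pd.DataFrame({"variant_id": ids, "beta": rng.normal(0, 2, m),
                            "se": rng.uniform(0.001, 1.0, m)})
        df2 = pd.DataFrame({"variant_id": ids, "beta": rng.normal(0, 2, m),
                            "se": rng.uniform(0.001, 1.0, m)})
        res = causal.coloc_abf(df1, df2)
        total = res.pp_h0 + res.pp_h1 + res.pp_h2 + res.pp_h3 + res.pp_h4
        assert total == pytest.approx(1.0, abs=1e-9)


class TestFinemap:
    def test_dominant_pip_single_member_set(self):
        df = pd.DataFrame({"variant_id": ["a", "b", "c"],
                           "beta": [0.5, 0.05, 0.02], "se": [0.05, 0.05, 0.05]})
        cs = causal.finemap_single_causal(df)
        assert cs.members == ["a"]
        assert cs.pips["pip"].iloc[0] > 0.95

    def test_symmetric_stats_uniform_pips(self):
        m = 20
        df = pd.DataFrame({"variant_id": [f"v{i:02d}" for i in range(m)],
                           "beta": np.full(m, 0.2), "se": np.full(m, 0.05)})
        cs = causal.finemap_single_causal(df)
        assert np.allclose(cs.pips["pip"], 1 / m)
        assert len(cs.members) == math.ceil(0.95 * m)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(59)
        df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(30)],
                           "beta": rng.normal(0, 0.1, 30),
                           "se": rng.uniform(0.02, 0.1, 30)})
        a = causal.finemap_single_causal(df)
        b = causal.finemap_single_causal(df.sample(frac=1, random_state=1))
        pa = a.pips.set_index("variant_id")["pip"]
        pb = b.pips.set_index("variant_id")["pip"]
        assert np.allclose(pa.sort_index(), pb.sort_index())

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            causal.finemap_single_causal(pd.DataFrame(columns=["variant_id", "beta", "se"]))

    def test_coverage_of_true_causal_variant(self):
        """Single causal z~10: causal inside the 95% set in >=90% of 200."""
        rng = np.random.default_rng(61)
        m, covered = 50, 0
        for _ in range(200):
            j = int(rng.integers(0, m))
            beta_true = np.zeros(m)
            beta_true[j] = 0.1  # se 0.01 -> z = 10
            beta = rng.normal(beta_true, 0.01)
            df = pd.DataFrame({"variant_id": [f"v{i}" for i in range(m)],
                               "beta": beta, "se": np.full(m, 0.01)})
            cs = causal.finemap_single_causal(df)
            covered += f"v{j}" in cs.members
        assert covered >= 180


class TestFDR:
    def test_step_up_hand_example(self):
        q = causal.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert causal.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        assert np.all(causal.bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(67)
        p = rng.uniform(0.001, 1, 50)
        assert np.all(causal.bh_fdr(p) >= p - 1e-15)

    def test_end_to_end_fdr_control_under_sparse_alternatives(self):
        """95% null proteins: observed FDR at q<0.05 stays below 0.10."""
        rng = np.random.default_rng(71)
        false_d, total_d = 0, 0
        for _ in range(20):
            n_prot, n_causal = 100, 5
            results = []
            for i in range(n_prot):
                effect = 0.5 if i < n_causal else 0.0
                be = rng.normal(0.3, 0.01)
                bo = rng.normal(effect * 0.3, 0.03)
                inst = make_instruments([be], [0.01], [bo], [0.03])
                results.append(causal.mr_wald(inst, protein=f"P{i}"))
            q = causal.bh_fdr([r.p for r in results])
            disc = np.flatnonzero(q < 0.05)
            total_d += disc.size
            false_d += int(np.sum(disc >= n_causal))
        assert total_d > 0
        assert false_d / total_d <= 0.10


class TestRouting:
    def test_method_matches_instrument_count(self):
        insts = {
            "P1": make_instruments([0.2], [0.01], [0.1], [0.05]),
            "P2": make_instruments([0.2, 0.3], [0.01] * 2, [0.1, 0.15], [0.05] * 2),
            "P3": make_instruments([0.2, 0.3, 0.25], [0.01] * 3,
                                   [0.1, 0.15, 0.12], [0.05] * 3),
        }
        df = causal.mr_per_protein(insts, n_boot=50)
        by = df.set_index(["protein", "method"])
        assert ("P1", "Wald ratio") in by.index
        assert ("P2", "Inverse variance weighted") in by.index
        assert ("P3", "Weighted median") in by.index
        primary = df[df["fdr"].notna()]
        assert len(primary) == 3
        assert np.all(primary["fdr"] >= primary["p"] - 1e-15)
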
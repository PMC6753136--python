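"""MR engine: IVW algebra, heterogeneity and pleiotropy diagnostics,
stepwise instrument refinement, harmonization, CpG pruning and
multivariable MR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meqtlkit import mr
from conftest import make_iv_table


def _table(gammas, Gammas, se_G=0.1, se_g=0.01):
    J = len(gammas)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(J)],
            "gamma": gammas,
            "se_gamma": se_g,
            "Gamma": Gammas,
            "se_Gamma": se_G,
            "maf": 0.3,
            "harmonization_action": "kept",
        }
    )


class TestIVW:
    def test_exact_ratio_agreement(self):
        # all Wald ratios equal 0.5 -> theta exactly 0.5, Q exactly 0
        t = _table([0.5, 0.4, 0.2], [0.25, 0.20, 0.10])
        theta, se, p = mr.ivw_mr(t)
        assert theta == pytest.approx(0.5, abs=1e-12)
        q, ph, _ = mr.cochran_q(t, theta)
        assert q == pytest.approx(0.0, abs=1e-12) and ph == 1.0

    def test_equals_weighted_through_origin_regression(self):
        rng = np.random.default_rng(0)
        t = make_iv_table(rng, n_iv=8, theta=0.3)
        theta, se, _ = mr.ivw_mr(t)
        # independent oracle: WLS of Gamma on gamma without intercept,
        # weights se_Gamma^-2  (algebraic identity with fixed-effect IVW)
        g = t["gamma"].to_numpy()
        G = t["Gamma"].to_numpy()
        w = t["se_Gamma"].to_numpy() ** -2.0
        theta_wls = np.sum(w * g * G) / np.sum(w * g * g)
        se_wls = np.sum(w * g * g) ** -0.5
        assert theta == pytest.approx(theta_wls, abs=1e-10)
        assert se == pytest.approx(se_wls, abs=1e-10)

    def test_null_is_unbiased(self):
        rng = np.random.default_rng(1)
        ests, ses = [], []
        for _ in range(500):
            t = make_iv_table(rng, n_iv=10, theta=0.0)
            theta, se, _ = mr.ivw_mr(t)
            ests.append(theta)
            ses.append(se)
        assert abs(np.mean(ests)) < 2 * np.mean(ses) / np.sqrt(500)

    def test_zero_gamma_iv_rejected_before_fit(self):
        t = _table([0.5, 0.0, 0.2], [0.25, 0.3, 0.10])
        theta, *_ = mr.ivw_mr(t)
        assert theta == pytest.approx(0.5, abs=1e-12)  # zero-gamma row dropped

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_order_and_sign_flips(self, seed):
        rng = np.random.default_rng(seed)
        t = make_iv_table(rng, n_iv=6, theta=0.4)
        theta0, se0, _ = mr.ivw_mr(t)
        perm = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        flip = perm.copy()
        flip.loc[::2, ["gamma", "Gamma"]] *= -1
        theta1, se1, _ = mr.ivw_mr(flip)
        assert theta1 == pytest.approx(theta0, rel=1e-10)
        assert se1 == pytest.approx(se0, rel=1e-10)

    def test_wald_ratio_fallback(self):
        theta, se, p = mr.wald_ratio(0.5, 0.01, 0.25, 0.1)
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(0.2)


class TestCochranQ:
    def test_hand_computed_fixture(self):
        # ratios (0.5, 0.5, 1.5) with ratio se 0.5 each
        t = _table([1.0, 1.0, 1.0], [0.5, 0.5, 1.5], se_G=0.5)
        theta, *_ = mr.ivw_mr(t)
        q, p, qj = mr.cochran_q(t, theta)
        # oracle by direct substitution
        ratios = np.array([0.5, 0.5, 1.5])
        th = ratios.mean()  # equal weights
        q_hand = float(np.sum((ratios - th) ** 2 / 0.25))
        assert q == pytest.approx(q_hand, abs=1e-12)
        assert len(qj) == 3 and qj.idxmax() == "rs2"

    def test_null_rejection_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sets = 1000
        for _ in range(n_sets):
            t = make_iv_table(rng, n_iv=6, theta=0.2)
            theta, *_ = mr.ivw_mr(t)
            _, p, _ = mr.cochran_q(t, theta)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sets <= 0.07


class TestEgger:
    def test_no_pleiotropy_mean_intercept_zero(self):
        rng = np.random.default_rng(3)
        ints = []
        for _ in range(200):
            t = make_iv_table(rng, n_iv=10, theta=0.4)
            b0, se0, p, b1 = mr.egger_intercept(t)
            ints.append(b0)
        mc_se = np.std(ints) / np.sqrt(len(ints))
        assert abs(np.mean(ints)) < 2 * mc_se + 1e-3

    def test_recovers_directional_pleiotropy(self):
        rng = np.random.default_rng(4)
        ints = []
        for _ in range(200):
            t = make_iv_table(rng, n_iv=10, theta=0.4, pleiotropy=0.1)
            b0, *_ = mr.egger_intercept(t)
            ints.append(b0)
        assert 0.07 <= np.mean(ints) <= 0.13

    def test_weights_irrelevant_when_se_equal(self):
        rng = np.random.default_rng(5)
        t = make_iv_table(rng, n_iv=8, theta=0.4)
        b0, _, _, b1 = mr.egger_intercept(t)
        # unweighted oracle (all se_Gamma equal in make_iv_table)
        flip = np.sign(t["gamma"].to_numpy())
        g, G = t["gamma"].to_numpy() * flip, t["Gamma"].to_numpy() * flip
        slope, intercept = np.polyfit(g, G, 1)
        assert b0 == pytest.approx(intercept, abs=1e-10)
        assert b1 == pytest.approx(slope, abs=1e-10)

    def test_collinear_exposures_rejected(self):
        t = _table([0.3, 0.3, -0.3], [0.1, 0.1, -0.1])
        with pytest.raises(mr.CollinearityError):
            mr.egger_intercept(t)


class TestHarmonize:
    @staticmethod
    def _outcome(swap=False, ea="A", oa="G"):
        if swap:
            ea, oa = oa, ea
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(5)],
                "effect_allele": ea,
                "other_allele": oa,
                "beta": [0.1, 0.2, -0.1, 0.05, 0.3],
                "se": 0.05,
                "maf": 0.3,
            }
        )

    @staticmethod
    def _exposure(ea="A", oa="G"):
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(5)],
                "effect_allele": ea,
                "other_allele": oa,
                "beta": [0.3, 0.5, -0.2, 0.1, 0.6],
                "se": 0.02,
                "maf": 0.3,
            }
        )

    def test_matching_alleles_all_kept(self):
        table = mr.harmonize(self._exposure(), self._outcome())
        assert (table["harmonization_action"] == "kept").all()

    def test_swapped_alleles_flip_and_ivw_invariant(self):
        t_ok = mr.harmonize(self._exposure(), self._outcome())
        # same underlying data reported on the other allele: alleles swapped
        # and betas negated in the file
        swapped_file = self._outcome(swap=True).assign(
            beta=lambda d: -d["beta"]
        )
        t_sw = mr.harmonize(self._exposure(), swapped_file)
        assert (t_sw["harmonization_action"] == "sign_flipped").all()
        assert np.allclose(t_sw["Gamma"], t_ok["Gamma"])
        theta_ok, *_ = mr.ivw_mr(t_ok)
        theta_sw, *_ = mr.ivw_mr(t_sw)
        assert theta_sw == pytest.approx(theta_ok, rel=1e-12)

    def test_ambiguous_palindromic_dropped(self):
        exp = self._exposure(ea="A", oa="T")
        out = self._outcome(ea="A", oa="T").assign(maf=0.50)
        table = mr.harmonize(exp, out)
        assert (table["harmonization_action"] == "dropped_palindromic").all()

    def test_unmatched_ids_dropped(self):
        out = self._outcome().iloc[:2]
        table = mr.harmonize(self._exposure(), out)
        assert (table["harmonization_action"].to_numpy()[2:] == "dropped_unmatched").all()


class TestStepwiseRefinement:
    def test_clean_table_no_exclusions(self):
        t = _table([0.5, 0.4, 0.3, 0.2], [0.25, 0.20, 0.15, 0.10])
        res = mr.stepwise_iv_refinement(t)
        assert res.status == "significant"
        assert res.n_iv_final == res.n_iv_initial == 4
        assert res.excluded_ivs == []

    def test_planted_outlier_excluded_first(self):
        rng = np.random.default_rng(6)
        first_hits, recovered = 0, 0
        n_rep = 100
        for _ in range(n_rep):
            t = make_iv_table(rng, n_iv=10, theta=0.4, outlier_ratio=10.0)
            res = mr.stepwise_iv_refinement(t)
            if res.excluded_ivs and res.excluded_ivs[0] == "rs0":
                first_hits += 1
            if res.status == "significant":
                recovered += 1
        assert first_hits >= 0.9 * n_rep
        assert recovered >= 0.9 * n_rep

    def test_mutually_inconsistent_ivs_never_significant(self):
        # 4 IVs with wildly different ratios and tiny errors: no 3-subset
        # passes the heterogeneity test
        t = _table([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0], se_G=0.01)
        res = mr.stepwise_iv_refinement(t)
        assert res.status in ("diagnostics_failed", "insufficient_ivs")
        assert res.n_iv_final >= 3

    def test_loop_terminates_within_j_minus_3(self):
        rng = np.random.default_rng(7)
        t = make_iv_table(rng, n_iv=12, theta=0.0)
        t["Gamma"] = rng.standard_normal(12)  # maximal heterogeneity
        res = mr.stepwise_iv_refinement(t)
        assert len(res.excluded_ivs) <= 12 - 3

    def test_insufficient_input(self):
        t = _table([0.5, 0.4], [0.25, 0.2])
        res = mr.stepwise_iv_refinement(t)
        assert res.status == "insufficient_ivs"


class TestPruneCpgs:
    @staticmethod
    def _positions(pos):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": pos},
            index=[f"cg{i}" for i in range(len(pos))],
        )

    def test_close_correlated_pair_keeps_best_p(self):
        posns = self._positions([1_000_000, 2_000_000])
        corr = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]],
                            index=posns.index, columns=posns.index)
        kept, pointer = mr.prune_cpgs(posns, corr, {"cg0": 1e-8, "cg1": 1e-5})
        assert kept == ["cg0"] and pointer == {"cg1": "cg0"}

    def test_distant_pair_both_kept(self):
        posns = self._positions([1_000_000, 4_000_001])
        corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                            index=posns.index, columns=posns.index)
        kept, _ = mr.prune_cpgs(posns, corr, {"cg0": 1e-8, "cg1": 1e-5})
        assert sorted(kept) == ["cg0", "cg1"]

    def test_matches_brute_force_clustering(self):
        posns = self._positions([1, 500_000, 900_000, 5_000_000, 5_400_000])
        r = np.eye(5)
        r[0, 1] = r[1, 0] = 0.8
        r[1, 2] = r[2, 1] = 0.75
        r[3, 4] = r[4, 3] = 0.9
        corr = pd.DataFrame(np.sqrt(r), index=posns.index, columns=posns.index)
        pvals = {f"cg{i}": p for i, p in enumerate([1e-3, 1e-9, 1e-5, 1e-4, 1e-7])}
        kept, pointer = mr.prune_cpgs(posns, corr, pvals)
        # brute force: transitive clusters {0,1,2} and {3,4}
        assert sorted(kept) == ["cg1", "cg4"]
        assert pointer == {"cg0": "cg1", "cg2": "cg1", "cg3": "cg4"}


class TestMultivariableMR:
    def test_single_exposure_reduces_to_ivw(self):
        rng = np.random.default_rng(8)
        t = make_iv_table(rng, n_iv=8, theta=0.4)
        out = mr.multivariable_mr({"cg0": t})
        theta_ivw, *_ = mr.ivw_mr(t)
        assert out["theta"].iloc[0] == pytest.approx(theta_ivw, abs=1e-10)

    def test_conditional_effect_recovery(self):
        rng = np.random.default_rng(9)
        t1_means, t2_means = [], []
        for _ in range(100):
            J = 12
            g1 = 0.2 * (1 + 0.5 * rng.standard_normal(J))
            g2 = 0.2 * (1 + 0.5 * rng.standard_normal(J))
            Gamma = 0.4 * g1 + 0.0 * g2 + 0.02 * rng.standard_normal(J)
            base = {
                "snp_id": [f"rs{i}" for i in range(J)],
                "se_gamma": 0.01, "se_Gamma": 0.02, "maf": 0.3,
                "harmonization_action": "kept", "Gamma": Gamma,
            }
            tables = {
                "cg1": pd.DataFrame({**base, "gamma": g1}),
                "cg2": pd.DataFrame({**base, "gamma": g2}),
            }
            out = mr.multivariable_mr(tables).set_index("exposure")
            t1_means.append(out.loc["cg1", "theta"])
            t2_means.append(out.loc["cg2", "theta"])
        assert 0.3 <= np.mean(t1_means) <= 0.5
        assert abs(np.mean(t2_means)) < 0.1

    def test_duplicated_exposures_rejected(self):
        rng = np.random.default_rng(10)
        t = make_iv_table(rng, n_iv=8, theta=0.4)
        with pytest.raises(mr.CollinearityError):
            mr.multivariable_mr({"cg0": t, "cg1": t.copy()})


class TestExpressionMR:
    def test_bonferroni_threshold_for_eight_genes(self, unrelated_cohort):
        geno = unrelated_cohort["geno"]
        rec = pd.DataFrame(
            {
                "snp_id": list(geno.dosages.columns[:2]),
                "beta": [0.5, 0.4], "se": [0.05, 0.05], "p": [1e-20, 1e-15],
                "effect_allele": "A", "other_allele": "G", "maf": [0.3, 0.3],
            }
        )
        outcome = rec.assign(beta=[0.25, 0.2])
        _, threshold = mr.mr_for_expression(rec, outcome, geno,
                                            alpha=0.05, n_genes_tested=8)
        assert threshold == pytest.approx(0.00625)

    def test_single_iv_wald_fallback(self, unrelated_cohort):
        geno = unrelated_cohort["geno"]
        snp = geno.dosages.columns[0]
        rec = pd.DataFrame(
            {
                "snp_id": [snp], "beta": [0.5], "se": [0.05], "p": [1e-20],
                "effect_allele": "A", "other_allele": "G", "maf": [0.3],
            }
        )
        outcome = pd.DataFrame(
            {"snp_id": [snp], "effect_allele": ["A"], "other_allele": ["G"],
             "beta": [0.25], "se": [0.05], "maf": [0.3]}
        )
        res, _ = mr.mr_for_expression(rec, outcome, geno)
        assert res.status == "single_iv_wald"
        assert res.theta == pytest.approx(0.5)
        assert res.se_theta == pytest.approx(0.1)

    def test_protective_gene_recovered(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            t = make_iv_table(rng, n_iv=5, theta=-0.8, se_Gamma=0.05)
            res = mr.stepwise_iv_refinement(t)
            if np.isfinite(res.theta) and res.or_value < 1 and res.p_mr < 0.00625:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestSelectIVs:
    def test_orthogonal_snps_all_retained(self):
        rng = np.random.default_rng(12)
        from meqtlkit.synthetic import GenotypeMatrix
        dos = pd.DataFrame(rng.integers(0, 3, size=(800, 5)).astype(float),
                           columns=[f"s{i}" for i in range(5)])
        geno = GenotypeMatrix(
            dosages=dos,
            snp_map=pd.DataFrame({"chrom": "chr1", "pos": range(1, 6)},
                                 index=dos.columns),
        )
        rec = pd.DataFrame({"snp_id": dos.columns, "p": [1e-8] * 5})
        kept, insufficient = mr.select_ivs(rec, geno)
        assert len(kept) == 5 and not insufficient

    def test_tight_ld_block_collapses_to_one(self):
        rng = np.random.default_rng(13)
        from meqtlkit.synthetic import GenotypeMatrix
        base = rng.integers(0, 3, size=800).astype(float)
        dos = pd.DataFrame(
            {f"s{i}": base + 0.01 * rng.standard_normal(800) for i in range(5)}
        )
        geno = GenotypeMatrix(
            dosages=dos,
            snp_map=pd.DataFrame({"chrom": "chr1", "pos": range(1, 6)},
                                 index=dos.columns),
        )
        rec = pd.DataFrame({"snp_id": dos.columns,
                            "p": [1e-8, 1e-6, 1e-5, 1e-4, 1e-3]})
        kept, insufficient = mr.select_ivs(rec, geno)
        assert kept == ["s0"] and insufficient

    def test_block_structure_keeps_best_per_block(self):
        rng = np.random.default_rng(14)
        from meqtlkit.synthetic import GenotypeMatrix
        cols, data = [], {}
        pv = []
        for b in range(3):
            base = rng.integers(0, 3, size=1000).astype(float)
            for i in range(4):
                name = f"b{b}_s{i}"
                cols.append(name)
                data[name] = base + 0.05 * rng.standard_normal(1000)
                pv.append(10.0 ** -(8 - i) if b == 0 else 10.0 ** -(7 - i + b))
        dos = pd.DataFrame(data)
        geno = GenotypeMatrix(
            dosages=dos,
            snp_map=pd.DataFrame({"chrom": "chr1", "pos": range(1, 13)},
                                 index=dos.columns),
        )
        rec = pd.DataFrame({"snp_id": cols, "p": pv})
        kept, insufficient = mr.select_ivs(rec, geno)
        assert len(kept) == 3 and not insufficient
        # brute-force oracle: lowest p within each block
        best = {b: min((p, c) for p, c in zip(pv, cols) if c.startswith(f"b{b}"))[1]
                for b in range(3)}
        assert sorted(kept) == sorted(best.values())
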
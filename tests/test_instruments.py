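import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from proxymr import (
    ReferencePanel,
    SimConfig,
    conditional_f_statistic,
    inverse_rank_normalise,
    ld_clump,
    linear_to_logodds,
    mean_f_statistic,
    multivariable_clump,
    region_exclude,
    run_gwas_binary,
    run_gwas_quantitative,
    simulate_trios,
)
from proxymr.instruments import InstrumentSet, _greedy_clump

from conftest import make_summary_stats


class TestInverseRankNormalise:
    def test_blom_formula_on_three_values(self):
        # oracle: direct numerical evaluation of Phi^-1((r - 3/8)/(n + 1/4))
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        out = inverse_rank_normalise([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [-0.8694, 0.0, 0.8694], atol=5e-5)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            inverse_rank_normalise(x), inverse_rank_normalise(np.exp(3 * x)), atol=1e-12
        )

    def test_odd_symmetric_input_middle_is_zero(self):
        out = inverse_rank_normalise([-5.0, -1.0, 0.0, 1.0, 5.0])
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            inverse_rank_normalise([2.0, 2.0, 2.0])

    def test_ties_get_average_ranks(self):
        out = inverse_rank_normalise([1.0, 1.0, 3.0])
        assert out[0] == out[1]

    def test_output_passes_normality_ks(self, rng):
        x = rng.exponential(size=10_000)
        z = inverse_rank_normalise(x)
        assert stats.kstest(z, "norm").pvalue > 0.01
        assert abs(z.mean()) < 0.01 and abs(z.std() - 1.0) < 0.01


def _meta(L):
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(L)],
            "chr": np.arange(L) % 22 + 1,
            "pos": np.arange(L) * 2_000_000 + 1,
            "effect_allele": ["A"] * L,
            "other_allele": ["C"] * L,
        }
    )


class TestGwasQuantitative:
    def test_recovers_planted_effect(self, rng):
        n, L = 20_000, 5
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        y = 0.2 * g[:, 0] + rng.normal(size=n)
        ss = run_gwas_quantitative(g, y, _meta(L))
        row = ss.table.iloc[0]
        assert abs(row["beta"] - 0.2) < 3 * row["se"]

    def test_matches_statsmodels_with_covariates(self, rng):
        n, L = 500, 3
        g = rng.binomial(2, 0.4, size=(n, L)).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.1 * g[:, 1] + cov @ [0.5, -0.3] + rng.normal(size=n)
        ss = run_gwas_quantitative(g, y, _meta(L), covariates=cov)
        for j in range(L):
            X = sm.add_constant(np.column_stack([g[:, j], cov]))
            fit = sm.OLS(y, X).fit()
            assert ss.table.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert ss.table.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert ss.table.loc[j, "pval"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        n, L = 2_000, 150
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        y = rng.normal(size=n)
        ss = run_gwas_quantitative(g, y, _meta(L))
        assert stats.kstest(ss.table["pval"], "uniform").pvalue > 0.001

    def test_duplicate_covariate_rejected(self, rng):
        n, L = 200, 2
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        cov = rng.normal(size=n)
        with pytest.raises(ValueError, match="rank deficient"):
            run_gwas_quantitative(
                g, rng.normal(size=n), _meta(L), covariates=np.column_stack([cov, cov])
            )

    def test_monomorphic_snp_excluded_with_warning(self, rng):
        n, L = 300, 4
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        g[:, 2] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            ss = run_gwas_quantitative(g, rng.normal(size=n), _meta(L))
        assert len(ss) == 3
        assert "rs3" not in set(ss.table["SNP"])


class TestGwasBinary:
    def test_too_few_cases_rejected(self, rng):
        n, L = 300, 3
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        status = np.zeros(n, dtype=int)
        status[:5] = 1
        with pytest.raises(ValueError, match="cases"):
            run_gwas_binary(g, status, _meta(L))

    def test_non_binary_status_rejected(self, rng):
        g = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        with pytest.raises(ValueError, match="0/1"):
            run_gwas_binary(g, np.full(100, 2), _meta(2))

    def test_null_betas_centred_on_zero(self, rng):
        n, L = 5_000, 50
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        status = (rng.random(n) < 0.2).astype(int)
        ss = run_gwas_binary(g, status, _meta(L))
        z = ss.table["beta"] / ss.table["se"]
        assert abs(z.mean()) < 3 / np.sqrt(L)

    def test_positive_liability_weight_gives_positive_betas(self, rng):
        n, L = 10_000, 10
        g = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        liab = g.sum(axis=1) * 0.1 + rng.normal(size=n)
        status = (liab > np.quantile(liab, 0.8)).astype(int)
        ss = run_gwas_binary(g, status, _meta(L))
        assert (ss.table["beta"] > 0).all()

    def test_scale_conversion_matches_logistic_fit(self, rng):
        # at prevalence 0.2 the mu(1-mu) rescaling should track a logistic
        # regression coefficient within ~10%
        n = 20_000
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        eta = -1.6 + 0.25 * g[:, 0]
        status = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ss = run_gwas_binary(g, status, _meta(1))
        converted = linear_to_logodds(ss)
        logit = sm.Logit(status, sm.add_constant(g)).fit(disp=0)
        assert converted.table.loc[0, "beta"] == pytest.approx(logit.params[1], rel=0.10)


class TestLinearToLogodds:
    def test_factor_at_half(self):
        ss = make_summary_stats([0.01], [0.005], scale="linear-probability")
        out = linear_to_logodds(ss, case_fraction=0.5)
        assert out.table.loc[0, "beta"] == pytest.approx(0.04)
        assert out.table.loc[0, "se"] == pytest.approx(0.02)
        assert out.scale == "log-odds"

    def test_factor_at_point_one(self):
        ss = make_summary_stats([0.009], [0.001], scale="linear-probability")
        out = linear_to_logodds(ss, case_fraction=0.1)
        assert out.table.loc[0, "beta"] == pytest.approx(0.1)

    def test_zero_beta_stays_zero(self):
        ss = make_summary_stats([0.0], [0.01], scale="linear-probability")
        assert linear_to_logodds(ss, case_fraction=0.37).table.loc[0, "beta"] == 0.0

    def test_scale_and_mu_validation(self):
        ss = make_summary_stats([0.1], [0.01], scale="sd-units")
        with pytest.raises(ValueError):
            linear_to_logodds(ss, case_fraction=0.5)
        ss2 = make_summary_stats([0.1], [0.01], scale="linear-probability")
        with pytest.raises(ValueError):
            linear_to_logodds(ss2, case_fraction=1.0)


def _oracle_greedy(table, r2_of, r2_thresh, window_bp):
    """Independent re-statement of the greedy rule (O(n^2), dict-based)."""
    rows = sorted(table.to_dict("records"), key=lambda r: (r["pval"], r["chr"], r["pos"]))
    kept = []
    for row in rows:
        conflict = any(
            k["chr"] == row["chr"]
            and abs(k["pos"] - row["pos"]) <= window_bp
            and r2_of(k["SNP"], row["SNP"]) >= r2_thresh
            for k in kept
        )
        if not conflict:
            kept.append(row)
    return [r["SNP"] for r in kept]


def _random_panel_and_stats(rng, L, n=400):
    # random dosages with some deliberately correlated pairs
    dos = rng.binomial(2, 0.3, size=(n, L)).astype(float)
    for j in range(1, L, 3):
        if rng.random() < 0.5:  # make SNP j a noisy copy of j-1
            flip = rng.random(n) < 0.05
            dos[:, j] = np.where(flip, rng.binomial(2, 0.3, n), dos[:, j - 1])
    panel = ReferencePanel(dosage=dos, snp_ids=[f"rs{i + 1}" for i in range(L)])
    ss = make_summary_stats(
        beta=rng.normal(size=L),
        se=np.full(L, 0.02),
        chrom=rng.integers(1, 4, L),
        pos=rng.integers(1, 3_000_000, L),
        pval=rng.uniform(1e-12, 1e-6, L),
    )
    return panel, ss


class TestLdClump:
    def test_duplicate_snps_keep_lower_p(self, rng):
        dos = rng.binomial(2, 0.3, size=(300, 5)).astype(float)
        dos[:, 1] = dos[:, 0]  # r^2 = 1
        panel = ReferencePanel(dosage=dos, snp_ids=[f"rs{i+1}" for i in range(5)])
        ss = make_summary_stats(
            beta=[0.1] * 5, se=[0.01] * 5,
            chrom=[1, 1, 2, 3, 4], pos=[100, 200, 100, 100, 100],
            pval=[1e-10, 1e-12, 1e-9, 1e-9, 1e-9],
        )
        instr = ld_clump(ss, panel, p_thresh=5e-8)
        kept = set(instr.snps["SNP"])
        assert "rs2" in kept and "rs1" not in kept
        assert len(instr) == 4

    def test_different_chromosomes_all_retained(self, rng):
        dos = rng.binomial(2, 0.3, size=(300, 4)).astype(float)
        panel = ReferencePanel(dosage=dos, snp_ids=[f"rs{i+1}" for i in range(4)])
        ss = make_summary_stats(
            beta=[0.1] * 4, se=[0.01] * 4, chrom=[1, 2, 3, 4],
            pos=[100] * 4, pval=[1e-9] * 4,
        )
        assert len(ld_clump(ss, panel, p_thresh=5e-8)) == 4

    def test_matches_bruteforce_oracle_small_inputs(self, rng):
        for _ in range(60):
            L = int(rng.integers(2, 9))
            panel, ss = _random_panel_and_stats(rng, L)
            instr = ld_clump(ss, panel, p_thresh=1e-4, r2_thresh=0.2, window_bp=1_000_000)
            expected = _oracle_greedy(ss.table, panel.r2, 0.2, 1_000_000)
            assert list(instr.snps["SNP"]) == sorted(
                expected, key=lambda s: expected.index(s)
            )

    def test_pairwise_constraint_holds_posthoc(self):
        cohort = simulate_trios(
            SimConfig(n_families=3000, n_snps=40, ld_block_size=4, ld_rho=0.9, seed=17)
        )
        panel = ReferencePanel.from_cohort(cohort)
        rng = np.random.default_rng(17)
        ss = make_summary_stats(
            beta=rng.normal(size=40), se=np.full(40, 0.02),
            snp=list(cohort.snp_meta["SNP"]), chrom=list(cohort.snp_meta["chr"]),
            pos=list(cohort.snp_meta["pos"]), pval=rng.uniform(1e-12, 1e-9, 40),
        )
        instr = ld_clump(ss, panel, p_thresh=5e-8, r2_thresh=0.1, window_bp=1_000_000)
        kept = instr.snps
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept.iloc[i], kept.iloc[j]
                if a["chr"] == b["chr"] and abs(a["pos"] - b["pos"]) <= 1_000_000:
                    assert panel.r2(a["SNP"], b["SNP"]) < 0.1

    def test_nothing_passes_threshold_warns_empty(self, rng):
        panel, ss = _random_panel_and_stats(rng, 4)
        with pytest.warns(UserWarning, match="no SNP"):
            instr = ld_clump(ss, panel, p_thresh=1e-30)
        assert len(instr) == 0


class TestMultivariableClump:
    def test_single_trait_reduces_to_ld_clump(self, rng):
        panel, ss = _random_panel_and_stats(rng, 8)
        uni = ld_clump(ss, panel, p_thresh=1e-4, r2_thresh=0.2)
        pooled = multivariable_clump([ss], panel, p_thresh=1e-4, r2_thresh=0.2)
        assert sorted(uni.snps["SNP"]) == sorted(pooled.snps["SNP"])

    def test_snp_significant_in_one_trait_instruments_all(self, rng):
        panel, _ = _random_panel_and_stats(rng, 3)
        common = dict(se=[0.01] * 3, chrom=[1, 2, 3], pos=[100] * 3)
        a = make_summary_stats(beta=[0.1, 0.0, 0.0], pval=[1e-10, 0.5, 0.5],
                               trait="apoB", **common)
        b = make_summary_stats(beta=[0.0, 0.0, 0.09], pval=[0.6, 0.7, 1e-9],
                               trait="TG", **common)
        instr = multivariable_clump([a, b], panel, p_thresh=5e-8)
        assert instr.beta.shape == (2, 2)
        assert set(instr.traits) == {"apoB", "TG"}
        # the TG-only SNP still carries an apoB column
        row = list(instr.snps["SNP"]).index("rs3")
        assert instr.beta[row, 0] == 0.0 and instr.beta[row, 1] == 0.09

    def test_pooled_count_not_more_than_sum_of_univariable(self, rng):
        for _ in range(10):
            panel, ss1 = _random_panel_and_stats(rng, 8)
            ss2 = make_summary_stats(
                beta=rng.normal(size=8), se=np.full(8, 0.02),
                chrom=list(ss1.table["chr"]), pos=list(ss1.table["pos"]),
                pval=rng.uniform(1e-12, 1e-6, 8), trait="second",
            )
            pooled = multivariable_clump([ss1, ss2], panel, p_thresh=1e-4, r2_thresh=0.2)
            n_uni = sum(
                len(ld_clump(s, panel, p_thresh=1e-4, r2_thresh=0.2)) for s in (ss1, ss2)
            )
            assert len(pooled) <= n_uni

    def test_disjoint_universes_rejected(self, rng):
        panel, ss1 = _random_panel_and_stats(rng, 4)
        ss2 = make_summary_stats(
            beta=[0.1], se=[0.01], snp=["other1"], pval=[1e-9], trait="b"
        )
        with pytest.raises(ValueError, match="disjoint"):
            multivariable_clump([ss1, ss2], panel)


def _toy_instrument(beta, se, traits):
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    L = beta.shape[0]
    snps = pd.DataFrame(
        {
            "SNP": [f"rs{i+1}" for i in range(L)],
            "chr": np.arange(L) % 22 + 1,
            "pos": np.arange(L) * 2_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "C",
            "eaf": 0.3,
        }
    )
    return InstrumentSet(
        snps=snps, beta=beta, se=se, pval=np.full_like(beta, 1e-9),
        n=np.full_like(beta, 10_000), traits=list(traits),
        scales=["sd-units"] * len(traits),
        p_thresh=5e-8, r2_thresh=0.001, window_bp=1_000_000,
    )


class TestInstrumentStrength:
    def test_mean_f_from_z_scores(self):
        instr = _toy_instrument([[0.10], [0.12]], [[0.01], [0.01]], ["t"])
        assert mean_f_statistic(instr, "t") == pytest.approx(122.0)

    def test_mean_f_unit_z(self):
        instr = _toy_instrument([[0.01]] * 4, [[0.01]] * 4, ["t"])
        assert mean_f_statistic(instr, "t") == pytest.approx(1.0)

    def test_mean_f_scales_with_sample_size(self, rng):
        L, effect = 12, 0.15
        g = rng.binomial(2, 0.3, size=(16_000, L)).astype(float)
        b = rng.normal(0, effect, L)
        y = g @ b + rng.normal(size=16_000)
        ss_n = run_gwas_quantitative(g[:8_000], y[:8_000], _meta(L))
        ss_2n = run_gwas_quantitative(g, y, _meta(L))
        f_n = np.mean((ss_n.table["beta"] / ss_n.table["se"]) ** 2)
        f_2n = np.mean((ss_2n.table["beta"] / ss_2n.table["se"]) ** 2)
        assert f_2n / f_n == pytest.approx(2.0, rel=0.25)

    def test_conditional_f_wls_oracle(self, rng):
        # 12-SNP, 3-trait fixture against an explicit normal-equations oracle
        beta = rng.normal(size=(12, 3))
        se = rng.uniform(0.01, 0.05, size=(12, 3))
        instr = _toy_instrument(beta, se, ["a", "b", "c"])
        f = conditional_f_statistic(instr, "a")
        w = 1.0 / se[:, 0] ** 2
        X = beta[:, 1:]
        delta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * beta[:, 0]))
        q = float(w @ (beta[:, 0] - X @ delta) ** 2)
        assert f == pytest.approx(q / (12 - 3 + 1), abs=1e-10)

    def test_conditional_f_reduces_when_others_zero(self):
        rng = np.random.default_rng(5)
        b = rng.normal(0.1, 0.02, 10)
        beta = np.column_stack([b, np.zeros(10)])
        se = np.full((10, 2), 0.01)
        instr = _toy_instrument(beta, se, ["a", "b"])
        L, K = 10, 2
        expected = L * mean_f_statistic(instr, "a") / (L - K + 1)
        assert conditional_f_statistic(instr, "a") == pytest.approx(expected, rel=1e-10)

    def test_collinear_target_gives_near_zero(self):
        rng = np.random.default_rng(6)
        other = rng.normal(size=(10, 1))
        beta = np.column_stack([2.0 * other[:, 0], other[:, 0]])
        instr = _toy_instrument(beta, np.full((10, 2), 0.01), ["a", "b"])
        assert conditional_f_statistic(instr, "a") == pytest.approx(0.0, abs=1e-16)

    def test_conditional_f_below_unconditional_for_correlated_traits(self, rng):
        shared = rng.normal(0.1, 0.03, 20)
        beta = np.column_stack([shared + rng.normal(0, 0.01, 20), shared])
        se = np.full((20, 2), 0.01)
        instr = _toy_instrument(beta, se, ["a", "b"])
        L, K = 20, 2
        unconditional = L * mean_f_statistic(instr, "a") / (L - K + 1)
        assert conditional_f_statistic(instr, "a") < unconditional

    def test_conditional_f_requires_two_traits(self):
        instr = _toy_instrument([[0.1]] * 5, [[0.01]] * 5, ["a"])
        with pytest.raises(ValueError):
            conditional_f_statistic(instr, "a")


class TestRegionExclude:
    def _stats(self):
        return make_summary_stats(
            beta=np.linspace(0.01, 0.1, 10), se=np.full(10, 0.01),
            chrom=[19] * 5 + [2] * 5, pos=list(range(100, 600, 100)) * 2,
        )

    def test_no_overlap_is_identity(self):
        ss = self._stats()
        out = region_exclude(ss, chrom=19, start_bp=10_000, end_bp=20_000)
        pd.testing.assert_frame_equal(out.table, ss.table)

    def test_counts_after_exclusion(self):
        out = region_exclude(self._stats(), chrom=19, start_bp=100, end_bp=300)
        assert len(out) == 7

    def test_all_inside_warns_empty(self):
        ss = make_summary_stats(beta=[0.1, 0.2], se=[0.01, 0.01],
                                chrom=[1, 1], pos=[100, 200])
        with pytest.warns(UserWarning, match="every SNP"):
            out = region_exclude(ss, chrom=1, start_bp=1, end_bp=1000)
        assert len(out) == 0

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            region_exclude(self._stats(), chrom=1, start_bp=500, end_bp=100)

    def test_works_on_instrument_set(self):
        instr = _toy_instrument([[0.1]] * 4, [[0.01]] * 4, ["t"])
        out = region_exclude(instr, chrom=1, start_bp=1, end_bp=10)
        assert len(out) == 3 and out.beta.shape == (3, 1)
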
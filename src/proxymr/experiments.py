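"""Reference simulation studies used for validation.

Each experiment builds its inputs, runs the package's own machinery, and
measures the quantity of interest. They are exercised both by the test
suite and by the acceptance report.
"""
from __future__ import annotations

import numpy as np

from ._streams import substream
from .cohort import SimConfig, simulate_trios
from .estimators import harmonise, harmonised_from_arrays, ivw, mr_egger, mvmr_ivw, \
    weighted_median, weighted_mode
from .instruments import run_gwas_binary, run_gwas_quantitative
from .screen import dilution_ratio


def dilution_experiment(
    seed: int,
    n_families: int = 2000,
    n_snps: int = 50,
    maf: float = 0.3,
    score_coef: float = 1.0,
    noise_sd: float = 0.25,
    n_reps: int = 4,
) -> dict:
    """Family-proxy dilution: proxy-design IVW over direct-design IVW.

    A continuous outcome is generated from a genotype score with the same
    coefficients twice -- once on the father, once on the offspring. SNP
    effects are always estimated against offspring dosage, so the parental
    (proxy) design should recover half the direct effect.

    ``n_reps`` independent replicates of the same-size design are averaged
    purely to shrink Monte-Carlo noise on the reported ratio.
    """
    ratios, ses = [], []
    last = {}
    for rep in range(n_reps):
        cohort = simulate_trios(
            SimConfig(
                n_families=n_families, n_snps=n_snps, maf_range=(maf, maf),
                seed=seed + 1_000_003 * rep,
            )
        )
        rng = substream(seed, f"dilution:{rep}")
        b = rng.normal(0.0, 0.10, n_snps)
        dos_off = cohort.dosages("offspring").astype(float)
        dos_fat = cohort.dosages("father").astype(float)

        g_off = dos_off @ b
        exposure = g_off + rng.normal(
            0.0, max(1e-6, np.sqrt(max(0.2, 1 - g_off.var()))), n_families
        )
        y_proxy = score_coef * (dos_fat @ b) + rng.normal(0.0, noise_sd, n_families)
        y_direct = score_coef * g_off + rng.normal(0.0, noise_sd, n_families)

        meta = cohort.snp_meta
        ss_exp = run_gwas_quantitative(dos_off, exposure, meta, trait_label="exposure")
        ss_proxy = run_gwas_quantitative(dos_off, y_proxy, meta, trait_label="proxy-outcome")
        ss_direct = run_gwas_quantitative(dos_off, y_direct, meta, trait_label="direct-outcome")

        est_proxy = ivw(harmonise(ss_exp, ss_proxy))
        est_direct = ivw(harmonise(ss_exp, ss_direct))
        res = dilution_ratio(est_proxy, est_direct)
        ratios.append(res.ratio)
        ses.append(res.se)
        last = {"proxy_beta": est_proxy.beta, "direct_beta": est_direct.beta}
    return {
        "ratio_pct": 100.0 * float(np.mean(ratios)),
        "ratio_se_pct": 100.0 * float(np.mean(ses)) / np.sqrt(n_reps),
        "n_families": n_families,
        "n_snps": n_snps,
        "n_reps": n_reps,
        **last,
    }


def recovery_experiment(
    seed: int,
    n: int = 20_000,
    n_snps: int = 50,
    theta: float = 0.3,
    maf: float = 0.3,
) -> dict:
    """Two-sample individual-level recovery of a planted causal effect by
    IVW, MR-Egger, weighted median and weighted mode."""
    rng = substream(seed, "recovery")
    b = rng.uniform(0.05, 0.25, n_snps) * rng.choice([-1.0, 1.0], n_snps)

    def sample():
        g = rng.binomial(2, maf, size=(n, n_snps)).astype(float)
        score = g @ b
        return g, score

    g1, score1 = sample()
    x = score1 + rng.normal(0.0, np.sqrt(max(0.1, 1 - score1.var())), n)
    g2, score2 = sample()
    y = theta * score2 + rng.normal(0.0, 1.0, n)

    import pandas as pd

    meta = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "chr": np.arange(n_snps) % 22 + 1,
            "pos": np.arange(n_snps) * 3_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "C",
        }
    )
    ss_exp = run_gwas_quantitative(g1, x, meta, trait_label="exposure")
    ss_out = run_gwas_quantitative(g2, y, meta, trait_label="outcome")
    h = harmonise(ss_exp, ss_out)
    return {
        "ivw": ivw(h),
        "mr_egger": mr_egger(h),
        "weighted_median": weighted_median(h, n_boot=500, seed=seed),
        "weighted_mode": weighted_mode(h, n_boot=200, seed=seed),
        "theta": theta,
    }


def coverage_experiment(
    seed: int,
    n_reps: int = 500,
    n_snps: int = 50,
    n: int = 20_000,
    theta: float = 0.3,
    maf: float = 0.3,
) -> dict:
    """Coverage of the IVW 95% CI over summary-level replicates.

    SNP effects are drawn from the sampling distribution implied by a
    two-sample design of size ``n`` per arm (standard errors
    1/sqrt(n * 2 maf (1-maf)) for unit-variance traits).
    """
    rng = substream(seed, "coverage")
    se = 1.0 / np.sqrt(n * 2 * maf * (1 - maf))
    covered = 0
    estimates = np.empty(n_reps)
    for r in range(n_reps):
        bx = rng.uniform(0.05, 0.25, n_snps) * rng.choice([-1.0, 1.0], n_snps)
        bx_hat = bx + rng.standard_normal(n_snps) * se
        by_hat = theta * bx + rng.standard_normal(n_snps) * se
        h = harmonised_from_arrays(bx_hat, np.full(n_snps, se), by_hat, np.full(n_snps, se))
        est = ivw(h)
        estimates[r] = est.beta
        covered += est.ci_low <= theta <= est.ci_high
    return {
        "coverage": covered / n_reps,
        "mean_estimate": float(estimates.mean()),
        "n_reps": n_reps,
        "theta": theta,
    }


def sign_reversal_experiment(
    seed: int,
    n_reps: int = 100,
    n: int = 8_000,
    n_snps: int = 40,
    maf: float = 0.3,
    genetic_corr: float = 0.9,
    direct_effects: tuple[float, float] = (0.4, -0.8),
    prevalence: float = 0.2,
) -> dict:
    """Univariable vs multivariable sign reversal with correlated exposures.

    Two exposures share most of their genetic basis (correlation ~0.9) but
    have opposite direct effects on a liability-threshold outcome. The
    univariable estimate of exposure 1 should take the sign of the combined
    effect (negative); MVMR should recover the planted positive direct sign.
    """
    import pandas as pd
    from scipy import stats as sps

    rng = substream(seed, "sign-reversal")
    a1, a2 = direct_effects
    var_pa = 2 * maf * (1 - maf)
    s = np.sqrt(0.25 / (n_snps * var_pa))  # ~25% exposure heritability
    meta = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "chr": np.arange(n_snps) % 22 + 1,
            "pos": np.arange(n_snps) * 3_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "C",
        }
    )
    thresh = sps.norm.isf(prevalence)
    successes = 0
    uni_betas, mv_betas = [], []
    for _ in range(n_reps):
        b1 = rng.standard_normal(n_snps) * s
        b2 = genetic_corr * b1 + np.sqrt(1 - genetic_corr**2) * rng.standard_normal(n_snps) * s

        g_exp = rng.binomial(2, maf, size=(n, n_snps)).astype(float)
        e_shared = rng.standard_normal(n)
        x1 = g_exp @ b1 + np.sqrt(0.75) * (0.6 * e_shared + 0.8 * rng.standard_normal(n))
        x2 = g_exp @ b2 + np.sqrt(0.75) * (0.6 * e_shared + 0.8 * rng.standard_normal(n))

        g_out = rng.binomial(2, maf, size=(n, n_snps)).astype(float)
        z1 = g_out @ b1 + np.sqrt(0.75) * rng.standard_normal(n)
        z2 = g_out @ b2 + np.sqrt(0.75) * rng.standard_normal(n)
        liab = a1 * z1 + a2 * z2 + rng.standard_normal(n)
        status = (liab > thresh * np.std(liab)).astype(int)

        ss_x1 = run_gwas_quantitative(g_exp, x1, meta, trait_label="exp1")
        ss_x2 = run_gwas_quantitative(g_exp, x2, meta, trait_label="exp2")
        ss_y = run_gwas_binary(g_out, status, meta, trait_label="disease")

        uni = ivw(harmonise(ss_x1, ss_y))
        mv = mvmr_ivw(harmonise([ss_x1, ss_x2], ss_y))[0]
        uni_betas.append(uni.beta)
        mv_betas.append(mv.beta)
        successes += (uni.beta < 0) and (mv.beta > 0)
    return {
        "success_fraction": successes / n_reps,
        "n_reps": n_reps,
        "mean_univariable": float(np.mean(uni_betas)),
        "mean_mvmr": float(np.mean(mv_betas)),
    }
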
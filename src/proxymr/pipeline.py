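"""End-to-end pipeline: simulate -> GWAS -> clump -> screen -> sensitivity.

One config file drives every stage; all randomness flows from the config
seed through named substreams, so repeated runs are byte-identical.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._streams import substream
from .catalog import DISEASES, default_catalog, prevalence
from .cohort import (
    DiseaseModel,
    DiseaseSpec,
    FamilyReportModel,
    LifespanModel,
    LipidEffectModel,
    SimConfig,
    TrioCohort,
    apply_report_noise,
    simulate_lipids,
    simulate_outcomes,
    simulate_trios,
)
from .config import RunConfig
from .estimators import harmonise
from .instruments import (
    ReferencePanel,
    SummaryStats,
    inverse_rank_normalise,
    ld_clump,
    linear_to_logodds,
    mean_f_statistic,
    conditional_f_statistic,
    multivariable_clump,
    run_gwas_binary,
    run_gwas_quantitative,
)
from .io import write_results
from .screen import mediation_proportion, sensitivity_suite, univariable_screen

TRAITS = ("apoB", "LDL", "TG")

#: liability weights (apoB, LDL, TG) for diseases with a lipid component;
#: the remaining catalogue diseases are simulated as pure noise.
_DISEASE_WEIGHTS = {
    "heart_disease": (0.30, 0.12, 0.10),
    "stroke": (0.15, 0.08, 0.05),
    "diabetes": (0.35, -0.40, 0.25),
    "high_blood_pressure": (0.10, 0.05, 0.10),
}


def default_disease_model(cfg, trait_cov: np.ndarray) -> DiseaseModel:
    diseases = {}
    for name in DISEASES:
        weights = _DISEASE_WEIGHTS.get(name, (0.0, 0.0, 0.0))
        prev = prevalence("father", name) if ("father", name) in _father_slots() else prevalence("mother", name)
        diseases[name] = DiseaseSpec.from_prevalence(name, weights, prev, trait_cov)
    lifespan = LifespanModel(
        baseline_years=cfg.lifespan_baseline,
        years_lost=tuple(cfg.lifespan_years_lost),
        noise_sd=cfg.lifespan_noise_sd,
        censor_age=cfg.censor_age,
    )
    return DiseaseModel(diseases=diseases, lifespan=lifespan)


def _father_slots():
    from .catalog import FAMILY_HISTORY_COUNTS

    return {(r, o) for (r, o) in FAMILY_HISTORY_COUNTS if r == "father"}


def _covariate_matrix(cohort: TrioCohort, names) -> np.ndarray | None:
    cols = []
    for name in names:
        if name == "age":
            cols.append(cohort.offspring_age)
        elif name == "sex":
            cols.append(cohort.offspring_sex.astype(float))
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols) if cols else None


def outcome_summary_stats(
    cohort: TrioCohort,
    reported: pd.DataFrame,
    covariates: np.ndarray | None,
    catalog=None,
) -> dict[tuple[str, str], SummaryStats]:
    """Per-slot GWAS of each reported relative outcome on offspring dosage.

    Binary slots come back on the log-odds scale (linear-probability OLS
    rescaled by mu*(1-mu)); age at death is a years-scale OLS among families
    whose parent has died.
    """
    dos = cohort.dosages("offspring").astype(float)
    stats_by_slot: dict[tuple[str, str], SummaryStats] = {}
    for slot in catalog or default_catalog():
        rows = reported[reported["role"] == slot.relative].sort_values("family")
        if slot.kind == "disease":
            fams = rows["family"].to_numpy()
            status = rows[slot.outcome].to_numpy().astype(int)
        elif slot.kind == "vital_status":
            fams = rows["family"].to_numpy()
            status = rows["alive"].to_numpy().astype(int)
        else:  # age at death, observed only for deceased parents
            dead = rows[rows["age_at_death"].notna()]
            fams = dead["family"].to_numpy()
            y = dead["age_at_death"].to_numpy(dtype=float)
            cov = covariates[fams] if covariates is not None else None
            ss = run_gwas_quantitative(
                dos[fams], y, cohort.snp_meta, covariates=cov,
                trait_label=f"{slot.relative}:{slot.outcome}", scale="years",
            )
            stats_by_slot[(slot.relative, slot.outcome)] = ss
            continue
        cov = covariates[fams] if covariates is not None else None
        try:
            ss = run_gwas_binary(
                dos[fams], status, cohort.snp_meta, covariates=cov,
                trait_label=f"{slot.relative}:{slot.outcome}",
            )
        except ValueError:
            continue  # slot unavailable (too few cases); screen logs it
        stats_by_slot[(slot.relative, slot.outcome)] = linear_to_logodds(ss)
    return stats_by_slot


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.simulate
    sim = SimConfig(
        n_families=cfg.n_families,
        n_snps=cfg.n_snps,
        maf_range=tuple(cfg.maf_range),
        ld_block_size=cfg.ld_block_size,
        ld_rho=cfg.ld_rho,
        n_siblings_dist=dict(cfg.n_siblings_dist),
        seed=config.seed,
    )
    cohort = simulate_trios(sim)
    mafs = cohort.snp_meta["maf"].to_numpy()
    model_rng = substream(config.seed, "lipid-model")
    lipid_model = LipidEffectModel.random(
        mafs, model_rng, h2=cfg.h2, n_causal=cfg.n_causal,
        shared_fraction=cfg.shared_fraction,
    )
    disease_model = default_disease_model(cfg, lipid_model.trait_covariance(mafs))
    outcomes = simulate_outcomes(
        cohort, lipid_model, disease_model, substream(config.seed, "outcomes")
    )
    report = FamilyReportModel(
        sensitivity=cfg.report_sensitivity, specificity=cfg.report_specificity
    )
    reported = apply_report_noise(outcomes, report, substream(config.seed, "report"))

    covariates = _covariate_matrix(cohort, config.gwas.covariates)
    traits = simulate_lipids(cohort, lipid_model, "offspring", substream(config.seed, "lipids"))
    exposure_stats = []
    for k, name in enumerate(TRAITS):
        y = inverse_rank_normalise(traits[:, k])
        exposure_stats.append(
            run_gwas_quantitative(
                cohort.dosages("offspring").astype(float), y, cohort.snp_meta,
                covariates=covariates, trait_label=name,
            )
        )

    panel = ReferencePanel.from_cohort(
        cohort, n_individuals=min(503, cohort.n_families),
        rng=substream(config.seed, "panel"),
    )
    cl = config.clump
    uni_instruments = {
        ss.trait: ld_clump(ss, panel, cl.p_thresh, cl.r2_thresh, cl.window_bp)
        for ss in exposure_stats
    }
    mv_instrument = multivariable_clump(
        exposure_stats, panel, cl.p_thresh, cl.r2_thresh, cl.window_bp
    )

    outcome_stats = outcome_summary_stats(cohort, reported, covariates)

    est = config.estimators
    screens = []
    for name in TRAITS:
        instr = uni_instruments[name]
        if len(instr) == 0:
            continue
        scr = univariable_screen(
            instr, name, outcome_stats, q=config.fdr_q,
            palindrome_eaf_limit=est.palindrome_eaf_limit,
        )
        screens.append(scr)
    screen_table = pd.concat(screens, ignore_index=True) if screens else pd.DataFrame()

    # sensitivity suite for every slot passing the apoB screen
    sens_frames = []
    flags_rows = []
    if len(screen_table):
        apob = screen_table[(screen_table["exposure"] == "apoB") & screen_table["pass"]]
        exp_ss = uni_instruments["apoB"].summary_stats("apoB")
        mv_ss = [mv_instrument.summary_stats(t) for t in mv_instrument.traits] if len(mv_instrument) else None
        for row in apob.itertuples():
            out_ss = outcome_stats.get((row.relative, row.outcome))
            if out_ss is None:
                continue
            h_uni = harmonise(exp_ss, out_ss, est.palindrome_eaf_limit)
            h_mv = (
                harmonise(mv_ss, out_ss, est.palindrome_eaf_limit)
                if mv_ss is not None and len(mv_instrument) > len(TRAITS) + 1
                else None
            )
            table, flags = sensitivity_suite(
                h_uni, h_mv, orient_trait="TG", n_boot=est.n_boot, seed=config.seed
            )
            table.insert(0, "relative", row.relative)
            table["outcome"] = row.outcome  # relative-specific slot label
            sens_frames.append(table)
            flags_rows.append(
                {
                    "relative": row.relative, "outcome": row.outcome,
                    "ivw_egger_sign_disagreement": flags["ivw_egger_sign_disagreement"],
                }
            )
    sens_table = (
        pd.concat(sens_frames, ignore_index=True) if sens_frames else pd.DataFrame()
    )

    mediation_table = _run_mediation(
        cohort, outcomes, covariates, uni_instruments, outcome_stats, panel, config
    )

    forest = _forest_table(screen_table, sens_table)

    strength_rows = []
    for name in TRAITS:
        instr = uni_instruments[name]
        if len(instr):
            strength_rows.append(
                {"trait": name, "setting": "univariable", "n_snps": len(instr),
                 "f_stat": mean_f_statistic(instr, name)}
            )
    if len(mv_instrument) > len(TRAITS):
        for name in TRAITS:
            strength_rows.append(
                {"trait": name, "setting": "multivariable", "n_snps": len(mv_instrument),
                 "f_stat": conditional_f_statistic(mv_instrument, name)}
            )
    strength_table = pd.DataFrame(strength_rows)

    tables = {
        "screen": screen_table,
        "sensitivity": sens_table,
        "mediation": mediation_table,
        "forest_data": forest,
        "instrument_strength": strength_table,
        "sensitivity_flags": pd.DataFrame(flags_rows),
    }
    write_results(tables, outdir)
    _write_log(outdir, config)
    return tables


def _run_mediation(cohort, outcomes, covariates, uni_instruments, outcome_stats,
                   panel, config) -> pd.DataFrame:
    """ApoB -> paternal age at death, mediated by offspring heart disease and
    diabetes liability (mediators entered jointly and singly)."""
    out_ss = outcome_stats.get(("father", "age_at_death"))
    apob_instr = uni_instruments.get("apoB")
    if out_ss is None or apob_instr is None or len(apob_instr) < 3:
        return pd.DataFrame()
    est = config.estimators
    apob_ss = apob_instr.summary_stats("apoB")
    dos = cohort.dosages("offspring").astype(float)
    own = outcomes[outcomes["role"] == "offspring"].sort_values("family")
    mediator_ss = {}
    for mediator in ("heart_disease", "diabetes"):
        try:
            ss = run_gwas_binary(
                dos, own[mediator].to_numpy().astype(int), cohort.snp_meta,
                covariates=covariates, trait_label=mediator,
            )
        except ValueError:
            continue
        mediator_ss[mediator] = linear_to_logodds(ss)
    if not mediator_ss:
        return pd.DataFrame()
    cl = config.clump
    rows = []
    combos = [tuple(mediator_ss)] + [(m,) for m in mediator_ss] if len(mediator_ss) > 1 else [tuple(mediator_ss)]
    for combo in combos:
        stats_list = [apob_ss] + [mediator_ss[m] for m in combo]
        instr = multivariable_clump(stats_list, panel, cl.p_thresh, cl.r2_thresh, cl.window_bp)
        if len(instr) <= len(stats_list):
            continue
        mv_ss = [instr.summary_stats(s.trait) for s in stats_list]
        h_total = harmonise(instr.summary_stats("apoB"), out_ss, est.palindrome_eaf_limit)
        h_direct = harmonise(mv_ss, out_ss, est.palindrome_eaf_limit)
        try:
            res = mediation_proportion(h_total, h_direct, seed=config.seed)
        except ValueError:
            continue
        rows.append(
            {
                "exposure": "apoB", "outcome": "father:age_at_death",
                "mediators": "+".join(combo), "mode": "joint" if len(combo) > 1 else "single",
                "total_beta": res.total.beta, "direct_beta": res.direct.beta,
                "proportion": res.proportion, "lo95": res.lo95, "hi95": res.hi95,
                "unstable": res.unstable,
            }
        )
    return pd.DataFrame(rows)


def _forest_table(screen_table: pd.DataFrame, sens_table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long format: one row per (outcome, exposure, method)."""
    cols = ["relative", "outcome", "exposure", "method", "nsnp", "beta",
            "lo95", "hi95", "pval", "scale", "or", "or_lo", "or_hi"]
    frames = []
    if len(screen_table):
        frames.append(screen_table[screen_table["available"]][
            [c for c in cols if c in screen_table.columns]
        ])
    if len(sens_table):
        frames.append(sens_table[[c for c in cols if c in sens_table.columns]])
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def _write_log(outdir: Path, config: RunConfig) -> None:
    import yaml
    from dataclasses import asdict

    lines = [
        f"proxymr version: {__version__}",
        f"seed: {config.seed}",
        f"config hash: {config.config_hash()}",
        "config:",
        yaml.safe_dump(_plain_dict(asdict(config)), sort_keys=True).rstrip(),
    ]
    (outdir / "run.log").write_text("\n".join(lines) + "\n")


def _plain_dict(obj):
    if isinstance(obj, dict):
        return {str(k): _plain_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain_dict(v) for v in obj]
    return obj
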
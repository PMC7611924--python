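"""The outcome screen and downstream sensitivity machinery.

Runs IVW MR of one exposure against every applicable family-proxy outcome
slot, adjusts the p-values with Benjamini-Hochberg across the slot family,
and provides the follow-up analyses applied to surviving outcomes:
sensitivity estimators, bidirectional MR, mediation through intermediate
diseases, reporting conversions, dilution checks, and sex-stratified
re-estimation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._streams import substream
from .catalog import OutcomeSlot, default_catalog
from .cohort import TrioCohort
from .estimators import (
    HarmonisedSet,
    MREstimate,
    harmonise,
    ivw,
    mr_egger,
    mvmr_egger,
    mvmr_ivw,
    to_odds_ratio,
    weighted_median,
    weighted_mode,
)
from .instruments import (
    InstrumentSet,
    SummaryStats,
    ld_clump,
    run_gwas_binary,
    run_gwas_quantitative,
)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# univariable screen
# ---------------------------------------------------------------------------


def _estimate_row(slot: OutcomeSlot, est: MREstimate) -> dict:
    row = {
        "relative": slot.relative,
        "outcome": slot.outcome,
        "kind": slot.kind,
        "exposure": est.exposure,
        "method": est.method,
        "nsnp": est.nsnp,
        "beta": est.beta,
        "se": est.se,
        "lo95": est.ci_low,
        "hi95": est.ci_high,
        "pval": est.pval,
        "scale": est.scale,
        "or": np.nan,
        "or_lo": np.nan,
        "or_hi": np.nan,
    }
    if est.scale == "log-odds":
        est = to_odds_ratio(est)
        row.update({"or": est.or_, "or_lo": est.or_lo, "or_hi": est.or_hi})
    return row


def univariable_screen(
    instrument: InstrumentSet,
    exposure_trait: str,
    outcome_stats: Mapping[tuple[str, str], SummaryStats],
    q: float = 0.05,
    palindrome_eaf_limit: float = 0.42,
    catalog: Sequence[OutcomeSlot] | None = None,
) -> pd.DataFrame:
    """IVW MR of one exposure against every catalogue slot, BH-adjusted.

    Slots without outcome statistics are marked unavailable and excluded
    from the FDR family. Returns one row per slot.
    """
    slots = list(catalog) if catalog is not None else default_catalog()
    exp_ss = instrument.summary_stats(exposure_trait)
    rows = []
    for slot in slots:
        ss = outcome_stats.get((slot.relative, slot.outcome))
        if ss is None:
            rows.append(
                {
                    "relative": slot.relative, "outcome": slot.outcome, "kind": slot.kind,
                    "exposure": exposure_trait, "method": "ivw", "nsnp": 0,
                    "beta": np.nan, "se": np.nan, "lo95": np.nan, "hi95": np.nan,
                    "pval": np.nan, "scale": "", "or": np.nan, "or_lo": np.nan,
                    "or_hi": np.nan, "available": False,
                }
            )
            continue
        h = harmonise(exp_ss, ss, palindrome_eaf_limit)
        row = _estimate_row(slot, ivw(h))
        row["available"] = True
        rows.append(row)
    result = pd.DataFrame(rows)
    avail = result["available"].to_numpy()
    adj = np.full(len(result), np.nan)
    if avail.any():
        adj[avail] = bh_fdr(result.loc[avail, "pval"].to_numpy())
    result["pval_fdr"] = adj
    result["pass"] = (result["pval_fdr"] < q).fillna(False)
    result["fdr_family_size"] = int(avail.sum())
    return result


# ---------------------------------------------------------------------------
# sensitivity suite
# ---------------------------------------------------------------------------


def sensitivity_suite(
    h_uni: HarmonisedSet,
    h_mv: HarmonisedSet | None = None,
    orient_trait: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """All sensitivity estimators for one outcome.

    Runs IVW, MR-Egger, weighted median and weighted mode on the
    univariable set and, when a multivariable set is supplied, MVMR-IVW and
    MVMR-Egger. Estimators whose SNP-count minimum is not met are skipped
    with a reason. Flags a sign disagreement between IVW and MR-Egger.
    """
    rows: list[dict] = []
    skipped: dict[str, str] = {}
    estimates: dict[str, MREstimate] = {}

    def push(est: MREstimate) -> None:
        estimates[est.method] = est
        slot = OutcomeSlot("", h_uni.outcome, "")
        row = _estimate_row(slot, est)
        row.pop("relative")
        row.pop("kind")
        if est.intercept is not None:
            row["intercept"] = est.intercept
            row["intercept_se"] = est.intercept_se
        rows.append(row)

    push(ivw(h_uni))
    for name, fn in (
        ("mr_egger", lambda: mr_egger(h_uni)),
        ("weighted_median", lambda: weighted_median(h_uni, n_boot=n_boot, seed=seed)),
        ("weighted_mode", lambda: weighted_mode(h_uni, n_boot=n_boot, seed=seed)),
    ):
        try:
            push(fn())
        except ValueError as err:
            skipped[name] = str(err)
    if h_mv is not None:
        try:
            for est in mvmr_ivw(h_mv):
                push(est)
            slopes, _ = mvmr_egger(h_mv, orient_trait or h_mv.exposures[-1])
            for est in slopes:
                push(est)
        except ValueError as err:
            skipped["mvmr"] = str(err)

    flags = {"ivw_egger_sign_disagreement": False}
    if "ivw" in estimates and "mr_egger" in estimates:
        flags["ivw_egger_sign_disagreement"] = (
            math.copysign(1, estimates["ivw"].beta) != math.copysign(1, estimates["mr_egger"].beta)
        )
    flags["skipped"] = skipped
    return pd.DataFrame(rows), flags


def bidirectional_mr(h: HarmonisedSet, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Reverse-direction MR (disease liability -> lipid trait) using IVW,
    MR-Egger and the weighted median."""
    rows = []
    for est in (
        ivw(h),
        mr_egger(h),
        weighted_median(h, n_boot=n_boot, seed=seed),
    ):
        rows.append(
            {
                "exposure": est.exposure, "outcome": est.outcome, "method": est.method,
                "nsnp": est.nsnp, "beta": est.beta, "se": est.se,
                "lo95": est.ci_low, "hi95": est.ci_high, "pval": est.pval,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    proportion: float
    lo95: float
    hi95: float
    total: MREstimate
    direct: MREstimate
    unstable: bool


def mediation_proportion(
    h_total: HarmonisedSet,
    h_direct: HarmonisedSet,
    n_draws: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Proportion of the total effect running through the mediators.

    total = univariable IVW of exposure on outcome; direct = MVMR estimate
    of the exposure (first column of ``h_direct``) with mediators included;
    proportion = 1 - direct/total. The CI comes from independent normal
    resampling of both estimates. A total-effect CI spanning zero flags the
    proportion as unstable.
    """
    total = ivw(h_total)
    direct = mvmr_ivw(h_direct)[0]
    if total.beta == 0:
        raise ValueError("total effect is exactly zero; proportion undefined")
    proportion = 1.0 - direct.beta / total.beta
    unstable = total.ci_low <= 0.0 <= total.ci_high
    rng = substream(seed, "mediation")
    t_draw = rng.normal(total.beta, total.se, n_draws)
    d_draw = rng.normal(direct.beta, direct.se, n_draws)
    ok = t_draw != 0
    props = 1.0 - d_draw[ok] / t_draw[ok]
    lo, hi = np.percentile(props, [2.5, 97.5])
    return MediationResult(
        proportion=float(proportion), lo95=float(lo), hi95=float(hi),
        total=total, direct=direct, unstable=bool(unstable),
    )


# ---------------------------------------------------------------------------
# reporting conversions
# ---------------------------------------------------------------------------


def years_to_months(years: float, rounded: bool = True) -> float:
    """Convert a years-scale effect to months (x12); rounded to one decimal
    for reporting unless ``rounded=False``."""
    months = years * 12.0
    return round(months, 1) if rounded else months


@dataclass
class DilutionResult:
    ratio: float
    se: float
    flagged: bool  # direct-estimate CI spans zero


def dilution_ratio(proxy: MREstimate, direct: MREstimate) -> DilutionResult:
    """Ratio of the family-proxy estimate to the direct estimate with a
    delta-method standard error (expected ~0.5 for first-degree relatives)."""
    if direct.beta == 0:
        raise ValueError("direct estimate is zero; ratio undefined")
    ratio = proxy.beta / direct.beta
    se = math.sqrt(
        proxy.se**2 / direct.beta**2
        + proxy.beta**2 * direct.se**2 / direct.beta**4
    )
    flagged = direct.ci_low <= 0.0 <= direct.ci_high
    return DilutionResult(ratio=float(ratio), se=float(se), flagged=flagged)


# ---------------------------------------------------------------------------
# sex stratification
# ---------------------------------------------------------------------------

#: outcomes whose instrument must come from one index-participant sex
INSTRUMENT_SEX = {"prostate_cancer": 0, "breast_cancer": 1}
_SEX_NAME = {0: "male", 1: "female"}


def sex_stratified_run(
    cohort: TrioCohort,
    exposure_trait_values: np.ndarray,
    exposure_label: str,
    outcome_status: Mapping[tuple[str, str], np.ndarray],
    slots: Sequence[OutcomeSlot],
    panel,
    covariates: np.ndarray | None = None,
    strata: Sequence[int] = (0, 1),
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_bp: int = 1_000_000,
    min_stratum: int = 100,
) -> pd.DataFrame:
    """Re-derive instruments within index-participant sex strata and
    re-estimate MR, reported side by side with the pooled instrument.

    ``outcome_status`` maps (relative, outcome) to a per-family 0/1 vector
    aligned with the cohort's family order.
    """
    for slot in slots:
        need = INSTRUMENT_SEX.get(slot.outcome)
        if need is not None and need not in strata:
            raise ValueError(
                f"{slot.outcome} requires the {_SEX_NAME[need]} stratum, "
                f"which was not requested"
            )
    dos = cohort.dosages("offspring").astype(float)
    rows = []

    def run(mask: np.ndarray, label: str, applicable) -> None:
        if mask.sum() < min_stratum:
            raise ValueError(f"stratum {label!r} too small for GWAS ({int(mask.sum())})")
        cov = covariates[mask] if covariates is not None else None
        exp_ss = run_gwas_quantitative(
            dos[mask], exposure_trait_values[mask], cohort.snp_meta,
            covariates=cov, trait_label=exposure_label,
        )
        instr = ld_clump(exp_ss, panel, p_thresh, r2_thresh, window_bp)
        if len(instr) == 0:
            return
        for slot in applicable:
            status = np.asarray(outcome_status[(slot.relative, slot.outcome)])
            out_ss = run_gwas_binary(
                dos[mask], status[mask], cohort.snp_meta, covariates=cov,
                trait_label=f"{slot.relative}:{slot.outcome}",
            )
            h = harmonise(instr.summary_stats(exposure_label), out_ss)
            est = ivw(h)
            rows.append(
                {
                    "stratum": label, "relative": slot.relative, "outcome": slot.outcome,
                    "exposure": exposure_label, "nsnp": est.nsnp, "beta": est.beta,
                    "se": est.se, "pval": est.pval,
                }
            )

    run(np.ones(cohort.n_families, dtype=bool), "pooled", slots)
    for sex in strata:
        applicable = [
            s for s in slots
            if INSTRUMENT_SEX.get(s.outcome) in (None, sex)
        ]
        run(cohort.offspring_sex == sex, _SEX_NAME[sex], applicable)
    return pd.DataFrame(rows)
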
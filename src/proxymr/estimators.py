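"""Harmonisation and univariable / multivariable MR estimators.

All estimators operate on a :class:`HarmonisedSet` of allele-aligned SNP
effects. Random-effects standard errors use multiplicative scaling by
``max(1, sqrt(Q/df))`` so they are never deflated below the fixed-effect
value. Estimates themselves are deterministic; only bootstrap standard
errors (weighted median / mode) consume randomness, through an explicit
seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream
from .instruments import SummaryStats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

Z95 = 1.96


@dataclass
class MREstimate:
    """A single MR estimate: effect per 1 SD of exposure on the outcome scale."""

    method: str
    exposure: str
    outcome: str
    beta: float
    se: float
    nsnp: int
    scale: str
    pval: float = field(default=None)  # type: ignore[assignment]
    q: float | None = None
    q_df: int | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    or_: float | None = None
    or_lo: float | None = None
    or_hi: float | None = None

    def __post_init__(self) -> None:
        if self.pval is None:
            self.pval = _wald_p(self.beta, self.se)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se


def _wald_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Attach OR = exp(beta) with exponentiated 95% CI (log-odds scale only)."""
    if est.scale != "log-odds":
        raise ValueError(f"odds ratios require a log-odds estimate, got {est.scale!r}")
    return replace(
        est,
        or_=math.exp(est.beta),
        or_lo=math.exp(est.ci_low),
        or_hi=math.exp(est.ci_high),
    )


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------


@dataclass
class HarmonisedSet:
    """Allele-aligned SNP-exposure and SNP-outcome effects (K exposures)."""

    snps: list[str]
    exposures: list[str]
    outcome: str
    exposure_beta: np.ndarray  # L x K
    exposure_se: np.ndarray
    outcome_beta: np.ndarray  # L
    outcome_se: np.ndarray
    outcome_scale: str
    log: pd.DataFrame  # SNP, action, detail

    def __post_init__(self) -> None:
        self.exposure_beta = np.atleast_2d(np.asarray(self.exposure_beta, float))
        self.exposure_se = np.atleast_2d(np.asarray(self.exposure_se, float))
        if self.exposure_beta.shape[0] != len(self.snps):
            self.exposure_beta = self.exposure_beta.T
            self.exposure_se = self.exposure_se.T
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def n_exposures(self) -> int:
        return self.exposure_beta.shape[1]


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _orient(ea_ref, oa_ref, ea, oa):
    """How the (ea, oa) coding relates to the reference: +1 same, -1 swapped,
    None irreconcilable. Strand complements count as the same letters."""
    comp_ea = _COMPLEMENT.get(ea_ref)
    comp_oa = _COMPLEMENT.get(oa_ref)
    if (ea, oa) in ((ea_ref, oa_ref), (comp_ea, comp_oa)):
        return 1
    if (ea, oa) in ((oa_ref, ea_ref), (comp_oa, comp_ea)):
        return -1
    return None


def harmonise(
    exposures: SummaryStats | Sequence[SummaryStats],
    outcome: SummaryStats,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonisedSet:
    """Align every dataset to the first exposure's effect allele.

    Strand flips are resolved by allele complement. Palindromic (A/T, C/G)
    SNPs are resolved by effect-allele-frequency agreement when both
    frequencies lie outside [limit, 1 - limit]; otherwise the SNP is
    dropped. Irreconcilable allele pairs are dropped with a logged reason.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    if not exposures:
        raise ValueError("need at least one exposure")
    others = list(exposures[1:]) + [outcome]

    ref = exposures[0].table.set_index("SNP")
    tables = [s.table.set_index("SNP") for s in others]
    shared = [s for s in ref.index if all(s in t.index for t in tables)]
    if not shared:
        raise ValueError("no shared SNPs between exposure and outcome")

    log_rows = []
    kept: list[str] = []
    exp_beta, exp_se, out_beta, out_se = [], [], [], []
    for snp in shared:
        r = ref.loc[snp]
        ea0, oa0, eaf0 = r["effect_allele"], r["other_allele"], r["eaf"]
        palindromic = _is_palindromic(ea0, oa0)
        betas = [float(r["beta"])]
        ses = [float(r["se"])]
        action, reason = "kept", ""
        for t in tables:
            row = t.loc[snp]
            sign = _orient(ea0, oa0, row["effect_allele"], row["other_allele"])
            if sign is None:
                action, reason = "dropped", "incompatible_alleles"
                break
            b = sign * float(row["beta"])
            eaf = float(row["eaf"]) if sign == 1 else 1.0 - float(row["eaf"])
            if palindromic:
                lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
                e0 = float(eaf0)
                if np.isnan(e0) or np.isnan(eaf):
                    action, reason = "dropped", "palindromic_missing_eaf"
                    break
                if lo <= e0 <= hi or lo <= eaf <= hi:
                    action, reason = "dropped", "palindromic_ambiguous_eaf"
                    break
                if (e0 < 0.5) != (eaf < 0.5):  # strand mismatch inferred from frequency
                    b = -b
                    action = "palindromic_flipped"
                elif action == "kept":
                    action = "palindromic_kept"
            elif sign == -1 and action == "kept":
                action = "flipped"
            betas.append(b)
            ses.append(float(row["se"]))
        log_rows.append({"SNP": snp, "action": action, "detail": reason})
        if action.startswith("dropped"):
            continue
        kept.append(snp)
        exp_beta.append(betas[:-1])
        exp_se.append(ses[:-1])
        out_beta.append(betas[-1])
        out_se.append(ses[-1])

    if not kept:
        raise ValueError("no SNPs survived harmonisation")
    return HarmonisedSet(
        snps=kept,
        exposures=[s.trait for s in exposures],
        outcome=outcome.trait,
        exposure_beta=np.asarray(exp_beta, float),
        exposure_se=np.asarray(exp_se, float),
        outcome_beta=np.asarray(out_beta, float),
        outcome_se=np.asarray(out_se, float),
        outcome_scale=outcome.scale,
        log=pd.DataFrame(log_rows, columns=["SNP", "action", "detail"]),
    )


def harmonised_from_arrays(
    exposure_beta,
    exposure_se,
    outcome_beta,
    outcome_se,
    exposures: Sequence[str] = ("exposure",),
    outcome: str = "outcome",
    outcome_scale: str = "sd-units",
) -> HarmonisedSet:
    """Build a HarmonisedSet directly from aligned effect arrays."""
    eb = np.atleast_2d(np.asarray(exposure_beta, float))
    if eb.shape[0] == 1 and len(np.asarray(outcome_beta).ravel()) != 1:
        eb = eb.T
    L = eb.shape[0]
    return HarmonisedSet(
        snps=[f"snp{i + 1}" for i in range(L)],
        exposures=list(exposures),
        outcome=outcome,
        exposure_beta=eb,
        exposure_se=np.asarray(exposure_se, float),
        outcome_beta=np.asarray(outcome_beta, float),
        outcome_se=np.asarray(outcome_se, float),
        outcome_scale=outcome_scale,
        log=pd.DataFrame(columns=["SNP", "action", "detail"]),
    )


def _require_univariable(h: HarmonisedSet, min_snps: int, method: str) -> None:
    if h.n_exposures != 1:
        raise ValueError(f"{method} is a univariable estimator (got K={h.n_exposures})")
    if len(h) < min_snps:
        raise ValueError(f"{method} requires at least {min_snps} SNPs (got {len(h)})")


# ---------------------------------------------------------------------------
# univariable estimators
# ---------------------------------------------------------------------------


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               exposure: str = "exposure", outcome: str = "outcome",
               scale: str = "sd-units") -> MREstimate:
    """Single-SNP ratio estimate with first-order standard error."""
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    return MREstimate(
        method="wald_ratio", exposure=exposure, outcome=outcome,
        beta=beta_out / beta_exp, se=se_out / abs(beta_exp), nsnp=1, scale=scale,
    )


def ivw(h: HarmonisedSet) -> MREstimate:
    """Inverse-variance-weighted estimate: no-intercept weighted regression of
    outcome effects on exposure effects, weights 1/se_out^2; multiplicative
    random-effects scaling max(1, sqrt(Q/(L-1))) for L >= 2."""
    _require_univariable(h, 1, "ivw")
    bx = h.exposure_beta[:, 0]
    by = h.outcome_beta
    w = 1.0 / h.outcome_se**2
    L = len(h)
    denom = float(w @ bx**2)
    if denom == 0:
        raise ValueError("all exposure effects are zero")
    slope = float(w @ (bx * by)) / denom
    se_fe = math.sqrt(1.0 / denom)
    resid = by - slope * bx
    q = float(w @ resid**2)
    phi = max(1.0, math.sqrt(q / (L - 1))) if L >= 2 else 1.0
    return MREstimate(
        method="ivw", exposure=h.exposures[0], outcome=h.outcome,
        beta=slope, se=se_fe * phi, nsnp=L, scale=h.outcome_scale,
        q=q, q_df=max(L - 1, 0),
    )


def _wls(design: np.ndarray, y: np.ndarray, w: np.ndarray, re_df: int):
    """Weighted least squares with multiplicative random-effects SE scaling."""
    sw = np.sqrt(w)
    a = design * sw[:, None]
    b = y * sw
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = b - a @ coef
    q = float(resid @ resid)
    xtx_inv = np.linalg.pinv(a.T @ a)
    phi = max(1.0, math.sqrt(q / re_df)) if re_df > 0 else 1.0
    se = np.sqrt(np.diag(xtx_inv)) * phi
    return coef, se, q


def mr_egger(h: HarmonisedSet) -> MREstimate:
    """MR-Egger regression: SNPs oriented so exposure effects are positive,
    then weighted regression with an intercept estimating average directional
    pleiotropy."""
    _require_univariable(h, 3, "mr_egger")
    sign = np.where(h.exposure_beta[:, 0] >= 0, 1.0, -1.0)
    bx = sign * h.exposure_beta[:, 0]
    by = sign * h.outcome_beta
    w = 1.0 / h.outcome_se**2
    L = len(h)
    design = np.column_stack([np.ones(L), bx])
    coef, se, q = _wls(design, by, w, L - 2)
    return MREstimate(
        method="mr_egger", exposure=h.exposures[0], outcome=h.outcome,
        beta=float(coef[1]), se=float(se[1]), nsnp=L, scale=h.outcome_scale,
        q=q, q_df=L - 2, intercept=float(coef[0]), intercept_se=float(se[0]),
    )


def _ratios(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    bx = h.exposure_beta[:, 0]
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; cannot form Wald ratios")
    return h.outcome_beta / bx, h.outcome_se / np.abs(bx)


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    # lexicographic tie-break on weight keeps the result independent of the
    # input order of equal ratios
    order = np.lexsort((weight, ratio))
    r = ratio[order]
    w = weight[order] / weight.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5)) - 1
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return float(r[k] + (r[k + 1] - r[k]) * frac)


def weighted_median(h: HarmonisedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of per-SNP Wald ratios (weights 1/se_ratio^2) with a
    seeded parametric-bootstrap standard error."""
    _require_univariable(h, 3, "weighted_median")
    ratio, se_ratio = _ratios(h)
    weight = 1.0 / se_ratio**2
    est = _weighted_median(ratio, weight)
    rng = substream(seed, "bootstrap:weighted_median")
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = h.exposure_beta[:, 0] + rng.standard_normal(len(h)) * h.exposure_se[:, 0]
        by = h.outcome_beta + rng.standard_normal(len(h)) * h.outcome_se
        bx = np.where(bx == 0, 1e-12, bx)
        r = by / bx
        w = (np.abs(bx) / h.outcome_se) ** 2
        boots[b] = _weighted_median(r, w)
    return MREstimate(
        method="weighted_median", exposure=h.exposures[0], outcome=h.outcome,
        beta=est, se=float(boots.std(ddof=1)), nsnp=len(h), scale=h.outcome_scale,
    )


def _mode_estimate(ratio: np.ndarray, weight: np.ndarray, bandwidth: float) -> float:
    lo = ratio.min() - 3 * bandwidth
    hi = ratio.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, 1024)
    dens = (weight[None, :] * stats.norm.pdf((grid[:, None] - ratio[None, :]) / bandwidth)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def _mode_bandwidth(ratio: np.ndarray, bandwidth_factor: float) -> float:
    spread = min(
        float(np.std(ratio, ddof=1)),
        float(stats.median_abs_deviation(ratio, scale="normal")),
    )
    if spread == 0:
        spread = max(float(np.std(ratio, ddof=1)), 1e-8)
    return bandwidth_factor * 0.9 * spread * len(ratio) ** (-1 / 5)


def weighted_mode(h: HarmonisedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the Gaussian-kernel-smoothed weighted density of per-SNP Wald
    ratios (modified Silverman bandwidth), bootstrap standard error."""
    _require_univariable(h, 3, "weighted_mode")
    ratio, se_ratio = _ratios(h)
    weight = 1.0 / se_ratio**2
    if np.allclose(ratio, ratio[0]):
        est = float(ratio[0])
    else:
        est = _mode_estimate(ratio, weight, _mode_bandwidth(ratio, bandwidth_factor))
    rng = substream(seed, "bootstrap:weighted_mode")
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = h.exposure_beta[:, 0] + rng.standard_normal(len(h)) * h.exposure_se[:, 0]
        by = h.outcome_beta + rng.standard_normal(len(h)) * h.outcome_se
        bx = np.where(bx == 0, 1e-12, bx)
        r = by / bx
        w = (np.abs(bx) / h.outcome_se) ** 2
        if np.allclose(r, r[0]):
            boots[b] = r[0]
        else:
            boots[b] = _mode_estimate(r, w, _mode_bandwidth(r, bandwidth_factor))
    return MREstimate(
        method="weighted_mode", exposure=h.exposures[0], outcome=h.outcome,
        beta=est, se=float(boots.std(ddof=1)), nsnp=len(h), scale=h.outcome_scale,
    )


# ---------------------------------------------------------------------------
# multivariable estimators
# ---------------------------------------------------------------------------


def mvmr_ivw(h: HarmonisedSet) -> list[MREstimate]:
    """Multivariable IVW: no-intercept weighted multiple regression of the
    outcome effects on the L x K exposure-effect matrix; returns one direct
    effect per exposure."""
    K = h.n_exposures
    L = len(h)
    if K < 2:
        raise ValueError("mvmr_ivw requires >= 2 exposures; use ivw for K=1")
    if L <= K:
        raise ValueError("mvmr_ivw requires more SNPs than exposures")
    w = 1.0 / h.outcome_se**2
    design = h.exposure_beta
    # an exposure with no instrument signal contributes a zero direct effect;
    # rank deficiency among the informative columns is a genuine error
    active = np.flatnonzero(np.any(design != 0, axis=0))
    sub = design[:, active]
    if np.linalg.matrix_rank(sub * np.sqrt(w)[:, None]) < len(active):
        raise ValueError("exposure effect matrix is rank deficient")
    coef_sub, se_sub, q = _wls(sub, h.outcome_beta, w, L - len(active))
    coef = np.zeros(K)
    se_full = np.full(K, np.nan)
    coef[active] = coef_sub
    se_full[active] = se_sub
    return [
        MREstimate(
            method="mvmr_ivw", exposure=h.exposures[k], outcome=h.outcome,
            beta=float(coef[k]), se=float(se_full[k]), nsnp=L, scale=h.outcome_scale,
            q=q, q_df=L - K, pval=_wald_p(float(coef[k]), float(se_full[k])) if np.isfinite(se_full[k]) else 1.0,
        )
        for k in range(K)
    ]


def mvmr_egger(h: HarmonisedSet, orient_trait: str) -> tuple[list[MREstimate], MREstimate]:
    """Multivariable MR-Egger: rows sign-flipped so the orienting trait's
    effects are positive, then weighted multiple regression with an
    intercept. Returns (per-exposure estimates, intercept estimate)."""
    K = h.n_exposures
    L = len(h)
    if orient_trait not in h.exposures:
        raise ValueError(f"orient trait {orient_trait!r} not among exposures")
    if K < 2:
        raise ValueError("mvmr_egger requires >= 2 exposures")
    if L <= K + 1:
        raise ValueError("mvmr_egger requires L > K + 1 SNPs")
    j = h.exposures.index(orient_trait)
    sign = np.where(h.exposure_beta[:, j] >= 0, 1.0, -1.0)
    bx = h.exposure_beta * sign[:, None]
    by = h.outcome_beta * sign
    w = 1.0 / h.outcome_se**2
    design = np.column_stack([np.ones(L), bx])
    coef, se, q = _wls(design, by, w, L - K - 1)
    slopes = [
        MREstimate(
            method="mvmr_egger", exposure=h.exposures[k], outcome=h.outcome,
            beta=float(coef[k + 1]), se=float(se[k + 1]), nsnp=L, scale=h.outcome_scale,
            q=q, q_df=L - K - 1,
            intercept=float(coef[0]), intercept_se=float(se[0]),
        )
        for k in range(K)
    ]
    intercept = MREstimate(
        method="mvmr_egger_intercept", exposure="(intercept)", outcome=h.outcome,
        beta=float(coef[0]), se=float(se[0]), nsnp=L, scale=h.outcome_scale,
    )
    return slopes, intercept
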
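"""GWAS on the synthetic cohort and genetic instrument construction.

Per-SNP association is estimated by ordinary least squares (quantitative
traits) or linear-probability OLS (binary family-history outcomes); the
latter can be rescaled to log-odds with the standard mu*(1-mu) factor.
Instruments are selected by greedy LD clumping against a reference panel,
with strength summarised by the mean F-statistic (univariable) and a
conditional F-statistic (multivariable).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SCALES = ("sd-units", "log-odds", "years", "linear-probability")

SUMMARY_COLUMNS = (
    "SNP",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass
class SummaryStats:
    """One GWAS result set: a table of per-SNP effects plus trait metadata."""

    table: pd.DataFrame
    trait: str
    scale: str = "sd-units"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown trait scale {self.scale!r}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        t = self.table
        if t["SNP"].duplicated().any():
            dupes = t.loc[t["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate SNP ids: {dupes[:5]}")
        if (t["se"] <= 0).any():
            raise ValueError("all standard errors must be > 0")
        pv = t["pval"].to_numpy(dtype=float)
        if (pv <= 0).any() or (pv > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        eaf = t["eaf"].to_numpy(dtype=float)
        bad = ~np.isnan(eaf) & ((eaf <= 0) | (eaf >= 1))
        if bad.any():
            raise ValueError("eaf must lie in (0, 1) or be missing")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ReferencePanel:
    """Genotype dosages used only to compute between-SNP r^2 for clumping."""

    dosage: np.ndarray  # individuals x SNPs
    snp_ids: Sequence[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if self.dosage.shape[1] != len(self._index):
            raise ValueError("dosage columns must match snp_ids")

    @classmethod
    def from_cohort(cls, cohort, role: str = "offspring", n_individuals: int | None = None,
                    rng: np.random.Generator | None = None) -> "ReferencePanel":
        dos = cohort.dosages(role).astype(float)
        if n_individuals is not None and n_individuals < dos.shape[0]:
            if rng is None:
                raise ValueError("rng required to subsample the panel")
            rows = rng.choice(dos.shape[0], size=n_individuals, replace=False)
            dos = dos[rows]
        return cls(dosage=dos, snp_ids=list(cohort.snp_meta["SNP"]))

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def r2(self, snp_a: str, snp_b: str) -> float:
        a = self.dosage[:, self._index[snp_a]]
        b = self.dosage[:, self._index[snp_b]]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        r = float(np.corrcoef(a, b)[0, 1])
        return r * r


@dataclass
class InstrumentSet:
    """A clumped SNP list with per-trait effects and strength diagnostics."""

    snps: pd.DataFrame  # SNP chr pos effect_allele other_allele eaf
    beta: np.ndarray  # L x K
    se: np.ndarray
    pval: np.ndarray
    n: np.ndarray
    traits: list[str]
    scales: list[str]
    p_thresh: float
    r2_thresh: float
    window_bp: int

    def __len__(self) -> int:
        return len(self.snps)

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in instrument set") from None

    def summary_stats(self, trait: str) -> SummaryStats:
        k = self.trait_index(trait)
        t = self.snps.copy()
        t["beta"] = self.beta[:, k]
        t["se"] = self.se[:, k]
        t["pval"] = self.pval[:, k]
        t["n"] = self.n[:, k]
        return SummaryStats(table=t[list(SUMMARY_COLUMNS)], trait=trait, scale=self.scales[k])


# ---------------------------------------------------------------------------
# trait normalisation
# ---------------------------------------------------------------------------


def inverse_rank_normalise(values: np.ndarray) -> np.ndarray:
    """Blom-offset inverse rank-normal transform.

    Maps value of rank ``r`` among ``n`` to ``Phi^-1((r - 3/8)/(n + 1/4))``,
    with average ranks for ties.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# per-SNP association
# ---------------------------------------------------------------------------


def _ols_scan(
    dosages: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP OLS of trait on dosage + covariates via residualisation.

    Returns (beta, se, pval, keep_mask); monomorphic SNPs are masked out.
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(trait, dtype=float)
    n, n_snps = x.shape
    if y.shape != (n,):
        raise ValueError("trait length must match dosage rows")
    z = np.ones((n, 1))
    if covariates is not None:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariate rows must match dosage rows")
        z = np.hstack([z, c])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("covariate matrix is rank deficient (duplicate column?)")
    keep = x.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} monomorphic SNP(s) from GWAS", stacklevel=3)
    q, _ = np.linalg.qr(z)
    y_r = y - q @ (q.T @ y)
    x_r = x[:, keep] - q @ (q.T @ x[:, keep])
    sxx = np.einsum("ij,ij->j", x_r, x_r)
    sxy = x_r.T @ y_r
    beta = sxy / sxx
    dof = n - z.shape[1] - 1
    if dof <= 0:
        raise ValueError("not enough observations for the model")
    rss = float(y_r @ y_r) - beta * sxy
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    pval = np.clip(2.0 * stats.t.sf(np.abs(tval), dof), 1e-300, 1.0)
    return beta, se, pval, keep


def _assemble(snp_meta: pd.DataFrame, keep: np.ndarray, eaf: np.ndarray,
              beta: np.ndarray, se: np.ndarray, pval: np.ndarray, n: int) -> pd.DataFrame:
    t = snp_meta.loc[keep, ["SNP", "chr", "pos", "effect_allele", "other_allele"]].copy()
    t["eaf"] = eaf[keep]
    t["beta"] = beta
    t["se"] = se
    t["pval"] = pval
    t["n"] = n
    return t.reset_index(drop=True)


def run_gwas_quantitative(
    dosages: np.ndarray,
    trait: np.ndarray,
    snp_meta: pd.DataFrame,
    covariates: np.ndarray | None = None,
    trait_label: str = "trait",
    scale: str = "sd-units",
) -> SummaryStats:
    """OLS association scan for a continuous (typically rank-normalised) trait."""
    beta, se, pval, keep = _ols_scan(dosages, trait, covariates)
    eaf = np.asarray(dosages, float).mean(axis=0) / 2.0
    table = _assemble(snp_meta, keep, eaf, beta, se, pval, len(trait))
    return SummaryStats(table=table, trait=trait_label, scale=scale)


def run_gwas_binary(
    dosages: np.ndarray,
    status: np.ndarray,
    snp_meta: pd.DataFrame,
    covariates: np.ndarray | None = None,
    trait_label: str = "disease",
    min_count: int = 10,
) -> SummaryStats:
    """Linear-probability OLS scan for a 0/1 outcome."""
    s = np.asarray(status)
    uniq = set(np.unique(s).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("status must be coded 0/1")
    n_case = int(s.sum())
    n_ctrl = int(s.size - n_case)
    if n_case < min_count or n_ctrl < min_count:
        raise ValueError(f"need >= {min_count} cases and controls (got {n_case}/{n_ctrl})")
    beta, se, pval, keep = _ols_scan(dosages, s.astype(float), covariates)
    eaf = np.asarray(dosages, float).mean(axis=0) / 2.0
    table = _assemble(snp_meta, keep, eaf, beta, se, pval, s.size)
    return SummaryStats(
        table=table, trait=trait_label, scale="linear-probability",
        case_fraction=n_case / s.size,
    )


def linear_to_logodds(stats_in: SummaryStats, case_fraction: float | None = None) -> SummaryStats:
    """Rescale linear-probability effects to approximate log-odds by dividing
    beta and se by mu*(1-mu), where mu is the case fraction."""
    if stats_in.scale != "linear-probability":
        raise ValueError("input must be on the linear-probability scale")
    mu = stats_in.case_fraction if case_fraction is None else case_fraction
    if mu is None or not 0.0 < mu < 1.0:
        raise ValueError("case_fraction must be in (0, 1)")
    factor = mu * (1.0 - mu)
    t = stats_in.table.copy()
    t["beta"] = t["beta"] / factor
    t["se"] = t["se"] / factor
    return SummaryStats(table=t, trait=stats_in.trait, scale="log-odds", case_fraction=mu)


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------


def _greedy_clump(
    candidates: pd.DataFrame,
    panel: ReferencePanel,
    r2_thresh: float,
    window_bp: int,
) -> list[str]:
    """Greedy index-SNP selection: ascending p (ties: chr then pos); accept a
    SNP unless an accepted SNP on the same chromosome within the window has
    panel r^2 >= threshold."""
    ordered = candidates.sort_values(["pval", "chr", "pos"], kind="mergesort")
    accepted: list[tuple[str, int, int]] = []
    for row in ordered.itertuples():
        ok = True
        for snp, chrom, pos in accepted:
            if chrom == row.chr and abs(pos - row.pos) <= window_bp:
                if panel.r2(snp, row.SNP) >= r2_thresh:
                    ok = False
                    break
        if ok:
            accepted.append((row.SNP, row.chr, row.pos))
    return [snp for snp, _, _ in accepted]


def _build_instrument_set(
    frames: list[pd.DataFrame],
    traits: list[str],
    scales: list[str],
    keep_ids: list[str],
    p_thresh: float,
    r2_thresh: float,
    window_bp: int,
) -> InstrumentSet:
    base = frames[0].set_index("SNP").loc[keep_ids]
    snps = base[["chr", "pos", "effect_allele", "other_allele", "eaf"]].reset_index()
    cols = {}
    for name in ("beta", "se", "pval", "n"):
        cols[name] = np.column_stack(
            [f.set_index("SNP").loc[keep_ids, name].to_numpy(dtype=float) for f in frames]
        )
    return InstrumentSet(
        snps=snps, beta=cols["beta"], se=cols["se"], pval=cols["pval"], n=cols["n"],
        traits=traits, scales=scales, p_thresh=p_thresh, r2_thresh=r2_thresh,
        window_bp=window_bp,
    )


def ld_clump(
    stats_in: SummaryStats,
    panel: ReferencePanel,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Select independent genome-wide-significant index SNPs for one trait."""
    t = stats_in.table
    cand = t[t["pval"] < p_thresh]
    if cand.empty:
        warnings.warn(f"no SNP passes p < {p_thresh:g} for {stats_in.trait}; empty instrument set")
        keep: list[str] = []
    else:
        missing = [s for s in cand["SNP"] if s not in panel]
        if missing:
            raise ValueError(f"reference panel lacks candidate SNPs: {missing[:5]}")
        keep = _greedy_clump(cand, panel, r2_thresh, window_bp)
    return _build_instrument_set(
        [t], [stats_in.trait], [stats_in.scale], keep, p_thresh, r2_thresh, window_bp
    )


def multivariable_clump(
    stats_list: Sequence[SummaryStats],
    panel: ReferencePanel,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Pool several traits' GWAS results (min p per SNP) before clumping, so
    one mutually independent SNP list instruments all traits jointly."""
    if len(stats_list) < 1:
        raise ValueError("need at least one summary-statistics set")
    shared = set(stats_list[0].table["SNP"])
    for s in stats_list[1:]:
        shared &= set(s.table["SNP"])
    if not shared:
        raise ValueError("summary-statistics sets have disjoint SNP universes")
    frames = [s.table[s.table["SNP"].isin(shared)].reset_index(drop=True) for s in stats_list]
    min_p = np.min(
        np.column_stack(
            [f.set_index("SNP").loc[sorted(shared), "pval"].to_numpy(float) for f in frames]
        ),
        axis=1,
    )
    pooled = frames[0].set_index("SNP").loc[sorted(shared)].reset_index()
    pooled["pval"] = min_p
    cand = pooled[pooled["pval"] < p_thresh]
    if cand.empty:
        warnings.warn(f"no SNP passes p < {p_thresh:g} in any trait; empty instrument set")
        keep: list[str] = []
    else:
        missing = [s for s in cand["SNP"] if s not in panel]
        if missing:
            raise ValueError(f"reference panel lacks candidate SNPs: {missing[:5]}")
        keep = _greedy_clump(cand, panel, r2_thresh, window_bp)
    return _build_instrument_set(
        frames,
        [s.trait for s in stats_list],
        [s.scale for s in stats_list],
        keep,
        p_thresh,
        r2_thresh,
        window_bp,
    )


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------


def mean_f_statistic(instrument: InstrumentSet, trait: str) -> float:
    """Mean of per-SNP squared z-scores, F = (1/L) sum (beta/se)^2."""
    if len(instrument) < 1:
        raise ValueError("empty instrument set")
    k = instrument.trait_index(trait)
    z = instrument.beta[:, k] / instrument.se[:, k]
    return float(np.mean(z**2))


def conditional_f_statistic(instrument: InstrumentSet, trait: str) -> float:
    """Conditional instrument strength of one exposure given the others.

    Weighted least squares (weights 1/se^2 of the target trait, no
    intercept) of the target trait's SNP effects on the other traits' SNP
    effects; the weighted residual sum of squares Q is scaled as
    F = Q / (L - K + 1). A target collinear with the other exposures gives
    F ~ 0 rather than an error.

    The cross-trait sampling covariance of the SNP effects is assumed zero
    (effects estimated in non-overlapping or summary-level data).
    """
    k = instrument.trait_index(trait)
    L, K = instrument.beta.shape
    if K < 2:
        raise ValueError("conditional F requires >= 2 exposures")
    if L <= K:
        raise ValueError("conditional F requires more SNPs than exposures")
    bt = instrument.beta[:, k]
    others = np.delete(instrument.beta, k, axis=1)
    w = 1.0 / instrument.se[:, k] ** 2
    sw = np.sqrt(w)
    delta, *_ = np.linalg.lstsq(others * sw[:, None], bt * sw, rcond=None)
    resid = sw * (bt - others @ delta)
    q = float(resid @ resid)
    return q / (L - K + 1)


# ---------------------------------------------------------------------------
# region exclusion
# ---------------------------------------------------------------------------


def region_exclude(obj, chrom: int, start_bp: int, end_bp: int):
    """Remove SNPs with 1-based position inside [start_bp, end_bp] on chrom.

    Accepts a SummaryStats or InstrumentSet and returns the same type.
    """
    if start_bp > end_bp:
        raise ValueError("inverted interval: start_bp > end_bp")
    if isinstance(obj, SummaryStats):
        t = obj.table
        inside = (t["chr"] == chrom) & (t["pos"] >= start_bp) & (t["pos"] <= end_bp)
        if inside.all():
            warnings.warn("region exclusion removed every SNP")
        return replace(obj, table=t[~inside].reset_index(drop=True))
    if isinstance(obj, InstrumentSet):
        t = obj.snps
        inside = ((t["chr"] == chrom) & (t["pos"] >= start_bp) & (t["pos"] <= end_bp)).to_numpy()
        if inside.all() and len(t):
            warnings.warn("region exclusion removed every SNP")
        keep = ~inside
        return replace(
            obj,
            snps=t[keep].reset_index(drop=True),
            beta=obj.beta[keep],
            se=obj.se[keep],
            pval=obj.pval[keep],
            n=obj.n[keep],
        )
    raise TypeError("region_exclude expects SummaryStats or InstrumentSet")
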
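"""Family-structured genotype and phenotype simulation.

Generates nuclear families -- father, mother, one genotyped index offspring
and a variable number of siblings -- with Mendelian transmission of parental
haplotypes, three correlated quantitative lipid-like traits on any family
member, liability-threshold diseases and a linear lifespan model in
relatives, and self-report misclassification of family history.

The simulated structure mirrors the design of family-proxy ("GWAS-by-proxy")
studies: exposures are measured on the index offspring while outcomes occur
in relatives who share half their alleles with the index individual, which
dilutes per-allele outcome effects by an expected factor of two.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream

ROLES = ("father", "mother", "offspring", "sibling")

TRAITS = ("apoB", "LDL", "TG")

#: physical-scale labels for 1 SD of each standardised trait
TRAIT_SD_LABELS = {"apoB": "0.24 g/L", "LDL": "SD units", "TG": "SD units"}

_DEFAULT_SIBLING_DIST = {0: 0.25, 1: 0.40, 2: 0.25, 3: 0.10}

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# configuration / model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the genotype simulation.

    ``ld_block_size`` SNPs form one linkage block; within a block adjacent
    haplotype alleles are identical with probability ``ld_rho`` (an
    autoregressive copying scheme), giving adjacent-allele correlation equal
    to ``ld_rho``. Blocks are mutually independent.
    """

    n_families: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_siblings_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_SIBLING_DIST)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        dist = dict(self.n_siblings_dist)
        if not set(dist) <= {0, 1, 2, 3}:
            raise ValueError("sibling counts must be in {0, 1, 2, 3}")
        probs = np.array(list(dist.values()), dtype=float)
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("sibling count probabilities must be >= 0 and sum to 1")


@dataclass
class TrioCohort:
    """Dosage matrices (individuals x SNPs, entries 0/1/2) for each role.

    ``sibling`` stacks all siblings across families; ``sibling_family`` maps
    each sibling row to its family index.
    """

    father: np.ndarray
    mother: np.ndarray
    offspring: np.ndarray
    sibling: np.ndarray
    sibling_family: np.ndarray
    snp_meta: pd.DataFrame  # SNP chr pos effect_allele other_allele maf
    offspring_sex: np.ndarray  # 0 = male, 1 = female
    offspring_age: np.ndarray

    @property
    def n_families(self) -> int:
        return self.father.shape[0]

    @property
    def n_snps(self) -> int:
        return self.father.shape[1]

    def dosages(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return getattr(self, "sibling" if role == "sibling" else role)

    def family_index(self, role: str) -> np.ndarray:
        """Family index of each row of ``dosages(role)``."""
        if role == "sibling":
            return self.sibling_family
        return np.arange(self.n_families)


@dataclass
class LipidEffectModel:
    """Per-allele genetic effects (SD units) for the three lipid traits.

    ``beta`` is (n_snps x 3) in trait order ``traits``. ``resid_corr`` is the
    correlation of the non-genetic residual across traits. ``shared_fraction``
    records the fraction of causal SNPs affecting all three traits.
    """

    beta: np.ndarray
    resid_corr: np.ndarray
    traits: tuple[str, ...] = TRAITS
    trait_sd_labels: Mapping[str, str] = field(default_factory=lambda: dict(TRAIT_SD_LABELS))
    shared_fraction: float = float("nan")

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        r = np.asarray(self.resid_corr, dtype=float)
        if r.shape != (len(self.traits),) * 2:
            raise ValueError("resid_corr shape must match number of traits")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("resid_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("resid_corr must be positive definite")
        self.resid_corr = r

    @classmethod
    def random(
        cls,
        mafs: np.ndarray,
        rng: np.random.Generator,
        h2: Sequence[float] = (0.10, 0.10, 0.10),
        n_causal: int | None = None,
        shared_fraction: float = 0.5,
        resid_corr: np.ndarray | None = None,
    ) -> "LipidEffectModel":
        """Draw a random effect model scaled to target per-trait heritability.

        Shared causal SNPs get the same raw effect for every trait (before
        per-trait scaling), inducing positive genetic correlation.
        """
        mafs = np.asarray(mafs, dtype=float)
        n_snps = mafs.size
        k = len(TRAITS)
        if n_causal is None:
            n_causal = max(2, n_snps // 2)
        if not 0.0 <= shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if resid_corr is None:
            resid_corr = np.array(
                [[1.0, 0.85, 0.30], [0.85, 1.0, 0.25], [0.30, 0.25, 1.0]]
            )
        n_shared = int(round(shared_fraction * n_causal))
        order = rng.permutation(n_snps)
        shared = order[:n_shared]
        pool = order[n_shared:]
        raw = np.zeros((n_snps, k))
        z = rng.standard_normal(n_shared)
        raw[shared] = z[:, None]
        n_specific = n_causal - n_shared
        for t in range(k):
            if n_specific == 0:
                break
            take = pool[(t * n_specific) % max(len(pool), 1) :][:n_specific]
            if len(take) < n_specific:  # wrap if the pool is small
                take = np.concatenate([take, pool[: n_specific - len(take)]])
            raw[take, t] += rng.standard_normal(len(take))
        var_per_allele = 2.0 * mafs * (1.0 - mafs)
        beta = np.zeros_like(raw)
        for t in range(k):
            vg = float(var_per_allele @ raw[:, t] ** 2)
            if vg > 0:
                beta[:, t] = raw[:, t] * math.sqrt(h2[t] / vg)
        return cls(beta=beta, resid_corr=np.asarray(resid_corr, float), shared_fraction=shared_fraction)

    def trait_covariance(self, mafs: np.ndarray) -> np.ndarray:
        """Model-implied covariance of the (approximately unit-variance) traits."""
        var_per_allele = 2.0 * np.asarray(mafs, float) * (1.0 - np.asarray(mafs, float))
        g_cov = self.beta.T @ (self.beta * var_per_allele[:, None])
        resid_sd = np.sqrt(np.clip(1.0 - np.diag(g_cov), 0.05, None))
        return g_cov + np.outer(resid_sd, resid_sd) * self.resid_corr


@dataclass(frozen=True)
class DiseaseSpec:
    """One liability-threshold disease.

    ``liability = weights . traits + env_sd * N(0,1)``; affected when the
    liability exceeds ``threshold``. When built with :meth:`from_prevalence`
    the liability has unit variance so the prevalence equals the upper-tail
    normal probability of the threshold.
    """

    name: str
    weights: tuple[float, float, float]
    env_sd: float
    threshold: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("liability threshold must be finite")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")

    @classmethod
    def from_prevalence(
        cls,
        name: str,
        weights: Sequence[float],
        prevalence: float,
        trait_cov: np.ndarray | None = None,
    ) -> "DiseaseSpec":
        if not 0.0 < prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        w = np.asarray(weights, dtype=float)
        cov = np.eye(w.size) if trait_cov is None else np.asarray(trait_cov, float)
        var_g = float(w @ cov @ w)
        if var_g >= 1.0:
            raise ValueError("liability weights explain >= 100% of unit liability variance")
        env_sd = math.sqrt(1.0 - var_g)
        threshold = float(stats.norm.isf(prevalence))
        return cls(name=name, weights=tuple(w), env_sd=env_sd, threshold=threshold)


@dataclass(frozen=True)
class LifespanModel:
    """Death age = baseline - sum(years-lost coefficient x trait) + noise.

    A relative is recorded alive when their simulated death age exceeds
    ``censor_age`` (a fixed parental age at study entry).
    """

    baseline_years: float = 73.0
    years_lost: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 12.0
    censor_age: float = 60.0


@dataclass
class DiseaseModel:
    diseases: dict[str, DiseaseSpec]
    lifespan: LifespanModel = field(default_factory=LifespanModel)


@dataclass(frozen=True)
class FamilyReportModel:
    """Self-report misclassification of relatives' disease status.

    ``sensitivity``/``specificity`` may be a scalar applied to every disease
    or a per-disease mapping. Siblings are collapsed to a single any-affected
    indicator per family.
    """

    sensitivity: float | Mapping[str, float] = 1.0
    specificity: float | Mapping[str, float] = 1.0
    aggregate_siblings: bool = True

    def rate(self, which: str, disease: str) -> float:
        value = getattr(self, which)
        p = float(value[disease]) if isinstance(value, Mapping) else float(value)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{which} for {disease!r} must be in [0, 1]")
        return p


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


def _draw_haplotypes(
    n_hap: int,
    block_maf: np.ndarray,
    block_of: np.ndarray,
    ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype matrix (n_hap x n_snps) under block-AR copying LD."""
    n_snps = block_of.size
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    maf = block_maf[block_of]
    hap[:, 0] = rng.random(n_hap) < maf[0]
    for j in range(1, n_snps):
        fresh = rng.random(n_hap) < maf[j]
        if ld_rho > 0 and block_of[j] == block_of[j - 1]:
            copy = rng.random(n_hap) < ld_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        else:
            hap[:, j] = fresh
    return hap


def _transmit(
    hap1: np.ndarray,
    hap2: np.ndarray,
    block_of: np.ndarray,
    n_blocks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row: a whole haplotype per block (free recombination
    between blocks, none within)."""
    sel = rng.integers(0, 2, size=(hap1.shape[0], n_blocks))[:, block_of]
    return np.where(sel == 0, hap1, hap2)


def simulate_trios(config: SimConfig) -> TrioCohort:
    """Simulate parental genotypes under Hardy-Weinberg with block LD and
    build each child from one transmitted haplotype per parent."""
    rng = substream(config.seed, "simulate")
    n_fam, n_snps = config.n_families, config.n_snps
    bs = config.ld_block_size
    n_blocks = math.ceil(n_snps / bs)
    block_of = np.repeat(np.arange(n_blocks), bs)[:n_snps]
    block_maf = rng.uniform(*config.maf_range, size=n_blocks)

    fh1 = _draw_haplotypes(n_fam, block_maf, block_of, config.ld_rho, rng)
    fh2 = _draw_haplotypes(n_fam, block_maf, block_of, config.ld_rho, rng)
    mh1 = _draw_haplotypes(n_fam, block_maf, block_of, config.ld_rho, rng)
    mh2 = _draw_haplotypes(n_fam, block_maf, block_of, config.ld_rho, rng)

    off_pat = _transmit(fh1, fh2, block_of, n_blocks, rng)
    off_mat = _transmit(mh1, mh2, block_of, n_blocks, rng)

    counts = np.array(sorted(config.n_siblings_dist), dtype=int)
    probs = np.array([config.n_siblings_dist[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    n_sib_per_family = rng.choice(counts, size=n_fam, p=probs)
    sibling_family = np.repeat(np.arange(n_fam), n_sib_per_family)
    sib_pat = _transmit(fh1[sibling_family], fh2[sibling_family], block_of, n_blocks, rng)
    sib_mat = _transmit(mh1[sibling_family], mh2[sibling_family], block_of, n_blocks, rng)

    # SNP map: blocks tile chromosomes 1..22; blocks on the same chromosome
    # sit >= 3 Mb apart so only within-block pairs fall inside a 1 Mb window.
    chrom = block_of % 22 + 1
    block_start = block_of * bs
    within = np.arange(n_snps) - block_start
    pos = 1 + (block_of // 22) * 3_000_000 + within * 10_000
    a1_idx = rng.integers(0, 4, size=n_snps)
    shift = rng.integers(1, 4, size=n_snps)
    a2_idx = (a1_idx + shift) % 4
    snp_meta = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "chr": chrom.astype(int),
            "pos": pos.astype(int),
            "effect_allele": _BASES[a1_idx],
            "other_allele": _BASES[a2_idx],
            "maf": block_maf[block_of],
        }
    )

    return TrioCohort(
        father=(fh1 + fh2).astype(np.int8),
        mother=(mh1 + mh2).astype(np.int8),
        offspring=(off_pat + off_mat).astype(np.int8),
        sibling=(sib_pat + sib_mat).astype(np.int8),
        sibling_family=sibling_family,
        snp_meta=snp_meta,
        offspring_sex=rng.integers(0, 2, size=n_fam).astype(np.int8),
        offspring_age=np.round(rng.uniform(40.0, 70.0, size=n_fam), 1),
    )


def mendelian_consistent(cohort: TrioCohort) -> np.ndarray:
    """Boolean (individuals x SNPs) matrix: child dosage achievable from one
    allele per parent. Checked for offspring and siblings jointly."""
    checks = []
    for role in ("offspring", "sibling"):
        child = cohort.dosages(role)
        fam = cohort.family_index(role)
        f, m = cohort.father[fam], cohort.mother[fam]
        lower = (f == 2).astype(int) + (m == 2).astype(int)
        upper = 2 - (f == 0).astype(int) - (m == 0).astype(int)
        checks.append((child >= lower) & (child <= upper))
    return np.vstack(checks)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def genetic_values(cohort: TrioCohort, model: LipidEffectModel, role: str) -> np.ndarray:
    """True genetic score (n x K) for the given role."""
    dos = cohort.dosages(role).astype(float)
    if dos.shape[1] != model.beta.shape[0]:
        raise ValueError("effect vectors do not match the cohort's SNP count")
    return dos @ model.beta


def simulate_lipids(
    cohort: TrioCohort,
    model: LipidEffectModel,
    role: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardised trait matrix (n x K): genetic value plus correlated
    Gaussian residual, scaled to mean 0 / SD 1 per trait."""
    g = genetic_values(cohort, model, role)
    n, k = g.shape
    var_g = g.var(axis=0) if n > 1 else np.zeros(k)
    resid_sd = np.sqrt(np.clip(1.0 - var_g, 0.05, None))
    chol = np.linalg.cholesky(model.resid_corr)
    resid = rng.standard_normal((n, k)) @ chol.T * resid_sd
    y = g + resid
    sd = y.std(axis=0)
    sd[sd == 0] = 1.0
    return (y - y.mean(axis=0)) / sd


_META_COLUMNS = ("family", "role", "member", "death_age", "age_at_death", "alive")


def simulate_outcomes(
    cohort: TrioCohort,
    lipid_model: LipidEffectModel,
    disease_model: DiseaseModel,
    rng: np.random.Generator,
    roles: Sequence[str] = ("father", "mother", "sibling", "offspring"),
) -> pd.DataFrame:
    """Outcome table with one row per family member.

    Disease status is assigned from each relative's *own* genotype through
    the liability threshold; death age follows the lifespan model (parents
    and offspring; siblings get no vital information). Offspring rows carry
    their own outcomes so direct-design analyses can be run on the same
    simulation.
    """
    if not disease_model.diseases:
        raise ValueError("no diseases configured")
    frames = []
    life = disease_model.lifespan
    for role in roles:
        dos = cohort.dosages(role)
        n = dos.shape[0]
        if n == 0:
            continue
        traits = simulate_lipids(cohort, lipid_model, role, rng)
        rec: dict[str, np.ndarray] = {
            "family": cohort.family_index(role),
            "role": np.repeat(role, n),
            "member": (
                _sibling_member_index(cohort.sibling_family)
                if role == "sibling"
                else np.zeros(n, dtype=int)
            ),
        }
        for spec in disease_model.diseases.values():
            liab = traits @ np.asarray(spec.weights) + rng.normal(0.0, spec.env_sd, n)
            rec[spec.name] = (liab > spec.threshold).astype(int)
        if role in ("father", "mother", "offspring"):
            death = (
                life.baseline_years
                - traits @ np.asarray(life.years_lost)
                + rng.normal(0.0, life.noise_sd, n)
            )
            alive = death > life.censor_age
            rec["death_age"] = death
            rec["age_at_death"] = np.where(alive, np.nan, death)
            rec["alive"] = alive.astype(float)
        else:
            rec["death_age"] = np.full(n, np.nan)
            rec["age_at_death"] = np.full(n, np.nan)
            rec["alive"] = np.full(n, np.nan)
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True)
    ordered = [c for c in _META_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in _META_COLUMNS]
    return out[ordered[:3] + extra + ordered[3:]]


def _sibling_member_index(sibling_family: np.ndarray) -> np.ndarray:
    member = np.zeros(sibling_family.size, dtype=int)
    last = {}
    for i, fam in enumerate(sibling_family):
        member[i] = last.get(fam, 0)
        last[fam] = member[i] + 1
    return member


def disease_columns(outcomes: pd.DataFrame) -> list[str]:
    return [c for c in outcomes.columns if c not in _META_COLUMNS]


def apply_report_noise(
    outcomes: pd.DataFrame,
    report: FamilyReportModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Flip each true disease status with the per-disease sensitivity /
    specificity and collapse siblings to one any-affected row per family."""
    reported = outcomes.copy()
    for disease in disease_columns(outcomes):
        sens = report.rate("sensitivity", disease)
        spec = report.rate("specificity", disease)
        truth = outcomes[disease].to_numpy()
        p_report = np.where(truth == 1, sens, 1.0 - spec)
        reported[disease] = (rng.random(len(outcomes)) < p_report).astype(int)
    if report.aggregate_siblings:
        sib = reported[reported["role"] == "sibling"]
        rest = reported[reported["role"] != "sibling"]
        if len(sib):
            agg = sib.groupby("family", as_index=False)[disease_columns(outcomes)].max()
            agg.insert(1, "role", "sibling")
            agg.insert(2, "member", -1)
            for c in ("death_age", "age_at_death", "alive"):
                agg[c] = np.nan
            reported = pd.concat([rest, agg[rest.columns]], ignore_index=True)
        else:
            reported = rest.reset_index(drop=True)
    return reported
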
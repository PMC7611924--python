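import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from proxymr import LipidEffectModel, SimConfig, SummaryStats, simulate_trios
from proxymr._streams import substream

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_summary_stats(
    beta,
    se,
    snp=None,
    chrom=None,
    pos=None,
    ea=None,
    oa=None,
    eaf=None,
    pval=None,
    n=10_000,
    trait="trait",
    scale="sd-units",
):
    """Assemble a SummaryStats table from plain arrays (test helper)."""
    beta = np.asarray(beta, dtype=float)
    L = beta.size
    se = np.asarray(se, dtype=float)
    table = pd.DataFrame(
        {
            "SNP": snp if snp is not None else [f"rs{i + 1}" for i in range(L)],
            "chr": chrom if chrom is not None else np.arange(L) % 22 + 1,
            "pos": pos if pos is not None else np.arange(L) * 2_000_000 + 1,
            "effect_allele": ea if ea is not None else ["A"] * L,
            "other_allele": oa if oa is not None else ["C"] * L,
            "eaf": eaf if eaf is not None else np.full(L, 0.3),
            "beta": beta,
            "se": se,
            "pval": pval if pval is not None else np.full(L, 0.5),
            "n": n,
        }
    )
    return SummaryStats(table=table, trait=trait, scale=scale)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_trios(SimConfig(n_families=800, n_snps=40, maf_range=(0.1, 0.5), seed=11))


@pytest.fixture(scope="session")
def lipid_model(small_cohort):
    return LipidEffectModel.random(
        small_cohort.snp_meta["maf"].to_numpy(),
        substream(11, "model"),
        h2=(0.3, 0.3, 0.25),
        n_causal=10,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
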
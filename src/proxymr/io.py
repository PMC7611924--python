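"""Plain-text file formats: summary-statistics TSV, genotype dosage text,
phenotype TSV and deterministic results tables."""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import TrioCohort
from .instruments import SUMMARY_COLUMNS, ReferencePanel, SummaryStats

SUMMARY_HEADER = list(SUMMARY_COLUMNS) + ["trait", "scale"]


def write_summary_stats(ss: SummaryStats, path: str | os.PathLike) -> None:
    t = ss.table.copy()
    t["trait"] = ss.trait
    t["scale"] = ss.scale
    t = t[SUMMARY_HEADER]
    t["eaf"] = t["eaf"].map(lambda v: "." if pd.isna(v) else f"{v:.6g}")
    t.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_summary_stats(path: str | os.PathLike) -> SummaryStats:
    """Read and validate a summary-statistics TSV.

    '.' marks a missing effect-allele frequency. Validation errors name the
    offending (1-based, header-inclusive) file line.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_HEADER if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    t = raw.copy()
    t["eaf"] = t["eaf"].replace(".", np.nan)
    for col in ("pos", "n"):
        t[col] = pd.to_numeric(t[col], errors="coerce").astype("Int64")
    t["chr"] = pd.to_numeric(t["chr"], errors="coerce").astype("Int64")
    for col in ("eaf", "beta", "se", "pval"):
        t[col] = pd.to_numeric(t[col], errors="coerce")
    for i, row in t.iterrows():
        line = i + 2  # header occupies line 1
        for col in ("beta", "se", "pval"):
            if pd.isna(row[col]):
                raise ValueError(f"{path} line {line}: non-numeric or missing {col}")
        if row["se"] <= 0:
            raise ValueError(f"{path} line {line}: se must be > 0 (got {row['se']})")
    traits = t["trait"].unique()
    scales = t["scale"].unique()
    if len(traits) != 1 or len(scales) != 1:
        raise ValueError(f"{path}: trait/scale columns must be constant")
    t["chr"] = t["chr"].astype(int)
    t["pos"] = t["pos"].astype(int)
    t["n"] = t["n"].astype(int)
    return SummaryStats(
        table=t[list(SUMMARY_COLUMNS)].reset_index(drop=True),
        trait=str(traits[0]),
        scale=str(scales[0]),
    )


# ---------------------------------------------------------------------------
# cohort persistence
# ---------------------------------------------------------------------------


def _individual_ids(cohort: TrioCohort) -> list[str]:
    ids = []
    for role in ("father", "mother", "offspring"):
        ids += [f"f{i}_{role}" for i in range(cohort.n_families)]
    member = {}
    for fam in cohort.sibling_family:
        member[fam] = member.get(fam, 0) + 1
        ids.append(f"f{fam}_sib{member[fam]}")
    return ids


def save_cohort_genotypes(cohort: TrioCohort, prefix: str | os.PathLike) -> None:
    """Transposed dosage text (rows = SNPs, cols = individuals) + SNP meta TSV."""
    prefix = str(prefix)
    dos = np.vstack([cohort.father, cohort.mother, cohort.offspring, cohort.sibling]).T
    frame = pd.DataFrame(dos, columns=_individual_ids(cohort))
    frame.insert(0, "SNP", cohort.snp_meta["SNP"])
    frame.to_csv(prefix + ".dosage.tsv", sep="\t", index=False)
    cohort.snp_meta.to_csv(prefix + ".snps.tsv", sep="\t", index=False, float_format="%.6g")


def load_reference_panel(prefix: str | os.PathLike) -> ReferencePanel:
    frame = pd.read_csv(str(prefix) + ".dosage.tsv", sep="\t")
    snps = frame.pop("SNP").tolist()
    return ReferencePanel(dosage=frame.to_numpy(dtype=float).T, snp_ids=snps)


def write_phenotypes(outcomes: pd.DataFrame, traits: pd.DataFrame | None,
                     path: str | os.PathLike) -> None:
    """Phenotype TSV: family id, role, trait values (index offspring only),
    outcome indicators, death age and vital status."""
    table = outcomes.copy()
    if traits is not None:
        table = table.merge(traits, how="left", left_on=["family", "role"],
                            right_on=["family", "role"])
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------


def write_results(tables: dict[str, pd.DataFrame], outdir: str | os.PathLike) -> list[Path]:
    """Write each table as ``<outdir>/<name>.tsv`` with a deterministic row
    sort and fixed 6-significant-digit float formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        out = df.copy()
        sort_cols = [c for c in out.columns if out[c].dtype == object]
        if sort_cols and len(out):
            out = out.sort_values(sort_cols, kind="mergesort")
        path = outdir / f"{name}.tsv"
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    return written
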
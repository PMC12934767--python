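"""Per-sample ASAS calling.

A heterozygous SNP inside an alternatively spliced region shows allele-specific
splicing when its allelic read ratio departs from the gene's constitutive
background in the same sample. The caller compares, per (SNP, event) pair, the
(ref, alt) counts at the target SNP against the haplotype-aggregated counts
over phased heterozygous constitutive SNPs of the same gene with a two-sided
Fisher's exact test, then applies Benjamini-Hochberg FDR within the sample.
Significant SNPs are designated *tag SNPs*. Events in HLA genes are removed
because of the genes' extreme polymorphism.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ALTERNATIVE, CONSTITUTIVE, GenotypeMatrix

__all__ = [
    "allelic_ratio",
    "annotate_phase",
    "call_asas_per_sample",
    "call_asas",
    "filter_hla",
    "default_hla_genes",
    "summarize_events",
]

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "sample_id",
    "snp_id",
    "event_id",
    "gene_id",
    "ratio_alt",
    "ratio_const",
    "p",
    "fdr",
    "significant",
    "reason_code",
]

# reason codes for untestable records
OK = ""
NO_CONSTITUTIVE = "NO_CONSTITUTIVE"
LOW_COVERAGE = "LOW_COVERAGE"


def allelic_ratio(ref_count: int, alt_count: int) -> float:
    """Reference-allele read fraction R = ref / (ref + alt)."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        raise ValueError("SNP untestable: zero total coverage")
    return ref_count / total


def annotate_phase(counts: pd.DataFrame, genotypes: GenotypeMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Attach het/phase columns to a count table from the phased genotypes.

    Adds ``het`` (bool) and ``phase`` in {REF_ON_H1, ALT_ON_H1, UNPHASED}.
    """
    ind_of_sample = metadata.set_index("sample_id")["individual_id"]
    out = counts.copy()
    inds = out["sample_id"].map(ind_of_sample)
    code = np.full(len(out), -1, dtype=np.int8)
    known = out["snp_id"].isin(genotypes.codes.columns).to_numpy()
    if known.any():
        sub = out.loc[known]
        # fancy-index the code matrix once
        row_idx = genotypes.codes.index.get_indexer(inds[known])
        col_idx = genotypes.codes.columns.get_indexer(sub["snp_id"])
        mat = genotypes.codes.to_numpy()
        code[known] = mat[row_idx, col_idx]
    out["genotype_code"] = code
    out["het"] = (code == GenotypeMatrix.HET_01) | (code == GenotypeMatrix.HET_10)
    out["phase"] = np.select(
        [code == GenotypeMatrix.HET_01, code == GenotypeMatrix.HET_10],
        ["REF_ON_H1", "ALT_ON_H1"],
        default="UNPHASED",
    )
    return out


def call_asas_per_sample(
    sample_counts: pd.DataFrame,
    min_coverage: int = 20,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """ASAS calls for one sample.

    ``sample_counts`` must carry ``het`` and ``phase`` columns (see
    :func:`annotate_phase`). Returns one row per candidate (SNP, event) pair;
    untestable candidates get a reason code instead of a p-value.
    """
    rows = []
    for gene_id, gdf in sample_counts.groupby("gene_id", sort=True):
        const = gdf[(gdf["region_class"] == CONSTITUTIVE) & gdf["het"] & (gdf["phase"] != "UNPHASED")]
        const = const[(const["ref_count"] + const["alt_count"]) > 0]
        h1 = int(
            const.loc[const["phase"] == "REF_ON_H1", "ref_count"].sum()
            + const.loc[const["phase"] == "ALT_ON_H1", "alt_count"].sum()
        )
        h2 = int(
            const.loc[const["phase"] == "REF_ON_H1", "alt_count"].sum()
            + const.loc[const["phase"] == "ALT_ON_H1", "ref_count"].sum()
        )
        have_const = len(const) > 0 and (h1 + h2) > 0
        ratio_const = h1 / (h1 + h2) if have_const else np.nan

        alt = gdf[(gdf["region_class"] == ALTERNATIVE) & gdf["het"]]
        for _, row in alt.iterrows():
            total = int(row["ref_count"] + row["alt_count"])
            base = {
                "sample_id": row["sample_id"],
                "snp_id": row["snp_id"],
                "event_id": row["event_id"],
                "gene_id": gene_id,
                "ratio_alt": np.nan,
                "ratio_const": ratio_const,
                "p": np.nan,
                "fdr": np.nan,
                "significant": False,
                "reason_code": OK,
            }
            if total < min_coverage:
                base["reason_code"] = LOW_COVERAGE
                if total > 0:
                    base["ratio_alt"] = allelic_ratio(int(row["ref_count"]), int(row["alt_count"]))
                rows.append(base)
                continue
            base["ratio_alt"] = allelic_ratio(int(row["ref_count"]), int(row["alt_count"]))
            if not have_const:
                base["reason_code"] = NO_CONSTITUTIVE
                rows.append(base)
                continue
            table = [[int(row["ref_count"]), int(row["alt_count"])], [h1, h2]]
            base["p"] = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append(base)

    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    tested = calls["p"].notna()
    if tested.any():
        fdr = multipletests(calls.loc[tested, "p"].to_numpy(), method="fdr_bh")[1]
        calls.loc[tested, "fdr"] = fdr
        calls.loc[tested, "significant"] = calls.loc[tested, "fdr"] <= fdr_threshold
    return calls


def call_asas(
    counts: pd.DataFrame,
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    min_coverage: int = 20,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """ASAS calls for every sample in the cohort (concatenated)."""
    annotated = annotate_phase(counts, genotypes, metadata)
    out = []
    for _, sdf in annotated.groupby("sample_id", sort=True):
        calls = call_asas_per_sample(sdf, min_coverage=min_coverage, fdr_threshold=fdr_threshold)
        if len(calls):
            out.append(calls)
    return (
        pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=CALL_COLUMNS)
    )


def default_hla_genes() -> set[str]:
    """Bundled HLA gene symbols (classical class I/II loci and paralogs)."""
    text = resources.files("asaskit.data").joinpath("hla_genes.txt").read_text()
    return {line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")}


def filter_hla(calls: pd.DataFrame, hla_gene_list: set[str] | None = None) -> pd.DataFrame:
    """Drop calls in HLA genes; logs the number removed."""
    genes = default_hla_genes() if hla_gene_list is None else set(hla_gene_list)
    mask = calls["gene_id"].isin(genes)
    if mask.any():
        logger.info("filter_hla: removed %d calls in HLA genes", int(mask.sum()))
    return calls[~mask].reset_index(drop=True)


def summarize_events(calls: pd.DataFrame, events: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Cross-sample event summary.

    Returns per-region unique significant event sets, per-event sample tallies,
    and event-type proportions over significant events.
    """
    sig = calls[calls["significant"].astype(bool)]
    region_of_sample = metadata.set_index("sample_id")["region"]
    sig = sig.assign(region=sig["sample_id"].map(region_of_sample))
    region_sets = {
        region: set(rdf["event_id"].unique()) for region, rdf in sig.groupby("region")
    }
    per_event = (
        calls[calls["p"].notna()]
        .groupby("event_id")
        .agg(samples_tested=("sample_id", "nunique"))
        .join(sig.groupby("event_id").agg(samples_significant=("sample_id", "nunique")))
        .fillna({"samples_significant": 0})
        .astype({"samples_significant": int})
        .reset_index()
    )
    type_of_event = events.set_index("event_id")["type"]
    uniq = sorted(set(sig["event_id"]))
    type_counts = pd.Series([type_of_event.get(e) for e in uniq]).value_counts()
    total = int(type_counts.sum())
    type_props = {
        t: (int(type_counts.get(t, 0)) / total if total else 0.0)
        for t in ["SE", "RI", "A3SS", "A5SS"]
    }
    return {
        "region_event_sets": region_sets,
        "per_event": per_event,
        "type_proportions": type_props,
        "n_unique_significant_events": len(uniq),
    }
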
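"""mRNA-protein abundance concordance.

Per-gene Spearman correlation between RPKM expression and protein abundance
across shared samples; samples with an RPKM of 0 are removed per gene, genes
with fewer than ``min_pairs`` usable samples are untestable, and significance
is Benjamini-Hochberg FDR at 0.05. The correlated fraction of two gene groups
(e.g. genes with 5' UTR ASAS events vs other ASAS genes) is compared with a
two-sided Fisher's exact test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["mrna_protein_correlation", "correlated_fraction_test"]

CORR_COLUMNS = ["gene_id", "n_samples_used", "rho", "p", "fdr", "significant", "reason_code"]


def mrna_protein_correlation(
    expression: pd.DataFrame,
    protein: pd.DataFrame,
    min_pairs: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation per gene between expression and protein matrices.

    Both matrices are genes x samples; only shared genes and samples are used.
    """
    samples = [s for s in expression.columns if s in set(protein.columns)]
    genes = [g for g in expression.index if g in set(protein.index)]
    rows = []
    for g in genes:
        x = expression.loc[g, samples].to_numpy(dtype=float)
        y = protein.loc[g, samples].to_numpy(dtype=float)
        keep = (x != 0) & ~np.isnan(x) & ~np.isnan(y)
        n_used = int(keep.sum())
        row = {
            "gene_id": g,
            "n_samples_used": n_used,
            "rho": np.nan,
            "p": np.nan,
            "fdr": np.nan,
            "significant": False,
            "reason_code": "",
        }
        if n_used < min_pairs:
            row["reason_code"] = "TOO_FEW_PAIRS"
        else:
            rho, p = stats.spearmanr(x[keep], y[keep])
            row["rho"], row["p"] = float(rho), float(p)
        rows.append(row)
    out = pd.DataFrame(rows, columns=CORR_COLUMNS)
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"].to_numpy(), method="fdr_bh")[1]
        out.loc[tested, "significant"] = out.loc[tested, "fdr"] <= fdr_threshold
    return out


def correlated_fraction_test(
    group_a_genes: set,
    group_b_genes: set,
    correlations: pd.DataFrame,
) -> tuple[list[list[int]], float]:
    """Two-sided Fisher test on significant-correlation fractions of two gene groups."""
    tested = correlations[correlations["p"].notna()]
    a = tested[tested["gene_id"].isin(group_a_genes)]
    b = tested[tested["gene_id"].isin(group_b_genes)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain tested genes")
    a_sig = int(a["significant"].sum())
    b_sig = int(b["significant"].sum())
    table = [[a_sig, len(a) - a_sig], [b_sig, len(b) - b_sig]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p
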
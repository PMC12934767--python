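"""Differential allelic imbalance between disease groups.

Tag-SNP allelic counts are compared between AD and control samples with a
beta-binomial likelihood-ratio test (see :mod:`asaskit.betabinom`). A SNP is
testable in a region when it was called a tag SNP in at least 5 AD and 5
control samples; a difference is significant when the nominal LRT p-value is
<= 0.05 *and* the absolute difference in group mean allelic ratios is >= 0.1
— the effect-size filter substitutes for multiplicity correction, screening
out differences small enough to be experimental variability.

Counts are *folded* to the major allele per sample (k = max(ref, alt)) before
the group comparison. The reference/alternative orientation of an allelic
ratio is arbitrary with respect to the causal haplotype, which differs across
individuals; unfolded group means therefore collapse toward 0.5 in every
group and carry no imbalance signal. Folding compares the magnitude of
allelic imbalance between groups, which is the quantity the test is after.

Disease-specific functional SNPs are the set difference of the AD-mode and
control-mode concordance calls, restricted to candidates testable in both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .betabinom import bb_lrt

__all__ = ["differential_scan", "disease_specific_functional"]

DIFF_COLUMNS = [
    "region",
    "snp_id",
    "event_id",
    "gene_id",
    "n_ad",
    "n_control",
    "mean_ad",
    "mean_control",
    "delta",
    "lrt_stat",
    "p",
    "significant",
    "reason_code",
]


def differential_scan(
    tag_calls: pd.DataFrame,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    min_per_group: int = 5,
    delta_min: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Beta-binomial group test per (region, SNP, event).

    ``tag_calls`` supplies which samples designated the SNP a tag SNP;
    ``counts`` supplies the per-sample (ref, alt) counts entering the test,
    folded to the per-sample major allele. Group mean ratios are unweighted
    means of per-sample folded ratios.
    """
    meta = metadata.set_index("sample_id")
    sig = tag_calls[tag_calls["significant"].astype(bool)].copy()
    if sig.empty:
        return pd.DataFrame(columns=DIFF_COLUMNS)
    sig["region"] = sig["sample_id"].map(meta["region"])
    sig["group"] = sig["sample_id"].map(meta["group"])

    count_ix = counts.set_index(["sample_id", "snp_id"])
    rows = []
    for (region, snp_id, event_id), grp in sig.groupby(["region", "snp_id", "event_id"], sort=True):
        gene_id = grp["gene_id"].iloc[0]
        n_ad_tag = grp.loc[grp["group"] == "AD", "sample_id"].nunique()
        n_ct_tag = grp.loc[grp["group"] == "control", "sample_id"].nunique()
        row = {
            "region": region,
            "snp_id": snp_id,
            "event_id": event_id,
            "gene_id": gene_id,
            "n_ad": n_ad_tag,
            "n_control": n_ct_tag,
            "mean_ad": np.nan,
            "mean_control": np.nan,
            "delta": np.nan,
            "lrt_stat": np.nan,
            "p": np.nan,
            "significant": False,
            "reason_code": "",
        }
        if n_ad_tag < min_per_group or n_ct_tag < min_per_group:
            row["reason_code"] = "MIN_PER_GROUP"
            rows.append(row)
            continue

        def group_counts(g):
            out = []
            for sid in grp.loc[grp["group"] == g, "sample_id"].unique():
                try:
                    c = count_ix.loc[(sid, snp_id)]
                except KeyError:
                    continue
                if isinstance(c, pd.DataFrame):
                    c = c[c["event_id"] == event_id].iloc[0] if (c["event_id"] == event_id).any() else c.iloc[0]
                total = int(c["ref_count"] + c["alt_count"])
                if total > 0:
                    out.append((max(int(c["ref_count"]), int(c["alt_count"])), total))
            return out

        ad_counts = group_counts("AD")
        ct_counts = group_counts("control")
        if len(ad_counts) < 2 or len(ct_counts) < 2:
            row["reason_code"] = "TOO_FEW_COUNTS"
            rows.append(row)
            continue
        ad_arr = np.asarray(ad_counts, dtype=float)
        ct_arr = np.asarray(ct_counts, dtype=float)
        row["mean_ad"] = float(np.mean(ad_arr[:, 0] / ad_arr[:, 1]))
        row["mean_control"] = float(np.mean(ct_arr[:, 0] / ct_arr[:, 1]))
        row["delta"] = abs(row["mean_ad"] - row["mean_control"])
        stat, p = bb_lrt(ad_arr, ct_arr)
        row["lrt_stat"] = stat
        row["p"] = p
        row["significant"] = bool(p <= alpha and row["delta"] >= delta_min)
        rows.append(row)
    return pd.DataFrame(rows, columns=DIFF_COLUMNS)


def disease_specific_functional(
    calls_ad: pd.DataFrame,
    calls_control: pd.DataFrame,
    testable_ad: set | None = None,
    testable_control: set | None = None,
) -> dict[str, set]:
    """Partition functional-SNP calls into {both, AD_only, control_only}.

    Candidates are identified by (candidate_snp, event_id); the partition is
    restricted to candidates testable (i.e. tested) in both modes. Testable
    sets default to the candidates with a computed p-value in each table.
    """

    def key_set(df, only_significant):
        sub = df
        if only_significant:
            sub = df[df["significant"].astype(bool)]
        else:
            sub = df[df["p"].notna()]
        return set(zip(sub["candidate_snp"], sub["event_id"]))

    t_ad = testable_ad if testable_ad is not None else key_set(calls_ad, False)
    t_ct = testable_control if testable_control is not None else key_set(calls_control, False)
    universe = t_ad & t_ct
    sig_ad = key_set(calls_ad, True) & universe
    sig_ct = key_set(calls_control, True) & universe
    return {
        "both": sig_ad & sig_ct,
        "AD_only": sig_ad - sig_ct,
        "control_only": sig_ct - sig_ad,
        "testable_both": universe,
    }
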
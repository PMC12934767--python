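"""Concordance-based nomination of functional splicing SNPs.

A *functional* SNP is a cis variant whose genotype explains the allelic
imbalance observed at a tag SNP across individuals. For individual i, the
imbalance at the tag SNP is

    d_i = 0.5 - R_i,        R_i = ref_i / (ref_i + alt_i),

and the concordance score of a candidate SNP is

    S_i = d_i^2 / 0.5^2             if the candidate is heterozygous,
    S_i = 1 - d_i^2 / 0.5^2         if the candidate is homozygous.

A truly functional heterozygous candidate drives imbalance (|d_i| -> 0.5,
S_i -> 1) while a homozygous candidate leaves both haplotypes equivalent
(d_i -> 0, S_i -> 1), so concordant candidates score high under either
genotype. When the candidate *is* the tag SNP, the heterozygous branch is
used. Significance is assessed by permuting candidate genotype labels across
individuals and comparing the observed mean score to the permutation null
(one-sided, add-one pseudocount), with Benjamini-Hochberg FDR per mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng
from .cohort import ALTERNATIVE, GenotypeMatrix
from .detect import annotate_phase

__all__ = [
    "ConcordanceConfig",
    "imbalance",
    "concordance_score",
    "score_candidate",
    "testability_filter",
    "permutation_pvalue",
    "run_mode",
    "distance_to_exon",
    "distance_profile",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "mode",
    "candidate_snp",
    "tag_snp",
    "event_id",
    "gene_id",
    "n_het",
    "n_total",
    "mean_si",
    "p",
    "fdr",
    "significant",
    "distance_to_exon",
    "reason_code",
]


@dataclass(frozen=True)
class ConcordanceConfig:
    het_fraction: float = 0.10      # inclusive lower bound on het share
    sample_fraction: float = 0.10   # strict lower bound on usable share of cohort
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    min_stratum_size: int = 20
    min_tag_coverage: int = 20
    seed: int = 0


def imbalance(r_i: float) -> float:
    """Allelic imbalance d = 0.5 - R for a ratio R in [0, 1]."""
    if not 0.0 <= r_i <= 1.0:
        raise ValueError(f"ratio must be in [0, 1], got {r_i}")
    return 0.5 - r_i


def concordance_score(d_i: float, genotype: str) -> float:
    """Concordance score S for imbalance d and candidate genotype HET/HOM."""
    if abs(d_i) > 0.5 + 1e-12:
        raise ValueError(f"|d| must be <= 0.5, got {d_i}")
    s_het = (d_i * d_i) / 0.25
    if genotype == "HET":
        return min(s_het, 1.0)
    if genotype == "HOM":
        return max(1.0 - s_het, 0.0)
    raise ValueError(f"genotype must be HET or HOM, got {genotype!r}")


@dataclass
class ScoredCandidate:
    """Per-individual concordance scores of one candidate-tag pairing."""

    candidate_snp: str
    tag_snp: str
    event_id: str
    gene_id: str
    individual_ids: list[str]
    d: np.ndarray          # imbalance at the tag, per usable individual
    het: np.ndarray        # candidate genotype is heterozygous, per individual
    n_missing: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def n_het(self) -> int:
        return int(self.het.sum())

    @property
    def n_total(self) -> int:
        return len(self.d)

    @property
    def s(self) -> np.ndarray:
        s_het = (self.d**2) / 0.25
        return np.where(self.het, s_het, 1.0 - s_het)

    @property
    def mean_si(self) -> float:
        return float(self.s.mean()) if self.n_total else float("nan")


def score_candidate(
    candidate_snp: str,
    tag_snp: str,
    genotypes: GenotypeMatrix,
    tag_ratios: pd.Series,
    event_id: str = "",
    gene_id: str = "",
) -> ScoredCandidate:
    """Score one candidate against per-individual tag allelic ratios.

    ``tag_ratios`` maps individual_id -> R_i for individuals with a testable
    tag ratio. Individuals with missing candidate genotypes are skipped and
    counted in ``n_missing``.
    """
    codes = genotypes.codes[candidate_snp]
    inds, d_vals, het_vals = [], [], []
    n_missing = 0
    for ind, r in tag_ratios.items():
        if ind not in codes.index or pd.isna(r):
            n_missing += 1
            continue
        c = int(codes.loc[ind])
        if c == GenotypeMatrix.MISSING:
            n_missing += 1
            continue
        het = c in (GenotypeMatrix.HET_01, GenotypeMatrix.HET_10)
        inds.append(ind)
        d_vals.append(imbalance(float(r)))
        het_vals.append(het)
    return ScoredCandidate(
        candidate_snp=candidate_snp,
        tag_snp=tag_snp,
        event_id=event_id,
        gene_id=gene_id,
        individual_ids=inds,
        d=np.asarray(d_vals, dtype=float),
        het=np.asarray(het_vals, dtype=bool),
        n_missing=n_missing,
    )


def testability_filter(
    record: ScoredCandidate,
    cohort_size: int,
    het_fraction: float = 0.10,
    sample_fraction: float = 0.10,
) -> tuple[bool, str]:
    """Apply the het-share and sample-count rules.

    Passes iff n_het >= het_fraction * n_total (inclusive) and
    n_total > sample_fraction * cohort_size (strict).
    """
    if record.n_total == 0:
        return False, "NO_USABLE_INDIVIDUALS"
    if record.n_het < het_fraction * record.n_total:
        return False, "HET_FRACTION"
    if not record.n_total > sample_fraction * cohort_size:
        return False, "SAMPLE_FRACTION"
    return True, ""


def permutation_pvalue(
    record: ScoredCandidate, n_permutations: int = 1000, seed: int = 0
) -> float:
    """One-sided permutation p for the mean concordance score.

    Candidate genotype labels (HET/HOM) are permuted across individuals;
    p = (1 + #{permuted mean >= observed}) / (1 + B).
    """
    n = record.n_total
    if n == 0 or record.het.all() or (~record.het).all():
        return 1.0
    rng = child_rng(seed, f"perm:{record.candidate_snp}:{record.tag_snp}")
    s_het = (record.d**2) / 0.25
    w = 2.0 * s_het - 1.0          # S_i = (1 - s_het) + het_i * w_i
    base = float(np.sum(1.0 - s_het))
    observed = base + float(np.sum(w[record.het]))
    perm = np.tile(record.het, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    perm_sums = base + perm @ w
    exceed = int(np.sum(perm_sums >= observed - 1e-12))
    return (1 + exceed) / (1 + n_permutations)


def _tag_ratio_by_individual(
    annotated_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    tag_snp: str,
    min_coverage: int,
) -> pd.Series:
    """Per-individual allelic ratio at a tag SNP (het, coverage-filtered).

    Counts are pooled across an individual's samples.
    """
    sub = annotated_counts[
        (annotated_counts["snp_id"] == tag_snp) & annotated_counts["het"]
    ]
    if sub.empty:
        return pd.Series(dtype=float)
    ind_of_sample = metadata.set_index("sample_id")["individual_id"]
    sub = sub.assign(individual_id=sub["sample_id"].map(ind_of_sample))
    agg = sub.groupby("individual_id")[["ref_count", "alt_count"]].sum()
    total = agg["ref_count"] + agg["alt_count"]
    agg = agg[total >= min_coverage]
    total = total[total >= min_coverage]
    return agg["ref_count"] / total


def run_mode(
    tag_calls: pd.DataFrame,
    counts: pd.DataFrame,
    genotypes: GenotypeMatrix,
    events: pd.DataFrame,
    metadata: pd.DataFrame,
    mode: str = "ALL",
    config: ConcordanceConfig | None = None,
) -> pd.DataFrame:
    """Full candidate scan for one analysis mode (ALL, AD or CONTROL).

    Tag SNPs are designated cohort-wide (significant in at least one sample of
    ``tag_calls``, whichever group); the stratified modes restrict only the
    samples used for scoring. An event strongly allele-specific in one group
    is therefore still *testable* in the other, which is what lets the
    disease-specific comparison distinguish "functional in AD only" from
    "untestable in controls". Every SNP of the tag's gene is scored as a
    candidate; records passing the testability filter get a permutation
    p-value and BH FDR within the mode.
    """
    cfg = config or ConcordanceConfig()
    if mode not in ("ALL", "AD", "CONTROL"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = metadata if mode == "ALL" else metadata[metadata["group"] == ("AD" if mode == "AD" else "control")]
    if len(meta) == 0:
        logger.warning("mode %s has zero samples; skipped", mode)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if len(meta) < cfg.min_stratum_size:
        logger.warning(
            "mode %s has %d samples (< %d); skipped", mode, len(meta), cfg.min_stratum_size
        )
        return pd.DataFrame(columns=RESULT_COLUMNS)

    sample_ids = set(meta["sample_id"])
    cohort_size = meta["individual_id"].nunique()
    sig_tags = (
        tag_calls[tag_calls["significant"].astype(bool)][["snp_id", "event_id", "gene_id"]]
        .drop_duplicates()
        .sort_values(["gene_id", "snp_id", "event_id"])
    )
    annotated = annotate_phase(counts[counts["sample_id"].isin(sample_ids)], genotypes, meta)
    event_bounds = events.set_index("event_id")[["exon_start", "exon_end"]]

    rows = []
    for _, tag in sig_tags.iterrows():
        tag_snp, event_id, gene_id = tag["snp_id"], tag["event_id"], tag["gene_id"]
        ratios = _tag_ratio_by_individual(annotated, meta, tag_snp, cfg.min_tag_coverage)
        gene_snps = genotypes.snps[genotypes.snps["gene_id"] == gene_id]
        for cand in sorted(gene_snps["snp_id"]):
            rec = score_candidate(cand, tag_snp, genotypes, ratios, event_id, gene_id)
            ok, reason = testability_filter(
                rec, cohort_size, cfg.het_fraction, cfg.sample_fraction
            )
            dist = np.nan
            if event_id in event_bounds.index:
                pos = int(gene_snps.set_index("snp_id").loc[cand, "pos"])
                dist = distance_to_exon(
                    pos,
                    int(event_bounds.loc[event_id, "exon_start"]),
                    int(event_bounds.loc[event_id, "exon_end"]),
                )
            row = {
                "mode": mode,
                "candidate_snp": cand,
                "tag_snp": tag_snp,
                "event_id": event_id,
                "gene_id": gene_id,
                "n_het": rec.n_het,
                "n_total": rec.n_total,
                "mean_si": rec.mean_si,
                "p": np.nan,
                "fdr": np.nan,
                "significant": False,
                "distance_to_exon": dist,
                "reason_code": reason,
            }
            if ok:
                if rec.het.all() or (~rec.het).all():
                    # error path: a single genotype class permutes to itself,
                    # so no test exists; p = 1 by convention, kept out of the
                    # BH family
                    row["p"] = 1.0
                    row["reason_code"] = "DEGENERATE_GENOTYPES"
                else:
                    row["p"] = permutation_pvalue(rec, cfg.n_permutations, cfg.seed)
            rows.append(row)

    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = out["p"].notna() & (out["reason_code"] == "")
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"].to_numpy(), method="fdr_bh")[1]
        out.loc[tested, "significant"] = out.loc[tested, "fdr"] <= cfg.fdr_threshold
    return out


def distance_to_exon(pos: int, exon_start: int, exon_end: int) -> int:
    """Signed distance from a SNP to an exon (0-based half-open interval).

    Negative upstream of exon_start, positive downstream of exon_end, and the
    distance to the nearest boundary (reported as a non-positive/non-negative
    tie toward 0) for positions inside the exon; 0 exactly at a boundary base.
    """
    if pos < exon_start:
        return pos - exon_start
    if pos >= exon_end:
        return pos - (exon_end - 1)
    # inside: distance to nearest boundary, sign toward that boundary
    to_start = pos - exon_start
    to_end = (exon_end - 1) - pos
    return -to_start if to_start <= to_end else to_end


def distance_profile(
    calls: pd.DataFrame,
    events: pd.DataFrame,
    testable_snps: pd.DataFrame,
    n_random_sets: int = 100,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
) -> dict:
    """Positional density of functional SNPs around ASAS exon boundaries.

    ``testable_snps`` needs columns (snp_id, pos, event_id); every testable
    SNP contributes a signed distance to its event exon. The observed profile
    is the per-bin count of significant calls divided by the per-bin testable
    count (masked where the testable count is zero); ``n_random_sets``
    same-size random draws from the testable set give the null profiles.
    """
    if bin_edges is None:
        bin_edges = np.arange(-525, 526, 50)
    bounds = events.set_index("event_id")[["exon_start", "exon_end"]]

    def distances(df: pd.DataFrame) -> np.ndarray:
        out = []
        for _, r in df.iterrows():
            if r["event_id"] not in bounds.index:
                continue
            out.append(
                distance_to_exon(
                    int(r["pos"]),
                    int(bounds.loc[r["event_id"], "exon_start"]),
                    int(bounds.loc[r["event_id"], "exon_end"]),
                )
            )
        return np.asarray(out, dtype=float)

    test_d = distances(testable_snps)
    test_hist = np.histogram(test_d, bins=bin_edges)[0].astype(float)
    mask = test_hist > 0

    sig = calls[calls["significant"].astype(bool)]
    obs_df = testable_snps.merge(
        sig[["candidate_snp", "event_id"]].drop_duplicates(),
        left_on=["snp_id", "event_id"],
        right_on=["candidate_snp", "event_id"],
    )
    obs_d = distances(obs_df)
    obs_hist = np.histogram(obs_d, bins=bin_edges)[0].astype(float)
    observed = np.full(len(test_hist), np.nan)
    observed[mask] = obs_hist[mask] / test_hist[mask]

    rng = child_rng(seed, "distance_profile")
    k = max(len(obs_d), 1)
    nulls = np.full((n_random_sets, len(test_hist)), np.nan)
    for b in range(n_random_sets):
        if len(test_d) == 0:
            break
        draw = rng.choice(test_d, size=min(k, len(test_d)), replace=False)
        h = np.histogram(draw, bins=bin_edges)[0].astype(float)
        nulls[b, mask] = h[mask] / test_hist[mask]
    return {
        "bin_edges": bin_edges,
        "observed": observed,
        "null_profiles": nulls,
        "testable_hist": test_hist,
        "n_observed": int(len(obs_d)),
    }
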
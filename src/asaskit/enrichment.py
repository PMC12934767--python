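"""Empirical enrichment and overlap statistics.

Implements the matched-background empirical GO enrichment, LD-aware GWAS
overlap with the ratio-of-proportions enrichment score, hypergeometric gene
overlap, Kolmogorov-Smirnov QTL p-value enrichment against a sampled
background, resampled effect-size comparison, and the resampling fold-change
statistic for per-SNP score deltas.

Empirical p-values use an add-one pseudocount, so p >= 1/(n_iterations + 1).
All sampling is seeded; a cohort-level master seed fans out to per-operation
child seeds (see :mod:`asaskit._seeds`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng

__all__ = [
    "matched_background_sets",
    "empirical_term_enrichment",
    "hypergeometric_overlap",
    "ld_overlap",
    "gwas_enrichment_score",
    "category_grouping",
    "ks_pvalue_enrichment",
    "resampled_effect_comparison",
    "resampling_fold_change",
    "direct_overlap_fisher",
]

logger = logging.getLogger(__name__)

# GWAS trait keyword lists (case-insensitive substring match)
AD_KEYWORDS = ["alzheimer", "dementia", "amyloid", "neurofibrillary tangles"]
BRAIN_KEYWORDS = ["neuroticism", "parkinson", "schizophrenia", "brain"]
IMMUNE_KEYWORDS = [
    "immune",
    "antigen",
    "microglia",
    "cytokine",
    "antibody",
    "interferon",
    "inflammatory",
]


def matched_background_sets(
    query_genes: list[str],
    universe: pd.DataFrame,
    n_sets: int = 10_000,
    seed: int = 0,
    tolerance: float = 0.10,
    max_tolerance: float = 0.25,
) -> tuple[list[list[str]], list[str]]:
    """Expression- and length-matched background gene sets.

    For each query gene, eligible matches are non-ASAS genes with expression
    and length within ±``tolerance`` (relative). A gene with no match has its
    window widened in +5% steps up to ±``max_tolerance`` and is dropped (with
    a warning) if still unmatched. Each returned set holds one match per query
    gene, sampled without replacement within the set.

    Returns ``(sets, kept_query_genes)``; downstream term counting must use
    the kept queries so that query and background counts cover the same
    number of genes.
    """
    uni = universe.set_index("gene_id")
    rng = child_rng(seed, "matched_background")
    eligible: dict[str, np.ndarray] = {}
    kept_queries = []
    pool = universe[~universe["is_asas"].astype(bool)]
    for g in query_genes:
        if g not in uni.index:
            logger.warning("query gene %s absent from universe; dropped", g)
            continue
        e, ln = float(uni.at[g, "expression"]), float(uni.at[g, "length"])
        tol = tolerance
        match = np.array([])
        while tol <= max_tolerance + 1e-9:
            m = pool[
                pool["expression"].between(e * (1 - tol), e * (1 + tol))
                & pool["length"].between(ln * (1 - tol), ln * (1 + tol))
                & (pool["gene_id"] != g)
            ]
            match = m["gene_id"].to_numpy()
            if len(match):
                break
            tol += 0.05
        if not len(match):
            logger.warning("query gene %s has no matched background; dropped", g)
            continue
        eligible[g] = match
        kept_queries.append(g)

    sets = []
    for _ in range(n_sets):
        chosen: list[str] = []
        used: set[str] = set()
        for g in kept_queries:
            cand = eligible[g]
            free = cand[~np.isin(cand, list(used))] if used else cand
            if len(free) == 0:
                free = cand  # pool exhausted within this set; allow reuse
            pick = free[rng.integers(len(free))]
            chosen.append(pick)
            used.add(pick)
        sets.append(chosen)
    return sets, kept_queries


def empirical_term_enrichment(
    query_genes: list[str],
    background_sets: list[list[str]],
    annotations: dict[str, set[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Empirical per-term enrichment against matched background sets.

    ``annotations`` maps gene_id -> set of term ids. For each term,
    p = (1 + #{sets with term count >= query count}) / (1 + n_sets), BH FDR.
    """
    n_sets = len(background_sets)

    query_counts: dict[str, int] = {}
    for g in query_genes:
        for t in annotations.get(g, ()):
            query_counts[t] = query_counts.get(t, 0) + 1
    terms = sorted(query_counts)
    term_ix = {t: i for i, t in enumerate(terms)}

    # gene x term incidence restricted to query terms, counted per set in bulk
    genes = sorted({g for bg in background_sets for g in bg})
    gene_ix = {g: i for i, g in enumerate(genes)}
    incidence = np.zeros((len(genes), len(terms)), dtype=np.int16)
    for g in genes:
        for t in annotations.get(g, ()):
            j = term_ix.get(t)
            if j is not None:
                incidence[gene_ix[g], j] = 1
    null_counts = np.empty((n_sets, len(terms)), dtype=np.int32)
    for i, bg in enumerate(background_sets):
        rows_ix = [gene_ix[g] for g in bg]
        null_counts[i] = incidence[rows_ix].sum(axis=0)

    rows = []
    for t in terms:
        obs = query_counts[t]
        null = null_counts[:, term_ix[t]]
        p = (1 + int(np.sum(null >= obs))) / (1 + n_sets) if obs > 0 else 1.0
        rows.append(
            {
                "term": t,
                "observed": obs,
                "null_mean": float(null.mean()) if n_sets else np.nan,
                "null_sd": float(null.std(ddof=0)) if n_sets else np.nan,
                "n_iterations": n_sets,
                "empirical_p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["empirical_p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["fdr"] <= fdr_threshold
    return out


def hypergeometric_overlap(query: set, target: set, background: set) -> float:
    """Upper-tail hypergeometric p for |query ∩ target| over query ∪ background."""
    universe = set(query) | set(background)
    if not universe:
        raise ValueError("empty universe")
    m = len(universe)
    n_target = len(set(target) & universe)
    n_query = len(set(query))
    k = len(set(query) & set(target) & universe)
    return float(stats.hypergeom.sf(k - 1, m, n_target, n_query))


def ld_overlap(
    asas_snps: pd.DataFrame,
    gwas_snps: pd.DataFrame,
    ld_map: pd.DataFrame,
    window: int = 200_000,
) -> pd.DataFrame:
    """Flag each query SNP's LD/direct overlap with GWAS SNPs per trait.

    A query SNP overlaps a trait when some GWAS SNP of that trait shares its
    LD block and lies within ``window`` bases; identical positions are flagged
    separately as direct overlaps. SNPs absent from the LD map are singleton
    blocks.
    """
    block_of = ld_map.set_index("snp_id")["block_id"].to_dict()

    def block(snp_id):
        return block_of.get(snp_id, f"singleton:{snp_id}")

    gwas = gwas_snps.assign(block=[block(s) for s in gwas_snps["snp_id"]])
    gwas_by_block: dict[str, pd.DataFrame] = {b: d for b, d in gwas.groupby("block")}
    gwas_pos = set(zip(gwas["chrom"], gwas["pos"]))

    rows = []
    for _, q in asas_snps.iterrows():
        b = block(q["snp_id"])
        traits: set[str] = set()
        if b in gwas_by_block:
            d = gwas_by_block[b]
            near = d[(d["chrom"] == q["chrom"]) & (np.abs(d["pos"] - q["pos"]) <= window)]
            traits = set(near["trait"])
        rows.append(
            {
                "snp_id": q["snp_id"],
                "chrom": q["chrom"],
                "pos": q["pos"],
                "block_id": b,
                "ld_overlap": bool(traits),
                "direct_overlap": (q["chrom"], q["pos"]) in gwas_pos,
                "traits": ";".join(sorted(traits)),
            }
        )
    return pd.DataFrame(rows)


def gwas_enrichment_score(
    x_trait: int, x_total: int, y_trait: int, y_total: int
) -> tuple[float, float]:
    """Ratio-of-proportions enrichment score with a Fisher's exact p.

    score = (x_trait/x_total) / (y_trait/y_total). When y_trait = 0 the score
    is computed with 0.5 added to every cell (Haldane continuity); the Fisher
    test always uses the raw table [[x_trait, x_total-x_trait],
    [y_trait, y_total-y_trait]].
    """
    if x_total <= 0 or y_total <= 0:
        raise ValueError("totals must be positive")
    if x_trait > x_total or y_trait > y_total:
        raise ValueError("trait counts cannot exceed totals")
    table = [[x_trait, x_total - x_trait], [y_trait, y_total - y_trait]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if y_trait == 0:
        score = ((x_trait + 0.5) / (x_total + 1.0)) / ((y_trait + 0.5) / (y_total + 1.0))
        logger.warning("y_trait = 0: enrichment score computed with 0.5 continuity")
    else:
        score = (x_trait / x_total) / (y_trait / y_total)
    return float(score), p


def category_grouping(trait_labels: list[str]) -> dict[str, str]:
    """Assign each trait to AD-related / brain-related / immune-related / other.

    Case-insensitive substring match; precedence AD > brain > immune.
    """
    out = {}
    for t in trait_labels:
        low = t.lower()
        if any(k in low for k in AD_KEYWORDS):
            out[t] = "AD-related"
        elif any(k in low for k in BRAIN_KEYWORDS):
            out[t] = "brain-related"
        elif any(k in low for k in IMMUNE_KEYWORDS):
            out[t] = "immune-related"
        else:
            out[t] = "other"
    return out


def ks_pvalue_enrichment(
    observed_p,
    all_tested_p,
    n_background: int | None = None,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """KS test of observed QTL p-values against a sampled background.

    The background is a uniform random sample (default the same size as
    ``observed_p``) from all tested p-values. ``alternative='greater'`` tests
    whether the observed p-values are stochastically smaller (their empirical
    CDF lies above the background's), which is the enrichment direction.
    Returns (D, p).
    """
    observed = np.asarray(observed_p, dtype=float)
    pool = np.asarray(all_tested_p, dtype=float)
    if len(observed) == 0 or len(pool) == 0:
        raise ValueError("both p-value lists must be non-empty")
    size = n_background if n_background is not None else len(observed)
    rng = child_rng(seed, "ks_background")
    background = rng.choice(pool, size=size, replace=size > len(pool))
    res = stats.ks_2samp(observed, background, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def resampled_effect_comparison(
    observed_effects,
    pool,
    seed: int = 0,
    n_iterations: int = 1000,
) -> tuple[float, dict]:
    """Compare |observed| effect sizes with a resampled background.

    One equal-size draw from the pool anchors a one-sided rank-sum test
    (observed > background); ``n_iterations`` further draws locate the
    observed median's percentile among resampled medians.
    """
    obs = np.abs(np.asarray(observed_effects, dtype=float))
    pl = np.abs(np.asarray(pool, dtype=float))
    if len(pl) < len(obs):
        raise ValueError("pool must be at least as large as observed")
    rng = child_rng(seed, "effect_background")
    bg = rng.choice(pl, size=len(obs), replace=False)
    p = float(stats.mannwhitneyu(obs, bg, alternative="greater").pvalue)
    medians = np.array(
        [np.median(rng.choice(pl, size=len(obs), replace=False)) for _ in range(n_iterations)]
    )
    obs_med = float(np.median(obs))
    percentile = float(np.mean(medians < obs_med) + 0.5 * np.mean(medians == obs_med))
    summary = {
        "observed_median": obs_med,
        "background_median_mean": float(medians.mean()),
        "percentile": percentile,
        "n_iterations": n_iterations,
    }
    return p, summary


def resampling_fold_change(
    functional_deltas,
    random_pool_deltas,
    n_iterations: int = 1000,
    seed: int = 0,
) -> dict:
    """Fold change of median score deltas for functional vs random SNPs.

    Each iteration draws |functional| values from the pool without replacement
    and records the median; fold_change = median(functional) / median of the
    iteration medians. A one-sided Mann-Whitney U (functional > pooled sampled
    deltas) tests the null of fold change 1; the empirical p is the add-one
    tail fraction of iteration medians at least the observed median.
    """
    obs = np.asarray(functional_deltas, dtype=float)
    pool = np.asarray(random_pool_deltas, dtype=float)
    if len(pool) < len(obs):
        raise ValueError("pool too small for without-replacement sampling")
    rng = child_rng(seed, "fold_change")
    medians = np.empty(n_iterations)
    sampled_all = []
    for i in range(n_iterations):
        draw = rng.choice(pool, size=len(obs), replace=False)
        medians[i] = np.median(draw)
        sampled_all.append(draw)
    obs_median = float(np.median(obs))
    denom = float(np.median(medians))
    fold = obs_median / denom if denom != 0 else np.nan
    if denom == 0:
        logger.warning("zero background median; fold change undefined")
    pooled = np.concatenate(sampled_all)
    mwu_p = float(stats.mannwhitneyu(obs, pooled, alternative="greater").pvalue)
    empirical_p = (1 + int(np.sum(medians >= obs_median))) / (1 + n_iterations)
    return {
        "fold_change": fold,
        "mwu_p": mwu_p,
        "empirical_p": empirical_p,
        "observed_median": obs_median,
        "background_median": denom,
        "n_iterations": n_iterations,
    }


def direct_overlap_fisher(
    asas_snps: pd.DataFrame,
    background_snps: pd.DataFrame,
    gwas_positions: set[tuple[str, int]],
) -> tuple[list[list[int]], float]:
    """Two-sided Fisher test on direct positional GWAS overlap.

    Both SNP tables need (chrom, pos); the background should be an equal-size
    sample from genes without ASAS events.
    """

    def n_overlap(df):
        return int(sum((c, p) in gwas_positions for c, p in zip(df["chrom"], df["pos"])))

    a = n_overlap(asas_snps)
    b = n_overlap(background_snps)
    table = [[a, len(asas_snps) - a], [b, len(background_snps) - b]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p
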
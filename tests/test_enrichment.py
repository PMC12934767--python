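"""Enrichment suite: matched backgrounds, overlap statistics, resampling."""

import numpy as np
import pandas as pd
import pytest

from asaskit import enrichment as en
from oracles import fisher_two_sided, hypergeom_upper


@pytest.fixture()
def universe(rng):
    n = 300
    genes = [f"g{i}" for i in range(n)]
    expr = rng.lognormal(3, 0.4, n)
    length = rng.integers(500, 5000, n)
    is_asas = np.zeros(n, dtype=bool)
    is_asas[:20] = True
    return pd.DataFrame(
        {"gene_id": genes, "expression": expr, "length": length, "is_asas": is_asas}
    )


def test_matched_background_windows():
    """Eligible matches sit inside the ±10% expression and length windows."""
    uni = pd.DataFrame(
        {
            "gene_id": ["q", "in1", "in2", "expr_out", "len_out", "asas_match"],
            "expression": [100.0, 95.0, 108.0, 120.0, 100.0, 100.0],
            "length": [1000, 1050, 920, 1000, 1200, 1000],
            "is_asas": [True, False, False, False, False, True],
        }
    )
    sets, kept = en.matched_background_sets(["q"], uni, n_sets=50, seed=1)
    picks = {s[0] for s in sets}
    assert picks <= {"in1", "in2"}
    assert picks == {"in1", "in2"}  # both get sampled over 50 sets


def test_matched_background_never_returns_asas_gene(universe):
    query = list(universe.loc[universe["is_asas"], "gene_id"])
    sets, _ = en.matched_background_sets(query, universe, n_sets=20, seed=2)
    asas = set(query)
    for s in sets:
        assert not (set(s) & asas)


def test_matched_background_deterministic(universe):
    q = list(universe.loc[universe["is_asas"], "gene_id"])[:5]
    assert en.matched_background_sets(q, universe, 30, seed=9) == en.matched_background_sets(
        q, universe, 30, seed=9
    )


def test_single_match_universe_gives_identical_sets():
    uni = pd.DataFrame(
        {
            "gene_id": ["q", "m", "far"],
            "expression": [100.0, 100.0, 5000.0],
            "length": [1000, 1000, 90000],
            "is_asas": [True, False, False],
        }
    )
    sets, _ = en.matched_background_sets(["q"], uni, n_sets=10, seed=0)
    assert all(s == ["m"] for s in sets)


def test_empirical_term_enrichment_pseudocount_and_nulls(universe):
    query = list(universe.loc[universe["is_asas"], "gene_id"])
    annotations = {g: {"planted"} for g in query}  # term in query only
    for g in universe.loc[~universe["is_asas"], "gene_id"]:
        annotations[g] = {"common"}
    sets, kept = en.matched_background_sets(query, universe, n_sets=200, seed=3)
    res = en.empirical_term_enrichment(kept, sets, annotations).set_index("term")
    assert res.at["planted", "empirical_p"] == pytest.approx(1 / 201)
    assert res["empirical_p"].min() >= 1 / 201


def test_empirical_term_zero_query_count_p_one():
    res = en.empirical_term_enrichment(["a"], [["b"]] * 10, {"a": set(), "b": {"t"}})
    assert len(res) == 0  # no query terms -> nothing tested


def test_planted_term_significant_unplanted_uniform(rng, universe):
    """One planted enriched term among many random ones."""
    query = list(universe.loc[universe["is_asas"], "gene_id"])
    terms = [f"t{i}" for i in range(100)]
    annotations = {}
    for g in universe["gene_id"]:
        annotations[g] = set(rng.choice(terms, size=5, replace=False))
    for g in query:
        annotations[g].add("planted")  # every query gene
    sets, kept = en.matched_background_sets(query, universe, n_sets=300, seed=4)
    res = en.empirical_term_enrichment(kept, sets, annotations).set_index("term")
    assert res.at["planted", "empirical_p"] <= 0.05
    others = res.drop("planted")["empirical_p"]
    assert 0.2 <= (others <= 0.5).mean() or others.median() > 0.2  # no mass at 0


def test_hypergeometric_overlap_matches_enumeration():
    query = {f"q{i}" for i in range(5)}
    background = {f"b{i}" for i in range(5)}
    target = set(query)  # all 5 targets inside query
    p = en.hypergeometric_overlap(query, target, background)
    assert p == pytest.approx(hypergeom_upper(5, 10, 5, 5), abs=1e-12)
    assert p == pytest.approx(1 / 252, abs=1e-12)  # 1 / C(10,5)


def test_hypergeometric_no_target_overlap_p_one():
    p = en.hypergeometric_overlap({"a"}, {"zzz"}, {"b", "c"})
    assert p == pytest.approx(1.0)


def test_hypergeometric_random_grid_against_oracle():
    from scipy.stats import hypergeom

    for m, K, n in [(20, 8, 6), (30, 15, 10), (12, 3, 5)]:
        for k in range(0, min(K, n) + 1):
            assert hypergeom.sf(k - 1, m, K, n) == pytest.approx(
                hypergeom_upper(k, m, K, n), abs=1e-10
            )


def test_ld_overlap_rules():
    asas = pd.DataFrame(
        {
            "snp_id": ["a1", "a2", "a3", "a4"],
            "chrom": ["chr1"] * 4,
            "pos": [100_000, 100_000, 400_000, 100_000],
        }
    )
    gwas = pd.DataFrame(
        {
            "snp_id": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "pos": [250_000, 100_000],
            "trait": ["Alzheimer's disease", "height"],
        }
    )
    ld = pd.DataFrame(
        {
            "snp_id": ["a1", "g1", "a3", "a4", "g2"],
            "block_id": ["B1", "B1", "B1", "B2", "B2"],
        }
    )
    res = en.ld_overlap(asas, gwas, ld, window=200_000).set_index("snp_id")
    assert res.at["a1", "ld_overlap"]          # same block, 150 kb away
    assert res.at["a3", "ld_overlap"]          # same block, 150 kb the other side
    assert res.at["a2", "block_id"].startswith("singleton")
    assert not res.at["a2", "ld_overlap"]
    assert res.at["a4", "ld_overlap"] and res.at["a4", "direct_overlap"]


def test_ld_overlap_window_boundary():
    asas = pd.DataFrame({"snp_id": ["a"], "chrom": ["chr1"], "pos": [0]})
    gwas = pd.DataFrame(
        {"snp_id": ["g"], "chrom": ["chr1"], "pos": [250_000], "trait": ["t"]}
    )
    ld = pd.DataFrame({"snp_id": ["a", "g"], "block_id": ["B", "B"]})
    res = en.ld_overlap(asas, gwas, ld, window=200_000)
    assert not res["ld_overlap"].iloc[0]  # 250 kb > 200 kb window


def test_gwas_enrichment_score():
    score, p = en.gwas_enrichment_score(5, 50, 2, 100)
    assert score == pytest.approx(5.0)
    assert p == pytest.approx(fisher_two_sided(5, 45, 2, 98), abs=1e-9)
    assert en.gwas_enrichment_score(50, 50, 100, 100)[0] == pytest.approx(1.0)


def test_gwas_enrichment_score_scale_invariant():
    s1, _ = en.gwas_enrichment_score(5, 50, 2, 100)
    s2, _ = en.gwas_enrichment_score(15, 150, 6, 300)
    assert s1 == pytest.approx(s2)


def test_gwas_enrichment_zero_background_continuity():
    score, p = en.gwas_enrichment_score(5, 50, 0, 100)
    assert np.isfinite(score) and score > 1
    assert 0 <= p <= 1


def test_fisher_agreement_with_oracle_sample():
    from scipy.stats import fisher_exact

    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
        if (a + b) == 0 or (c + d) == 0:
            continue
        p_scipy = fisher_exact([[a, b], [c, d]])[1]
        assert p_scipy == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-8)


def test_category_grouping():
    cats = en.category_grouping(
        [
            "Alzheimer's disease (late onset)",
            "interferon signaling",
            "standing height",
            "Parkinson's disease",
            "Amyloid beta levels in brain",  # AD beats brain by precedence
        ]
    )
    assert cats["Alzheimer's disease (late onset)"] == "AD-related"
    assert cats["interferon signaling"] == "immune-related"
    assert cats["standing height"] == "other"
    assert cats["Parkinson's disease"] == "brain-related"
    assert cats["Amyloid beta levels in brain"] == "AD-related"


def test_ks_enrichment_direction_and_null(rng):
    pool = rng.uniform(0, 1, 3000)
    strong = rng.uniform(0, 0.05, 100)
    d, p = en.ks_pvalue_enrichment(strong, pool, seed=1)
    assert p < 1e-6
    # null: observed drawn from the pool itself
    ps = [
        en.ks_pvalue_enrichment(rng.choice(pool, 100, replace=False), pool, seed=int(s))[1]
        for s in range(40)
    ]
    assert np.mean(np.array(ps) <= 0.05) < 0.25


def test_ks_identical_lists_d_zero():
    obs = np.linspace(0.01, 0.99, 50)
    d, _ = en.ks_pvalue_enrichment(obs, obs, n_background=50, seed=3)
    # background is a bootstrap draw of the same values; D stays small
    assert d <= 0.3


def test_resampled_effect_comparison_null_and_shifted(rng):
    pool = rng.normal(0, 1, 2000)
    p_null, s_null = en.resampled_effect_comparison(rng.choice(pool, 80, replace=False), pool, seed=5, n_iterations=200)
    assert 0.0 < p_null
    assert 0.05 < s_null["percentile"] < 0.95
    p_big, s_big = en.resampled_effect_comparison(pool[:80] * 4.0, pool, seed=5, n_iterations=200)
    assert p_big < 1e-4
    assert s_big["percentile"] > 0.99


def test_resampling_fold_change_recovers_factor_two(rng):
    pool = rng.exponential(1.0, 4000)
    functional = 2.0 * rng.exponential(1.0, 150)
    res = en.resampling_fold_change(functional, pool, n_iterations=400, seed=6)
    assert res["fold_change"] == pytest.approx(2.0, rel=0.25)
    assert res["mwu_p"] < 1e-4
    assert res["empirical_p"] >= 1 / 401


def test_resampling_fold_change_null_near_one(rng):
    pool = rng.exponential(1.0, 4000)
    res = en.resampling_fold_change(rng.choice(pool, 150, replace=False), pool,
                                    n_iterations=400, seed=7)
    assert res["fold_change"] == pytest.approx(1.0, abs=0.25)


def test_resampling_fold_change_deterministic(rng):
    pool = rng.exponential(1.0, 1000)
    obs = pool[:50] * 1.5
    r1 = en.resampling_fold_change(obs, pool, n_iterations=100, seed=8)
    r2 = en.resampling_fold_change(obs, pool, n_iterations=100, seed=8)
    assert r1 == r2


def test_direct_overlap_fisher():
    asas = pd.DataFrame({"chrom": ["chr1"] * 10, "pos": range(10)})
    bg = pd.DataFrame({"chrom": ["chr1"] * 10, "pos": range(100, 110)})
    gwas = {("chr1", i) for i in range(3)}  # hits only the ASAS set
    table, p = en.direct_overlap_fisher(asas, bg, gwas)
    assert table == [[3, 7], [0, 10]]
    assert p == pytest.approx(fisher_two_sided(3, 7, 0, 10), abs=1e-10)
    _, p_empty = en.direct_overlap_fisher(asas, bg, set())
    assert p_empty == pytest.approx(1.0)
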
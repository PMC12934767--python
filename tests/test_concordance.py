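"""Concordance scoring: formulas, testability, permutation test, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asaskit as ak
from asaskit.concordance import ScoredCandidate, distance_to_exon


@pytest.mark.parametrize("r,d", [(0.5, 0.0), (0.0, 0.5), (0.75, -0.25), (1.0, -0.5)])
def test_imbalance(r, d):
    assert ak.imbalance(r) == pytest.approx(d)


@pytest.mark.parametrize(
    "d,genotype,expected",
    [
        (0.5, "HET", 1.0),
        (0.0, "HOM", 1.0),
        (0.3, "HET", 0.36),
        (0.3, "HOM", 0.64),
        (0.0, "HET", 0.0),
        (-0.5, "HOM", 0.0),
    ],
)
def test_concordance_score_formula(d, genotype, expected):
    assert ak.concordance_score(d, genotype) == pytest.approx(expected)


def test_concordance_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        ak.concordance_score(0.6, "HET")
    with pytest.raises(ValueError):
        ak.concordance_score(0.1, "het")


@given(st.floats(min_value=-0.5, max_value=0.5, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_score_bounded_and_branches_complementary(d):
    s_het = ak.concordance_score(d, "HET")
    s_hom = ak.concordance_score(d, "HOM")
    assert 0.0 <= s_het <= 1.0
    assert 0.0 <= s_hom <= 1.0
    assert s_het + s_hom == pytest.approx(1.0, abs=1e-12)


def _record(d, het, **kw):
    return ScoredCandidate(
        candidate_snp=kw.get("cand", "c"),
        tag_snp=kw.get("tag", "t"),
        event_id="E",
        gene_id="G",
        individual_ids=[f"I{i}" for i in range(len(d))],
        d=np.asarray(d, dtype=float),
        het=np.asarray(het, dtype=bool),
    )


def test_mean_si_hand_computed():
    """Mixed toy cohort of 4 individuals: average of the four branch formulas."""
    rec = _record([0.5, 0.0, 0.3, -0.2], [True, False, True, False])
    expected = np.mean([1.0, 1.0, 0.36, 1 - 0.04 / 0.25])
    assert rec.mean_si == pytest.approx(expected)


def test_all_het_full_imbalance_and_all_hom_balanced():
    assert _record([0.5, -0.5], [True, True]).mean_si == pytest.approx(1.0)
    assert _record([0.0, 0.0], [False, False]).mean_si == pytest.approx(1.0)


def test_score_candidate_skips_missing_genotypes(small_cohort):
    g = small_cohort.genotypes
    ratios = pd.Series(0.3, index=pd.Index(g.individuals, name="individual_id"))
    ratios_with_bogus = pd.concat([ratios, pd.Series({"NOBODY": 0.4})])
    rec = ak.score_candidate("G000_fsnp", "G000_E0_tag", g, ratios_with_bogus)
    assert rec.n_total == len(g.individuals)
    assert rec.n_missing == 1
    assert np.allclose(rec.d, 0.2)


@pytest.mark.parametrize(
    "n_het,n_total,cohort,expected,reason",
    [
        (9, 95, 100, False, "HET_FRACTION"),
        (10, 11, 100, True, ""),
        (2, 10, 100, False, "SAMPLE_FRACTION"),  # "exceeded" is strict: 10 !> 10
        (2, 11, 100, True, ""),
        (0, 0, 100, False, "NO_USABLE_INDIVIDUALS"),
    ],
)
def test_testability_filter(n_het, n_total, cohort, expected, reason):
    rec = _record([0.1] * n_total, [True] * n_het + [False] * (n_total - n_het))
    ok, why = ak.testability_filter(rec, cohort)
    assert ok is expected
    assert why == reason


def test_permutation_p_degenerate_labels():
    assert ak.permutation_pvalue(_record([0.4, 0.2, 0.1], [True] * 3)) == 1.0
    assert ak.permutation_pvalue(_record([0.4, 0.2, 0.1], [False] * 3)) == 1.0


def test_permutation_p_detects_concordance():
    """Hets carry strong imbalance, homs none: p at the permutation floor."""
    d = np.array([0.45] * 10 + [0.02] * 30)
    het = np.array([True] * 10 + [False] * 30)
    p = ak.permutation_pvalue(_record(d, het), n_permutations=999, seed=3)
    assert p <= 0.01


def test_permutation_p_invariant_to_individual_relabeling():
    d = np.array([0.4, 0.1, 0.3, 0.0, 0.2, 0.05])
    het = np.array([True, False, True, False, True, False])
    r1 = _record(d, het)
    r2 = ScoredCandidate(
        candidate_snp="c", tag_snp="t", event_id="E", gene_id="G",
        individual_ids=[f"X{i}" for i in range(6)], d=d, het=het,
    )
    assert ak.permutation_pvalue(r1, 500, seed=9) == ak.permutation_pvalue(r2, 500, seed=9)


def test_pseudocount_floor():
    d = np.array([0.5] * 5 + [0.0] * 20)
    het = np.array([True] * 5 + [False] * 20)
    p = ak.permutation_pvalue(_record(d, het), n_permutations=200, seed=1)
    assert p >= 1 / 201


@pytest.mark.parametrize(
    "pos,start,end,expected",
    [(950, 1000, 1200, -50), (1000, 1000, 1200, 0), (1250, 1000, 1200, 51), (1199, 1000, 1200, 0)],
)
def test_distance_to_exon(pos, start, end, expected):
    assert distance_to_exon(pos, start, end) == expected


def test_run_mode_recovers_planted_functional(small_cohort, small_calls):
    c = small_cohort
    res = ak.run_mode(
        small_calls, c.counts, c.genotypes, c.events, c.metadata,
        mode="ALL", config=ak.ConcordanceConfig(seed=7),
    )
    assert set(res["mode"]) <= {"ALL"}
    # every tested record satisfies the output invariants
    tested = res[res["p"].notna()]
    assert ((tested["fdr"] >= tested["p"] - 1e-12) | tested["fdr"].isna()).all()
    sig = res[res["significant"]]
    assert (sig["fdr"] <= 0.05).all()
    # the 60-individual fixture has limited permutation power; at least one
    # planted SNP survives FDR, and planted SNPs dominate the top ranks
    hits = sum(
        bool(sig[(sig["candidate_snp"] == f)].shape[0]) for f in c.truth.functional_snp_ids
    )
    assert hits >= 1
    top = (
        tested[tested["candidate_snp"] != tested["tag_snp"]]
        .sort_values(["p", "mean_si"], ascending=[True, False])
        .groupby("gene_id")
        .head(1)
    )
    planted_top = top["candidate_snp"].isin(c.truth.functional_snp_ids).mean()
    assert planted_top >= 0.75


def test_run_mode_skips_tiny_stratum(small_cohort, small_calls):
    c = small_cohort
    meta = c.metadata.copy()
    meta.loc[meta.index[:-5], "group"] = "control"
    meta.loc[meta.index[-5:], "group"] = "AD"
    res = ak.run_mode(small_calls, c.counts, c.genotypes, c.events, meta, mode="AD")
    assert res.empty


def test_distance_profile_flat_under_uniform_placement(rng):
    """Uniformly placed SNPs give a flat normalized profile (observed and null)."""
    events = pd.DataFrame(
        {"event_id": ["E0"], "exon_start": [1000], "exon_end": [1150]}
    )
    pos = rng.integers(600, 1550, size=800)
    testable = pd.DataFrame({"snp_id": [f"s{i}" for i in range(800)], "pos": pos,
                             "event_id": "E0"})
    chosen = rng.choice(800, size=300, replace=False)
    calls = pd.DataFrame(
        {
            "candidate_snp": [f"s{i}" for i in chosen],
            "event_id": "E0",
            "significant": True,
        }
    )
    prof = ak.distance_profile(calls, events, testable, n_random_sets=100, seed=5)
    null_mean = np.nanmean(prof["null_profiles"], axis=0)
    null_mean = null_mean[~np.isnan(null_mean)]
    assert len(null_mean) > 3
    assert np.max(null_mean) / np.median(null_mean) <= 2.0
    obs = prof["observed"][~np.isnan(prof["observed"])]
    assert np.max(obs) / np.median(obs) <= 2.0
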
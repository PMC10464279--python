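"""Hypergeometric and permutation enrichment, GO over-representation, overlaps."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from methylsleep.enrichment import (enrich_measure, gene_overlap,
                                    go_enrichment, hypergeom_enrichment,
                                    permutation_enrichment)


def enumerate_upper_tail(N, K, n, k):
    """Exhaustive subset enumeration of P(X >= k) for tiny N."""
    total = comb(N, n)
    count = 0
    items = range(N)          # first K items are the successes
    for subset in combinations(items, n):
        if sum(1 for x in subset if x < K) >= k:
            count += 1
    return count / total


def test_hypergeom_hand_example():
    # C(4,4)*C(6,1)/C(10,5) = 6/252
    assert hypergeom_enrichment(10, 4, 5, 4) == pytest.approx(6 / 252)


def test_hypergeom_trivial_tails():
    assert hypergeom_enrichment(10, 4, 5, 0) == 1.0
    assert hypergeom_enrichment(10, 4, 10, 4) == 1.0  # n = N forces k = K


def test_hypergeom_rejects_inconsistent_counts():
    for bad in [(10, 4, 5, 5), (10, 11, 5, 2), (10, 4, 11, 2), (5, 3, 3, -1)]:
        with pytest.raises(ValueError):
            hypergeom_enrichment(*bad)


def test_hypergeom_small_cases_match_enumeration():
    for N in (5, 8):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_enrichment(N, K, n, k) == pytest.approx(
                        enumerate_upper_tail(N, K, n, k), abs=1e-12)


def test_hypergeom_monotone_in_overlap():
    # more hits inside the group (totals fixed) never increases p
    ps = [hypergeom_enrichment(100, 20, 30, k) for k in range(0, 21)]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def _annotation(n_genes=20, sites_per_gene=5, n_intergenic=10):
    rows = []
    pos = 1
    for g in range(n_genes):
        for _ in range(sites_per_gene):
            rows.append((f"chr1:{pos}", "chr1", pos, f"g{g}", "intragenic"))
            pos += 10
    for _ in range(n_intergenic):
        rows.append((f"chr1:{pos}", "chr1", pos, None, "intergenic"))
        pos += 10
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos",
                                       "gene_id", "zone"])


def _site_p(ann, seed=0):
    rng = np.random.default_rng(seed)
    sids = ann["site_id"].unique()
    return pd.Series(rng.random(len(sids)), index=sids)


def test_permutation_trivial_cases():
    ann = _annotation()
    site_p = _site_p(ann)
    all_genes = {f"g{i}" for i in range(20)}
    p, obs = permutation_enrichment(ann, site_p, all_genes, n_perm=200, seed=1)
    assert p == 1.0                      # group = universe: null >= obs always
    p0, obs0 = permutation_enrichment(ann, site_p + 1.0, {"g0", "g1"},
                                      n_perm=200, seed=1)
    assert obs0 == 0 and p0 == 1.0       # no nominal hit anywhere


def test_permutation_seed_reproducible_and_floor():
    ann = _annotation()
    site_p = _site_p(ann, seed=5)
    a = permutation_enrichment(ann, site_p, {"g0", "g1", "g2"},
                               n_perm=500, seed=42)
    b = permutation_enrichment(ann, site_p, {"g0", "g1", "g2"},
                               n_perm=500, seed=42)
    assert a == b
    assert a[0] >= 1 / 501


def test_permutation_site_level_null_unit():
    ann = _annotation()
    site_p = _site_p(ann, seed=6)
    p, _ = permutation_enrichment(ann, site_p, {"g0", "g3"}, n_perm=300,
                                  seed=3, null_unit="site")
    assert 1 / 301 <= p <= 1.0
    with pytest.raises(ValueError):
        permutation_enrichment(ann, site_p, {"g0"}, null_unit="sample")


def test_permutation_rejects_foreign_gene_set():
    ann = _annotation()
    with pytest.raises(ValueError, match="no gene"):
        permutation_enrichment(ann, _site_p(ann), {"zz"}, n_perm=10, seed=0)


def test_enrich_measure_counts_are_consistent():
    ann = _annotation()
    rng = np.random.default_rng(2)
    sids = ann["site_id"].unique()
    rec = pd.DataFrame({
        "site_id": sids, "measure": "sol_sr",
        "p": rng.random(len(sids)),
    })
    rep = enrich_measure("sol_sr", ann, rec, {"g0", "g1", "g2"},
                         n_perm=200, seed=7)
    assert rep.n_universe == 100          # intergenic sites excluded
    assert rep.n_group == 15
    assert rep.n_overlap <= min(rep.n_hits, rep.n_group)
    assert 1 / 201 <= rep.p_permutation <= 1.0
    assert 0 < rep.p_hypergeometric <= 1.0


def test_go_enrichment_enumeration_case():
    universe = {f"g{i}" for i in range(10)}
    sig = {"g0", "g1", "g2"}
    tm = pd.DataFrame({
        "gene_id": ["g0", "g1", "g2", "g5", "g6", "g7"],
        "term_id": ["T1"] * 3 + ["T2"] * 3,
        "term_name": ["hit term"] * 3 + ["miss term"] * 3,
        "ontology": ["BP"] * 6,
    })
    res = go_enrichment(sig, universe, tm).set_index("term_id")
    # all 3 significant genes in a size-3 term of a 10-gene universe
    assert res.loc["T1", "p"] == pytest.approx(1 / comb(10, 3), abs=1e-12)
    assert res.loc["T2", "p"] == 1.0      # disjoint term
    assert (res["mapped"] <= res["n_term"]).all()
    assert res.loc["T1", "n_term"] == 3 and res.loc["T1", "mapped"] == 3


def test_go_enrichment_empty_significant_set():
    tm = pd.DataFrame({"gene_id": ["g0"], "term_id": ["T"],
                       "term_name": ["t"], "ontology": ["BP"]})
    res = go_enrichment(set(), {"g0", "g1"}, tm)
    assert res.empty
    with pytest.raises(ValueError):
        go_enrichment({"g9"}, {"g0"}, tm)  # not a subset of the universe


def test_go_q_values_bh_within_ontology():
    rng = np.random.default_rng(3)
    universe = {f"g{i}" for i in range(30)}
    sig = set(list(sorted(universe))[:8])
    rows = []
    for t in range(6):
        genes = rng.choice(sorted(universe), size=10, replace=False)
        onto = "BP" if t < 3 else "MF"
        rows += [(g, f"T{t}", f"term{t}", onto) for g in genes]
    tm = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name",
                                     "ontology"])
    res = go_enrichment(sig, universe, tm)
    for _, grp in res.groupby("ontology"):
        from methylsleep.association import bh_fdr
        np.testing.assert_allclose(grp["q"], bh_fdr(grp["p"].to_numpy()))


def test_gene_overlap_counts():
    sets = {
        "sol_sr": {"a", "b", "c"},
        "sol_act": {"b", "c", "d"},
        "sol_psg": {"c", "d", "e"},
    }
    out = gene_overlap(sets).set_index("measures")
    assert out.loc["sol_act+sol_sr", "n_overlap"] == 2
    assert out.loc["sol_act+sol_psg", "n_overlap"] == 2
    assert out.loc["sol_psg+sol_sr", "n_overlap"] == 1
    triple = out.loc["sol_sr+sol_act+sol_psg"]
    assert triple["n_overlap"] == 1 and triple["genes"] == "c"
    same = gene_overlap({"x": {"a"}, "y": {"a"}}).iloc[0]
    assert same["n_overlap"] == 1
    assert gene_overlap({"x": {"a"}, "y": {"b"}}).iloc[0]["n_overlap"] == 0
    with pytest.raises(ValueError):
        gene_overlap({"x": {"a"}})
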
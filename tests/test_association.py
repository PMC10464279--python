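"""Per-site OLS, EWAS bookkeeping, BH FDR and the significance summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylsleep as ms
from methylsleep.association import bh_fdr, build_design, fit_site


def test_fit_site_exact_noiseless_line():
    level = np.linspace(0.1, 0.9, 10)
    y = 2.0 + 60.0 * level
    fit = fit_site(y, level)
    assert fit.beta == pytest.approx(60.0, abs=1e-9)
    assert fit.p < 1e-12
    assert fit.n == 10


def test_fit_site_orthogonal_covariate_leaves_beta_unchanged():
    rng = np.random.default_rng(0)
    n = 40
    level = np.tile([0.2, 0.4, 0.6, 0.8], n // 4)
    cov = np.tile([1.0, -1.0, -1.0, 1.0], n // 4)  # orthogonal to level by design
    assert abs(np.corrcoef(level, cov)[0, 1]) < 1e-12
    y = 5 + 30 * level + 2 * cov + rng.normal(0, 1, n)
    with_cov = fit_site(y, level, cov[:, None])
    without = fit_site(y, level)
    assert with_cov.beta == pytest.approx(without.beta, abs=1e-9)


def test_fit_site_matches_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(1)
    n = 80
    level = rng.beta(2, 2, n)
    C = np.column_stack([rng.normal(17, 2, n), rng.integers(0, 2, n)])
    y = 10 + 25 * level + 0.5 * C[:, 0] + rng.normal(0, 5, n)
    fit = fit_site(y, level, C)
    ref = sm.OLS(y, sm.add_constant(np.column_stack([level, C]))).fit()
    assert fit.beta == pytest.approx(ref.params[1])
    assert fit.se == pytest.approx(ref.bse[1])
    assert fit.p == pytest.approx(ref.pvalues[1])


def test_fit_site_complete_case_and_errors():
    level = np.array([0.1, 0.5, np.nan, 0.9, 0.3, 0.7])
    y = 1 + 2 * level
    y[4] = np.nan
    fit = fit_site(y, level)
    assert fit.n == 4
    with pytest.raises(ValueError, match="variance"):
        fit_site(np.arange(6.0), np.full(6, 0.5))
    with pytest.raises(ValueError, match="samples"):
        fit_site(np.arange(3.0), np.array([0.1, 0.5, 0.9]),
                 np.eye(3))  # 5 parameters, 3 rows


def test_fit_site_drops_aliased_covariate():
    rng = np.random.default_rng(2)
    n = 30
    level = rng.beta(2, 2, n)
    c1 = rng.normal(size=n)
    C = np.column_stack([c1, 2 * c1])            # aliased pair
    y = 3 + 10 * level + c1 + rng.normal(0, 1, n)
    fit = fit_site(y, level, C)
    ref = fit_site(y, level, c1[:, None])
    assert fit.beta == pytest.approx(ref.beta)
    assert fit.se == pytest.approx(ref.se)


def test_beta_scales_with_phenotype_units():
    rng = np.random.default_rng(3)
    n = 60
    level = rng.beta(2, 2, n)
    y = 4 + 12 * level + rng.normal(0, 2, n)
    f1 = fit_site(y, level)
    f60 = fit_site(60 * y, level)
    assert f60.beta == pytest.approx(60 * f1.beta)
    assert f60.se == pytest.approx(60 * f1.se)
    assert f60.p == pytest.approx(f1.p)


def test_beta_invariant_to_covariate_centering():
    rng = np.random.default_rng(4)
    n = 60
    level = rng.beta(2, 2, n)
    C = rng.normal(size=(n, 2))
    y = 1 + 8 * level + C @ [1.0, -2.0] + rng.normal(0, 1, n)
    a = fit_site(y, level, C)
    b = fit_site(y, level, (C - C.mean(0)) / C.std(0))
    assert a.beta == pytest.approx(b.beta)
    assert a.p == pytest.approx(b.p)


# ------------------------------------------------------------------ BH

def test_bh_hand_examples():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5)
    np.testing.assert_allclose(bh_fdr([0.001, 1.0]), [0.002, 1.0])
    np.testing.assert_allclose(bh_fdr([0.2]), [0.2])  # m = 1


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_fdr([0.1, np.nan])


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 50))
def test_bh_q_dominates_p_and_is_monotone(seed, m):
    p = np.random.default_rng(seed).random(m)
    q = bh_fdr(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-15).all()
    # step-up oracle: independent textbook implementation
    ranked = np.empty(m)
    sorted_p = p[order]
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        ranked[order[i]] = running
    np.testing.assert_allclose(q, ranked, atol=1e-12)


def test_bh_rejections_match_textbook_rule():
    rng = np.random.default_rng(9)
    p = rng.random(200) ** 3
    q = bh_fdr(p)
    m = len(p)
    sorted_p = np.sort(p)
    ks = np.nonzero(sorted_p <= 0.05 * (np.arange(m) + 1) / m)[0]
    k = ks.max() + 1 if len(ks) else 0
    expected = set(np.argsort(p)[:k])
    assert set(np.nonzero(q < 0.05 + 1e-15)[0]) == expected or \
        set(np.nonzero(q <= 0.05)[0]) == expected


# ---------------------------------------------------------------- EWAS

def test_run_ewas_bookkeeping_and_alignment(filtered_callset, small_dataset):
    rec, skipped = ms.run_ewas(filtered_callset, small_dataset.cohort)
    assert len(rec) + len(skipped) == 9 * filtered_callset.n_sites
    assert set(rec["measure"]) <= set(ms.MEASURES)
    assert ((rec["q"] >= rec["p"] - 1e-15) & (rec["q"] <= 1)).all()
    # shuffling subject rows (ids kept) changes nothing
    shuffled = small_dataset.cohort.sample(frac=1, random_state=0)
    rec2, _ = ms.run_ewas(filtered_callset, shuffled)
    pd.testing.assert_frame_equal(rec, rec2)


def test_run_ewas_requires_overlapping_subjects(filtered_callset, small_dataset):
    other = small_dataset.cohort.copy()
    other.index = ["X" + s for s in other.index]
    with pytest.raises(ValueError, match="overlapping"):
        ms.run_ewas(filtered_callset, other)


def test_build_design_batch_one_hot(small_dataset):
    cohort = small_dataset.cohort
    X = build_design(cohort, list(cohort.index))
    n_batches = cohort["batch"].nunique()
    assert X.shape == (len(cohort), 4 + n_batches - 1)


def test_significant_summary_toy_counts():
    ann = pd.DataFrame({
        "site_id": ["s1", "s2", "s3", "s4", "s5"],
        "chrom": "chr1", "pos": range(5),
        "gene_id": ["gA", "gA", "gB", None, "gC"],
        "zone": ["intragenic", "upstream", "intragenic", "intergenic",
                 "intragenic"],
    })
    rows = []
    for m in ms.MEASURES:
        for s, q in [("s1", 0.01), ("s2", 0.2), ("s3", 0.04), ("s4", 0.01),
                     ("s5", 0.04)]:
            qq = q if m == "sol_sr" else 0.9
            rows.append((s, "chr1", 1, m, 1.0, 0.5, qq, 10, qq))
    rec = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "measure",
                                      "beta", "se", "p", "n", "q"])
    summary = ms.significant_summary(rec, ann, {"gB"})
    row = summary.loc["sol_sr"]
    # s1 (gA), s3 (gB), s5 (gC) significant & annotated; s4 intergenic ignored
    assert (row["genewide_genes"], row["genewide_sites"]) == (3, 3)
    assert (row["gwas_genes"], row["gwas_sites"]) == (1, 1)
    assert (summary.drop("sol_sr").to_numpy() == 0).all()
    assert (summary["gwas_sites"] <= summary["genewide_sites"]).all()
    assert (summary["gwas_genes"] <= summary["genewide_genes"]).all()
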
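"""Per-site covariate-adjusted association and FDR control.

For each retained CpG site and each of the nine sleep measures, the
sleep measure is regressed on the site's methylation proportion by
ordinary least squares, adjusting for age, sex, race, BMI percentile
and sequencing batch (one-hot, first batch reference):

    measure_s = b0 + b1 * level_is + g' covariates_s + e_s

The reported effect ``beta`` is b1 — phenotype units per unit change in
methylation proportion, i.e. per 100% methylation change (minutes for
SOL, hours for bedtime and SOT).  p-values are two-sided t-tests on b1
with residual degrees of freedom; Benjamini–Hochberg q-values are
computed within each measure across its estimable sites.  Each site is
fit complete-case: samples masked at that site are dropped from that
site's fit only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import MethylationCallSet
from .phenotypes import MEASURES

log = logging.getLogger(__name__)

__all__ = [
    "SiteFit",
    "fit_site",
    "build_design",
    "run_ewas",
    "bh_fdr",
    "significant_summary",
]


@dataclass(frozen=True)
class SiteFit:
    beta: float
    se: float
    p: float
    n: int


def fit_site(y, level, covariates=None) -> SiteFit:
    """OLS of a phenotype on [1, methylation level, covariates].

    Rows with a NaN anywhere are dropped (complete-case).  Requires the
    remaining n to exceed the parameter count by at least one residual
    degree of freedom and the methylation levels to vary.  An aliased
    covariate column (rank deficiency) is dropped with a warning; the
    methylation column itself is never dropped.

    Raises ``ValueError`` when the fit is not estimable (too few
    samples, or zero methylation variance).
    """
    y = np.asarray(y, dtype=float)
    level = np.asarray(level, dtype=float)
    if covariates is None:
        covariates = np.empty((len(y), 0))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    keep = np.isfinite(y) & np.isfinite(level) & np.all(np.isfinite(C), axis=1)
    y, level, C = y[keep], level[keep], C[keep]
    n = len(y)
    X = np.column_stack([np.ones(n), level, C])
    if n < X.shape[1] + 1:
        raise ValueError(f"only {n} usable samples for {X.shape[1]} parameters")
    if np.ptp(level) == 0:
        raise ValueError("zero methylation variance")

    rank = np.linalg.matrix_rank(X)
    while rank < X.shape[1]:
        # drop the last aliased covariate column (never intercept/level)
        dropped = False
        for j in range(X.shape[1] - 1, 1, -1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                log.warning("dropping aliased covariate column %d", j)
                X, dropped = Xr, True
                break
        if not dropped:
            raise ValueError("design irreducibly rank deficient")
        rank = np.linalg.matrix_rank(X)

    k = X.shape[1]
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(beta_hat[1])
    if se == 0.0:
        p = 0.0 if beta != 0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(beta / se), df))
    return SiteFit(beta=beta, se=se, p=p, n=n)


def build_design(phenotypes: pd.DataFrame, subjects) -> np.ndarray:
    """Covariate matrix for the given subjects (row order preserved).

    Age, male, minority and BMI percentile enter as numeric columns;
    batch as one-hot indicators with the first (sorted) batch as
    reference.  Missing covariates become NaN rows, dropped per fit.
    """
    sub = phenotypes.reindex([str(s) for s in subjects])
    cols = [sub[c].astype(float).to_numpy()
            for c in ("age", "male", "minority", "bmi_pct") if c in sub.columns]
    if "batch" in sub.columns:
        dummies = pd.get_dummies(sub["batch"].astype(str), drop_first=True,
                                 dtype=float)
        # a subject with missing batch gets NaN indicators -> complete-case drop
        dummies[sub["batch"].isna().to_numpy()] = np.nan
        for c in sorted(dummies.columns):
            cols.append(dummies[c].to_numpy())
    if not cols:
        return np.empty((len(sub), 0))
    return np.column_stack(cols)


def run_ewas(callset: MethylationCallSet, phenotypes: pd.DataFrame,
             measures=None) -> tuple[pd.DataFrame, list[dict]]:
    """Fit every (retained site, measure) pair and control FDR per measure.

    Subjects are aligned by id between the call set's sample list and
    the phenotype table's index; at least one overlapping subject is
    required.  Returns the association records (site_id, chrom, pos,
    measure, beta, se, p, q, n) and a skip log accounting for every
    (site, measure) pair without a record.
    """
    measures = list(measures) if measures is not None else list(MEASURES)
    common = [s for s in callset.samples if s in phenotypes.index]
    if not common:
        raise ValueError("no overlapping subjects between call set and phenotypes")
    cols = [callset.samples.index(s) for s in common]
    levels = callset.level[:, cols]
    C = build_design(phenotypes, common)

    records, skipped = [], []
    for measure in measures:
        if measure not in phenotypes.columns:
            raise KeyError(f"measure {measure!r} missing from phenotype table")
        y = phenotypes[measure].reindex(common).astype(float).to_numpy()
        rows = []
        for i in range(callset.n_sites):
            sid = callset.sites.index[i]
            try:
                fit = fit_site(y, levels[i], C)
            except ValueError as err:
                skipped.append({"site_id": sid, "measure": measure,
                                "reason": str(err)})
                continue
            rows.append((sid, callset.sites["chrom"].iloc[i],
                         int(callset.sites["pos"].iloc[i]), measure,
                         fit.beta, fit.se, fit.p, fit.n))
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "measure",
                                         "beta", "se", "p", "n"])
        df["q"] = bh_fdr(df["p"].to_numpy())
        records.append(df)
    out = (pd.concat(records, ignore_index=True) if records else
           pd.DataFrame(columns=["site_id", "chrom", "pos", "measure",
                                 "beta", "se", "p", "n", "q"]))
    return out, skipped


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min_{j>=i} min(1, p_(j) * m / j) over the m input p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_summary(records: pd.DataFrame, annotated: pd.DataFrame,
                        gwas_set: set[str], q_threshold: float = 0.05
                        ) -> pd.DataFrame:
    """Per-measure counts of significant gene sites and unique genes.

    Mirrors the headline summary-table shape: for each measure, the
    number of annotated (non-intergenic) sites with q below threshold
    and the number of unique genes containing them, for the gene-wide
    analysis and restricted to the GWAS-informed gene set.  A site is
    counted once per group regardless of how many genes it maps to.
    """
    mapped = annotated[annotated["zone"] != "intergenic"]
    site2genes = mapped.groupby("site_id")["gene_id"].agg(set)
    rows = []
    for measure in MEASURES:
        rec = records[(records["measure"] == measure)
                      & (records["q"] < q_threshold)]
        sig = [s for s in rec["site_id"] if s in site2genes.index]
        genes = set().union(*site2genes.loc[sig]) if sig else set()
        gwas_sites = [s for s in sig if site2genes[s] & gwas_set]
        gwas_genes = (set().union(*(site2genes[s] & gwas_set
                                    for s in gwas_sites))
                      if gwas_sites else set())
        rows.append((measure, len(genes), len(sig),
                     len(gwas_genes), len(gwas_sites)))
    return pd.DataFrame(rows, columns=[
        "measure", "genewide_genes", "genewide_sites",
        "gwas_genes", "gwas_sites"]).set_index("measure")
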
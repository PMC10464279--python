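"""Gene-set enrichment of nominal association hits, and GO over-representation.

The question: among the analyzable CpG sites that map to genes, are the
sites nominally associated with a sleep measure (p < 0.05) over-represented
within a prespecified (GWAS-informed) gene set?

Two tests are run per measure:

* **hypergeometric** — at the site level.  Universe N = annotated
  (non-intergenic) analyzable sites, K = nominal hits among them, n =
  sites in the gene group, k = observed hits in the group; the p-value
  is the upper tail P(X >= k).
* **permutation** — by default at the *gene* level: null replicates draw
  random gene subsets of the same gene count from the annotated gene
  universe and recount hit sites in the drawn genes, preserving the
  intra-gene clustering of sites under the null.  A site-level null
  (random site subsets of size n) is available via ``null_unit``.
  p = (1 + #{null >= observed}) / (n_perm + 1), never below
  1/(n_perm + 1), and bit-reproducible given a seed.

GO over-representation is at the gene level: universe = annotated genes
with at least one analyzable site; "significant" genes contain at least
one site with q < 0.05; per-term one-sided hypergeometric with BH
adjustment within each ontology.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import INTERGENIC
from .association import bh_fdr

__all__ = [
    "EnrichmentReport",
    "hypergeom_enrichment",
    "permutation_enrichment",
    "enrich_measure",
    "go_enrichment",
    "gene_overlap",
]


@dataclass(frozen=True)
class EnrichmentReport:
    """Both enrichment tests for one sleep measure."""
    measure: str
    n_universe: int        # N: annotated analyzable sites
    n_hits: int            # K: sites with p < p_threshold
    n_group: int           # n: GWAS-informed sites
    n_overlap: int         # k: hits inside the group
    p_hypergeometric: float
    p_permutation: float
    n_permutations: int
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts successes when drawing ``n`` items without replacement from
    ``N`` of which ``K`` are successes.
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    # sf(k-1) = P(X >= k); clip guards tiny negative rounding
    return float(min(1.0, max(stats.hypergeom.sf(k - 1, N, K, n), 0.0)))


def _site_gene_table(annotated: pd.DataFrame, site_p: pd.Series) -> pd.DataFrame:
    """Non-intergenic (site, gene) mappings restricted to sites with a p-value."""
    mapped = annotated[annotated["zone"] != INTERGENIC]
    mapped = mapped[mapped["site_id"].isin(site_p.index)]
    return mapped[["site_id", "gene_id"]]


def permutation_enrichment(annotated: pd.DataFrame, site_p: pd.Series,
                           gwas_set: set[str], n_perm: int = 1000,
                           seed: int = 0, p_threshold: float = 0.05,
                           null_unit: str = "gene") -> tuple[float, int]:
    """Permutation p-value for over-representation of nominal hits.

    Returns ``(p, observed)`` where observed is the count of sites with
    p < ``p_threshold`` mapping to ``gwas_set``.  See the module
    docstring for the two null units.
    """
    if null_unit not in ("gene", "site"):
        raise ValueError("null_unit must be 'gene' or 'site'")
    tab = _site_gene_table(annotated, site_p)
    genes = tab["gene_id"].drop_duplicates().sort_values().to_numpy()
    group_genes = np.array(sorted(set(gwas_set) & set(genes)))
    if len(group_genes) == 0:
        raise ValueError("GWAS-informed set shares no gene with the universe")
    if len(group_genes) > len(genes):
        raise ValueError("gene universe smaller than the GWAS-informed set")

    hit_sites = set(site_p.index[site_p < p_threshold])
    is_hit = tab["site_id"].isin(hit_sites).to_numpy()

    # per-gene site and hit-site counts (a multi-gene site counts toward
    # each of its genes in the gene-level null)
    per_gene = tab.assign(hit=is_hit).groupby("gene_id")["hit"]
    gene_sites = per_gene.size().reindex(genes).to_numpy()
    gene_hits = per_gene.sum().reindex(genes).to_numpy().astype(int)

    in_group = tab["gene_id"].isin(group_genes).to_numpy()
    observed = tab.loc[in_group & is_hit, "site_id"].nunique()

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    if null_unit == "gene":
        g = len(group_genes)
        for b in range(n_perm):
            idx = rng.choice(len(genes), size=g, replace=False)
            null[b] = gene_hits[idx].sum()
    else:
        sites = tab["site_id"].drop_duplicates().sort_values().to_numpy()
        site_hit = np.isin(sites, list(hit_sites))
        n_group = tab.loc[in_group, "site_id"].nunique()
        for b in range(n_perm):
            idx = rng.choice(len(sites), size=n_group, replace=False)
            null[b] = site_hit[idx].sum()
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return float(p), int(observed)


def enrich_measure(measure: str, annotated: pd.DataFrame, records: pd.DataFrame,
                   gwas_set: set[str], n_perm: int = 1000, seed: int = 0,
                   p_threshold: float = 0.05,
                   null_unit: str = "gene") -> EnrichmentReport:
    """Run both enrichment tests for one measure's association records."""
    rec = records[records["measure"] == measure].set_index("site_id")
    site_p = rec["p"]
    tab = _site_gene_table(annotated, site_p)
    universe_sites = tab["site_id"].drop_duplicates()
    N = len(universe_sites)
    hits = set(site_p.index[site_p < p_threshold]) & set(universe_sites)
    K = len(hits)
    in_group = tab["gene_id"].isin(gwas_set)
    group_sites = set(tab.loc[in_group, "site_id"])
    n = len(group_sites)
    k = len(group_sites & hits)
    p_hyp = hypergeom_enrichment(N, K, n, k)
    p_perm, _ = permutation_enrichment(annotated, site_p, gwas_set,
                                       n_perm=n_perm, seed=seed,
                                       p_threshold=p_threshold,
                                       null_unit=null_unit)
    return EnrichmentReport(measure=measure, n_universe=N, n_hits=K,
                            n_group=n, n_overlap=k, p_hypergeometric=p_hyp,
                            p_permutation=p_perm, n_permutations=n_perm,
                            seed=seed)


def go_enrichment(significant_genes: set[str], universe: set[str],
                  term_map: pd.DataFrame) -> pd.DataFrame:
    """Per-term gene-level over-representation of significant genes.

    ``term_map`` carries columns gene_id, term_id, term_name, ontology
    (taken as given — no ontology-graph propagation).  Only universe
    genes count toward term sizes; q-values are BH within each ontology.
    Returns a DataFrame (term_id, term_name, ontology, n_term, mapped,
    p, q) sorted by (ontology, p, term_id); empty significant set gives
    an empty frame.
    """
    tm = term_map[term_map["gene_id"].isin(universe)]
    if tm.empty:
        raise ValueError("term map covers no gene in the universe")
    if not set(significant_genes) <= set(universe):
        raise ValueError("significant genes must be a subset of the universe")
    if not significant_genes:
        return pd.DataFrame(columns=["term_id", "term_name", "ontology",
                                     "n_term", "mapped", "p", "q"])
    N, K = len(universe), len(significant_genes)
    rows = []
    for (tid, tname, onto), grp in tm.groupby(
            ["term_id", "term_name", "ontology"], sort=True):
        term_genes = set(grp["gene_id"])
        n_term = len(term_genes)
        mapped = len(term_genes & significant_genes)
        p = hypergeom_enrichment(N, K, n_term, mapped)
        rows.append((tid, tname, onto, n_term, mapped, p))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "ontology",
                                      "n_term", "mapped", "p"])
    out["q"] = np.nan
    for onto, idx in out.groupby("ontology").groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return (out.sort_values(["ontology", "p", "term_id"], kind="mergesort")
            .reset_index(drop=True))


def gene_overlap(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise (and all-measure) intersections of significant gene sets.

    Returns one row per measure pair plus, when all three methods of a
    construct are present (e.g. sol_sr/sol_act/sol_psg), a triple row —
    the "associated by all three methods" report.  Columns: measures
    (``+``-joined), n_overlap, genes (comma-joined sorted members).
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two measures to intersect")
    rows = []
    names = sorted(gene_sets)
    for a, b in combinations(names, 2):
        inter = gene_sets[a] & gene_sets[b]
        rows.append((f"{a}+{b}", len(inter), ",".join(sorted(inter))))
    for construct in ("bedtime", "sol", "sot"):
        trio = [f"{construct}_{m}" for m in ("sr", "act", "psg")]
        if all(t in gene_sets for t in trio):
            inter = gene_sets[trio[0]] & gene_sets[trio[1]] & gene_sets[trio[2]]
            rows.append(("+".join(trio), len(inter), ",".join(sorted(inter))))
    return pd.DataFrame(rows, columns=["measures", "n_overlap", "genes"])
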
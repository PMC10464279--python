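"""CpG-site-to-gene annotation with extended gene borders.

Gene bodies are single intervals per gene id (1-based inclusive
internally; BED6 on disk, converted at the boundary).  Borders are
extended 1500 bp upstream and 500 bp downstream of the gene boundaries
before overlap testing; by default the extension is strand-aware
(upstream means 5' of the gene), with an unstranded mode that applies
−1500/+500 in genomic coordinates regardless of strand.

A site overlapping no extended interval is intergenic; a site may map
to several genes and every mapping is kept.  The per-gene zone is
``intragenic`` when the site lies within the original gene body, else
``upstream``/``downstream`` by which extension flank contains it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "extend_gene",
    "annotate_sites",
    "site_groups",
    "read_bed6",
    "write_bed6",
    "read_gene_set",
    "read_term_map",
    "INTERGENIC",
]

UPSTREAM_BP = 1500
DOWNSTREAM_BP = 500
INTERGENIC = "intergenic"


def extend_gene(start: int, end: int, strand: str,
                upstream: int = UPSTREAM_BP, downstream: int = DOWNSTREAM_BP,
                stranded: bool = True) -> tuple[int, int]:
    """Extended interval (1-based inclusive) around a gene body.

    For a + strand gene [start-upstream, end+downstream]; for a − strand
    gene the flanks are mirrored.  With ``stranded=False`` every gene is
    treated as + strand.  Clipped at position 1.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("extensions must be >= 0")
    if start > end:
        raise ValueError("gene start > end")
    if strand == "-" and stranded:
        lo, hi = start - downstream, end + upstream
    else:
        lo, hi = start - upstream, end + downstream
    return max(lo, 1), hi


def annotate_sites(sites: pd.DataFrame, genes: pd.DataFrame,
                   upstream: int = UPSTREAM_BP, downstream: int = DOWNSTREAM_BP,
                   stranded: bool = True) -> pd.DataFrame:
    """Map every CpG site to the genes whose extended borders contain it.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based), indexed by
        site id.
    genes
        DataFrame with columns ``chrom``, ``start``, ``end`` (1-based
        inclusive), ``strand`` and index gene id.

    Returns
    -------
    Long-format DataFrame with one row per (site, gene) mapping plus one
    row per intergenic site, columns ``site_id``, ``chrom``, ``pos``,
    ``gene_id`` (NaN for intergenic) and ``zone`` (intragenic, upstream,
    downstream, or intergenic).  Order follows the input site order,
    then gene id — independent of input ordering of either table.
    """
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene model with start > end")
    if genes.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    trees: dict[str, IntervalTree] = {}
    bodies: dict[str, tuple[int, int, str]] = {}
    for gid, g in genes.sort_index().iterrows():
        lo, hi = extend_gene(int(g["start"]), int(g["end"]), g["strand"],
                             upstream, downstream, stranded)
        # IntervalTree is half-open; +1 converts the inclusive end.
        trees.setdefault(g["chrom"], IntervalTree()).addi(lo, hi + 1, gid)
        bodies[gid] = (int(g["start"]), int(g["end"]), g["strand"])

    missing = set(sites["chrom"]) - set(trees)
    if missing and len(genes):
        log.warning("no gene models on %s; sites there become intergenic",
                    sorted(missing))

    rows = []
    for sid, s in sites.iterrows():
        pos = int(s["pos"])
        hits = sorted(iv.data for iv in trees.get(s["chrom"], IntervalTree())[pos])
        if not hits:
            rows.append((sid, s["chrom"], pos, np.nan, INTERGENIC))
            continue
        for gid in hits:
            start, end, strand = bodies[gid]
            if start <= pos <= end:
                zone = "intragenic"
            elif pos < start:
                zone = ("upstream" if strand == "+" or not stranded
                        else "downstream")
            else:
                zone = ("downstream" if strand == "+" or not stranded
                        else "upstream")
            rows.append((sid, s["chrom"], pos, gid, zone))
    return pd.DataFrame(rows,
                        columns=["site_id", "chrom", "pos", "gene_id", "zone"])


def site_groups(annotated: pd.DataFrame, gwas_set: set[str]
                ) -> tuple[set, set]:
    """Split annotated sites into gene-wide and GWAS-informed groups.

    Gene-wide = every non-intergenic site; GWAS-informed = the subset
    mapping to at least one gene in ``gwas_set`` (always a subset of
    gene-wide).  GWAS genes absent from the annotation's gene universe
    are dropped with a warning.
    """
    if not gwas_set:
        raise ValueError("empty GWAS-informed gene set")
    mapped = annotated[annotated["zone"] != INTERGENIC]
    universe = set(mapped["gene_id"].dropna())
    stray = set(gwas_set) - universe
    if stray:
        log.warning("%d GWAS-informed gene(s) absent from the gene universe "
                    "dropped: %s", len(stray), sorted(stray)[:10])
    usable = set(gwas_set) & universe
    gene_wide = set(mapped["site_id"])
    gwas_sites = set(mapped.loc[mapped["gene_id"].isin(usable), "site_id"])
    return gene_wide, gwas_sites


def read_bed6(path) -> pd.DataFrame:
    """Read BED6 gene models (0-based half-open on disk -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "name": str})
    if df["name"].duplicated().any():
        raise ValueError(f"duplicate gene names in {path}")
    out = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "start": df["start"].to_numpy() + 1,
        "end": df["end"].to_numpy(),
        "strand": df["strand"].to_numpy(),
    }, index=pd.Index(df["name"], name="gene_id"))
    if not out["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return out


def write_bed6(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene models as BED6 (0-based half-open)."""
    pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(int) - 1,
        "end": genes["end"].astype(int),
        "name": genes.index,
        "score": 0,
        "strand": genes["strand"],
    }).to_csv(path, sep="\t", header=False, index=False)


def read_gene_set(path) -> set[str]:
    """Plain-text gene list, one id per line; blank lines and # comments skipped."""
    with open(path) as fh:
        genes = {line.strip() for line in fh
                 if line.strip() and not line.startswith("#")}
    if not genes:
        raise ValueError(f"gene-set file {path} is empty")
    return genes


def read_term_map(path) -> pd.DataFrame:
    """Gene->term TSV with columns gene_id, term_id, term_name, ontology."""
    df = pd.read_csv(path, sep="\t",
                     names=["gene_id", "term_id", "term_name", "ontology"],
                     header=0 if _has_header(path) else None, dtype=str)
    if df.empty:
        raise ValueError(f"term map {path} is empty")
    return df.drop_duplicates(["gene_id", "term_id"])


def _has_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.lower().startswith("gene_id")
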
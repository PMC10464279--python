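"""End-to-end orchestration: filter -> associate -> annotate -> summarize
-> enrich -> GO -> top tables -> overlaps, with a machine-readable manifest.

All stage outputs are plain TSV/CSV/JSON in the run directory, every
summary number is recomputable from them, and one root seed drives the
permutation stage — rerunning the same config reproduces byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (INTERGENIC, annotate_sites, read_bed6, read_gene_set,
                         read_term_map)
from .association import run_ewas, significant_summary
from .enrichment import enrich_measure, gene_overlap, go_enrichment
from .methylation import (MethylationCallSet, apply_site_filters,
                          read_coverage_files, write_level_matrix)
from .phenotypes import MEASURES, load_phenotypes

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_top_table"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Inputs, thresholds and settings for one pipeline run."""
    coverage_files: list[str]
    sample_ids: list[str]
    phenotype_file: str
    gene_model_file: str
    gwas_gene_file: str
    term_map_file: str | None = None
    out_dir: str = "run"
    min_coverage: int = 10
    min_sample_fraction: float = 0.5
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    upstream: int = 1500
    downstream: int = 500
    stranded: bool = True
    n_permutations: int = 1000
    null_unit: str = "gene"
    top_n: int = 10
    measures: list[str] = field(default_factory=lambda: list(MEASURES))
    seed: int = 0

    def validate(self) -> None:
        for p in [self.phenotype_file, self.gene_model_file,
                  self.gwas_gene_file, *self.coverage_files] + (
                      [self.term_map_file] if self.term_map_file else []):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if len(self.coverage_files) != len(self.sample_ids):
            raise ValueError("one sample id per coverage file required")
        for name in ("q_threshold", "p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def make_top_table(records: pd.DataFrame, annotated: pd.DataFrame,
                   top_n: int = 10) -> pd.DataFrame:
    """Top-N association rows for one measure, sorted by q.

    One row per site; a site mapping to several genes lists them
    comma-joined, with the zone per gene in the same order.  Ties in q
    break deterministically by (chrom, pos).
    """
    mapped = annotated[annotated["zone"] != INTERGENIC]
    gene_join = (mapped.sort_values("gene_id")
                 .groupby("site_id")
                 .agg(gene=("gene_id", ",".join), zone=("zone", ",".join)))
    out = records.merge(gene_join, left_on="site_id", right_index=True,
                        how="inner")
    out = out.sort_values(["q", "chrom", "pos"], kind="mergesort").head(top_n)
    return out[["chrom", "pos", "gene", "beta", "se", "q", "zone"]].reset_index(
        drop=True)


def _write(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=_FLOAT_FMT, **kw)
    return len(df)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Any stage failure raises with the stage named; artifacts written
    before the failure are retained.  Returns the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_coverage": config.min_coverage,
            "min_sample_fraction": config.min_sample_fraction,
            "q_threshold": config.q_threshold,
            "p_threshold": config.p_threshold,
        },
        "stages": {},
    }
    stage = "load"
    try:
        callset = read_coverage_files(config.coverage_files, config.sample_ids)
        phenotypes = load_phenotypes(config.phenotype_file)
        genes = read_bed6(config.gene_model_file)
        gwas = read_gene_set(config.gwas_gene_file)
        manifest["stages"]["load"] = {
            "sites_in": callset.n_sites, "samples": callset.n_samples,
            "subjects": len(phenotypes), "genes": len(genes),
            "gwas_genes": len(gwas)}

        stage = "filter"
        filtered = apply_site_filters(callset, config.min_coverage,
                                      config.min_sample_fraction)
        write_level_matrix(filtered, out / "filtered_levels.tsv")
        manifest["stages"]["filter"] = {
            "sites_in": callset.n_sites,
            "sites_retained": filtered.n_sites,
            "sites_dropped": callset.n_sites - filtered.n_sites}

        stage = "associate"
        records, skipped = run_ewas(filtered, phenotypes, config.measures)
        _write(records, out / "association_records.tsv")
        pd.DataFrame(skipped).to_csv(out / "association_skipped.tsv",
                                     sep="\t", index=False)
        manhattan = records[["measure", "chrom", "pos", "p"]].copy()
        with np.errstate(divide="ignore"):
            manhattan["neg_log10_p"] = -np.log10(manhattan.pop("p"))
        _write(manhattan, out / "manhattan.tsv")
        manifest["stages"]["associate"] = {
            "records": len(records), "skipped": len(skipped)}

        stage = "annotate"
        annotated = annotate_sites(filtered.sites, genes,
                                   config.upstream, config.downstream,
                                   config.stranded)
        _write(annotated, out / "annotation.tsv")
        n_intergenic = int((annotated["zone"] == INTERGENIC).sum())
        manifest["stages"]["annotate"] = {
            "mappings": len(annotated) - n_intergenic,
            "intergenic_sites": n_intergenic,
            "annotated_sites": int(
                annotated.loc[annotated["zone"] != INTERGENIC,
                              "site_id"].nunique()),
            "genes_hit": int(annotated["gene_id"].nunique())}

        stage = "summarize"
        summary = significant_summary(records, annotated, gwas,
                                      config.q_threshold)
        summary.reset_index().pipe(_write, out / "significant_summary.tsv")
        manifest["stages"]["summarize"] = {
            "total_significant_sites": int(summary["genewide_sites"].sum())}

        stage = "enrich"
        reports = []
        for i, measure in enumerate(config.measures):
            if records[records["measure"] == measure].empty:
                continue
            reports.append(enrich_measure(
                measure, annotated, records, gwas,
                n_perm=config.n_permutations,
                seed=(config.seed * 1009 + i) % (2**31),
                p_threshold=config.p_threshold,
                null_unit=config.null_unit).as_dict())
        enrich_df = pd.DataFrame(reports)
        _write(enrich_df, out / "enrichment.tsv")
        Path(out / "enrichment.json").write_text(
            json.dumps(reports, indent=2, sort_keys=True) + "\n")
        manifest["stages"]["enrich"] = {"measures_tested": len(reports)}

        stage = "go"
        mapped = annotated[annotated["zone"] != INTERGENIC]
        universe = set(mapped["gene_id"].dropna())
        go_rows = 0
        if config.term_map_file:
            term_map = read_term_map(config.term_map_file)
            frames = []
            for measure in config.measures:
                rec = records[(records["measure"] == measure)
                              & (records["q"] < config.q_threshold)]
                sig_genes = set(mapped.loc[
                    mapped["site_id"].isin(rec["site_id"]), "gene_id"])
                res = go_enrichment(sig_genes & universe, universe, term_map)
                res.insert(0, "measure", measure)
                if not res.empty:
                    frames.append(res)
            go_df = (pd.concat(frames, ignore_index=True) if frames else
                     pd.DataFrame(columns=["measure", "term_id", "term_name",
                                           "ontology", "n_term", "mapped",
                                           "p", "q"]))
            go_rows = _write(go_df, out / "go_enrichment.tsv")
        manifest["stages"]["go"] = {"rows": go_rows}

        stage = "report"
        site2genes = mapped.groupby("site_id")["gene_id"].agg(set)
        gene_sets: dict[str, set] = {}
        for measure in config.measures:
            rec = records[records["measure"] == measure]
            top = make_top_table(rec, annotated, config.top_n)
            _write(top, out / f"top_{measure}.tsv")
            sig = [s for s in rec.loc[rec["q"] < config.q_threshold, "site_id"]
                   if s in site2genes.index]
            gene_sets[measure] = set().union(*site2genes.loc[sig]) if sig else set()
        if len(gene_sets) >= 2:
            _write(gene_overlap(gene_sets), out / "gene_overlaps.tsv")
        manifest["stages"]["report"] = {
            "significant_genes": {m: len(g) for m, g in sorted(gene_sets.items())}}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "run_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return out
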
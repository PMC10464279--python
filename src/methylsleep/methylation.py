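"""Per-CpG methylation call sets: I/O and site filtering.

The pipeline starts from per-sample bisulfite methylation calls in the
Bismark-coverage dialect (TSV: chrom, start, end, methylation %, count
methylated, count unmethylated; 1-based inclusive, start == end for a
CpG).  Counts are authoritative — the percentage column is recomputed
and only compared as a consistency check.

Filtering follows the standard RRBS two-stage rule: a site x sample
cell is *available* iff its coverage (meth + unmeth reads) is at least
``min_coverage``; a site is retained iff it is available in at least
``min_sample_fraction`` of *all* samples.  Unavailable cells at
retained sites are masked, never imputed: each site's regression is
complete-case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MethylationCallSet",
    "read_coverage_files",
    "write_coverage_file",
    "apply_site_filters",
    "write_level_matrix",
    "read_level_matrix",
]


def site_ids(chrom, pos) -> pd.Index:
    """Canonical ``chrom:pos`` site identifiers."""
    return pd.Index([f"{c}:{p}" for c, p in zip(chrom, pos)], name="site_id")


@dataclass
class MethylationCallSet:
    """Sites x samples matrices of methylated/unmethylated read counts.

    ``sites`` is a DataFrame (index site_id, columns chrom, pos) in the
    row order of the count matrices; ``samples`` gives the column order.
    ``min_coverage`` records the availability threshold once
    :func:`apply_site_filters` has run; before filtering it is 1 (any
    covered cell defines a level).
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    unmeth: np.ndarray
    min_coverage: int = 1

    def __post_init__(self):
        self.meth = np.asarray(self.meth)
        self.unmeth = np.asarray(self.unmeth)
        shape = (len(self.sites), len(self.samples))
        if self.meth.shape != shape or self.unmeth.shape != shape:
            raise ValueError(f"count matrices must have shape {shape}")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def available(self) -> np.ndarray:
        """Boolean mask: cell carries an analyzable methylation level."""
        return self.coverage >= max(self.min_coverage, 1)

    @property
    def level(self) -> np.ndarray:
        """Methylation proportion meth/(meth+unmeth); NaN where unavailable."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(cov > 0, self.meth / np.where(cov > 0, cov, 1), np.nan)
        lv[~self.available] = np.nan
        return lv


def read_coverage_files(paths, sample_ids) -> MethylationCallSet:
    """Read one Bismark-coverage-style TSV per sample into a call set.

    Sites are the union across samples; a sample lacking a site gets
    zero coverage there.  Duplicate (chrom, pos) within one file is an
    error; a percentage column inconsistent with the counts (beyond
    0.05) is logged as a warning and ignored.
    """
    paths = list(paths)
    sample_ids = [str(s) for s in sample_ids]
    if len(paths) != len(sample_ids):
        raise ValueError("need exactly one path per sample id")
    frames = []
    for path, sid in zip(paths, sample_ids):
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "pct", "meth", "unmeth"],
            dtype={"chrom": str},
        )
        if df.isna().any().any():
            raise ValueError(f"malformed line(s) in {path}")
        if df.duplicated(["chrom", "start"]).any():
            raise ValueError(f"duplicate (chrom, pos) in {path}")
        cov = df["meth"] + df["unmeth"]
        with np.errstate(invalid="ignore"):
            pct = np.where(cov > 0, 100.0 * df["meth"] / cov.where(cov > 0, 1), 0.0)
        if np.nanmax(np.abs(pct - df["pct"].to_numpy()), initial=0.0) > 0.05:
            log.warning(
                "%s: percentage column inconsistent with counts; counts win", path
            )
        frames.append(pd.DataFrame({
            "chrom": df["chrom"], "pos": df["start"].astype(int),
            "meth": df["meth"].astype(int), "unmeth": df["unmeth"].astype(int),
            "sample": sid,
        }))
    allcalls = pd.concat(frames, ignore_index=True)
    sites = (allcalls[["chrom", "pos"]].drop_duplicates()
             .sort_values(["chrom", "pos"], kind="mergesort")
             .reset_index(drop=True))
    if (sites["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    sites.index = site_ids(sites["chrom"], sites["pos"])
    row = {sid: i for i, sid in enumerate(sites.index)}
    col = {s: j for j, s in enumerate(sample_ids)}
    meth = np.zeros((len(sites), len(sample_ids)), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    r = np.fromiter(
        (row[f"{c}:{p}"] for c, p in zip(allcalls["chrom"], allcalls["pos"])),
        dtype=np.int64, count=len(allcalls))
    c = np.fromiter((col[s] for s in allcalls["sample"]),
                    dtype=np.int64, count=len(allcalls))
    meth[r, c] = allcalls["meth"].to_numpy()
    unmeth[r, c] = allcalls["unmeth"].to_numpy()
    return MethylationCallSet(sites=sites, samples=sample_ids,
                              meth=meth, unmeth=unmeth)


def write_coverage_file(callset: MethylationCallSet, sample: str, path) -> None:
    """Write one sample's calls in the Bismark-coverage dialect.

    Cells with zero coverage are omitted (the site was not observed in
    that sample).
    """
    j = callset.samples.index(sample)
    m, u = callset.meth[:, j], callset.unmeth[:, j]
    cov = m + u
    keep = cov > 0
    with np.errstate(invalid="ignore"):
        pct = np.where(keep, 100.0 * m / np.where(keep, cov, 1), 0.0)
    df = pd.DataFrame({
        "chrom": callset.sites["chrom"].to_numpy()[keep],
        "start": callset.sites["pos"].to_numpy()[keep],
        "end": callset.sites["pos"].to_numpy()[keep],
        "pct": np.round(pct[keep], 6),
        "meth": m[keep], "unmeth": u[keep],
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def apply_site_filters(callset: MethylationCallSet,
                       min_coverage: int = 10,
                       min_sample_fraction: float = 0.5) -> MethylationCallSet:
    """Drop sites with inadequate coverage or availability.

    A cell is available iff coverage >= ``min_coverage``; a site is
    retained iff available in >= ``min_sample_fraction`` of all samples
    (exactly-at-threshold retained — only strictly-below is excluded).
    The returned call set carries ``min_coverage`` so that cells below
    threshold stay masked downstream.

    Idempotent, and monotone: raising either threshold never adds sites.
    """
    if callset.n_sites == 0 or callset.n_samples == 0:
        raise ValueError("cannot filter an empty call set")
    if min_coverage < 0 or not (0.0 <= min_sample_fraction <= 1.0):
        raise ValueError("thresholds out of range")
    avail = callset.coverage >= max(min_coverage, 1) if min_coverage > 0 \
        else np.ones_like(callset.meth, dtype=bool)
    frac = avail.sum(axis=1) / callset.n_samples
    keep = frac >= min_sample_fraction
    return MethylationCallSet(
        sites=callset.sites.loc[keep].copy(),
        samples=list(callset.samples),
        meth=callset.meth[keep],
        unmeth=callset.unmeth[keep],
        min_coverage=max(min_coverage, 1),
    )


def write_level_matrix(callset: MethylationCallSet, path) -> None:
    """Wide TSV of per-sample levels and coverages for a (filtered) set."""
    lv, cov = callset.level, callset.coverage
    cols = {"chrom": callset.sites["chrom"], "pos": callset.sites["pos"]}
    for j, s in enumerate(callset.samples):
        cols[f"level.{s}"] = np.round(lv[:, j], 8)
        cols[f"cov.{s}"] = cov[:, j]
    out = pd.DataFrame(cols, index=callset.sites.index)
    out.to_csv(path, sep="\t", index=True, index_label="site_id", na_rep="NA")


def read_level_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site_id", na_values="NA")
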
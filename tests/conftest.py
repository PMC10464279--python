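import numpy as np
import pandas as pd
import pytest

import methylsleep as ms


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with one planted bedtime effect."""
    cfg = ms.SimulationConfig(
        n_subjects=60, n_genes=40, n_intergenic_sites=80, seed=11,
        planted_effects=(ms.PlantedEffect("G0002", "bedtime_psg", 2.0),))
    return ms.generate_dataset(cfg)


@pytest.fixture(scope="session")
def filtered_callset(small_dataset):
    return ms.apply_site_filters(small_dataset.callset)


@pytest.fixture()
def toy_sites():
    chrom = ["chr1"] * 4
    pos = [50, 150, 250, 350]
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos},
        index=pd.Index([f"chr1:{p}" for p in pos], name="site_id"))


def brute_force_filter(coverage: np.ndarray, min_coverage: int,
                       min_fraction: float) -> np.ndarray:
    """Independent cell-by-cell scan reproducing the site filter."""
    keep = []
    n_sites, n_samples = coverage.shape
    for i in range(n_sites):
        available = 0
        for j in range(n_samples):
            if coverage[i, j] >= max(min_coverage, 1):
                available += 1
        keep.append(available / n_samples >= min_fraction)
    return np.array(keep)


def brute_force_annotation(sites: pd.DataFrame, genes: pd.DataFrame,
                           upstream=1500, downstream=500, stranded=True):
    """O(S*G) overlap scan, returning {(site_id, gene_id): zone}."""
    out = {}
    for sid, s in sites.iterrows():
        hit = False
        for gid, g in genes.iterrows():
            if g["chrom"] != s["chrom"]:
                continue
            if g["strand"] == "-" and stranded:
                lo, hi = g["start"] - downstream, g["end"] + upstream
            else:
                lo, hi = g["start"] - upstream, g["end"] + downstream
            lo = max(lo, 1)
            if lo <= s["pos"] <= hi:
                hit = True
                if g["start"] <= s["pos"] <= g["end"]:
                    zone = "intragenic"
                elif s["pos"] < g["start"]:
                    zone = ("upstream" if g["strand"] == "+" or not stranded
                            else "downstream")
                else:
                    zone = ("downstream" if g["strand"] == "+" or not stranded
                            else "upstream")
                out[(sid, gid)] = zone
        if not hit:
            out[(sid, None)] = "intergenic"
    return out
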
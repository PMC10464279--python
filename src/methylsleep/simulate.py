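"""Synthetic cohorts, genomes and methylation call sets with known truth.

Every downstream stage of the pipeline is testable without external
data: this module simulates (i) an adolescent cohort whose nine
sleep-initiation measures and covariates match the study population's
summary statistics (n = 263; e.g. PSG sleep-onset latency mean 25.7,
SD 21.45 minutes; PSG bedtime 22:00 +/- 0:12), (ii) a small genome of
non-overlapping stranded genes with CpG sites inside and outside their
extended borders, and (iii) per-site x per-subject bisulfite read
counts with over-dispersed coverage and beta-distributed methylation
proportions.

Causal direction matches the analysis model: methylation is drawn
first and, for *planted* effects, the designated phenotype is
regenerated as a linear function of the planted site's observed
methylation level plus covariate terms and Gaussian noise — so the
per-site OLS estimand is exactly the planted effect.  Sleep-onset time
is always recomputed as bedtime + SOL/60, so planting targets bedtime
or SOL and SOT inherits the (rescaled) signal.

All randomness flows from ``config.seed``: the same config reproduces
byte-identical outputs, including file serializations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import extend_gene
from .methylation import MethylationCallSet, site_ids, write_coverage_file
from .phenotypes import CLOCK_MAX, CLOCK_MIN, MEASURES

__all__ = [
    "PhenotypeSpec",
    "CovariateParams",
    "PlantedEffect",
    "SimulationConfig",
    "Genome",
    "GroundTruth",
    "SimulatedDataset",
    "generate_genome",
    "generate_cohort",
    "generate_methylation",
    "generate_dataset",
    "write_dataset",
]

# rng stream tags, one per stage, so stages can be regenerated independently
_RNG_GENOME, _RNG_COHORT, _RNG_METH, _RNG_PLANT = 11, 12, 13, 14


@dataclass(frozen=True)
class PhenotypeSpec:
    """Marginal distribution of one measure on the pipeline's scale.

    ``dist`` is ``"clock"`` (truncated normal, decimal hours on the
    continuous clock) or ``"lognormal"`` (moment-matched, truncated;
    minutes).  ``sd == 0`` degenerates to the constant mean.
    """
    mean: float
    sd: float
    lower: float
    upper: float
    dist: str  # "clock" | "lognormal"


#: Defaults calibrated to the study cohort's phenotype summary table.
#: Bedtimes: truncated normal on the continuous clock.  SOLs:
#: moment-matched lognormal with wide plausibility bounds (the printed
#: min-max are sample extremes, not distribution truncation points).
DEFAULT_PHENOTYPES: dict[str, PhenotypeSpec] = {
    "bedtime_sr": PhenotypeSpec(23 + 40 / 60, 1.5, CLOCK_MIN, CLOCK_MAX - 3, "clock"),
    "bedtime_act": PhenotypeSpec(23 + 59 / 60, 4 / 3, CLOCK_MIN, CLOCK_MAX - 3, "clock"),
    "bedtime_psg": PhenotypeSpec(22.0, 0.2, 21.0, 23.1, "clock"),
    "sol_sr": PhenotypeSpec(24.1, 19.6, 0.0, 600.0, "lognormal"),
    "sol_act": PhenotypeSpec(7.5, 8.5, 0.0, 600.0, "lognormal"),
    "sol_psg": PhenotypeSpec(25.7, 21.45, 0.0, 600.0, "lognormal"),
}


@dataclass(frozen=True)
class CovariateParams:
    """Cohort covariate distributions (defaults from the study sample)."""
    age_mean: float = 17.3
    age_sd: float = 2.1
    age_range: tuple[float, float] = (13.0, 23.0)
    male_fraction: float = 0.559
    minority_fraction: float = 0.232
    bmi_mean: float = 64.5
    bmi_sd: float = 29.0
    bmi_range: tuple[float, float] = (0.7, 99.8)
    n_batches: int = 4


@dataclass(frozen=True)
class PlantedEffect:
    """A true methylation->phenotype effect planted in one gene.

    ``effect`` is in phenotype units per unit methylation proportion
    (minutes for SOL, hours for bedtime).  The planted site is the
    gene's first intragenic CpG.  ``measure`` must be a bedtime or SOL
    measure; SOT is recomputed from its components.
    """
    gene_id: str
    measure: str
    effect: float


@dataclass
class SimulationConfig:
    n_subjects: int = 263
    n_genes: int = 300
    n_intergenic_sites: int = 600
    sites_per_gene_mean: float = 8.0
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_length: int = 5_000_000
    coverage_mean: float = 30.0
    coverage_dispersion: float = 3.0   # NB size; var = m + m^2/size
    missing_fraction: float = 0.05     # cells zeroed at random
    high_missing_site_fraction: float = 0.05
    high_missing_rate: float = 0.7     # missing prob at high-missing sites
    meth_beta_params: tuple[float, float] = (2.0, 2.0)
    within_construct_corr: float = 0.5
    covariate_effect_scale: float = 0.3  # age slope, in measure-SD per age-SD
    phenotype_params: dict[str, PhenotypeSpec] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if self.n_genes < 0 or self.n_intergenic_sites < 0:
            raise ValueError("counts must be >= 0")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction in [0, 1)")
        if not (-1 < self.within_construct_corr < 1):
            raise ValueError("within_construct_corr in (-1, 1)")
        a, b = self.meth_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be > 0")
        for m, spec in self.phenotype_params.items():
            if spec.sd < 0:
                raise ValueError(f"{m}: sd must be >= 0")
        for pe in self.planted_effects:
            if pe.measure not in self.phenotype_params:
                raise ValueError(
                    f"planted measure {pe.measure!r} must be a bedtime/SOL "
                    "measure (SOT is derived)")


@dataclass
class Genome:
    """Gene models plus CpG coordinates, with the generator's own bookkeeping.

    ``truth`` is a long-format (site_id, chrom, pos, gene_id, zone)
    table identical in shape to the annotation module's output — the
    oracle that annotation is tested against.
    """
    genes: pd.DataFrame
    sites: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class GroundTruth:
    """Planted (site, measure, effect) triples and truly associated genes."""
    planted: list[dict]
    genes_by_measure: dict[str, list[str]]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"planted": self.planted, "genes_by_measure": self.genes_by_measure},
            indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(planted=d["planted"], genes_by_measure=d["genes_by_measure"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Genome
    cohort: pd.DataFrame
    callset: MethylationCallSet
    truth: GroundTruth


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([tag, config.seed & 0x7FFFFFFF])


# ---------------------------------------------------------------- genome

def generate_genome(config: SimulationConfig) -> Genome:
    """Place non-overlapping stranded genes and CpG sites on chromosomes.

    Extended gene borders (strand-aware −1500/+500) are kept at least
    1 kb apart, and intergenic sites are drawn from the complement of
    all extended intervals — so the generator's intragenic/intergenic
    bookkeeping is exact, not approximate.
    """
    config.validate()
    rng = _rng(config, _RNG_GENOME)
    chroms = list(config.chrom_names)
    lo_len, hi_len = config.gene_length_range
    min_gap = 2 * (1500 + 500) + 1000

    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1

    gene_rows, site_rows = [], []
    gidx = 0
    for chrom, n_g in zip(chroms, per_chrom):
        lengths = rng.integers(lo_len, hi_len + 1, size=n_g)
        needed = int(lengths.sum()) + (n_g + 1) * min_gap
        if needed > config.chrom_length:
            raise ValueError(
                f"{n_g} genes need {needed} bp but {chrom} has "
                f"{config.chrom_length} bp; enlarge chrom_length or drop genes")
        slack = config.chrom_length - needed
        # distribute slack over the n_g + 1 gaps
        extra = rng.multinomial(slack, np.full(n_g + 1, 1.0 / (n_g + 1)))
        pos = 1
        for j in range(n_g):
            pos += min_gap + int(extra[j])
            start, end = pos, pos + int(lengths[j]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"G{gidx:04d}"
            gene_rows.append((gid, chrom, start, end, strand))
            n_sites = 1 + rng.poisson(max(config.sites_per_gene_mean - 1, 0))
            elo, ehi = extend_gene(start, end, strand)
            positions = np.sort(rng.choice(
                np.arange(elo, ehi + 1), size=min(n_sites, ehi - elo + 1),
                replace=False))
            for p in positions:
                p = int(p)
                if start <= p <= end:
                    zone = "intragenic"
                elif p < start:
                    zone = "upstream" if strand == "+" else "downstream"
                else:
                    zone = "downstream" if strand == "+" else "upstream"
                site_rows.append((chrom, p, gid, zone))
            pos = end + 1
            gidx += 1

    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end", "strand"]
                         ).set_index("gene_id")

    # intergenic sites: uniform over the complement of extended intervals
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for gid, g in genes.iterrows():
        lo, hi = extend_gene(int(g["start"]), int(g["end"]), g["strand"])
        blocked[g["chrom"]].append((lo, hi))
    taken = {(c, p) for c, p, _, _ in site_rows}
    n_inter = config.n_intergenic_sites
    per_chrom_i = [n_inter // len(chroms)] * len(chroms)
    for i in range(n_inter % len(chroms)):
        per_chrom_i[i] += 1
    for chrom, n_i in zip(chroms, per_chrom_i):
        intervals = sorted(blocked[chrom])
        got = 0
        attempts = 0
        while got < n_i:
            attempts += 1
            if attempts > 200 * max(n_i, 1):
                raise ValueError(
                    f"cannot place {n_i} intergenic sites on {chrom}; "
                    "chromosome too crowded")
            p = int(rng.integers(1, config.chrom_length + 1))
            if any(lo <= p <= hi for lo, hi in intervals):
                continue
            if (chrom, p) in taken:
                continue
            taken.add((chrom, p))
            site_rows.append((chrom, p, None, "intergenic"))
            got += 1

    truth = pd.DataFrame(site_rows, columns=["chrom", "pos", "gene_id", "zone"])
    truth = truth.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    truth.insert(0, "site_id", site_ids(truth["chrom"], truth["pos"]))
    sites = (truth[["site_id", "chrom", "pos"]].drop_duplicates("site_id")
             .set_index("site_id"))
    return Genome(genes=genes, sites=sites, truth=truth)


# ---------------------------------------------------------------- cohort

def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out >= hi)
    return out


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with given mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _correlated_normals(rng, n: int, k: int, corr: float) -> np.ndarray:
    """n x k standard normals with exchangeable pairwise correlation."""
    cov = np.full((k, k), corr) + np.eye(k) * (1.0 - corr)
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, k)) @ L.T


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw subjects' sleep measures and covariates (no planted effects).

    Bedtimes are truncated normals on the continuous clock scale; SOLs
    moment-matched truncated lognormals; methods within a construct
    share a configurable latent correlation.  SOT := bedtime + SOL/60
    exactly.  The index is the subject id.
    """
    config.validate()
    rng = _rng(config, _RNG_COHORT)
    n = config.n_subjects
    r = config.within_construct_corr
    idx = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    out = pd.DataFrame(index=idx)

    methods = ("sr", "act", "psg")
    z_bed = _correlated_normals(rng, n, 3, r)
    z_sol = _correlated_normals(rng, n, 3, r)
    for j, m in enumerate(methods):
        spec = config.phenotype_params[f"bedtime_{m}"]
        if spec.sd == 0:
            out[f"bedtime_{m}"] = spec.mean
        else:
            v = spec.mean + spec.sd * z_bed[:, j]
            bad = (v < spec.lower) | (v >= spec.upper)
            while bad.any():
                v[bad] = spec.mean + spec.sd * rng.standard_normal(int(bad.sum()))
                bad = (v < spec.lower) | (v >= spec.upper)
            out[f"bedtime_{m}"] = v
    for j, m in enumerate(methods):
        spec = config.phenotype_params[f"sol_{m}"]
        if spec.sd == 0:
            out[f"sol_{m}"] = spec.mean
        else:
            mu, sigma = _lognormal_params(spec.mean, spec.sd)
            v = np.exp(mu + sigma * z_sol[:, j])
            bad = (v < spec.lower) | (v >= spec.upper)
            while bad.any():
                v[bad] = np.exp(mu + sigma * rng.standard_normal(int(bad.sum())))
                bad = (v < spec.lower) | (v >= spec.upper)
            out[f"sol_{m}"] = v
    for m in methods:
        out[f"sot_{m}"] = out[f"bedtime_{m}"] + out[f"sol_{m}"] / 60.0

    cp = config.covariate_params
    out["age"] = _truncated_normal(rng, cp.age_mean, cp.age_sd, *cp.age_range, n)
    out["male"] = (rng.random(n) < cp.male_fraction).astype(int)
    out["minority"] = (rng.random(n) < cp.minority_fraction).astype(int)
    out["bmi_pct"] = _truncated_normal(rng, cp.bmi_mean, cp.bmi_sd,
                                       *cp.bmi_range, n)
    out["batch"] = [f"B{rng.integers(cp.n_batches)+1}" for _ in range(n)]
    return out


# ----------------------------------------------------------- methylation

def generate_methylation(config: SimulationConfig, genome: Genome,
                         cohort: pd.DataFrame
                         ) -> tuple[MethylationCallSet, GroundTruth, pd.DataFrame]:
    """Draw read counts and apply planted effects to the cohort.

    Per site x sample: coverage ~ negative binomial (mean
    ``coverage_mean``, size ``coverage_dispersion``), with a random
    fraction of cells — and a larger fraction at designated
    high-missing sites — zeroed to emulate missing calls; the
    methylated count is binomial(coverage, pi) with pi ~ Beta(a, b).

    For each planted effect the designated measure is regenerated as
    ``measure mean + effect * (level - mean level) + covariate terms +
    N(0, measure SD)`` using the *observed* methylation level at the
    gene's planted site (true pi where coverage is zero), then the
    construct's SOT is recomputed.  Returns the call set, the ground
    truth, and the (possibly modified) cohort.
    """
    config.validate()
    rng = _rng(config, _RNG_METH)
    sites = genome.sites
    S, n = len(sites), len(cohort)
    if S == 0:
        raise ValueError("genome has no CpG sites")

    # planted sites are resolved up front so they are never designated
    # high-missing: a planted effect must stay analyzable to be ground truth
    row_of = {sid: i for i, sid in enumerate(sites.index)}
    planted_site_rows: dict[tuple[str, str], int] = {}
    for pe in config.planted_effects:
        g = genome.truth[genome.truth["gene_id"] == pe.gene_id]
        if g.empty:
            raise ValueError(f"planted gene {pe.gene_id!r} absent from the genome")
        intra = g[g["zone"] == "intragenic"]
        sid = (intra if not intra.empty else g)["site_id"].iloc[0]
        planted_site_rows[(pe.measure, pe.gene_id)] = row_of[sid]

    m = config.coverage_mean
    size = config.coverage_dispersion
    cov = rng.negative_binomial(size, size / (size + m), size=(S, n))
    miss = rng.random((S, n)) < config.missing_fraction
    if config.high_missing_site_fraction > 0:
        eligible = np.setdiff1d(np.arange(S),
                                np.fromiter(planted_site_rows.values(), int))
        n_hm = min(int(round(config.high_missing_site_fraction * S)),
                   len(eligible))
        hm_idx = rng.choice(eligible, size=n_hm, replace=False)
        miss[hm_idx] |= rng.random((n_hm, n)) < config.high_missing_rate
    cov[miss] = 0

    a, b = config.meth_beta_params
    pi = rng.beta(a, b, size=(S, n))
    meth = rng.binomial(cov, pi)
    callset = MethylationCallSet(
        sites=sites[["chrom", "pos"]].copy(), samples=list(cohort.index),
        meth=meth, unmeth=cov - meth)

    cohort = cohort.copy()
    planted_rows: list[dict] = []
    genes_by_measure: dict[str, set[str]] = {}
    if config.planted_effects:
        prng = _rng(config, _RNG_PLANT)
        level = np.where(cov > 0, meth / np.where(cov > 0, cov, 1), pi)
        by_measure: dict[str, list[PlantedEffect]] = {}
        for pe in config.planted_effects:
            by_measure.setdefault(pe.measure, []).append(pe)
        cp = config.covariate_params
        for measure, effects in by_measure.items():
            spec = config.phenotype_params[measure]
            age_coef = (config.covariate_effect_scale * spec.sd
                        / max(cp.age_sd, 1e-12))
            male_shift = 0.2 * spec.sd
            y = np.full(n, spec.mean, dtype=float)
            y += age_coef * (cohort["age"].to_numpy() - cp.age_mean)
            y += male_shift * (cohort["male"].to_numpy() - cp.male_fraction)
            for pe in effects:
                row = planted_site_rows[(pe.measure, pe.gene_id)]
                sid = sites.index[row]
                lv = level[row]
                y += pe.effect * (lv - lv.mean())
                planted_rows.append({"site_id": sid, "gene_id": pe.gene_id,
                                     "measure": measure,
                                     "effect": float(pe.effect)})
                genes_by_measure.setdefault(measure, set()).add(pe.gene_id)
            y += prng.normal(0.0, spec.sd, size=n)
            cohort[measure] = y
        for meth_name in ("sr", "act", "psg"):
            cohort[f"sot_{meth_name}"] = (cohort[f"bedtime_{meth_name}"]
                                          + cohort[f"sol_{meth_name}"] / 60.0)

    truth = GroundTruth(
        planted=sorted(planted_rows, key=lambda d: (d["measure"], d["site_id"])),
        genes_by_measure={k: sorted(v) for k, v in genes_by_measure.items()})
    return callset, truth, cohort


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Convenience wrapper: genome + cohort + methylation in one call."""
    genome = generate_genome(config)
    cohort = generate_cohort(config)
    callset, truth, cohort = generate_methylation(config, genome, cohort)
    return SimulatedDataset(config=config, genome=genome, cohort=cohort,
                            callset=callset, truth=truth)


# ------------------------------------------------------------------ I/O

def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Serialize a simulated dataset to the pipeline's on-disk formats.

    Writes per-sample Bismark-coverage TSVs, BED6 gene models, the
    cohort CSV, the ground-truth JSON and the annotation-truth TSV.
    Returns a manifest of relative paths.
    """
    from .annotation import write_bed6  # local import avoids cycle at init

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov_dir = outdir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for s in ds.callset.samples:
        write_coverage_file(ds.callset, s, cov_dir / f"{s}.cov.tsv")
    write_bed6(ds.genome.genes, outdir / "genes.bed")
    cohort = ds.cohort.copy()
    cohort.insert(0, "subject_id", cohort.index)
    cohort.to_csv(outdir / "cohort.csv", index=False, float_format="%.10g")
    ds.truth.to_json(outdir / "ground_truth.json")
    ds.genome.truth.to_csv(outdir / "annotation_truth.tsv", sep="\t",
                           index=False, na_rep="NA")
    return {
        "coverage_dir": "coverage",
        "genes": "genes.bed",
        "cohort": "cohort.csv",
        "ground_truth": "ground_truth.json",
        "annotation_truth": "annotation_truth.tsv",
    }
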
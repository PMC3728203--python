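"""Multi-cohort study simulator with LD blocks, covariate effects and planted cis-eQTLs.

The LD model is a haplotype-pool mosaic: each block has a small pool of
haplotypes shared by all cohorts, and every individual draws two pool
haplotypes per block independently.  This yields exact 0/1/2 dosages,
blocky pairwise r-squared, and independence between blocks by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CovariateTable, ExpressionMatrix, GenotypeMatrix, SnpRecord

SMOKING_SIM_LEVELS = ("never", "ex", "current")  # ordinal coding 0/1/2 for simulation


@dataclass(frozen=True)
class PlantedEqtl:
    """A planted SNP-probeset effect: h2 is the target variance explained."""

    snp_index: int
    probeset_index: int
    h2: float
    direction: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class CovariateParams:
    """Covariate generating distribution; defaults resemble an older, mostly
    male, mostly ever-smoking surgical cohort."""

    age_mean: float = 63.3
    age_sd: float = 9.9
    age_bounds: tuple[float, float] = (18.0, 95.0)
    male_fraction: float = 0.559
    # (never, ex, current)
    smoking_probs: tuple[float, float, float] = (0.088, 0.692, 0.220)


@dataclass
class SimulationConfig:
    seed: int
    cohort_sizes: tuple[int, ...] = (409, 339, 363)
    cohort_names: tuple[str, ...] = ("cohort1", "cohort2", "cohort3")
    n_blocks: int = 14
    snps_per_block: int = 50
    haplotypes_per_block: int = 6
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "4"
    start_pos: int = 88_875_909
    locus_span_bp: int = 2_000_000
    n_probesets: int = 50
    n_genes: int = 14
    planted_eqtls: tuple[PlantedEqtl, ...] = ()
    covariates: CovariateParams = field(default_factory=CovariateParams)
    beta_age: float = 0.01
    beta_sex: float = 0.2
    beta_smoking: float = 0.1  # per ordinal level (never=0, ex=1, current=2)
    noise_sd: float = 1.0
    outlier_fraction: float = 0.0
    outlier_magnitude_sd: float = 5.0

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != len(self.cohort_names):
            raise ValueError("cohort_sizes and cohort_names lengths differ")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.haplotypes_per_block < 1:
            raise ValueError("haplotypes_per_block must be >= 1")
        n_snps = self.n_blocks * self.snps_per_block
        for pe in self.planted_eqtls:
            if not (0 <= pe.snp_index < n_snps):
                raise ValueError(f"planted SNP index {pe.snp_index} out of range")
            if not (0 <= pe.probeset_index < self.n_probesets):
                raise ValueError(f"planted probeset index {pe.probeset_index} out of range")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genotypes: dict[str, GenotypeMatrix]
    expression: dict[str, ExpressionMatrix]
    covariates: dict[str, CovariateTable]
    truth: pd.DataFrame  # cohort, snp_id, probeset_id, true_beta, true_h2, direction


def draw_block_pools(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """One haplotype pool per block: (haplotypes_per_block, snps_per_block) 0/1 arrays.

    Per-SNP allele frequencies are drawn uniformly from ``maf_range`` and
    realized as allele counts in the pool, clipped to [1, K-1] so pools of
    two or more haplotypes are always polymorphic.  A single-haplotype pool
    is monomorphic by construction.
    """
    pools = []
    k = config.haplotypes_per_block
    for _ in range(config.n_blocks):
        freqs = rng.uniform(config.maf_range[0], config.maf_range[1], config.snps_per_block)
        pool = np.zeros((k, config.snps_per_block), dtype=np.int8)
        for j, f in enumerate(freqs):
            if k == 1:
                pool[0, j] = int(rng.random() < f)
            else:
                count = int(np.clip(round(f * k), 1, k - 1))
                pool[rng.choice(k, size=count, replace=False), j] = 1
        pools.append(pool)
    return pools


def genotypes_from_pools(
    pools: list[np.ndarray],
    n_samples: int,
    rng: np.random.Generator,
    sample_prefix: str = "S",
    chrom: str = "4",
    start_pos: int = 1,
    locus_span_bp: int = 2_000_000,
) -> GenotypeMatrix:
    """Draw diploid individuals as two independent pool haplotypes per block."""
    if any(p.shape[0] < 1 for p in pools):
        raise ValueError("haplotypes_per_block must be >= 1")
    n_snps = sum(p.shape[1] for p in pools)
    dosages = np.empty((n_samples, n_snps), dtype=float)
    col = 0
    for pool in pools:
        k, m = pool.shape
        ha = pool[rng.integers(0, k, n_samples)]
        hb = pool[rng.integers(0, k, n_samples)]
        dosages[:, col : col + m] = ha + hb
        col += m
    width = len(str(n_snps))
    step = max(locus_span_bp // max(n_snps, 1), 1)
    snps = [
        SnpRecord(
            snp_id=f"snp{i + 1:0{width}d}",
            chrom=chrom,
            pos=start_pos + i * step,
            ref_allele="A",
            alt_allele="G",
        )
        for i in range(n_snps)
    ]
    sample_ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosages=dosages)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, GenotypeMatrix]:
    """Per-cohort genotype matrices sharing one set of block haplotype pools."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pools = draw_block_pools(config, rng)
    out = {}
    for name, n in zip(config.cohort_names, config.cohort_sizes):
        out[name] = genotypes_from_pools(
            pools,
            n,
            rng,
            sample_prefix=f"{name}_",
            chrom=config.chrom,
            start_pos=config.start_pos,
            locus_span_bp=config.locus_span_bp,
        )
    return out


def simulate_covariates(
    n_samples: int,
    params: CovariateParams,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
) -> CovariateTable:
    """Truncated-normal age, Bernoulli sex, multinomial smoking."""
    lo, hi = params.age_bounds
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=params.age_mean, scale=params.age_sd, size=n_samples, random_state=rng
    )
    sex = np.where(rng.random(n_samples) < params.male_fraction, "male", "female")
    smoking_idx = rng.choice(3, size=n_samples, p=params.smoking_probs)
    smoking = [SMOKING_SIM_LEVELS[i] for i in smoking_idx]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    return CovariateTable(sample_ids=sample_ids, age=age, sex=list(sex), smoking=smoking)


def _smoking_level(s: str) -> float:
    return float(SMOKING_SIM_LEVELS.index(s)) if s in SMOKING_SIM_LEVELS else np.nan


def simulate_expression(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    cohort: str = "",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression = covariate effects + planted genetic effects + noise.

    For a planted eQTL the genetic coefficient is scaled to the realized
    genotype variance so that Var(beta*g) / (Var(beta*g) + noise_sd^2)
    equals the requested h2.  Returns the matrix and the per-cohort truth
    table (snp_id, probeset_id, true_beta, true_h2).
    """
    n = genotypes.n_samples
    if covariates.n_samples != n:
        raise ValueError("genotype and covariate sample counts differ")
    smoking_num = np.array([_smoking_level(s) for s in covariates.smoking])
    sex_num = np.array([1.0 if s == "male" else 0.0 for s in covariates.sex])
    base = (
        config.beta_age * covariates.age
        + config.beta_sex * sex_num
        + config.beta_smoking * smoking_num
    )
    base = np.where(np.isfinite(base), base, 0.0)

    values = rng.normal(0.0, config.noise_sd, size=(n, config.n_probesets))
    values += base[:, None]

    truth_rows = []
    for pe in config.planted_eqtls:
        g = genotypes.dosages[:, pe.snp_index]
        var_g = float(np.var(g))
        if var_g == 0:
            raise ValueError(
                f"planted eQTL at SNP index {pe.snp_index}: genotype is monomorphic "
                "in this cohort (variance 0), h2 is undefined"
            )
        if pe.h2 > 0:
            beta = pe.direction * config.noise_sd * np.sqrt(pe.h2 / (1 - pe.h2) / var_g)
        else:
            beta = 0.0
        values[:, pe.probeset_index] += beta * g
        truth_rows.append(
            {
                "cohort": cohort,
                "snp_id": genotypes.snps[pe.snp_index].snp_id,
                "probeset_id": _probeset_id(pe.probeset_index, config.n_probesets),
                "true_beta": beta,
                "true_h2": pe.h2,
                "direction": pe.direction,
            }
        )

    if config.outlier_fraction > 0:
        hit = rng.random((n, config.n_probesets)) < config.outlier_fraction
        values += hit * rng.normal(0.0, config.outlier_magnitude_sd, size=(n, config.n_probesets))

    probesets = [
        (_probeset_id(j, config.n_probesets), _gene_symbol(j, config))
        for j in range(config.n_probesets)
    ]
    em = ExpressionMatrix(
        sample_ids=list(genotypes.sample_ids), probesets=probesets, values=values
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["cohort", "snp_id", "probeset_id", "true_beta", "true_h2", "direction"],
    )
    return em, truth


def _probeset_id(j: int, n_probesets: int) -> str:
    return f"ps{j + 1:0{len(str(n_probesets))}d}"


def _gene_symbol(j: int, config: SimulationConfig) -> str:
    return f"GENE{j % config.n_genes + 1}"


def gene_list(config: SimulationConfig) -> list[str]:
    return [f"GENE{i + 1}" for i in range(config.n_genes)]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full deterministic multi-cohort study: genotypes, covariates, expression, truth."""
    root = np.random.SeedSequence(config.seed)
    ss_pools, ss_cohorts = root.spawn(2)
    pools = draw_block_pools(config, np.random.default_rng(ss_pools))

    genotypes: dict[str, GenotypeMatrix] = {}
    expression: dict[str, ExpressionMatrix] = {}
    covariates: dict[str, CovariateTable] = {}
    truths = []
    for ss, name, n in zip(
        ss_cohorts.spawn(len(config.cohort_names)), config.cohort_names, config.cohort_sizes
    ):
        rng = np.random.default_rng(ss)
        gm = genotypes_from_pools(
            pools,
            n,
            rng,
            sample_prefix=f"{name}_",
            chrom=config.chrom,
            start_pos=config.start_pos,
            locus_span_bp=config.locus_span_bp,
        )
        cov = simulate_covariates(n, config.covariates, rng, sample_ids=list(gm.sample_ids))
        em, truth = simulate_expression(gm, cov, config, rng, cohort=name)
        genotypes[name] = gm
        expression[name] = em
        covariates[name] = cov
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        expression=expression,
        covariates=covariates,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> str:
    """Write a simulated study as the file formats the pipeline reads.

    Produces per-cohort VCF / expression TSV / covariate TSV, the truth
    table, and a ready-to-run pipeline config YAML; returns the config path.
    """
    import os

    import yaml

    from . import data_io

    os.makedirs(outdir, exist_ok=True)
    cfg = study.config
    cohort_entries = []
    for name in cfg.cohort_names:
        data_io.write_vcf(study.genotypes[name], os.path.join(outdir, f"{name}.vcf"))
        data_io.write_expression_tsv(
            study.expression[name], os.path.join(outdir, f"{name}_expression.tsv")
        )
        data_io.write_covariates_tsv(
            study.covariates[name], os.path.join(outdir, f"{name}_covariates.tsv")
        )
        cohort_entries.append(
            {
                "name": name,
                "genotypes": f"{name}.vcf",
                "expression": f"{name}_expression.tsv",
                "covariates": f"{name}_covariates.tsv",
            }
        )
    study.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)

    # one locus spanning the simulated region, anchored on two pseudo-GWAS SNPs
    first = study.genotypes[cfg.cohort_names[0]].snps
    gwas = [
        {"snp_id": first[0].snp_id, "pos": first[0].pos},
        {"snp_id": first[-1].snp_id, "pos": first[-1].pos},
    ]
    doc = {
        "discovery": cfg.cohort_names[0],
        "seed": cfg.seed,
        "flank_bp": 0,
        "alpha": 0.05,
        "alpha_rep": 0.05,
        "outdir": "reports",
        "cohorts": cohort_entries,
        "loci": [
            {
                "name": "simlocus",
                "chrom": cfg.chrom,
                "start": first[0].pos,
                "end": first[-1].pos,
                "genes": gene_list(cfg),
                "gwas_snps": gwas,
            }
        ],
    }
    config_path = os.path.join(outdir, "pipeline_config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path


def default_config(seed: int, **overrides) -> SimulationConfig:
    """Default synthetic study: 3 cohorts of ~400, 700 SNPs in 14 LD blocks,
    50 probesets, a spread of planted effects from weak to very strong."""
    planted = (
        PlantedEqtl(snp_index=25, probeset_index=0, h2=0.55, direction=-1),
        PlantedEqtl(snp_index=120, probeset_index=5, h2=0.30, direction=1),
        PlantedEqtl(snp_index=333, probeset_index=12, h2=0.10, direction=1),
        PlantedEqtl(snp_index=480, probeset_index=20, h2=0.05, direction=-1),
    )
    kwargs = dict(
        seed=seed,
        cohort_sizes=(409, 339, 363),
        cohort_names=("cohort1", "cohort2", "cohort3"),
        planted_eqtls=planted,
        outlier_fraction=0.01,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
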
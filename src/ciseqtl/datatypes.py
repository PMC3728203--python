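"""Shared data containers for the cis-eQTL pipeline.

Conventions used throughout the package:

* genomic positions are 1-based inclusive base pairs;
* allele dosages are 0/1/2 copies of the counted allele, stored as floats
  with ``NaN`` as the missing sentinel;
* expression values are continuous log-scale intensities, ``NaN`` missing;
* all downstream statistics use pairwise-complete deletion, so per-test
  sample sizes may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("current", "ex", "never", "unknown")

#: values a non-missing dosage may take
VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with its genomic location and allele coding.

    ``counted_allele`` is the allele the dosage counts; it defaults to the
    alt allele so effect directions are always interpretable.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    counted_allele: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")
        if not self.counted_allele:
            object.__setattr__(self, "counted_allele", self.alt_allele)
        if self.counted_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError(
                f"SNP {self.snp_id}: counted allele {self.counted_allele!r} is neither "
                f"ref ({self.ref_allele!r}) nor alt ({self.alt_allele!r})"
            )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with SNP metadata."""

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray  # (n_samples, n_snps) float64, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique([s.snp_id for s in self.snps], "SNP")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, VALID_DOSAGES).all():
            bad = finite[~np.isin(finite, VALID_DOSAGES)][0]
            raise ValueError(f"invalid dosage value {bad!r}; expected 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype panel") from None

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def subset_snps(self, indices: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[i] for i in indices],
            dosages=self.dosages[:, indices].copy(),
        )

    def window(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """SNPs on ``chrom`` with start <= pos <= end (1-based inclusive)."""
        idx = [i for i, s in enumerate(self.snps) if s.chrom == chrom and start <= s.pos <= end]
        return self.subset_snps(idx)


@dataclass
class ExpressionMatrix:
    """Samples x probesets continuous expression values (log scale)."""

    sample_ids: list[str]
    probesets: list[tuple[str, str]]  # (probeset_id, gene_symbol)
    values: np.ndarray  # (n_samples, n_probesets) float64, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probesets)):
            raise ValueError(
                f"expression shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.probesets)} probesets"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique([p for p, _ in self.probesets], "probeset")
        if np.isinf(self.values).any():
            raise ValueError("expression values must be finite where not missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probesets(self) -> int:
        return len(self.probesets)

    @property
    def probeset_ids(self) -> list[str]:
        return [p for p, _ in self.probesets]

    def gene_of(self, probeset_id: str) -> str:
        for p, g in self.probesets:
            if p == probeset_id:
                return g
        raise KeyError(f"probeset {probeset_id!r} not in expression matrix")

    def trait(self, probeset_id: str) -> np.ndarray:
        return self.values[:, self.probeset_ids.index(probeset_id)]


@dataclass
class CovariateTable:
    """Per-sample age / sex / smoking status; missing values allowed."""

    sample_ids: list[str]
    age: np.ndarray  # float years, NaN = missing
    sex: list[str]  # "male" / "female" / "" (missing)
    smoking: list[str]  # "current" / "ex" / "never" / "unknown"

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.age) == len(self.sex) == len(self.smoking) == n):
            raise ValueError("covariate columns have inconsistent lengths")
        _check_unique(self.sample_ids, "sample")
        finite = self.age[np.isfinite(self.age)]
        if finite.size and (finite <= 0).any():
            raise ValueError("age must be > 0 where present")
        for s in self.sex:
            if s and s not in SEX_LEVELS:
                raise ValueError(f"invalid sex value {s!r}")
        for s in self.smoking:
            if s not in SMOKING_LEVELS:
                raise ValueError(f"invalid smoking value {s!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def complete_mask(self) -> np.ndarray:
        """True where age, sex and smoking are all observed."""
        age_ok = np.isfinite(self.age)
        sex_ok = np.array([s in SEX_LEVELS for s in self.sex])
        smoke_ok = np.array([s in ("current", "ex", "never") for s in self.smoking])
        return age_ok & sex_ok & smoke_ok


@dataclass
class LocusDefinition:
    """A GWAS locus: window bounds plus the disease-associated SNPs in it.

    ``genes`` lists the gene symbols whose probesets are tested as cis
    targets; probe-to-locus assignment is by this explicit list, never by
    coordinates.
    """

    name: str
    chrom: str
    start: int
    end: int
    gwas_snps: list[SnpRecord] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.name}: start {self.start} > end {self.end}")
        for s in self.gwas_snps:
            if not (self.start <= s.pos <= self.end):
                raise ValueError(
                    f"locus {self.name}: GWAS SNP {s.snp_id} at {s.pos} outside "
                    f"[{self.start}, {self.end}]"
                )


# status values for a single SNP-probeset test
STATUS_OK = "ok"
STATUS_UNTESTABLE = "untestable"
STATUS_DEGENERATE = "degenerate"


@dataclass
class EqtlResult:
    """One SNP-probeset association test."""

    snp_id: str
    probeset_id: str
    gene: str
    beta: float
    se: float
    wald: float
    p: float
    r2: float
    n: int
    cohort: str = ""
    status: str = STATUS_OK

    @property
    def direction(self) -> int:
        if not np.isfinite(self.beta) or self.beta == 0:
            return 0
        return 1 if self.beta > 0 else -1

    @property
    def testable(self) -> bool:
        return self.status != STATUS_UNTESTABLE


@dataclass
class LocusThreshold:
    """Per-locus Bonferroni threshold from effective test counts."""

    locus: str
    m_snps: int
    m_probes: int
    meff_snps: float
    meff_probes: float
    alpha: float
    threshold: float

    @property
    def display(self) -> str:
        """3-significant-digit form for reports; full precision kept in ``threshold``."""
        return f"{self.threshold:.2e}"


@dataclass
class AdjustedTrait:
    """Covariate-adjusted residuals for one probeset.

    ``residuals`` is NaN exactly where expression or a covariate was
    missing, or where ``outlier_mask`` is True.
    """

    probeset_id: str
    residuals: np.ndarray
    outlier_mask: np.ndarray
    n_used: int
    iterations: int = 0
    converged: bool = True
    scale: float = float("nan")
    gene: str = ""

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.residuals.shape != self.outlier_mask.shape:
            raise ValueError("residuals and outlier_mask shapes differ")
        if np.isfinite(self.residuals[self.outlier_mask]).any():
            raise ValueError("residuals must be NaN where outlier_mask is True")
        n = int(np.isfinite(self.residuals).sum())
        if n != self.n_used:
            raise ValueError(f"n_used={self.n_used} but {n} residuals are non-missing")
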
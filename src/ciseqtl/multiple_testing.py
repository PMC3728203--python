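"""Effective number of independent tests and per-locus Bonferroni thresholds.

The effective number follows the spectral-decomposition definition: for
eigenvalues lambda_i of the correlation matrix,

    Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]

Monomorphic SNPs (or constant traits) cannot enter a correlation matrix;
they are excluded and each counts as one additional independent test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import AdjustedTrait, GenotypeMatrix, LocusThreshold

_SYM_TOL = 1e-10


def meff_li_ji(corr: np.ndarray) -> float:
    """Effective number of independent variables from a correlation matrix.

    Requires a square symmetric matrix with unit diagonal and entries in
    [-1, 1].  Eigenvalues numerically below zero (possible with
    pairwise-complete estimation) are clipped to 0 before scoring.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {corr.shape}")
    if np.isnan(corr).any():
        raise ValueError("correlation matrix contains missing entries; complete it first")
    if not np.allclose(corr, corr.T, atol=_SYM_TOL):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=_SYM_TOL):
        raise ValueError("correlation matrix diagonal must be 1")
    if (np.abs(corr) > 1 + _SYM_TOL).any():
        raise ValueError("correlation entries must lie in [-1, 1]")
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    lam = np.abs(lam)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


@dataclass
class CorrelationResult:
    """Pairwise correlation matrix over the usable columns plus exclusions."""

    corr: np.ndarray
    ids: list[str]
    n_excluded: int
    excluded_ids: list[str]


def _pairwise_correlation(values: np.ndarray, ids: list[str], what: str) -> CorrelationResult:
    """Pearson correlations with pairwise-complete deletion; constant columns excluded."""
    values = np.asarray(values, dtype=float)
    keep, dropped = [], []
    for j in range(values.shape[1]):
        col = values[:, j]
        col = col[np.isfinite(col)]
        if col.size >= 2 and np.ptp(col) > 0:
            keep.append(j)
        else:
            dropped.append(j)
    if not keep:
        return CorrelationResult(
            corr=np.empty((0, 0)),
            ids=[],
            n_excluded=len(dropped),
            excluded_ids=[ids[j] for j in dropped],
        )
    sub = values[:, keep]
    if len(keep) == 1:
        corr = np.ones((1, 1))
    elif np.isfinite(sub).all():
        corr = np.corrcoef(sub, rowvar=False)
    else:
        m = np.ma.masked_invalid(sub)
        corr = np.ma.corrcoef(m, rowvar=False).filled(np.nan)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationResult(
        corr=corr,
        ids=[ids[j] for j in keep],
        n_excluded=len(dropped),
        excluded_ids=[ids[j] for j in dropped],
    )


def snp_correlation(genotypes: GenotypeMatrix) -> CorrelationResult:
    """Dosage correlation matrix over polymorphic SNPs; monomorphic SNPs excluded
    (each later counts as one independent test)."""
    return _pairwise_correlation(genotypes.dosages, genotypes.snp_ids, "SNP")


def probe_correlation(traits: list[AdjustedTrait]) -> CorrelationResult:
    """Correlation of adjusted residual vectors; constant traits excluded."""
    if not traits:
        return CorrelationResult(np.empty((0, 0)), [], 0, [])
    values = np.column_stack([t.residuals for t in traits])
    return _pairwise_correlation(values, [t.probeset_id for t in traits], "probeset")


def effective_tests(result: CorrelationResult) -> float:
    """Meff over a correlation result: spectral count plus one per excluded column."""
    if result.corr.size == 0:
        if result.n_excluded:
            warnings.warn(
                "all columns are constant; effective test count falls back to the raw count",
                stacklevel=2,
            )
        return float(result.n_excluded)
    return meff_li_ji(result.corr) + float(result.n_excluded)


def locus_threshold(
    meff_snps: float,
    meff_probes: float,
    alpha: float = 0.05,
    locus: str = "",
    m_snps: int = 0,
    m_probes: int = 0,
) -> LocusThreshold:
    """Composite Bonferroni threshold alpha / (Meff_SNP x Meff_probe)."""
    if meff_snps < 1 or meff_probes < 1:
        raise ValueError("effective test counts must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return LocusThreshold(
        locus=locus,
        m_snps=m_snps,
        m_probes=m_probes,
        meff_snps=float(meff_snps),
        meff_probes=float(meff_probes),
        alpha=alpha,
        threshold=alpha / (meff_snps * meff_probes),
    )
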
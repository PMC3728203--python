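"""Single-SNP quantitative-trait association on adjusted residuals.

Each test is a simple linear regression of the residualized trait on the
allele dosage.  The slope is tested with a Wald statistic referred to a
Student-t distribution with n - 2 degrees of freedom (two-sided), and the
variance explained is the squared Pearson correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import (
    STATUS_DEGENERATE,
    STATUS_OK,
    STATUS_UNTESTABLE,
    AdjustedTrait,
    EqtlResult,
    GenotypeMatrix,
    LocusDefinition,
)

#: below this, the post-fit residual sum of squares counts as exact collinearity
_DEGENERATE_RSS = 1e-12


def fit_single(
    g: np.ndarray,
    y: np.ndarray,
    snp_id: str = "",
    probeset_id: str = "",
    gene: str = "",
    cohort: str = "",
) -> EqtlResult:
    """Regress residual expression on dosage over pairwise-complete samples.

    Returns an untestable result (NaN statistics) when fewer than 3
    complete pairs remain, the SNP is monomorphic on the complete subset,
    or the trait is constant.  Perfect collinearity yields the smallest
    representable positive p with a degenerate-fit flag.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(g) & np.isfinite(y)
    n = int(mask.sum())

    def _untestable() -> EqtlResult:
        return EqtlResult(
            snp_id=snp_id,
            probeset_id=probeset_id,
            gene=gene,
            beta=np.nan,
            se=np.nan,
            wald=np.nan,
            p=np.nan,
            r2=np.nan,
            n=n,
            cohort=cohort,
            status=STATUS_UNTESTABLE,
        )

    if n < 3:
        return _untestable()
    gc = g[mask]
    yc = y[mask]
    sxx = float(np.sum((gc - gc.mean()) ** 2))
    if sxx == 0.0:  # monomorphic in this cohort
        return _untestable()
    syy = float(np.sum((yc - yc.mean()) ** 2))
    if syy == 0.0:  # constant trait: zero outcome variance
        r = _untestable()
        r.beta = 0.0
        r.r2 = 0.0
        return r
    sxy = float(np.sum((gc - gc.mean()) * (yc - yc.mean())))
    beta = sxy / sxx
    rss = syy - beta * sxy
    r2 = (sxy * sxy) / (sxx * syy)
    if rss <= _DEGENERATE_RSS * syy:
        return EqtlResult(
            snp_id=snp_id,
            probeset_id=probeset_id,
            gene=gene,
            beta=beta,
            se=0.0,
            wald=np.inf if beta > 0 else -np.inf,
            p=np.nextafter(0.0, 1.0),
            r2=r2,
            n=n,
            cohort=cohort,
            status=STATUS_DEGENERATE,
        )
    se = float(np.sqrt(rss / (n - 2) / sxx))
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return EqtlResult(
        snp_id=snp_id,
        probeset_id=probeset_id,
        gene=gene,
        beta=beta,
        se=se,
        wald=t,
        p=p,
        r2=r2,
        n=n,
        cohort=cohort,
        status=STATUS_OK,
    )


def scan_locus(
    genotypes: GenotypeMatrix,
    adjusted_traits: list[AdjustedTrait],
    locus: LocusDefinition,
    cohort: str = "",
    maf: float = 0.0,
) -> list[EqtlResult]:
    """Test every SNP in the locus window against every locus probeset.

    Returns exactly ``n_snps_in_window x n_probesets_in_locus`` results
    (testable or flagged) in deterministic SNP-major order.  ``maf`` is an
    optional minor-allele-frequency filter (default 0: no filter).
    """
    window = genotypes.window(locus.chrom, locus.start, locus.end)
    traits = [
        t for t in adjusted_traits if not locus.genes or t.gene in locus.genes
    ]
    if window.n_snps == 0 or not traits:
        warnings.warn(
            f"locus {locus.name}: empty scan "
            f"({window.n_snps} SNPs in window, {len(traits)} probesets)",
            stacklevel=2,
        )
        return []
    results: list[EqtlResult] = []
    for j, snp in enumerate(window.snps):
        g = window.dosages[:, j]
        if maf > 0:
            gf = g[np.isfinite(g)]
            if gf.size == 0:
                continue
            af = gf.mean() / 2.0
            if min(af, 1 - af) < maf:
                continue
        for trait in traits:
            results.append(
                fit_single(
                    g,
                    trait.residuals,
                    snp_id=snp.snp_id,
                    probeset_id=trait.probeset_id,
                    gene=trait.gene,
                    cohort=cohort,
                )
            )
    return results
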
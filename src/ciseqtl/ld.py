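"""Pairwise linkage disequilibrium from unphased dosages and GWAS-SNP linkage.

r-squared is the squared Pearson correlation of the two dosage vectors
(the composite-LD approximation; no phasing model).  An eQTL-SNP is
"linked" to the disease signal when its best r-squared against any GWAS
SNP in the locus exceeds the threshold (default 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import EqtlResult, GenotypeMatrix, SnpRecord


def r2_dosage(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    Returns NaN (with a warning) when either SNP is monomorphic on the
    complete subset — undefined LD, deliberately not 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = np.isfinite(g1) & np.isfinite(g2)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 pairwise-complete samples, got {n}")
    a = g1[mask]
    b = g2[mask]
    va = np.var(a)
    vb = np.var(b)
    if va == 0.0 or vb == 0.0:
        warnings.warn("monomorphic SNP on the complete subset: r2 undefined", stacklevel=2)
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric r-squared matrix over all SNP pairs (NaN where undefined)."""
    ids = genotypes.snp_ids
    m = len(ids)
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    r2 = r2_dosage(genotypes.dosages[:, i], genotypes.dosages[:, j])
                except ValueError:
                    r2 = float("nan")
            out[i, j] = out[j, i] = r2
    return pd.DataFrame(out, index=ids, columns=ids)


NOT_GENOTYPED = "not_genotyped"


def link_to_gwas(
    eqtl_results: list[EqtlResult],
    gwas_snps: list[SnpRecord],
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """Best r-squared from each significant eQTL-SNP to any GWAS SNP in the panel.

    Returns one row per unique eQTL-SNP: ``eqtl_snp, best_gwas_snp, r2,
    linked, status`` plus one row per GWAS SNP absent from the genotype
    panel (status "not_genotyped", no r-squared reported).
    """
    if not gwas_snps:
        raise ValueError("empty GWAS SNP list")
    panel = set(genotypes.snp_ids)
    present = [s for s in gwas_snps if s.snp_id in panel]
    absent = [s for s in gwas_snps if s.snp_id not in panel]

    eqtl_ids = sorted({r.snp_id for r in eqtl_results})
    rows = []
    for snp_id in eqtl_ids:
        g_e = genotypes.dosage_of(snp_id)
        best_r2 = float("nan")
        best_snp = ""
        for gs in present:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = r2_dosage(g_e, genotypes.dosage_of(gs.snp_id))
            if np.isfinite(r2) and (not np.isfinite(best_r2) or r2 > best_r2):
                best_r2 = r2
                best_snp = gs.snp_id
        if present and np.isfinite(best_r2):
            rows.append(
                {
                    "eqtl_snp": snp_id,
                    "best_gwas_snp": best_snp,
                    "r2": best_r2,
                    "linked": bool(best_r2 > r2_threshold),
                    "status": "ok",
                }
            )
        else:
            rows.append(
                {
                    "eqtl_snp": snp_id,
                    "best_gwas_snp": "",
                    "r2": float("nan"),
                    "linked": False,
                    "status": NOT_GENOTYPED,
                }
            )
    for gs in absent:
        rows.append(
            {
                "eqtl_snp": "",
                "best_gwas_snp": gs.snp_id,
                "r2": float("nan"),
                "linked": False,
                "status": NOT_GENOTYPED,
            }
        )
    return pd.DataFrame(
        rows, columns=["eqtl_snp", "best_gwas_snp", "r2", "linked", "status"]
    )
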
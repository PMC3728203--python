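"""Readers and writers for genotypes, expression, covariates, loci and results.

All positions are stored 1-based inclusive internally.  BED-style locus
input (0-based half-open) is converted at the boundary by
:func:`read_locus_bed` and never anywhere else.
"""

from __future__ import annotations

import csv
import math
import os
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CovariateTable,
    EqtlResult,
    ExpressionMatrix,
    GenotypeMatrix,
    LocusDefinition,
    SnpRecord,
)


class VcfParseError(ValueError):
    pass


def _check_vcf_header_samples(path: str | os.PathLike) -> None:
    """Fail with an explicit message on duplicate sample IDs (plain-text VCF only)."""
    try:
        with open(path, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":  # gzip/BGZF: leave header checks to htslib
                return
            fh.seek(0)
            for raw in fh:
                line = raw.decode("utf-8", errors="replace").rstrip("\n")
                if line.startswith("#CHROM"):
                    samples = line.split("\t")[9:]
                    dup = sorted({s for s in samples if samples.count(s) > 1})
                    if dup:
                        raise VcfParseError(f"duplicate sample IDs in VCF header: {dup}")
                    return
                if not line.startswith("#"):
                    return
    except OSError as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic VCF into an additive dosage matrix.

    Dosage counts the alt allele (0/1/2); missing genotypes become NaN.
    Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    _check_vcf_header_samples(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise VcfParseError(f"duplicate sample IDs in VCF header: {dup}")

    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    try:
        for i, var in enumerate(vcf, start=1):
            if len(var.ALT) != 1:
                raise VcfParseError(
                    f"record {i} ({var.CHROM}:{var.POS}): multi-allelic ALT "
                    f"{','.join(var.ALT) or '.'} not supported; split or filter first"
                )
            snp_id = var.ID or f"{var.CHROM}:{var.POS}"
            snps.append(
                SnpRecord(
                    snp_id=snp_id,
                    chrom=str(var.CHROM),
                    pos=int(var.POS),
                    ref_allele=var.REF,
                    alt_allele=var.ALT[0],
                    counted_allele=var.ALT[0],
                )
            )
            # gts012: 0/1/2 = alt count, 3 = missing
            g = var.gt_types.astype(float)
            g[g == 3] = np.nan
            rows.append(g)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path} near record {len(snps) + 1}: {exc}") from exc

    dosages = (
        np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0), dtype=float)
    )
    return GenotypeMatrix(sample_ids=samples, snps=snps, dosages=dosages)


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write dosages back out as a minimal VCF 4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(gm.snps):
            gts = [
                "./." if not math.isfinite(d) else _GT_BY_DOSAGE[int(d)]
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    return float("nan") if cell in ("", "NA", "nan") else float(cell)


def read_matrix_tsv(
    path: str | os.PathLike, orientation: str = "samples_by_features"
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a rectangular TSV with a header row and a leading ID column.

    Returns ``(sample_ids, feature_ids, values)`` with values oriented
    samples x features.  ``orientation`` describes the file layout:
    ``"samples_by_features"`` (rows are samples) or ``"features_by_samples"``
    (rows are features; output is transposed to the internal convention).
    Empty cells become NaN; ragged rows raise with the row number.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        col_ids = header[1:]
        row_ids: list[str] = []
        data: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: ragged row {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            row_ids.append(row[0])
            data.append([_parse_cell(c) for c in row[1:]])
    values = np.array(data, dtype=float) if data else np.empty((0, len(col_ids)))
    if orientation == "features_by_samples":
        return col_ids, row_ids, values.T
    return row_ids, col_ids, values


def write_matrix_tsv(
    path: str | os.PathLike,
    sample_ids: list[str],
    feature_ids: list[str],
    values: np.ndarray,
    corner: str = "sample_id",
) -> None:
    with open(path, "w") as fh:
        fh.write(corner + "\t" + "\t".join(feature_ids) + "\n")
        for i, sid in enumerate(sample_ids):
            cells = ["" if not math.isfinite(v) else repr(float(v)) for v in values[i]]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_expression_tsv(path: str | os.PathLike) -> ExpressionMatrix:
    """Expression TSV: rows are probesets with columns probeset_id, gene, <samples...>."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["probeset_id", "gene"]:
            raise ValueError(
                f"{path}: expected leading columns 'probeset_id', 'gene', got {header[:2]}"
            )
        sample_ids = header[2:]
        probesets: list[tuple[str, str]] = []
        data: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: ragged row {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            probesets.append((row[0], row[1]))
            data.append([_parse_cell(c) for c in row[2:]])
    values = np.array(data, dtype=float).T if data else np.empty((len(sample_ids), 0))
    return ExpressionMatrix(sample_ids=sample_ids, probesets=probesets, values=values)


def write_expression_tsv(em: ExpressionMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("probeset_id\tgene\t" + "\t".join(em.sample_ids) + "\n")
        for j, (pid, gene) in enumerate(em.probesets):
            cells = ["" if not math.isfinite(v) else repr(float(v)) for v in em.values[:, j]]
            fh.write(f"{pid}\t{gene}\t" + "\t".join(cells) + "\n")


def read_covariates_tsv(path: str | os.PathLike) -> CovariateTable:
    """Covariate TSV with columns sample_id, age, sex, smoking."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "age", "sex", "smoking"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate columns {missing}")
    age = np.array([_parse_cell(a) for a in df["age"]])
    smoking = [s if s else "unknown" for s in df["smoking"]]
    return CovariateTable(
        sample_ids=list(df["sample_id"]),
        age=age,
        sex=list(df["sex"]),
        smoking=smoking,
    )


def write_covariates_tsv(cov: CovariateTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tage\tsex\tsmoking\n")
        for i, sid in enumerate(cov.sample_ids):
            a = "" if not math.isfinite(cov.age[i]) else repr(float(cov.age[i]))
            fh.write(f"{sid}\t{a}\t{cov.sex[i]}\t{cov.smoking[i]}\n")


def read_locus_yaml(path: str | os.PathLike) -> list[LocusDefinition]:
    """Locus definitions from YAML/JSON.

    Each entry: name, chrom, gwas_snps ([{snp_id, pos, ref, alt}]), genes,
    and either explicit start/end or nothing (the window is then built by
    the pipeline from the GWAS SNPs and its flank).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    loci = doc["loci"] if isinstance(doc, dict) else doc
    out = []
    for entry in loci:
        gwas = [
            SnpRecord(
                snp_id=s["snp_id"],
                chrom=str(entry["chrom"]),
                pos=int(s["pos"]),
                ref_allele=s.get("ref", "A"),
                alt_allele=s.get("alt", "G"),
            )
            for s in entry.get("gwas_snps", [])
        ]
        positions = [s.pos for s in gwas]
        start = int(entry.get("start", min(positions) if positions else 1))
        end = int(entry.get("end", max(positions) if positions else 1))
        out.append(
            LocusDefinition(
                name=str(entry["name"]),
                chrom=str(entry["chrom"]),
                start=start,
                end=end,
                gwas_snps=gwas,
                genes=[str(g) for g in entry.get("genes", [])],
            )
        )
    return out


def read_locus_bed(path: str | os.PathLike) -> list[LocusDefinition]:
    """BED locus input (0-based half-open) converted to 1-based inclusive here."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            out.append(
                LocusDefinition(name=name, chrom=chrom, start=start0 + 1, end=end0)
            )
    return out


RESULT_COLUMNS = ["snp_id", "probeset_id", "gene", "beta", "se", "wald", "p", "r2", "n", "cohort", "status"]


def results_to_frame(results: Iterable[EqtlResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "probeset_id": r.probeset_id,
                "gene": r.gene,
                "beta": r.beta,
                "se": r.se,
                "wald": r.wald,
                "p": r.p,
                "r2": r.r2,
                "n": r.n,
                "cohort": r.cohort,
                "status": r.status,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
    # deterministic ordering: p ascending (NaN last), then snp_id, probeset_id
    return df.sort_values(
        ["p", "snp_id", "probeset_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def write_results(results: Iterable[EqtlResult], path: str | os.PathLike) -> None:
    """Write eQTL results as a deterministic-ordered TSV (header-only if empty)."""
    df = results_to_frame(results)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_results(path: str | os.PathLike) -> list[EqtlResult]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EqtlResult(
                snp_id=str(row.snp_id),
                probeset_id=str(row.probeset_id),
                gene=str(row.gene),
                beta=float(row.beta) if pd.notna(row.beta) else float("nan"),
                se=float(row.se) if pd.notna(row.se) else float("nan"),
                wald=float(row.wald) if pd.notna(row.wald) else float("nan"),
                p=float(row.p) if pd.notna(row.p) else float("nan"),
                r2=float(row.r2) if pd.notna(row.r2) else float("nan"),
                n=int(row.n),
                cohort="" if pd.isna(row.cohort) else str(row.cohort),
                status=str(row.status),
            )
        )
    return out
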
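"""End-to-end orchestration: windows, adjustment, scans, thresholds, replication, LD.

``run`` executes the full discovery/replication procedure per locus and
writes a deterministic TSV report bundle plus a JSON run log.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, adjustment, association, data_io, ld, multiple_testing, replication
from .datatypes import (
    AdjustedTrait,
    CovariateTable,
    EqtlResult,
    ExpressionMatrix,
    GenotypeMatrix,
    LocusDefinition,
    SnpRecord,
)

log = logging.getLogger("ciseqtl")

DEFAULT_FLANK_BP = 1_000_000


class InputError(ValueError):
    """Bad or inconsistent input files / config (CLI exit code 2)."""


class ComputationError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


def build_locus_window(
    gwas_snps: list[SnpRecord],
    flank_bp: int = DEFAULT_FLANK_BP,
    name: str = "",
    genes: list[str] | None = None,
) -> LocusDefinition:
    """Analysis window: flank on each side of the most distant GWAS SNPs.

    start = min(pos) - flank (floored at 1), end = max(pos) + flank.
    All SNPs must lie on one chromosome.
    """
    if not gwas_snps:
        raise ValueError("need at least one GWAS SNP to build a locus window")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    chroms = {s.chrom for s in gwas_snps}
    if len(chroms) != 1:
        raise ValueError(f"GWAS SNPs span multiple chromosomes: {sorted(chroms)}")
    positions = [s.pos for s in gwas_snps]
    return LocusDefinition(
        name=name or f"{gwas_snps[0].chrom}:{min(positions)}-{max(positions)}",
        chrom=gwas_snps[0].chrom,
        start=max(min(positions) - flank_bp, 1),
        end=max(positions) + flank_bp,
        gwas_snps=list(gwas_snps),
        genes=list(genes or []),
    )


@dataclass
class CohortData:
    name: str
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    covariates: CovariateTable


@dataclass
class PipelineConfig:
    cohorts: list[CohortData]
    discovery: str
    loci: list[LocusDefinition]
    flank_bp: int = DEFAULT_FLANK_BP
    alpha: float = 0.05
    alpha_rep: float = 0.05
    r2_link_threshold: float = 0.5
    maf: float = 0.0
    require_direction: bool = False
    outdir: str = "results"
    seed: int | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate cohort names: {names}")
        if names.count(self.discovery) != 1 or self.discovery not in names:
            raise InputError(f"exactly one discovery cohort required; got {self.discovery!r}")
        if self.flank_bp < 0:
            raise InputError("flank_bp must be >= 0")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Read a YAML/JSON pipeline config referencing per-cohort data files.

    Layout::

        discovery: cohort1
        flank_bp: 1000000
        alpha: 0.05
        alpha_rep: 0.05
        r2_link_threshold: 0.5
        outdir: results
        cohorts:
          - name: cohort1
            genotypes: cohort1.vcf
            expression: cohort1_expression.tsv
            covariates: cohort1_covariates.tsv
        loci:
          - name: locusA
            chrom: "4"
            genes: [GENE1, GENE2]
            gwas_snps:
              - {snp_id: rs1, pos: 89875909}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    try:
        cohorts = []
        for c in doc["cohorts"]:
            cohorts.append(
                CohortData(
                    name=str(c["name"]),
                    genotypes=data_io.read_vcf(_resolve(c["genotypes"])),
                    expression=data_io.read_expression_tsv(_resolve(c["expression"])),
                    covariates=data_io.read_covariates_tsv(_resolve(c["covariates"])),
                )
            )
        flank = int(doc.get("flank_bp", DEFAULT_FLANK_BP))
        loci = []
        for entry in doc["loci"]:
            gwas = [
                SnpRecord(snp_id=s["snp_id"], chrom=str(entry["chrom"]), pos=int(s["pos"]))
                for s in entry.get("gwas_snps", [])
            ]
            genes = [str(g) for g in entry.get("genes", [])]
            if "start" in entry and "end" in entry:
                loci.append(
                    LocusDefinition(
                        name=str(entry["name"]),
                        chrom=str(entry["chrom"]),
                        start=int(entry["start"]),
                        end=int(entry["end"]),
                        gwas_snps=gwas,
                        genes=genes,
                    )
                )
            else:
                loci.append(build_locus_window(gwas, flank, name=str(entry["name"]), genes=genes))
        return PipelineConfig(
            cohorts=cohorts,
            discovery=str(doc["discovery"]),
            loci=loci,
            flank_bp=flank,
            alpha=float(doc.get("alpha", 0.05)),
            alpha_rep=float(doc.get("alpha_rep", 0.05)),
            r2_link_threshold=float(doc.get("r2_link_threshold", 0.5)),
            maf=float(doc.get("maf", 0.0)),
            require_direction=bool(doc.get("require_direction", False)),
            outdir=str(doc.get("outdir", "results")),
            seed=doc.get("seed"),
        )
    except KeyError as exc:
        raise InputError(f"config {path}: missing key {exc}") from exc


@dataclass
class LocusReport:
    locus: LocusDefinition
    threshold: "multiple_testing.LocusThreshold"
    discovery_results: list[EqtlResult]
    significant: list[EqtlResult]
    replication_records: list
    linkage: pd.DataFrame
    counts: dict = field(default_factory=dict)


def _adjust_cohort(cohort: CohortData) -> list[AdjustedTrait]:
    try:
        return adjustment.adjust_expression(cohort.expression, cohort.covariates)
    except ValueError as exc:
        raise ComputationError(f"adjustment stage, cohort {cohort.name}: {exc}") from exc


def run(config: PipelineConfig) -> dict[str, LocusReport]:
    """Full pipeline; writes the report bundle under ``config.outdir``.

    Per locus: adjust traits per cohort, scan the discovery cohort, derive
    the composite Meff threshold, scan replication cohorts, classify
    replication, and link significant eQTL-SNPs to the GWAS SNPs by LD.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    discovery = next(c for c in config.cohorts if c.name == config.discovery)
    others = [c for c in config.cohorts if c.name != config.discovery]

    adjusted: dict[str, list[AdjustedTrait]] = {}
    for cohort in config.cohorts:
        log.info("adjusting %d traits in cohort %s", cohort.expression.n_probesets, cohort.name)
        adjusted[cohort.name] = _adjust_cohort(cohort)

    reports: dict[str, LocusReport] = {}
    threshold_rows = []
    log_entries = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "alpha": config.alpha,
        "alpha_rep": config.alpha_rep,
        "r2_link_threshold": config.r2_link_threshold,
        "maf_filter": config.maf,
        "flank_bp": config.flank_bp,
        "seed": config.seed,
        "discovery_cohort": config.discovery,
        "cohorts": {c.name: c.genotypes.n_samples for c in config.cohorts},
        "loci": {},
    }

    for locus in config.loci:
        try:
            report = _run_locus(config, locus, discovery, others, adjusted)
        except (ValueError, KeyError) as exc:
            raise ComputationError(f"locus {locus.name}: {exc}") from exc
        reports[locus.name] = report
        th = report.threshold
        threshold_rows.append(
            {
                "locus": locus.name,
                "m_snps": th.m_snps,
                "m_probes": th.m_probes,
                "meff_snps": th.meff_snps,
                "meff_probes": th.meff_probes,
                "alpha": th.alpha,
                "threshold": th.threshold,
                "threshold_display": th.display,
            }
        )
        log_entries["loci"][locus.name] = report.counts

        data_io.write_results(report.discovery_results, outdir / f"eqtl_full_{locus.name}.tsv")
        data_io.write_results(report.significant, outdir / f"eqtl_significant_{locus.name}.tsv")
        replication.records_to_frame(report.replication_records).to_csv(
            outdir / f"replication_{locus.name}.tsv",
            sep="\t",
            index=False,
            na_rep="NA",
            float_format="%.12g",
        )
        report.linkage.to_csv(
            outdir / f"ld_linkage_{locus.name}.tsv",
            sep="\t",
            index=False,
            na_rep="NA",
            float_format="%.12g",
        )
        _write_boxplot_data(
            report, discovery, adjusted[discovery.name], outdir / f"boxplot_{locus.name}.tsv"
        )

    pd.DataFrame(
        threshold_rows,
        columns=[
            "locus",
            "m_snps",
            "m_probes",
            "meff_snps",
            "meff_probes",
            "alpha",
            "threshold",
            "threshold_display",
        ],
    ).to_csv(outdir / "thresholds.tsv", sep="\t", index=False, na_rep="NA", float_format="%.12g")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log_entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return reports


def _run_locus(
    config: PipelineConfig,
    locus: LocusDefinition,
    discovery: CohortData,
    others: list[CohortData],
    adjusted: dict[str, list[AdjustedTrait]],
) -> LocusReport:
    window = discovery.genotypes.window(locus.chrom, locus.start, locus.end)
    locus_traits = [
        t for t in adjusted[discovery.name] if not locus.genes or t.gene in locus.genes
    ]
    log.info("locus %s: %d SNPs in window, %d probesets", locus.name, window.n_snps, len(locus_traits))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        disc_results = association.scan_locus(
            discovery.genotypes,
            adjusted[discovery.name],
            locus,
            cohort=discovery.name,
            maf=config.maf,
        )

    if window.n_snps >= 1 and locus_traits:
        meff_snp = multiple_testing.effective_tests(multiple_testing.snp_correlation(window))
        meff_probe = multiple_testing.effective_tests(
            multiple_testing.probe_correlation(locus_traits)
        )
        meff_snp = max(meff_snp, 1.0)
        meff_probe = max(meff_probe, 1.0)
    else:
        meff_snp = meff_probe = 1.0
    threshold = multiple_testing.locus_threshold(
        meff_snp,
        meff_probe,
        alpha=config.alpha,
        locus=locus.name,
        m_snps=window.n_snps,
        m_probes=len(locus_traits),
    )

    significant = [
        r
        for r in disc_results
        if r.testable and np.isfinite(r.p) and r.p < threshold.threshold
    ]

    rep_results = {}
    for cohort in others:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_results[cohort.name] = association.scan_locus(
                cohort.genotypes, adjusted[cohort.name], locus, cohort=cohort.name, maf=config.maf
            )
    records = replication.classify(
        disc_results,
        rep_results,
        threshold.threshold,
        alpha_rep=config.alpha_rep,
        require_direction=config.require_direction,
    )

    if locus.gwas_snps and significant:
        linkage = ld.link_to_gwas(
            significant, locus.gwas_snps, discovery.genotypes, config.r2_link_threshold
        )
    else:
        linkage = pd.DataFrame(columns=["eqtl_snp", "best_gwas_snp", "r2", "linked", "status"])

    summary = replication.summarize(records)
    counts = {
        "snps_in_window": window.n_snps,
        "probesets_tested": len(locus_traits),
        "tests_performed": len(disc_results),
        "testable": sum(1 for r in disc_results if r.testable),
        "significant": len(significant),
        **summary,
    }
    return LocusReport(
        locus=locus,
        threshold=threshold,
        discovery_results=disc_results,
        significant=significant,
        replication_records=records,
        linkage=linkage,
        counts=counts,
    )


def _write_boxplot_data(
    report: LocusReport,
    discovery: CohortData,
    traits: list[AdjustedTrait],
    path: Path,
) -> None:
    """Genotype-group residual export for the top eQTL of each significant probeset."""
    trait_by_id = {t.probeset_id: t for t in traits}
    best: dict[str, EqtlResult] = {}
    for r in report.significant:
        cur = best.get(r.probeset_id)
        if cur is None or r.p < cur.p:
            best[r.probeset_id] = r
    rows = []
    for pid in sorted(best):
        r = best[pid]
        g = discovery.genotypes.dosage_of(r.snp_id)
        resid = trait_by_id[pid].residuals
        for sid, gi, yi in zip(discovery.genotypes.sample_ids, g, resid):
            if np.isfinite(gi) and np.isfinite(yi):
                rows.append(
                    {
                        "snp_id": r.snp_id,
                        "probeset_id": pid,
                        "sample_id": sid,
                        "dosage": int(gi),
                        "residual": yi,
                    }
                )
    pd.DataFrame(rows, columns=["snp_id", "probeset_id", "sample_id", "dosage", "residual"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
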
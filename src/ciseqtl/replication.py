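"""Replication classification of discovery-cohort eQTLs across cohorts.

A discovery result below its locus threshold is carried into the
replication cohorts, where nominal p < alpha_rep counts as replicating.
Direction consistency (same slope sign across all significant cohorts) is
recorded, and optionally required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EqtlResult

NOT_SIGNIFICANT = "not_significant"
DISCOVERY_ONLY = "discovery_only"
REPLICATED_ONE = "replicated_one"
REPLICATED_BOTH = "replicated_both"

#: rank order used by the monotonicity property: later = stronger
STATUS_ORDER = (NOT_SIGNIFICANT, DISCOVERY_ONLY, REPLICATED_ONE, REPLICATED_BOTH)


@dataclass
class ReplicationRecord:
    snp_id: str
    probeset_id: str
    gene: str
    discovery_p: float
    threshold: float
    rep_p: dict[str, float]
    rep_direction: dict[str, int]
    status: str
    direction_consistent: bool

    @property
    def status_rank(self) -> int:
        return STATUS_ORDER.index(self.status)


def _key(r: EqtlResult) -> tuple[str, str]:
    return (r.snp_id, r.probeset_id)


def classify(
    discovery: list[EqtlResult],
    replications: dict[str, list[EqtlResult]],
    threshold: float,
    alpha_rep: float = 0.05,
    require_direction: bool = False,
) -> list[ReplicationRecord]:
    """One record per discovery-significant (SNP, probeset) pair.

    Untestable pairs in a replication cohort count as non-replicating
    there.  ``replicated_one`` means significant in at least one but not
    all replication cohorts; ``replicated_both`` requires all of them.
    With ``require_direction`` a replication cohort only counts when its
    slope sign matches the discovery slope.
    """
    rep_maps = {}
    for cohort, results in replications.items():
        rep_maps[cohort] = {_key(r): r for r in results}

    disc_sig = [r for r in discovery if r.testable and np.isfinite(r.p) and r.p < threshold]
    missing: list[tuple[str, tuple[str, str]]] = []
    for r in disc_sig:
        for cohort, m in rep_maps.items():
            if _key(r) not in m:
                missing.append((cohort, _key(r)))
    if missing:
        shown = ", ".join(f"{c}:{k[0]}/{k[1]}" for c, k in missing[:10])
        raise ValueError(
            f"{len(missing)} discovery-significant pairs missing from replication cohorts: {shown}"
        )

    records = []
    for r in discovery:
        if not (r.testable and np.isfinite(r.p)):
            continue
        if r.p >= threshold:
            continue
        rep_p: dict[str, float] = {}
        rep_dir: dict[str, int] = {}
        n_rep = 0
        sig_dirs = [r.direction]
        for cohort, m in rep_maps.items():
            rr = m[_key(r)]
            rep_p[cohort] = rr.p
            rep_dir[cohort] = rr.direction
            ok = rr.testable and np.isfinite(rr.p) and rr.p < alpha_rep
            if ok and require_direction:
                ok = rr.direction == r.direction
            if ok:
                n_rep += 1
                sig_dirs.append(rr.direction)
        if n_rep == 0:
            status = DISCOVERY_ONLY
        elif n_rep == len(rep_maps):
            status = REPLICATED_BOTH
        else:
            status = REPLICATED_ONE
        records.append(
            ReplicationRecord(
                snp_id=r.snp_id,
                probeset_id=r.probeset_id,
                gene=r.gene,
                discovery_p=r.p,
                threshold=threshold,
                rep_p=rep_p,
                rep_direction=rep_dir,
                status=status,
                direction_consistent=len(set(sig_dirs)) == 1,
            )
        )
    return records


def summarize(records: list[ReplicationRecord]) -> dict[str, int]:
    counts = {s: 0 for s in STATUS_ORDER if s != NOT_SIGNIFICANT}
    for r in records:
        counts[r.status] += 1
    counts["total_significant"] = len(records)
    return counts


def records_to_frame(records: list[ReplicationRecord]) -> pd.DataFrame:
    cohorts = sorted({c for r in records for c in r.rep_p}) if records else []
    rows = []
    for r in sorted(records, key=lambda x: (x.discovery_p, x.snp_id, x.probeset_id)):
        row = {
            "snp_id": r.snp_id,
            "probeset_id": r.probeset_id,
            "gene": r.gene,
            "discovery_p": r.discovery_p,
            "threshold": r.threshold,
        }
        for c in cohorts:
            row[f"p_{c}"] = r.rep_p.get(c, float("nan"))
            row[f"direction_{c}"] = r.rep_direction.get(c, 0)
        row["status"] = r.status
        row["direction_consistent"] = r.direction_consistent
        rows.append(row)
    cols = ["snp_id", "probeset_id", "gene", "discovery_p", "threshold"]
    for c in cohorts:
        cols += [f"p_{c}", f"direction_{c}"]
    cols += ["status", "direction_consistent"]
    return pd.DataFrame(rows, columns=cols)
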
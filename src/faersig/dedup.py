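"""Case deduplication: collapse report versions to one record per case.

FAERS re-publishes a case every time it is amended, so a caseid usually has
several versions with distinct primaryids.  The retention rule is: keep the
version with the highest FDA receipt date (``fda_dt``); if several versions
share that date, keep the one with the largest ``primaryid``.  A version with
a missing ``fda_dt`` ranks below any dated version.  Child tables are taken
only from the surviving version, never merged across versions.

Deleted/problem cases listed in the quarterly deletion files are removed
after version selection (deletion lists address cases, not versions, so the
order does not change the surviving caseid set).
"""
from __future__ import annotations

from collections.abc import Iterable, Set
from pathlib import Path

from .types import (
    CaseRecord,
    CaseVersion,
    DrugMention,
    EventMention,
    OutcomeMention,
    TherapyRecord,
)

__all__ = ["sort_key", "deduplicate", "apply_deletions", "write_audit_log"]


def sort_key(version: CaseVersion) -> tuple[int, int]:
    """Retention key: lexicographic (fda_dt, primaryid), missing date lowest."""
    return (version.fda_dt if version.fda_dt is not None else -1, version.primaryid)


def deduplicate(
    versions: Iterable[CaseVersion],
    drugs: Iterable[DrugMention] = (),
    events: Iterable[EventMention] = (),
    outcomes: Iterable[OutcomeMention] = (),
    therapies: Iterable[TherapyRecord] = (),
) -> list[CaseRecord]:
    """Reduce versions to one :class:`CaseRecord` per caseid.

    Child rows are attached from the surviving primaryid only.  The result is
    sorted by caseid, so the operation is order-independent and idempotent.
    """
    best: dict[int, CaseVersion] = {}
    for v in versions:
        cur = best.get(v.caseid)
        if cur is None or sort_key(v) > sort_key(cur):
            best[v.caseid] = v

    surviving_pids = {v.primaryid for v in best.values()}

    def group(rows):
        by_pid: dict[int, list] = {}
        for r in rows:
            if r.primaryid in surviving_pids:
                by_pid.setdefault(r.primaryid, []).append(r)
        return by_pid

    drugs_by = group(drugs)
    events_by = group(events)
    outcomes_by = group(outcomes)
    therapies_by = group(therapies)

    records = []
    for caseid in sorted(best):
        v = best[caseid]
        records.append(
            CaseRecord(
                caseid=caseid,
                primaryid=v.primaryid,
                fda_dt=v.fda_dt,
                version=v,
                drugs=tuple(drugs_by.get(v.primaryid, ())),
                events=tuple(events_by.get(v.primaryid, ())),
                outcomes=tuple(outcomes_by.get(v.primaryid, ())),
                therapies=tuple(therapies_by.get(v.primaryid, ())),
            )
        )
    return records


def apply_deletions(
    records: Iterable[CaseRecord], deleted_caseids: Set[int]
) -> tuple[list[CaseRecord], int]:
    """Drop cases on the deletion list; returns (kept records, n removed)."""
    records = list(records)
    kept = [r for r in records if r.caseid not in deleted_caseids]
    return kept, len(records) - len(kept)


def write_audit_log(
    path: str | Path,
    versions_seen: int,
    survivors: Iterable[CaseRecord],
    deletions_applied: int,
) -> None:
    """Write a small TSV audit trail of the dedup stage."""
    survivors = list(survivors)
    lines = ["metric\tvalue"]
    lines.append(f"versions_seen\t{versions_seen}")
    lines.append(f"cases_after_dedup\t{len(survivors)}")
    lines.append(f"deletions_applied\t{deletions_applied}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
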
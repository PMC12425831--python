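"""End-to-end orchestration: ingest -> dedup -> deletions -> cohort ->
contingency tables -> four-algorithm signals -> rankings, with a manifest
recording the attrition flow at every stage.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import (
    BaselineSummary,
    CohortSpec,
    OnsetDistribution,
    annual_counts,
    match_target_cases,
    onset_distribution,
    summarize_baseline,
)
from .dedup import apply_deletions, deduplicate
from .faers_io import QuarterData, attach_therapy_dates, read_meddra_map, read_quarter
from .types import CaseRecord, MeddraMap
from .signals import (
    SignalRow,
    Thresholds,
    build_tables,
    case_pt_pairs,
    case_soc_pairs,
    compute_signal_rows,
    rank_signals,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze", "run_pipeline", "discover_quarters"]


@dataclass
class RunConfig:
    quarter_dirs: tuple[str, ...]
    meddra_path: str
    out_dir: str
    cohort: CohortSpec = field(default_factory=CohortSpec)
    thresholds: Thresholds = field(default_factory=Thresholds)
    chi2_variant: str = "yates"
    ic025_variant: str = "z196"
    ebgm_quantile: float = 0.05
    top_k: int = 30
    seed: int = 0


@dataclass
class PipelineResult:
    baseline: BaselineSummary
    annual: dict[int, int]
    annual_mean: int
    onset: OnsetDistribution
    pt_rows: list[SignalRow]
    soc_rows: list[SignalRow]
    top_by_frequency: list[SignalRow]
    top_by_ebgm05: list[SignalRow]
    manifest: dict


def discover_quarters(directory: str | Path) -> list[str]:
    """Quarter labels present in a directory, from its DEMO file names."""
    labels = []
    for path in sorted(Path(directory).iterdir()):
        name = path.name.upper()
        if name.startswith("DEMO") and name.endswith(".TXT"):
            labels.append(name[4:-4])
    return labels


def _merge_quarters(quarters: list[QuarterData]) -> QuarterData:
    merged = QuarterData(label="ALL")
    for q in quarters:
        merged.case_versions.extend(q.case_versions)
        merged.drugs.extend(q.drugs)
        merged.events.extend(q.events)
        merged.outcomes.extend(q.outcomes)
        merged.therapies.extend(q.therapies)
        merged.indications.extend(q.indications)
        merged.report_sources.extend(q.report_sources)
        merged.deleted_caseids |= q.deleted_caseids
    return merged


def analyze(
    data: QuarterData,
    meddra: MeddraMap,
    spec: CohortSpec | None = None,
    thresholds: Thresholds | None = None,
    chi2_variant: str = "yates",
    ic025_variant: str = "z196",
    ebgm_quantile: float = 0.05,
    top_k: int = 30,
) -> PipelineResult:
    """Run every analysis stage over an in-memory corpus."""
    spec = spec or CohortSpec()
    thresholds = thresholds or Thresholds()

    drugs = attach_therapy_dates(data.drugs, data.therapies, data.indications)
    records = deduplicate(data.case_versions, drugs, data.events, data.outcomes, data.therapies)
    n_after_dedup = len(records)
    records, n_deleted = apply_deletions(records, data.deleted_caseids)
    logger.info("dedup: %d versions -> %d cases, %d deleted",
                len(data.case_versions), n_after_dedup, n_deleted)

    target = match_target_cases(records, spec)
    cohort_records = [r for r in records if r.caseid in target]
    logger.info("cohort: %d target cases", len(cohort_records))

    baseline = summarize_baseline(cohort_records)
    annual, annual_mean = annual_counts(cohort_records, window=spec.window)
    onset = onset_distribution(cohort_records, spec)

    pt_pairs = case_pt_pairs(records)
    soc_pairs = case_soc_pairs(records, meddra)
    pt_tables = build_tables(pt_pairs, target)
    soc_tables = build_tables(soc_pairs, target)
    # only terms observed in the target cohort are scored
    pt_tables = {t: tab for t, tab in pt_tables.items() if tab.a > 0}
    soc_tables = {t: tab for t, tab in soc_tables.items() if tab.a > 0}
    logger.info("signals: %d PT terms, %d SOC terms", len(pt_tables), len(soc_tables))

    kwargs = dict(thresholds=thresholds, chi2_variant=chi2_variant,
                  ic025_variant=ic025_variant, ebgm_quantile=ebgm_quantile)
    pt_rows = compute_signal_rows(pt_tables, level="PT", **kwargs)
    soc_rows = compute_signal_rows(soc_tables, level="SOC", **kwargs)

    manifest = {
        "version": __version__,
        "counts": {
            "versions_read": len(data.case_versions),
            "cases_after_dedup": n_after_dedup,
            "deletions_applied": n_deleted,
            "cases_after_deletions": len(records),
            "target_cases": len(cohort_records),
            "case_pt_pairs": len(pt_pairs),
            "target_case_pt_pairs": sum(1 for cid, _ in pt_pairs if cid in target),
            "pt_terms_scored": len(pt_tables),
            "soc_terms_scored": len(soc_tables),
            "pt_signals": int(sum(bool(r.is_signal) for r in pt_rows)),
            "soc_signals": int(sum(bool(r.is_signal) for r in soc_rows)),
        },
        "cohort_spec": {
            "name_patterns": list(spec.name_patterns),
            "role_codes": sorted(spec.role_codes),
            "window": list(spec.window),
        },
        "thresholds": dataclasses.asdict(thresholds),
        "flags": {
            "chi2_variant": chi2_variant,
            "ic025_variant": ic025_variant,
            "ebgm_quantile": ebgm_quantile,
        },
    }
    return PipelineResult(
        baseline=baseline,
        annual=annual,
        annual_mean=annual_mean,
        onset=onset,
        pt_rows=pt_rows,
        soc_rows=soc_rows,
        top_by_frequency=rank_signals(pt_rows, "frequency", top_k),
        top_by_ebgm05=rank_signals(pt_rows, "ebgm05", top_k),
        manifest=manifest,
    )


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "nan"
    return f"{x:.4f}"


def _signal_tsv(rows: list[SignalRow]) -> str:
    header = "term\tlevel\tN\tROR\tROR_CI95_low\tROR_CI95_high\tPRR\tchi2\tIC\tIC025\tEBGM\tEBGM05\tis_signal"
    lines = [header]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.term,
                    r.level,
                    str(r.a),
                    _fmt(r.ror),
                    _fmt(r.ror_ci95[0]),
                    _fmt(r.ror_ci95[1]),
                    _fmt(r.prr),
                    _fmt(r.chi2),
                    _fmt(r.ic),
                    _fmt(r.ic025),
                    _fmt(r.ebgm),
                    _fmt(r.ebgm05),
                    str(r.is_signal).lower(),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _baseline_tsv(b: BaselineSummary) -> str:
    lines = ["block\tcategory\tcount\tpercentage"]
    for block_name, block in (
        ("sex", b.sex), ("age", b.age), ("weight", b.weight),
        ("occupation", b.occupation), ("country", b.country), ("outcome", b.outcome),
    ):
        for label, (count, pct) in block.items():
            lines.append(f"{block_name}\t{label}\t{count}\t{pct:.2f}")
    lines.append(f"total\tn_patients\t{b.n_patients}\t")
    lines.append(f"total\tn_ae_reports\t{b.n_ae_reports}\t")
    lines.append(f"total\toutcome_denominator\t{b.outcome_denominator}\t")
    return "\n".join(lines) + "\n"


def _baseline_json(b: BaselineSummary) -> dict:
    return {
        "n_patients": b.n_patients,
        "n_ae_reports": b.n_ae_reports,
        "outcome_denominator": b.outcome_denominator,
        "blocks": {
            name: {label: {"count": c, "pct": p} for label, (c, p) in block.items()}
            for name, block in (
                ("sex", b.sex), ("age", b.age), ("weight", b.weight),
                ("occupation", b.occupation), ("country", b.country), ("outcome", b.outcome),
            )
        },
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline from files on disk and write all outputs.

    A fatal error in any stage aborts with the stage named; partially
    written outputs are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "ingest"
    try:
        quarters = []
        checksums = {}
        for d in config.quarter_dirs:
            for label in discover_quarters(d):
                quarters.append(read_quarter(d, label))
            for path in sorted(Path(d).glob("*.txt")):
                checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        if not quarters:
            raise FileNotFoundError(f"no quarterly DEMO files found under {config.quarter_dirs}")
        meddra = read_meddra_map(config.meddra_path)
        data = _merge_quarters(quarters)

        stage = "analysis"
        result = analyze(
            data,
            meddra,
            spec=config.cohort,
            thresholds=config.thresholds,
            chi2_variant=config.chi2_variant,
            ic025_variant=config.ic025_variant,
            ebgm_quantile=config.ebgm_quantile,
            top_k=config.top_k,
        )
        result.manifest["input_checksums"] = checksums
        result.manifest["seed"] = config.seed

        stage = "write"

        def emit(name: str, text: str) -> None:
            path = out_dir / name
            path.write_text(text, encoding="utf-8")
            written.append(path)

        emit("baseline.tsv", _baseline_tsv(result.baseline))
        emit(
            "annual_counts.tsv",
            "year\tpatients\n"
            + "\n".join(f"{y}\t{c}" for y, c in sorted(result.annual.items()))
            + f"\nmean\t{result.annual_mean}\n",
        )
        emit(
            "onset.tsv",
            "bin_days\tcount\tpercentage\n"
            + "\n".join(
                f"{label}\t{result.onset.counts[label]}\t{result.onset.percentages[label]:.2f}"
                for label in result.onset.counts
            )
            + f"\nevaluable\t{result.onset.n_evaluable}\t\nexcluded\t{result.onset.n_excluded}\t\n",
        )
        emit("signals_pt.tsv", _signal_tsv(result.pt_rows))
        emit("signals_soc.tsv", _signal_tsv(result.soc_rows))
        emit("top_by_frequency.tsv", _signal_tsv(result.top_by_frequency))
        emit("top_by_ebgm05.tsv", _signal_tsv(result.top_by_ebgm05))
        report = {
            "baseline": _baseline_json(result.baseline),
            "annual_counts": {str(y): c for y, c in result.annual.items()},
            "annual_mean": result.annual_mean,
            "onset": {
                "counts": result.onset.counts,
                "percentages": result.onset.percentages,
                "n_evaluable": result.onset.n_evaluable,
                "n_excluded": result.onset.n_excluded,
            },
        }
        emit("report.json", json.dumps(report, sort_keys=True, indent=1) + "\n")
        emit("manifest.json", json.dumps(result.manifest, sort_keys=True, indent=1) + "\n")
        return result
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {err}") from err
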
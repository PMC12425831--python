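"""Target-drug cohort selection and descriptive summaries.

Given deduplicated case records, this module identifies the cases where the
drug under study is the primary suspect, and computes the descriptive
surfaces of a pharmacovigilance profile: demographic baseline blocks
(sex / age / weight / reporter occupation / reporter country / outcome),
annual case counts, the time-to-onset histogram, and PT -> SOC aggregation.

Counting conventions
--------------------
* "patients" = deduplicated cases; "AE reports" = distinct case-PT pairs.
* Sex/age/weight/occupation block percentages use the patient denominator.
* The outcome block counts one severity-prioritized outcome per case and
  reports its own (event-level) denominator alongside, since spontaneous-
  report outcome tallies are not patient-level in general.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from collections.abc import Iterable, Sequence

from .types import CaseRecord, MeddraMap, OUTCOME_CODES, OCCUPATIONS

__all__ = [
    "percentage",
    "CohortSpec",
    "BaselineSummary",
    "OnsetDistribution",
    "match_target_cases",
    "case_matches",
    "prioritize_outcome",
    "summarize_baseline",
    "annual_counts",
    "onset_distribution",
    "map_events_to_soc",
    "ONSET_BINS",
    "SEVERITY_ORDER",
]

# Most to least severe FAERS outcome: death, life-threatening,
# hospitalization, disability, congenital anomaly, required intervention,
# other.
SEVERITY_ORDER = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
_SEVERITY_RANK = {code: i for i, code in enumerate(SEVERITY_ORDER)}

# Onset-day bins: [0,30], (30,180], (180,360], (360,720], (720, inf)
ONSET_BINS = ("0-30", "31-180", "181-360", "361-720", ">720")
_ONSET_EDGES = (30, 180, 360, 720)

AGE_BINS = ("<18", "18-44", "45-64", "65-75", ">75", "unknown")
WEIGHT_BINS = ("<73", "73-87", "88-104", ">104", "unknown")


def percentage(count: int, denominator: int) -> float:
    """Percent of *denominator*, rounded half-up to two decimals (0 if empty)."""
    if denominator == 0:
        return 0.0
    q = (Decimal(count) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class CohortSpec:
    """Which drug mentions define the cohort.

    A case belongs to the cohort iff at least one of its drug mentions has a
    role code in ``role_codes`` and a name (brand or active ingredient)
    containing one of ``name_patterns`` as a case-insensitive substring.
    """

    name_patterns: tuple[str, ...] = ("TIOTROPIUM", "SPIRIVA")
    role_codes: frozenset[str] = frozenset({"PS"})
    window: tuple[int, int] = (2004, 2024)  # first and last report year

    def __post_init__(self) -> None:
        if not self.name_patterns:
            raise ValueError("name_patterns must be non-empty")
        object.__setattr__(
            self, "name_patterns", tuple(p.casefold() for p in self.name_patterns)
        )
        object.__setattr__(self, "role_codes", frozenset(self.role_codes))


def case_matches(record: CaseRecord, spec: CohortSpec) -> bool:
    for d in record.drugs:
        if d.role_code not in spec.role_codes:
            continue
        haystack = d.drug_name.casefold()
        if d.active_ingredient:
            haystack += "\x00" + d.active_ingredient.casefold()
        if any(p in haystack for p in spec.name_patterns):
            return True
    return False


def match_target_cases(records: Iterable[CaseRecord], spec: CohortSpec) -> set[int]:
    """Caseids whose surviving version names the target drug in a kept role."""
    return {r.caseid for r in records if case_matches(r, spec)}


def prioritize_outcome(codes: Sequence[str]) -> str:
    """Most severe outcome code of a non-empty multiset."""
    if not codes:
        raise ValueError("prioritize_outcome requires at least one outcome code")
    for code in codes:
        if code not in _SEVERITY_RANK:
            raise ValueError(f"unknown outcome code {code!r}")
    return min(codes, key=_SEVERITY_RANK.__getitem__)


@dataclass
class BaselineSummary:
    """Counts and percentages per demographic block (cf. a Table-1 layout)."""

    n_patients: int
    n_ae_reports: int
    sex: dict[str, tuple[int, float]]
    age: dict[str, tuple[int, float]]
    weight: dict[str, tuple[int, float]]
    occupation: dict[str, tuple[int, float]]
    country: dict[str, tuple[int, float]]  # top-k, ranked
    outcome: dict[str, tuple[int, float]]
    outcome_denominator: int = 0


def _age_bin(age: float | None) -> str:
    if age is None:
        return "unknown"
    if age < 18:
        return "<18"
    if age < 45:
        return "18-44"
    if age < 65:
        return "45-64"
    if age <= 75:  # boundary 65 and 75 both belong to the 65-75 bin
        return "65-75"
    return ">75"


def _weight_bin(w: float | None) -> str:
    if w is None:
        return "unknown"
    if w < 73:
        return "<73"
    if w < 88:
        return "73-87"
    if w <= 104:
        return "88-104"
    return ">104"


def summarize_baseline(records: Sequence[CaseRecord], top_k_countries: int = 5) -> BaselineSummary:
    """Demographic baseline of a deduplicated cohort.

    Sex, age, weight and occupation blocks each sum to ``n_patients`` and use
    it as the percentage denominator.  Countries are ranked and the top-k
    reported.  The outcome block counts one prioritized (most severe) outcome
    per case — cases without outcome rows count as ``unknown`` — and uses the
    block total as its denominator.
    """
    n = len(records)
    n_pairs = sum(len(r.pts) for r in records)

    sex_c: Counter = Counter()
    age_c: Counter = Counter()
    wt_c: Counter = Counter()
    occ_c: Counter = Counter()
    country_c: Counter = Counter()
    out_c: Counter = Counter()

    for r in records:
        v = r.version
        sex_c[v.sex] += 1
        age_c[_age_bin(v.age_years)] += 1
        wt_c[_weight_bin(v.weight_kg)] += 1
        occ_c[v.reporter_occupation] += 1
        if v.reporter_country:
            country_c[v.reporter_country] += 1
        codes = [o.outcome_code for o in r.outcomes]
        out_c[prioritize_outcome(codes) if codes else "unknown"] += 1

    def block(counter: Counter, labels: Sequence[str], denom: int) -> dict[str, tuple[int, float]]:
        return {lab: (counter.get(lab, 0), percentage(counter.get(lab, 0), denom)) for lab in labels}

    outcome_denom = sum(out_c.values())
    top = country_c.most_common()
    top.sort(key=lambda kv: (-kv[1], kv[0]))
    return BaselineSummary(
        n_patients=n,
        n_ae_reports=n_pairs,
        sex=block(sex_c, ("F", "M", "unknown"), n),
        age=block(age_c, AGE_BINS, n),
        weight=block(wt_c, WEIGHT_BINS, n),
        occupation=block(occ_c, OCCUPATIONS, n),
        country={c: (k, percentage(k, n)) for c, k in top[:top_k_countries]},
        outcome=block(out_c, OUTCOME_CODES + ("unknown",), outcome_denom),
        outcome_denominator=outcome_denom,
    )


def annual_counts(
    records: Iterable[CaseRecord], window: tuple[int, int] = (2004, 2024)
) -> tuple[dict[int, int], int]:
    """Patient count per report year (from the survivor's fda_dt) and the
    integer annual mean over the window (floor of n_patients / n_years)."""
    start, end = window
    counts = {year: 0 for year in range(start, end + 1)}
    total = 0
    for r in records:
        if r.fda_dt is None:
            continue
        year = r.fda_dt // 10000
        if start <= year <= end:
            counts[year] += 1
            total += 1
    n_years = end - start + 1
    return counts, total // n_years


@dataclass
class OnsetDistribution:
    """Histogram of days from suspect-drug therapy start to event onset."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_evaluable: int
    n_excluded: int


def _to_date(yyyymmdd: int) -> date:
    return date(yyyymmdd // 10000, yyyymmdd // 100 % 100, yyyymmdd % 100)


def onset_bin(days: int) -> str:
    for edge, label in zip(_ONSET_EDGES, ONSET_BINS):
        if days <= edge:
            return label
    return ONSET_BINS[-1]


def onset_distribution(records: Iterable[CaseRecord], spec: CohortSpec) -> OnsetDistribution:
    """Time-to-onset histogram over the cohort.

    Onset = event date minus the earliest day-precision therapy start date of
    a suspect drug mention matching *spec*.  Cases with missing or imprecise
    dates, or negative onsets, are excluded and tallied, never silently
    dropped.
    """
    counts = {label: 0 for label in ONSET_BINS}
    n_eval = 0
    n_excl = 0
    for r in records:
        v = r.version
        start = None
        for d in r.drugs:
            if (
                d.role_code in spec.role_codes
                and d.therapy_start_dt is not None
                and d.therapy_start_prec == "D"
                and any(
                    p in d.drug_name.casefold()
                    or (d.active_ingredient or "").casefold().find(p) >= 0
                    for p in spec.name_patterns
                )
            ):
                if start is None or d.therapy_start_dt < start:
                    start = d.therapy_start_dt
        if start is None or v.event_dt is None or v.event_dt_prec != "D":
            n_excl += 1
            continue
        days = (_to_date(v.event_dt) - _to_date(start)).days
        if days < 0:
            n_excl += 1
            continue
        counts[onset_bin(days)] += 1
        n_eval += 1
    pct = {label: percentage(c, n_eval) for label, c in counts.items()}
    return OnsetDistribution(counts=counts, percentages=pct, n_evaluable=n_eval, n_excluded=n_excl)


def map_events_to_soc(
    records: Iterable[CaseRecord], mapping: MeddraMap
) -> tuple[dict[int, frozenset[str]], dict[str, int]]:
    """Per-case SOC sets and per-SOC counts of case-PT pairs.

    A PT absent from the mapping is routed to the sentinel SOC ``unmapped``
    and counted there; a case with two PTs in the same SOC contributes two to
    that SOC's pair count but only one entry to its SOC set.
    """
    case_socs: dict[int, frozenset[str]] = {}
    soc_counts: Counter = Counter()
    for r in records:
        socs = set()
        for pt in r.pts:
            soc = mapping.soc_of(pt) or "unmapped"
            socs.add(soc)
            soc_counts[soc] += 1
        case_socs[r.caseid] = frozenset(socs)
    return case_socs, dict(soc_counts)
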
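"""Core record types for FAERS-style spontaneous-report data.

One *case* (a patient incident, identified by ``caseid``) may be filed
repeatedly over time; each filing is a *version* identified by a unique
``primaryid`` and carries the FDA receipt date ``fda_dt``.  Child tables
(drug mentions, adverse-event terms, outcomes, therapy dates) hang off the
``primaryid`` of a version.

Dates are held as ``YYYYMMDD`` integers with an explicit precision marker,
because FAERS dates are frequently partial (``YYYYMM`` or ``YYYY``); partial
dates are padded to the first day/month and flagged so that time-to-onset
analyses can exclude them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DAY",
    "MONTH",
    "YEAR",
    "SEXES",
    "ROLE_CODES",
    "OUTCOME_CODES",
    "OCCUPATIONS",
    "normalize_term",
    "CaseVersion",
    "DrugMention",
    "EventMention",
    "OutcomeMention",
    "TherapyRecord",
    "IndicationRecord",
    "MeddraMap",
    "CaseRecord",
]

# Date precision markers ('' means the date is absent).
DAY = "D"
MONTH = "M"
YEAR = "Y"

SEXES = ("F", "M", "unknown")
ROLE_CODES = ("PS", "SS", "C", "I")
# FAERS seriousness codes: death, life-threatening, hospitalization,
# disability, congenital anomaly, required intervention, other.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
OCCUPATIONS = (
    "consumer",
    "pharmacist",
    "physician",
    "other-health-professional",
    "registered-nurse",
    "lawyer",
    "unknown",
)


def normalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace of a dictionary term."""
    return " ".join(term.split()).casefold()


@dataclass(frozen=True, slots=True)
class CaseVersion:
    """One report version as filed (a DEMO row)."""

    primaryid: int
    caseid: int
    fda_dt: int | None
    event_dt: int | None = None
    event_dt_prec: str = ""
    sex: str = "unknown"
    age_years: float | None = None
    weight_kg: float | None = None
    reporter_occupation: str = "unknown"
    reporter_country: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.reporter_occupation not in OCCUPATIONS:
            raise ValueError(f"unknown reporter occupation {self.reporter_occupation!r}")
        if self.age_years is not None and not (0.0 <= self.age_years <= 150.0):
            raise ValueError(f"age_years out of range: {self.age_years!r}")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be positive: {self.weight_kg!r}")


@dataclass(frozen=True, slots=True)
class DrugMention:
    """One drug row attached to a report version.

    ``therapy_start_dt`` is populated by joining the THER table on
    ``(primaryid, drug_seq)``; it is absent straight after parsing DRUG.
    """

    primaryid: int
    drug_seq: int
    drug_name: str
    role_code: str
    active_ingredient: str | None = None
    therapy_start_dt: int | None = None
    therapy_start_prec: str = ""
    indication_pt: str | None = None

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"role_code must be one of {ROLE_CODES}, got {self.role_code!r}")


@dataclass(frozen=True, slots=True)
class EventMention:
    """One adverse-event row: a MedDRA Preferred Term on a report version."""

    primaryid: int
    pt: str

    def __post_init__(self) -> None:
        norm = normalize_term(self.pt)
        if not norm:
            raise ValueError("pt must be non-empty after whitespace normalization")
        object.__setattr__(self, "pt", norm)


@dataclass(frozen=True, slots=True)
class OutcomeMention:
    primaryid: int
    outcome_code: str

    def __post_init__(self) -> None:
        if self.outcome_code not in OUTCOME_CODES:
            raise ValueError(f"outcome_code must be one of {OUTCOME_CODES}")


@dataclass(frozen=True, slots=True)
class TherapyRecord:
    """One THER row: therapy start date for a drug sequence of a version."""

    primaryid: int
    drug_seq: int
    start_dt: int | None
    start_prec: str = ""


@dataclass(frozen=True, slots=True)
class IndicationRecord:
    """One INDI row: indication PT for a drug sequence of a version."""

    primaryid: int
    drug_seq: int
    indication_pt: str


@dataclass(frozen=True)
class MeddraMap:
    """A PT -> primary SOC mapping (each PT maps to exactly one SOC).

    MedDRA itself is licensed and never bundled; users supply a two-column
    TSV extract, or the synthetic generator emits a toy mapping.
    """

    entries: dict[str, str]
    version_label: str = ""

    def soc_of(self, pt: str) -> str | None:
        return self.entries.get(normalize_term(pt))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CaseRecord:
    """One deduplicated case: the surviving version plus its child rows."""

    caseid: int
    primaryid: int
    fda_dt: int | None
    version: CaseVersion
    drugs: tuple[DrugMention, ...] = ()
    events: tuple[EventMention, ...] = ()
    outcomes: tuple[OutcomeMention, ...] = ()
    therapies: tuple[TherapyRecord, ...] = field(default=())

    @property
    def pts(self) -> frozenset[str]:
        """Distinct event PTs of this case."""
        return frozenset(e.pt for e in self.events)
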
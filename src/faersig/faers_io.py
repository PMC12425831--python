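"""Reading and writing FAERS-style quarterly ASCII tables.

The public quarterly extracts are ``'$'``-delimited text files with a single
header row, one table per entity: DEMO (report versions), DRUG, REAC
(adverse-event PTs), OUTC, THER, INDI and RPSR, plus an optional per-quarter
deleted-case list (one caseid per line).  Files are located by quarter label,
e.g. ``DEMO24Q4.txt`` for 2024 Q4.

Parsing is header-driven, never positional: a synonym table harmonizes the
pre-2012 layout (``ISR``/``CASE``, ``gndr_cod``) with the current one
(``primaryid``/``caseid``, ``sex``).  Malformed rows are tallied per file —
never silently dropped — and partial dates are padded and flagged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .types import (
    DAY,
    MONTH,
    YEAR,
    OCCUPATIONS,
    OUTCOME_CODES,
    ROLE_CODES,
    CaseVersion,
    DrugMention,
    EventMention,
    IndicationRecord,
    MeddraMap,
    OutcomeMention,
    TherapyRecord,
    normalize_term,
)

logger = logging.getLogger(__name__)

TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

# canonical column name -> accepted header spellings (case-insensitive)
_SYNONYMS: dict[str, tuple[str, ...]] = {
    "primaryid": ("primaryid", "isr"),
    "caseid": ("caseid", "case"),
    "fda_dt": ("fda_dt",),
    "event_dt": ("event_dt",),
    "sex": ("sex", "gndr_cod"),
    "age": ("age",),
    "age_cod": ("age_cod",),
    "wt": ("wt",),
    "wt_cod": ("wt_cod",),
    "occp_cod": ("occp_cod",),
    "reporter_country": ("reporter_country",),
    "drug_seq": ("drug_seq",),
    "role_cod": ("role_cod",),
    "drugname": ("drugname",),
    "prod_ai": ("prod_ai",),
    "pt": ("pt",),
    "outc_cod": ("outc_cod", "outc_code"),
    "dsg_drug_seq": ("dsg_drug_seq", "drug_seq"),
    "start_dt": ("start_dt",),
    "indi_drug_seq": ("indi_drug_seq", "drug_seq"),
    "indi_pt": ("indi_pt",),
    "rpsr_cod": ("rpsr_cod",),
}

_OCCUPATION_CODES = {
    "CN": "consumer",
    "PH": "pharmacist",
    "MD": "physician",
    "HP": "other-health-professional",
    "OT": "other-health-professional",
    "RN": "registered-nurse",
    "LW": "lawyer",
}
_OCC_TO_CODE = {
    "consumer": "CN",
    "pharmacist": "PH",
    "physician": "MD",
    "other-health-professional": "HP",
    "registered-nurse": "RN",
    "lawyer": "LW",
    "unknown": "",
}

# age unit code -> factor converting to years
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}
_LBS_TO_KG = 0.453592


@dataclass
class ParseStats:
    """Row tally for one parsed file: parsed + malformed == total."""

    rows_total: int = 0
    rows_parsed: int = 0
    rows_malformed: int = 0


@dataclass
class QuarterData:
    """Everything read from (or written to) one quarterly file set."""

    label: str
    case_versions: list[CaseVersion] = field(default_factory=list)
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[EventMention] = field(default_factory=list)
    outcomes: list[OutcomeMention] = field(default_factory=list)
    therapies: list[TherapyRecord] = field(default_factory=list)
    indications: list[IndicationRecord] = field(default_factory=list)
    report_sources: list[tuple[int, str]] = field(default_factory=list)
    deleted_caseids: set[int] = field(default_factory=set)
    stats: dict[str, ParseStats] = field(default_factory=dict)


def parse_faers_date(text: str) -> tuple[int | None, str]:
    """Parse a FAERS date string into (YYYYMMDD int, precision flag).

    Full dates (8 digits) get precision 'D'; partial dates YYYYMM / YYYY are
    padded to the first day / first month and flagged 'M' / 'Y'.  Anything
    unparseable or calendar-invalid yields ``(None, '')``.
    """
    text = text.strip()
    if not text or not text.isdigit():
        return None, ""
    try:
        if len(text) == 8:
            value = int(text)
            date(value // 10000, value // 100 % 100, value % 100)
            return value, DAY
        if len(text) == 6:
            value = int(text) * 100 + 1
            date(value // 10000, value // 100 % 100, 1)
            return value, MONTH
        if len(text) == 4:
            year = int(text)
            if not 1900 <= year <= 2200:
                return None, ""
            return year * 10000 + 101, YEAR
    except ValueError:
        return None, ""
    return None, ""


def format_faers_date(value: int | None, prec: str) -> str:
    if value is None or not prec:
        return ""
    if prec == DAY:
        return f"{value:08d}"
    if prec == MONTH:
        return f"{value // 100:06d}"
    return f"{value // 10000:04d}"


def quarter_suffix(label: str) -> str:
    """Normalize a quarter label ('2024Q4' or '24Q4') to the 4-char suffix."""
    label = label.strip().upper()
    if len(label) == 6 and label[4] == "Q":
        return label[2:]
    if len(label) == 4 and label[2] == "Q":
        return label
    raise ValueError(f"quarter label not understood: {label!r}")


def _find_file(directory: Path, stem: str) -> Path | None:
    wanted = f"{stem}.txt".lower()
    for path in sorted(directory.iterdir()):
        if path.name.lower() == wanted:
            return path
    return None


def _read_table(path: Path, stats: ParseStats) -> pd.DataFrame:
    """Read one '$'-delimited table; ragged rows count as malformed."""
    bad = 0

    def on_bad(fields: list[str]) -> None:
        nonlocal bad
        bad += 1
        return None

    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=on_bad,
    )
    df.columns = [c.strip().casefold() for c in df.columns]
    stats.rows_total = len(df) + bad
    stats.rows_malformed = bad
    return df


def _col(df: pd.DataFrame, canonical: str) -> str | None:
    for name in _SYNONYMS[canonical]:
        if name in df.columns:
            return name
    return None


def _get(row, df: pd.DataFrame, canonical: str) -> str:
    name = _col(df, canonical)
    if name is None:
        return ""
    return str(getattr(row, name)).strip()


def _parse_int(text: str) -> int | None:
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        return None


def _parse_age_years(value: str, code: str) -> float | None:
    factor = _AGE_FACTORS.get(code.strip().upper())
    if factor is None:
        return None
    try:
        years = float(value) * factor
    except ValueError:
        return None
    return years if 0.0 <= years <= 150.0 else None


def _parse_weight_kg(value: str, code: str) -> float | None:
    code = code.strip().upper()
    if code in ("", "KG", "KGS"):
        factor = 1.0
    elif code in ("LBS", "LB"):
        factor = _LBS_TO_KG
    else:
        return None
    try:
        kg = float(value) * factor
    except ValueError:
        return None
    return kg if kg > 0 else None


def read_quarter(directory: str | Path, label: str) -> QuarterData:
    """Read one quarter's file set from *directory*.

    A missing DEMO file is fatal for the quarter; any other missing table is
    treated as empty.  Every well-formed data row yields exactly one record;
    malformed rows (ragged, or with unusable identifiers / closed-set codes)
    are counted in ``stats`` and logged.
    """
    directory = Path(directory)
    suffix = quarter_suffix(label)
    out = QuarterData(label=suffix)

    demo_path = _find_file(directory, f"DEMO{suffix}")
    if demo_path is None:
        raise FileNotFoundError(f"DEMO table for quarter {suffix} not found in {directory}")

    for table in TABLES:
        stats = ParseStats()
        out.stats[table] = stats
        path = demo_path if table == "DEMO" else _find_file(directory, f"{table}{suffix}")
        if path is None:
            continue
        df = _read_table(path, stats)
        parser = _ROW_PARSERS[table]
        for row in df.itertuples(index=False):
            if parser(row, df, out):
                stats.rows_parsed += 1
            else:
                stats.rows_malformed += 1
        if stats.rows_malformed:
            logger.warning(
                "%s%s: %d malformed of %d rows", table, suffix, stats.rows_malformed, stats.rows_total
            )

    deleted_path = _find_file(directory, f"DELETED{suffix}")
    if deleted_path is not None:
        for line in deleted_path.read_text().splitlines():
            cid = _parse_int(line)
            if cid is not None:
                out.deleted_caseids.add(cid)
    return out


def _parse_demo(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    cid = _parse_int(_get(row, df, "caseid"))
    if pid is None or cid is None:
        return False
    fda_dt, _ = parse_faers_date(_get(row, df, "fda_dt"))
    event_dt, event_prec = parse_faers_date(_get(row, df, "event_dt"))
    sex = _get(row, df, "sex").upper()
    country = _get(row, df, "reporter_country").upper() or None
    out.case_versions.append(
        CaseVersion(
            primaryid=pid,
            caseid=cid,
            fda_dt=fda_dt,
            event_dt=event_dt,
            event_dt_prec=event_prec,
            sex=sex if sex in ("F", "M") else "unknown",
            age_years=_parse_age_years(_get(row, df, "age"), _get(row, df, "age_cod")),
            weight_kg=_parse_weight_kg(_get(row, df, "wt"), _get(row, df, "wt_cod")),
            reporter_occupation=_OCCUPATION_CODES.get(_get(row, df, "occp_cod").upper(), "unknown"),
            reporter_country=country,
        )
    )
    return True


def _parse_drug(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    seq = _parse_int(_get(row, df, "drug_seq"))
    name = _get(row, df, "drugname")
    role = _get(row, df, "role_cod").upper()
    if pid is None or seq is None or not name or role not in ROLE_CODES:
        return False
    ai = _get(row, df, "prod_ai") or None
    out.drugs.append(
        DrugMention(primaryid=pid, drug_seq=seq, drug_name=name, role_code=role, active_ingredient=ai)
    )
    return True


def _parse_reac(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    pt = _get(row, df, "pt")
    if pid is None or not normalize_term(pt):
        return False
    out.events.append(EventMention(primaryid=pid, pt=pt))
    return True


def _parse_outc(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    code = _get(row, df, "outc_cod").upper()
    if pid is None or code not in OUTCOME_CODES:
        return False
    out.outcomes.append(OutcomeMention(primaryid=pid, outcome_code=code))
    return True


def _parse_ther(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    seq = _parse_int(_get(row, df, "dsg_drug_seq"))
    if pid is None or seq is None:
        return False
    start, prec = parse_faers_date(_get(row, df, "start_dt"))
    out.therapies.append(TherapyRecord(primaryid=pid, drug_seq=seq, start_dt=start, start_prec=prec))
    return True


def _parse_indi(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    seq = _parse_int(_get(row, df, "indi_drug_seq"))
    pt = _get(row, df, "indi_pt")
    if pid is None or seq is None or not normalize_term(pt):
        return False
    out.indications.append(IndicationRecord(primaryid=pid, drug_seq=seq, indication_pt=normalize_term(pt)))
    return True


def _parse_rpsr(row, df, out: QuarterData) -> bool:
    pid = _parse_int(_get(row, df, "primaryid"))
    code = _get(row, df, "rpsr_cod").upper()
    if pid is None or not code:
        return False
    out.report_sources.append((pid, code))
    return True


_ROW_PARSERS = {
    "DEMO": _parse_demo,
    "DRUG": _parse_drug,
    "REAC": _parse_reac,
    "OUTC": _parse_outc,
    "THER": _parse_ther,
    "INDI": _parse_indi,
    "RPSR": _parse_rpsr,
}


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_quarter(quarter: QuarterData, directory: str | Path) -> dict[str, Path]:
    """Emit a quarter's file set byte-compatible with :func:`read_quarter`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = quarter_suffix(quarter.label)
    paths: dict[str, Path] = {}

    def emit(table: str, header: list[str], rows: list[list[str]]) -> None:
        path = directory / f"{table}{suffix}.txt"
        lines = ["$".join(header)] + ["$".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[table] = path

    emit(
        "DEMO",
        ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod", "wt", "wt_cod", "occp_cod", "reporter_country"],
        [
            [
                str(v.primaryid),
                str(v.caseid),
                format_faers_date(v.fda_dt, DAY if v.fda_dt is not None else ""),
                format_faers_date(v.event_dt, v.event_dt_prec),
                v.sex if v.sex != "unknown" else "",
                _fmt_num(v.age_years),
                "YR" if v.age_years is not None else "",
                _fmt_num(v.weight_kg),
                "KG" if v.weight_kg is not None else "",
                _OCC_TO_CODE[v.reporter_occupation],
                v.reporter_country or "",
            ]
            for v in quarter.case_versions
        ],
    )
    emit(
        "DRUG",
        ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        [
            [str(d.primaryid), str(d.drug_seq), d.role_code, d.drug_name, d.active_ingredient or ""]
            for d in quarter.drugs
        ],
    )
    emit("REAC", ["primaryid", "pt"], [[str(e.primaryid), e.pt] for e in quarter.events])
    emit("OUTC", ["primaryid", "outc_cod"], [[str(o.primaryid), o.outcome_code] for o in quarter.outcomes])
    emit(
        "THER",
        ["primaryid", "dsg_drug_seq", "start_dt"],
        [
            [str(t.primaryid), str(t.drug_seq), format_faers_date(t.start_dt, t.start_prec)]
            for t in quarter.therapies
        ],
    )
    emit(
        "INDI",
        ["primaryid", "indi_drug_seq", "indi_pt"],
        [[str(i.primaryid), str(i.drug_seq), i.indication_pt] for i in quarter.indications],
    )
    emit("RPSR", ["primaryid", "rpsr_cod"], [[str(p), c] for p, c in quarter.report_sources])
    if quarter.deleted_caseids:
        path = directory / f"DELETED{suffix}.txt"
        path.write_text("\n".join(str(c) for c in sorted(quarter.deleted_caseids)) + "\n", encoding="utf-8")
        paths["DELETED"] = path
    return paths


def attach_therapy_dates(drugs: list[DrugMention], therapies: list[TherapyRecord],
                         indications: list[IndicationRecord] | None = None) -> list[DrugMention]:
    """Join THER start dates (and INDI indications) onto drug mentions.

    Keyed on ``(primaryid, drug_seq)``; the earliest valid start date wins if
    a drug sequence has several therapy episodes.
    """
    import dataclasses

    starts: dict[tuple[int, int], tuple[int, str]] = {}
    for t in therapies:
        if t.start_dt is None:
            continue
        key = (t.primaryid, t.drug_seq)
        if key not in starts or t.start_dt < starts[key][0]:
            starts[key] = (t.start_dt, t.start_prec)
    indic: dict[tuple[int, int], str] = {}
    for i in indications or ():
        indic.setdefault((i.primaryid, i.drug_seq), i.indication_pt)

    out = []
    for d in drugs:
        key = (d.primaryid, d.drug_seq)
        changes: dict[str, object] = {}
        if key in starts:
            changes["therapy_start_dt"], changes["therapy_start_prec"] = starts[key]
        if key in indic:
            changes["indication_pt"] = indic[key]
        out.append(dataclasses.replace(d, **changes) if changes else d)
    return out


def read_meddra_map(path: str | Path, version_label: str = "") -> MeddraMap:
    """Read a two-column ``pt<TAB>soc`` mapping file.

    Lines starting with ``#`` are comments.  Keys (and SOC names) are
    case-folded and whitespace-normalized; a PT mapped to two different SOCs
    is a fatal error, honouring MedDRA's primary-SOC convention.
    """
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'pt<TAB>soc', got {line!r}")
        pt = normalize_term(parts[0])
        soc = normalize_term(parts[1])
        if not pt or not soc:
            raise ValueError(f"{path}:{lineno}: empty pt or soc")
        if pt in entries and entries[pt] != soc:
            raise ValueError(
                f"conflicting SOC mapping for pt {pt!r}: {entries[pt]!r} vs {soc!r}"
            )
        entries[pt] = soc
    return MeddraMap(entries=entries, version_label=version_label)


def write_meddra_map(mapping: MeddraMap, path: str | Path) -> None:
    lines = [f"{pt}\t{soc}" for pt, soc in sorted(mapping.entries.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
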
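"""Synthetic FAERS-like corpora with known ground truth.

The generator emulates the statistical structure a disproportionality
pipeline consumes: many drugs with a skewed (Zipf-like) reporting frequency,
one target drug, a categorical adverse-event law per case, multi-version
cases sharing a caseid, per-field demographic missingness, therapy-start /
event dates, outcome codes, per-quarter packaging, and deletion lists.

Planted associations tilt the per-draw event distribution of target-drug
cases: a planted PT's baseline weight is multiplied by its reporting-odds
multiplier rho and the weights renormalized.  Each case draws its number of
events from a truncated geometric law and then draws PTs from the (possibly
tilted) categorical; the analyzed unit downstream is the distinct case-PT
pair, so repeated draws of one PT within a case collapse.  This law has an
exact closed form for the expected 2x2 cells (:func:`expected_table`), which
is what makes parameter-recovery tests possible.

None of this is a claim about how FAERS reporting actually arises; it is a
controllable test harness whose defaults mirror the corpus shape the
pipeline targets (tens of thousands of cases, ~2 distinct PTs per case,
heavy demographic missingness).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .faers_io import QuarterData, write_quarter, write_meddra_map
from .types import (
    CaseVersion,
    DrugMention,
    EventMention,
    MeddraMap,
    OutcomeMention,
    TherapyRecord,
)

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticCorpus", "ExpectedTable", "generate", "expected_table"]

_COUNTRIES = ("US", "NA", "CA", "JP", "GB", "DE", "FR")
_COUNTRY_P = (0.76, 0.148, 0.021, 0.008, 0.004, 0.004, 0.003)
_OCC = ("consumer", "pharmacist", "physician", "other-health-professional",
        "registered-nurse", "lawyer", "unknown")
_OCC_P = (0.741, 0.093, 0.089, 0.038, 0.0005, 0.0005, 0.038)
_OUTCOME_CODES = ("HO", "OT", "DE", "LT", "DS", "RI", "CA")
_OUTCOME_P = (0.45, 0.33, 0.13, 0.03, 0.04, 0.015, 0.005)


def _default_missingness() -> dict[str, float]:
    # Mirrors the heavy missingness of real spontaneous reports:
    # age unknown for ~half of patients, weight for ~80%, most cases without
    # an evaluable therapy-start date.
    return {
        "sex": 0.06,
        "age": 0.50,
        "weight": 0.80,
        "country": 0.01,
        "event_dt": 0.20,
        "therapy_start": 0.65,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic reporting system."""

    n_cases: int = 100_000
    n_drugs: int = 50
    n_pts: int = 200
    target_drug_name: str = "TIOTROPIUM BROMIDE"
    target_drug_rank: int = 5  # Zipf rank of the target drug (1 = most reported)
    baseline_pt_probs: tuple[float, ...] | None = None  # uniform when None
    mean_events: float = 2.0  # mean of the truncated geometric events-per-case law
    max_events: int = 8
    planted_associations: tuple[tuple[str, float], ...] = ()
    duplicate_version_rate: float = 0.10
    deleted_case_rate: float = 0.02
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    date_range: tuple[int, int] = (20040101, 20241231)
    n_socs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 1 <= self.target_drug_rank <= self.n_drugs:
            raise ValueError("target_drug_rank out of range")
        if self.mean_events < 1.0:
            raise ValueError("mean_events must be >= 1")
        if not 0.0 <= self.duplicate_version_rate <= 1.0:
            raise ValueError("duplicate_version_rate must be a probability")
        for key, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{key!r}] must be a probability")
        names = set(self.pt_names())
        for pt, rho in self.planted_associations:
            if pt not in names:
                raise ValueError(f"planted pt {pt!r} is not among the {self.n_pts} generated PTs")
            if rho < 0:
                raise ValueError("reporting-odds multiplier rho must be >= 0")
        if self.baseline_pt_probs is not None:
            w = np.asarray(self.baseline_pt_probs, dtype=float)
            if len(w) != self.n_pts or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("baseline_pt_probs must be a probability vector over n_pts")

    # --- derived vocabulary -------------------------------------------------
    def pt_names(self) -> list[str]:
        return [f"pt_{i:04d}" for i in range(1, self.n_pts + 1)]

    def drug_names(self) -> list[str]:
        """Drug vocabulary ordered by Zipf rank; target sits at its rank."""
        others = [f"drug_{i:03d}" for i in range(1, self.n_drugs)]
        names = others[: self.target_drug_rank - 1] + [self.target_drug_name] + others[self.target_drug_rank - 1:]
        return names

    def drug_probs(self) -> np.ndarray:
        ranks = np.arange(1, self.n_drugs + 1, dtype=float)
        w = 1.0 / ranks
        return w / w.sum()

    def base_weights(self) -> np.ndarray:
        if self.baseline_pt_probs is not None:
            return np.asarray(self.baseline_pt_probs, dtype=float)
        return np.full(self.n_pts, 1.0 / self.n_pts)

    def tilted_weights(self) -> np.ndarray:
        w = self.base_weights().copy()
        idx = {name: i for i, name in enumerate(self.pt_names())}
        for pt, rho in self.planted_associations:
            w[idx[pt]] *= rho
        total = w.sum()
        if total <= 0:
            raise ValueError("tilted event weights sum to zero")
        return w / total

    def meddra_map(self) -> MeddraMap:
        entries = {
            name: f"soc_{i % self.n_socs:02d}" for i, name in enumerate(self.pt_names())
        }
        return MeddraMap(entries=entries, version_label="synthetic")


@dataclass
class GroundTruth:
    """What the generator actually did, for cross-module contract tests."""

    planted: dict[str, float]
    versions: dict[int, list[int]]  # caseid -> all emitted primaryids
    survivor: dict[int, int]  # caseid -> retention-rule survivor primaryid
    target_caseids: set[int]  # cases whose suspect drug is the target
    deleted_caseids: set[int]
    n_versions: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": self.planted,
            "versions": {str(k): v for k, v in self.versions.items()},
            "survivor": {str(k): v for k, v in self.survivor.items()},
            "target_caseids": sorted(self.target_caseids),
            "deleted_caseids": sorted(self.deleted_caseids),
            "n_versions": self.n_versions,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            planted=payload["planted"],
            versions={int(k): v for k, v in payload["versions"].items()},
            survivor={int(k): v for k, v in payload["survivor"].items()},
            target_caseids=set(payload["target_caseids"]),
            deleted_caseids=set(payload["deleted_caseids"]),
            n_versions=payload["n_versions"],
        )


@dataclass
class SyntheticCorpus:
    """In-memory corpus plus ground truth; can be written as quarterly files."""

    config: GeneratorConfig
    case_versions: list[CaseVersion]
    drugs: list[DrugMention]
    events: list[EventMention]
    outcomes: list[OutcomeMention]
    therapies: list[TherapyRecord]
    meddra_map: MeddraMap
    ground_truth: GroundTruth

    def as_quarter_data(self) -> QuarterData:
        """The whole corpus as one merged in-memory file set (no disk I/O)."""
        return QuarterData(
            label="ALL",
            case_versions=list(self.case_versions),
            drugs=list(self.drugs),
            events=list(self.events),
            outcomes=list(self.outcomes),
            therapies=list(self.therapies),
            deleted_caseids=set(self.ground_truth.deleted_caseids),
        )

    def quarters(self) -> dict[str, QuarterData]:
        """Split records into per-quarter file sets keyed by quarter label."""
        def label_of(dt: int) -> str:
            year = dt // 10000
            q = (dt // 100 % 100 - 1) // 3 + 1
            return f"{year % 100:02d}Q{q}"

        by_pid: dict[int, str] = {}
        quarters: dict[str, QuarterData] = {}
        for v in self.case_versions:
            lab = label_of(v.fda_dt)
            by_pid[v.primaryid] = lab
            quarters.setdefault(lab, QuarterData(label=lab)).case_versions.append(v)
        for d in self.drugs:
            quarters[by_pid[d.primaryid]].drugs.append(d)
        for e in self.events:
            quarters[by_pid[e.primaryid]].events.append(e)
        for o in self.outcomes:
            quarters[by_pid[o.primaryid]].outcomes.append(o)
        for t in self.therapies:
            quarters[by_pid[t.primaryid]].therapies.append(t)
        for caseid in sorted(self.ground_truth.deleted_caseids):
            pid = self.ground_truth.survivor[caseid]
            quarters[by_pid[pid]].deleted_caseids.add(caseid)
        return quarters

    def write(self, directory: str | Path) -> list[str]:
        """Write the quarterly files, mapping TSV and ground-truth sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        quarters = self.quarters()
        labels = []
        for label in sorted(quarters):
            write_quarter(quarters[label], directory)
            labels.append(label)
        write_meddra_map(self.meddra_map, directory / "meddra_map.tsv")
        self.ground_truth.to_json(directory / "ground_truth.json")
        return labels


def _dates_to_int(base: np.datetime64, offsets: np.ndarray) -> np.ndarray:
    idx = pd.DatetimeIndex(base + offsets.astype("timedelta64[D]"))
    return (idx.year * 10000 + idx.month * 100 + idx.day).to_numpy()


def generate(config: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticCorpus:
    """Draw a full corpus; deterministic given ``config.seed``.

    When *out_dir* is given the quarterly file set, the toy PT->SOC mapping
    and the ground-truth JSON sidecar are written there as well.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    miss = {**_default_missingness(), **config.missingness}

    drug_names = config.drug_names()
    pt_names = config.pt_names()
    target_idx = drug_names.index(config.target_drug_name)

    # --- per-case structure -------------------------------------------------
    drug_idx = rng.choice(config.n_drugs, size=n, p=config.drug_probs())
    is_target = drug_idx == target_idx
    q = 1.0 / config.mean_events
    k = np.minimum(rng.geometric(q, size=n), config.max_events)

    case_rep = np.repeat(np.arange(n), k)
    draw_is_target = is_target[case_rep]
    pts_draw = np.empty(case_rep.size, dtype=np.int64)
    n_t = int(draw_is_target.sum())
    pts_draw[draw_is_target] = rng.choice(config.n_pts, size=n_t, p=config.tilted_weights())
    pts_draw[~draw_is_target] = rng.choice(config.n_pts, size=case_rep.size - n_t, p=config.base_weights())
    pair_df = (
        pd.DataFrame({"case": case_rep, "pt": pts_draw})
        .drop_duplicates()
        .sort_values(["case", "pt"], kind="mergesort")
    )

    # --- dates --------------------------------------------------------------
    start, end = config.date_range
    base = np.datetime64(f"{start // 10000:04d}-{start // 100 % 100:02d}-{start % 100:02d}")
    endd = np.datetime64(f"{end // 10000:04d}-{end // 100 % 100:02d}-{end % 100:02d}")
    span = int((endd - base) / np.timedelta64(1, "D"))
    fda_off = rng.integers(0, span + 1, size=n)
    lag = np.minimum(rng.exponential(30.0, size=n).astype(np.int64), fda_off)
    event_off = fda_off - lag
    event_present = rng.random(n) >= miss["event_dt"]
    onset = np.rint(rng.lognormal(np.log(100.0), 1.4, size=n)).astype(np.int64)
    ther_off = event_off - onset
    ther_present = (rng.random(n) >= miss["therapy_start"]) & event_present & (ther_off >= -span)
    fda_int = _dates_to_int(base, fda_off)
    event_int = _dates_to_int(base, event_off)
    ther_int = _dates_to_int(base, ther_off)

    # --- demographics -------------------------------------------------------
    p_f = (1.0 - miss["sex"]) * 0.635
    p_m = (1.0 - miss["sex"]) * 0.365
    sex = rng.choice(np.array(["F", "M", "unknown"]), size=n, p=[p_f, p_m, miss["sex"]])
    age = np.clip(rng.normal(70.0, 12.0, size=n), 1.0, 110.0).round(0)
    age_missing = rng.random(n) < miss["age"]
    weight = np.clip(rng.normal(80.0, 18.0, size=n), 35.0, 200.0).round(1)
    weight_missing = rng.random(n) < miss["weight"]
    occupation = rng.choice(np.array(_OCC), size=n, p=np.array(_OCC_P) / np.sum(_OCC_P))
    country = rng.choice(np.array(_COUNTRIES), size=n, p=np.array(_COUNTRY_P) / np.sum(_COUNTRY_P))
    country_missing = rng.random(n) < miss["country"]

    # --- concomitant drugs and outcomes ------------------------------------
    n_con = rng.poisson(0.8, size=n)
    con_rep = np.repeat(np.arange(n), n_con)
    con_drug = rng.choice(config.n_drugs, size=con_rep.size)
    con_role = rng.choice(np.array(["C", "SS"]), size=con_rep.size, p=[0.7, 0.3])

    has_outcome = rng.random(n) < 0.35
    n_out = np.where(has_outcome, 1 + (rng.random(n) < 0.15), 0)
    out_rep = np.repeat(np.arange(n), n_out)
    out_code = rng.choice(np.array(_OUTCOME_CODES), size=out_rep.size,
                          p=np.array(_OUTCOME_P) / np.sum(_OUTCOME_P))

    # --- duplicate versions -------------------------------------------------
    dup = rng.random(n) < config.duplicate_version_rate
    n_extra = np.where(dup, 1 + (rng.random(n) < 0.2), 0)
    extra_rep = np.repeat(np.arange(n), n_extra)
    extra_tie = rng.random(extra_rep.size) < 0.3  # same fda_dt, pid breaks the tie
    extra_back = rng.integers(1, 180, size=extra_rep.size)
    extra_off = np.where(extra_tie, fda_off[extra_rep],
                         np.maximum(fda_off[extra_rep] - extra_back, 0))
    extra_int = _dates_to_int(base, extra_off)
    extra_sex_perturbed = rng.random(extra_rep.size) < 0.3

    deleted = rng.random(n) < config.deleted_case_rate

    # --- primaryid assignment ----------------------------------------------
    m = n + int(n_extra.sum())
    pid_pool = rng.permutation(m) + 1
    main_pid = pid_pool[:n]
    extra_pid = pid_pool[n:]

    # --- assemble records ---------------------------------------------------
    caseids = np.arange(1, n + 1)
    case_versions: list[CaseVersion] = []
    drugs: list[DrugMention] = []
    events: list[EventMention] = []
    outcomes: list[OutcomeMention] = []
    therapies: list[TherapyRecord] = []
    versions_by_case: dict[int, list[int]] = {}

    pair_case = pair_df["case"].to_numpy()
    pair_pt = pair_df["pt"].to_numpy()
    pair_splits = np.searchsorted(pair_case, np.arange(n + 1))
    con_splits = np.searchsorted(con_rep, np.arange(n + 1))
    out_splits = np.searchsorted(out_rep, np.arange(n + 1))
    extra_splits = np.searchsorted(extra_rep, np.arange(n + 1))

    def emit_children(pid: int, i: int) -> None:
        drugs.append(
            DrugMention(primaryid=pid, drug_seq=1, drug_name=drug_names[drug_idx[i]],
                        role_code="PS")
        )
        for j in range(con_splits[i], con_splits[i + 1]):
            drugs.append(
                DrugMention(primaryid=pid, drug_seq=2 + j - con_splits[i],
                            drug_name=drug_names[con_drug[j]], role_code=str(con_role[j]))
            )
        for j in range(pair_splits[i], pair_splits[i + 1]):
            events.append(EventMention(primaryid=pid, pt=pt_names[pair_pt[j]]))
        for j in range(out_splits[i], out_splits[i + 1]):
            outcomes.append(OutcomeMention(primaryid=pid, outcome_code=str(out_code[j])))
        if ther_present[i]:
            therapies.append(
                TherapyRecord(primaryid=pid, drug_seq=1, start_dt=int(ther_int[i]), start_prec="D")
            )

    for i in range(n):
        cid = int(caseids[i])
        pid = int(main_pid[i])
        version_pids = [pid]
        case_versions.append(
            CaseVersion(
                primaryid=pid,
                caseid=cid,
                fda_dt=int(fda_int[i]),
                event_dt=int(event_int[i]) if event_present[i] else None,
                event_dt_prec="D" if event_present[i] else "",
                sex=str(sex[i]),
                age_years=float(age[i]) if not age_missing[i] else None,
                weight_kg=float(weight[i]) if not weight_missing[i] else None,
                reporter_occupation=str(occupation[i]),
                reporter_country=None if country_missing[i] else str(country[i]),
            )
        )
        emit_children(pid, i)
        for j in range(extra_splits[i], extra_splits[i + 1]):
            epid = int(extra_pid[j])
            version_pids.append(epid)
            case_versions.append(
                CaseVersion(
                    primaryid=epid,
                    caseid=cid,
                    fda_dt=int(extra_int[j]),
                    event_dt=int(event_int[i]) if event_present[i] else None,
                    event_dt_prec="D" if event_present[i] else "",
                    sex="unknown" if extra_sex_perturbed[j] else str(sex[i]),
                    age_years=float(age[i]) if not age_missing[i] else None,
                    weight_kg=float(weight[i]) if not weight_missing[i] else None,
                    reporter_occupation=str(occupation[i]),
                    reporter_country=None if country_missing[i] else str(country[i]),
                )
            )
            emit_children(epid, i)
        versions_by_case[cid] = version_pids

    # retention rule applied generator-side, independently of the dedup module
    fda_by_pid = {v.primaryid: v.fda_dt for v in case_versions}
    survivor = {
        cid: max(pids, key=lambda p: (fda_by_pid[p], p))
        for cid, pids in versions_by_case.items()
    }

    truth = GroundTruth(
        planted={pt: float(rho) for pt, rho in config.planted_associations},
        versions=versions_by_case,
        survivor=survivor,
        target_caseids={int(c) for c in caseids[is_target]},
        deleted_caseids={int(c) for c in caseids[deleted]},
        n_versions=len(case_versions),
    )
    corpus = SyntheticCorpus(
        config=config,
        case_versions=case_versions,
        drugs=drugs,
        events=events,
        outcomes=outcomes,
        therapies=therapies,
        meddra_map=config.meddra_map(),
        ground_truth=truth,
    )
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus


class ExpectedTable(NamedTuple):
    """Analytically expected 2x2 cells (real-valued)."""

    a: float
    b: float
    c: float
    d: float


def _k_pmf(config: GeneratorConfig) -> np.ndarray:
    """Truncated geometric events-per-case law, tail mass lumped at max."""
    q = 1.0 / config.mean_events
    ks = np.arange(1, config.max_events + 1)
    pmf = q * (1 - q) ** (ks - 1)
    pmf[-1] = (1 - q) ** (config.max_events - 1)
    return pmf


def _inclusion_probs(config: GeneratorConfig, weights: np.ndarray) -> np.ndarray:
    """P(case includes PT j) = E_k[1 - (1 - w_j)^k] under the draw law."""
    pmf = _k_pmf(config)
    ks = np.arange(1, config.max_events + 1)
    return np.array([(pmf * (1.0 - (1.0 - w) ** ks)).sum() for w in weights])


def expected_table(config: GeneratorConfig, drug: str, pt: str) -> ExpectedTable:
    """Expected 2x2 cells for (drug, pt) under the generator's sampling law.

    Counts are distinct case-PT pairs, scaled by the post-deletion case
    population; duplicate versions do not affect them (the survivor carries
    the same event list).
    """
    drug_names = config.drug_names()
    pt_names = config.pt_names()
    if drug not in drug_names:
        raise ValueError(f"unknown drug {drug!r}")
    if pt not in pt_names:
        raise ValueError(f"unknown pt {pt!r}")
    j = pt_names.index(pt)
    g = drug_names.index(drug)
    target_idx = drug_names.index(config.target_drug_name)

    n_eff = config.n_cases * (1.0 - config.deleted_case_rate)
    probs = config.drug_probs()
    n_target = n_eff * probs[target_idx]
    n_other = n_eff - n_target

    incl_t = _inclusion_probs(config, config.tilted_weights())
    incl_b = _inclusion_probs(config, config.base_weights())
    m_t = incl_t.sum()  # expected distinct PTs per target case
    m_b = incl_b.sum()

    total_pairs = n_target * m_t + n_other * m_b
    pairs_with_pt = n_target * incl_t[j] + n_other * incl_b[j]

    if g == target_idx:
        n_g, incl_g, m_g = n_target, incl_t, m_t
    else:
        n_g = n_eff * probs[g]
        incl_g, m_g = incl_b, incl_b.sum()
    a = n_g * incl_g[j]
    b = n_g * m_g - a
    c = pairs_with_pt - a
    d = (total_pairs - n_g * m_g) - c
    return ExpectedTable(a=a, b=b, c=c, d=d)
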
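"""Cohort selection and descriptive summaries (baseline, onset, SOC)."""
from itertools import combinations

import pytest

from faersig.cohort import (
    CohortSpec,
    annual_counts,
    map_events_to_soc,
    match_target_cases,
    onset_bin,
    onset_distribution,
    percentage,
    prioritize_outcome,
    summarize_baseline,
)
from faersig.types import (
    CaseRecord,
    CaseVersion,
    DrugMention,
    EventMention,
    MeddraMap,
    OutcomeMention,
)


def mk_case(cid, fda=20200101, sex="unknown", age=None, weight=None, occ="unknown",
            country=None, event_dt=None, event_prec="", drugs=(), events=(), outcomes=()):
    v = CaseVersion(primaryid=cid, caseid=cid, fda_dt=fda, event_dt=event_dt,
                    event_dt_prec=event_prec, sex=sex, age_years=age, weight_kg=weight,
                    reporter_occupation=occ, reporter_country=country)
    return CaseRecord(caseid=cid, primaryid=cid, fda_dt=fda, version=v,
                      drugs=tuple(drugs), events=tuple(events), outcomes=tuple(outcomes))


def drug(cid, name, role="PS", start=None, prec=""):
    return DrugMention(primaryid=cid, drug_seq=1, drug_name=name, role_code=role,
                       therapy_start_dt=start, therapy_start_prec=prec)


class TestMatching:
    spec = CohortSpec(name_patterns=("TIOTROPIUM", "SPIRIVA"))

    def test_brand_suffix_matches_by_substring(self):
        r = mk_case(1, drugs=[drug(1, "Spiriva Respimat")])
        assert match_target_cases([r], self.spec) == {1}

    def test_non_suspect_role_is_excluded(self):
        r = mk_case(1, drugs=[drug(1, "TIOTROPIUM BROMIDE", role="C")])
        assert match_target_cases([r], self.spec) == set()

    def test_active_ingredient_field_also_matches(self):
        d = DrugMention(primaryid=1, drug_seq=1, drug_name="SOME BRAND",
                        role_code="PS", active_ingredient="tiotropium bromide")
        assert match_target_cases([mk_case(1, drugs=[d])], self.spec) == {1}

    def test_empty_pattern_list_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CohortSpec(name_patterns=())


class TestPercentage:
    def test_half_up_rounding(self):
        assert percentage(1, 800) == 0.13  # 0.125 rounds up
        assert percentage(38771, 65045) == 59.61
        assert percentage(0, 0) == 0.0


class TestBaseline:
    def test_sex_block_counts_and_percentages(self):
        records = (
            [mk_case(i, sex="F") for i in range(3)]
            + [mk_case(10 + i, sex="M") for i in range(2)]
            + [mk_case(20 + i) for i in range(3)]
        )
        b = summarize_baseline(records)
        assert b.n_patients == 8
        assert b.sex["F"] == (3, 37.5)
        assert b.sex["M"] == (2, 25.0)
        assert b.sex["unknown"] == (3, 37.5)
        assert sum(c for c, _ in b.sex.values()) == b.n_patients

    @pytest.mark.parametrize(
        "age,bin_label",
        [(17.9, "<18"), (18, "18-44"), (44.9, "18-44"), (45, "45-64"),
         (64.9, "45-64"), (65, "65-75"), (75, "65-75"), (75.1, ">75"), (None, "unknown")],
    )
    def test_age_bin_edges(self, age, bin_label):
        b = summarize_baseline([mk_case(1, age=age)])
        assert b.age[bin_label] == (1, 100.0)

    @pytest.mark.parametrize(
        "weight,bin_label",
        [(72.9, "<73"), (73, "73-87"), (87.9, "73-87"), (88, "88-104"),
         (104, "88-104"), (104.1, ">104"), (None, "unknown")],
    )
    def test_weight_bin_edges(self, weight, bin_label):
        b = summarize_baseline([mk_case(1, weight=weight)])
        assert b.weight[bin_label] == (1, 100.0)

    def test_blocks_sum_to_n_patients(self):
        records = [mk_case(i, age=float(20 + 7 * i % 80), weight=float(40 + 13 * i % 100))
                   for i in range(30)]
        b = summarize_baseline(records)
        for block in (b.sex, b.age, b.weight, b.occupation):
            assert sum(c for c, _ in block.values()) == 30

    def test_empty_cohort_degenerates_to_zero(self):
        b = summarize_baseline([])
        assert b.n_patients == 0
        assert all(c == 0 and p == 0.0 for c, p in b.sex.values())

    def test_country_ranked_top_k(self):
        records = ([mk_case(i, country="US") for i in range(5)]
                   + [mk_case(10 + i, country="JP") for i in range(2)]
                   + [mk_case(20 + i, country=c) for i, c in enumerate("ABCDEF")])
        b = summarize_baseline(records, top_k_countries=2)
        assert list(b.country) == ["US", "JP"]

    def test_ae_reports_count_distinct_case_pt_pairs(self):
        r = mk_case(1, events=[EventMention(1, "cough"), EventMention(1, "cough"),
                               EventMention(1, "dyspnoea")])
        assert summarize_baseline([r]).n_ae_reports == 2


class TestOutcomePriority:
    def test_exhaustive_subsets_match_severity_argmax_oracle(self):
        # independent oracle: explicit severity scores, most severe wins
        score = {"DE": 7, "LT": 6, "HO": 5, "DS": 4, "CA": 3, "RI": 2, "OT": 1}
        codes = list(score)
        for k in range(1, len(codes) + 1):
            for subset in combinations(codes, k):
                assert prioritize_outcome(list(subset)) == max(subset, key=score.get)

    def test_examples(self):
        assert prioritize_outcome(["HO", "DE"]) == "DE"
        assert prioritize_outcome(["OT"]) == "OT"
        assert prioritize_outcome(["RI", "CA", "DS"]) == "DS"

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            prioritize_outcome([])

    def test_baseline_outcome_block_uses_prioritized_code(self):
        r = mk_case(1, outcomes=[OutcomeMention(1, "HO"), OutcomeMention(1, "DE")])
        b = summarize_baseline([r])
        assert b.outcome["DE"] == (1, 100.0)
        assert b.outcome["HO"][0] == 0


class TestAnnualCounts:
    def test_mean_is_floor_over_window_years(self):
        records = [mk_case(i, fda=20040000 + 10000 * (i % 21) + 115) for i in range(433)]
        counts, mean = annual_counts(records, window=(2004, 2024))
        assert sum(counts.values()) == 433
        assert mean == 433 // 21

    def test_single_year_window_mean_equals_total(self):
        records = [mk_case(i, fda=20200101 + i) for i in range(5)]
        _, mean = annual_counts(records, window=(2020, 2020))
        assert mean == 5

    def test_empty_cohort_all_zero(self):
        counts, mean = annual_counts([], window=(2004, 2006))
        assert counts == {2004: 0, 2005: 0, 2006: 0} and mean == 0


class TestOnset:
    spec = CohortSpec(name_patterns=("TIOTROPIUM",))

    @pytest.mark.parametrize(
        "days,label",
        [(0, "0-30"), (30, "0-30"), (31, "31-180"), (45, "31-180"), (180, "31-180"),
         (181, "181-360"), (360, "181-360"), (361, "361-720"), (720, "361-720"), (730, ">720")],
    )
    def test_half_open_bin_edges(self, days, label):
        assert onset_bin(days) == label

    def _case(self, cid, start, event, prec="D", start_prec="D"):
        return mk_case(cid, event_dt=event, event_prec=prec,
                       drugs=[drug(cid, "TIOTROPIUM", start=start, prec=start_prec)])

    def test_onset_days_binned_and_percentaged(self):
        records = [
            self._case(1, 20200101, 20200215),  # 45 days -> 31-180
            self._case(2, 20200101, 20200110),  # 9 days -> 0-30
            self._case(3, 20200101, 20220110),  # >720
        ]
        d = onset_distribution(records, self.spec)
        assert d.n_evaluable == 3 and d.n_excluded == 0
        assert d.counts["31-180"] == 1 and d.counts["0-30"] == 1 and d.counts[">720"] == 1
        assert d.percentages["31-180"] == 33.33

    def test_negative_and_imprecise_onsets_excluded_and_tallied(self):
        records = [
            self._case(1, 20200110, 20200101),  # negative
            self._case(2, 20200101, 20200201, start_prec="M"),  # imprecise start
            self._case(3, 20200101, None, prec=""),  # no event date
            self._case(4, 20200101, 20200301),  # evaluable
        ]
        d = onset_distribution(records, self.spec)
        assert d.n_evaluable == 1 and d.n_excluded == 3
        assert sum(d.counts.values()) == d.n_evaluable


class TestSocMapping:
    mapping = MeddraMap({"dyspnoea": "respiratory disorders", "cough": "respiratory disorders"})

    def test_counts_case_pt_pairs_per_soc(self):
        records = [
            mk_case(1, events=[EventMention(1, "dyspnoea")]),
            mk_case(2, events=[EventMention(2, "dyspnoea")]),
        ]
        _, soc_counts = map_events_to_soc(records, self.mapping)
        assert soc_counts == {"respiratory disorders": 2}

    def test_two_pts_same_soc_contribute_two_pairs_one_soc(self):
        r = mk_case(1, events=[EventMention(1, "dyspnoea"), EventMention(1, "cough")])
        case_socs, soc_counts = map_events_to_soc([r], self.mapping)
        assert soc_counts["respiratory disorders"] == 2
        assert case_socs[1] == frozenset({"respiratory disorders"})

    def test_unmapped_pt_tallied_never_dropped(self):
        r = mk_case(1, events=[EventMention(1, "vertigo")])
        _, soc_counts = map_events_to_soc([r], self.mapping)
        assert soc_counts == {"unmapped": 1}
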
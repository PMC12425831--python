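"""ROR, PRR + chi-square, BCPNN IC: formulas, oracles, invariants."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from faersig.signals import (
    ContingencyTable,
    SignalRow,
    Thresholds,
    bcpnn_ic,
    build_tables,
    joint_signal,
    prr_chi2,
    rank_signals,
    ror,
)

LN2 = math.log(2)


def mc_ic_oracle(table: ContingencyTable, n_draws: int, seed: int):
    """Posterior-sampling oracle for the IC moments.

    Samples the three independent Beta posteriors of the joint, drug and
    event reporting probabilities and returns the mean/sd of
    log2(p11/(p1*p2)) with Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(seed)
    a, n = table.a, table.N
    n1, n2 = table.a + table.b, table.a + table.c
    g = (n + 2) * (n + 2) / ((n1 + 1) * (n2 + 1))
    p11 = rng.beta(1 + a, g - 1 + n - a, size=n_draws)
    p1 = rng.beta(1 + n1, 1 + n - n1, size=n_draws)
    p2 = rng.beta(1 + n2, 1 + n - n2, size=n_draws)
    ic = (np.log(p11) - np.log(p1) - np.log(p2)) / LN2
    mean = ic.mean()
    sd = ic.std(ddof=1)
    # SE of the sample sd via the fourth moment (draws are skewed)
    centered = ic - mean
    se_sd = math.sqrt((np.mean(centered**4) - sd**4) / n_draws) / (2 * sd)
    return mean, sd, sd / math.sqrt(n_draws), se_sd


class TestBuildTables:
    def test_direct_count_example(self):
        pairs = {(1, "x"), (2, "y"), (3, "y"), (4, "z"),
                 (5, "x"), (6, "x"), (7, "y"), (8, "y"), (9, "z"), (10, "z")}
        target = {1, 2, 3, 4}
        tables = build_tables(pairs, target)
        assert tables["x"] == ContingencyTable(1, 3, 2, 4)

    def test_margins_shared_and_a_conserved(self):
        rng = np.random.default_rng(0)
        pairs = {(int(c), f"t{rng.integers(8)}") for c in rng.integers(0, 60, size=150)}
        target = set(range(20))
        tables = build_tables(pairs, target)
        n_target = sum(1 for c, _ in pairs if c in target)
        for t in tables.values():
            assert t.a + t.b == n_target
            assert t.N == len(pairs)
        assert sum(t.a for t in tables.values()) == n_target


class TestRor:
    def test_independence_table_gives_one(self):
        value, _ = ror(ContingencyTable(10, 90, 100, 900))
        assert value == pytest.approx(1.0)

    def test_threefold_table_with_woolf_interval(self):
        value, (lo, hi) = ror(ContingencyTable(25, 75, 100, 900))
        assert value == pytest.approx(3.0)
        se = math.sqrt(1 / 25 + 1 / 75 + 1 / 100 + 1 / 900)
        assert lo == pytest.approx(math.exp(math.log(3.0) - 1.96 * se), rel=1e-12)
        assert hi == pytest.approx(math.exp(math.log(3.0) + 1.96 * se), rel=1e-12)

    def test_zero_cell_haldane_correction_hand_value(self):
        value, (lo, hi) = ror(ContingencyTable(0, 100, 50, 850))
        assert value == pytest.approx((0.5 * 850.5) / (100.5 * 50.5), rel=1e-12)
        assert math.isfinite(lo) and math.isfinite(hi) and lo < value < hi

    def test_interval_matches_standard_2x2_routine(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
            value, (lo, hi) = ror(ContingencyTable(a, b, c, d))
            sm = Table2x2([[a, b], [c, d]])
            assert value == pytest.approx(sm.oddsratio, rel=1e-12)
            smlo, smhi = sm.oddsratio_confint()
            assert lo == pytest.approx(smlo, rel=1e-4)  # z=1.96 vs 1.959964
            assert hi == pytest.approx(smhi, rel=1e-4)


class TestPrrChi2:
    def test_independence_table_gives_one(self):
        prr, _ = prr_chi2(ContingencyTable(10, 90, 100, 900))
        assert prr == pytest.approx(1.0)

    def test_frozen_textbook_values(self):
        prr, yates = prr_chi2(ContingencyTable(25, 75, 100, 900), "yates")
        _, pearson = prr_chi2(ContingencyTable(25, 75, 100, 900), "pearson")
        assert prr == pytest.approx(2.5)
        assert pearson == pytest.approx(20.31, abs=0.005)
        assert yates == pytest.approx(18.85, abs=0.005)

    def test_zero_nontarget_count_reports_infinity(self):
        prr, _ = prr_chi2(ContingencyTable(5, 95, 0, 900))
        assert math.isinf(prr) and prr > 0

    def test_chi2_matches_scipy_both_variants(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
            t = ContingencyTable(a, b, c, d)
            e_a = (a + b) * (a + c) / t.N
            obs = [[a, b], [c, d]]
            _, pearson = prr_chi2(t, "pearson")
            assert pearson == pytest.approx(chi2_contingency(obs, correction=False).statistic, rel=1e-10)
            if abs(a - e_a) >= 0.5:  # scipy's correction overshoots below 0.5
                _, yates = prr_chi2(t, "yates")
                assert yates == pytest.approx(chi2_contingency(obs, correction=True).statistic, rel=1e-10)
            checked += 1

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_row_swap_inverts_prr_and_ror_prr_relation(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        swapped = ContingencyTable(c, d, a, b)
        prr, _ = prr_chi2(t)
        prr_swapped, _ = prr_chi2(swapped)
        assert prr_swapped == pytest.approx(1.0 / prr, rel=1e-10)
        # algebraic link between the two ratios
        value, _ = ror(t)
        assert value / prr == pytest.approx(d * (a + b) / (b * (c + d)), rel=1e-10)


class TestBcpnn:
    def test_scaled_independence_table_shrinks_to_zero(self):
        ics = [bcpnn_ic(ContingencyTable(10 * k, 90 * k, 100 * k, 900 * k))[0]
               for k in (1, 10, 100, 1000)]
        assert all(abs(ics[i + 1]) < abs(ics[i]) for i in range(len(ics) - 1))
        assert abs(ics[-1]) < 0.01

    def test_ic025_strictly_below_ic(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = ContingencyTable(*(int(x) for x in rng.integers(0, 300, size=4) + [1, 1, 1, 1]))
            ic, ic025 = bcpnn_ic(t)
            assert ic025 < ic

    @pytest.mark.parametrize("cells", [(25, 75, 100, 900), (3, 50, 8, 1000), (200, 1800, 700, 90000)])
    def test_closed_form_moments_match_sampling_oracle(self, cells):
        t = ContingencyTable(*cells)
        ic, ic025 = bcpnn_ic(t)
        sd_closed = (ic - ic025) / 1.96
        mc_mean, mc_sd, se_mean, se_sd = mc_ic_oracle(t, n_draws=200_000, seed=7)
        assert abs(ic - mc_mean) < 3 * se_mean
        assert abs(sd_closed - mc_sd) < 3 * se_sd

    def test_sd2_variant_is_wider(self):
        t = ContingencyTable(25, 75, 100, 900)
        _, lo_z = bcpnn_ic(t, "z196")
        _, lo_2sd = bcpnn_ic(t, "sd2")
        assert lo_2sd < lo_z


class TestMonotonicity:
    def test_all_statistics_increase_in_a_with_margins_fixed(self):
        from faersig.signals import PriorHyperparams, ebgm

        n, n1, n2 = 5000, 300, 260
        theta = PriorHyperparams(0.5, 0.3, 3.0, 2.0, 0.4)
        rors, prrs, ics, ebs = [], [], [], []
        for a in range(1, 51):
            t = ContingencyTable(a, n1 - a, n2 - a, n - n1 - n2 + a)
            rors.append(ror(t)[0])
            prrs.append(prr_chi2(t)[0])
            ics.append(bcpnn_ic(t)[0])
            ebs.append(ebgm(t, theta)[0])
        for seq in (rors, prrs, ics, ebs):
            assert all(x < y for x, y in zip(seq, seq[1:]))


class TestJointRule:
    def _row(self, **kw):
        base = dict(term="x", level="PT", a=10, ror=3.0, ror_ci95=(2.0, 4.5),
                    prr=3.0, chi2=25.0, ic=1.5, ic025=0.8, ebgm=3.0, ebgm05=2.5)
        base.update(kw)
        return SignalRow(**base)

    def test_all_passing_is_signal(self):
        assert joint_signal(self._row(), Thresholds())

    @pytest.mark.parametrize(
        "kw",
        [dict(a=2), dict(ror_ci95=(0.9, 4.5)), dict(prr=1.9), dict(chi2=3.9),
         dict(ic025=-0.1), dict(ic025=0.0), dict(ebgm05=2.0)],
    )
    def test_any_failing_criterion_vetoes(self, kw):
        assert not joint_signal(self._row(**kw), Thresholds())


class TestRanking:
    def _rows(self):
        return [
            SignalRow(term=t, level="PT", a=a, ror=1, ror_ci95=(1, 1), prr=1,
                      chi2=1, ic=0, ic025=0, ebgm=1, ebgm05=e)
            for t, a, e in [("p", 10, 3.0), ("q", 10, 5.0), ("r", 50, 1.0), ("s", 2, 9.0)]
        ]

    def test_frequency_ranking_breaks_ties_by_ebgm05(self):
        ranked = rank_signals(self._rows(), "frequency")
        assert [r.term for r in ranked] == ["r", "q", "p", "s"]

    def test_ebgm05_ranking(self):
        ranked = rank_signals(self._rows(), "ebgm05", k=2)
        assert [r.term for r in ranked] == ["s", "q"]

    def test_k_larger_than_rows_and_permutation(self):
        rows = self._rows()
        ranked = rank_signals(rows, "frequency", k=100)
        assert sorted(r.term for r in ranked) == sorted(r.term for r in rows)
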
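import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.disproportionality import (ContingencyTable, SignalResult,
                                         bh_adjust_log, build_table,
                                         compute_pair, detect_signal,
                                         ic_with_ic025, log_p_from_chi2, prr,
                                         ror_with_ci, run_screen, volcano_data,
                                         yates_chi2)

VCM_ARF = ContingencyTable(510, 1808, 31495, 921364)

tables = st.tuples(st.integers(0, 500), st.integers(1, 500),
                   st.integers(1, 500), st.integers(1, 500)) \
    .map(lambda t: ContingencyTable(*t))
positive_tables = st.tuples(st.integers(1, 500), st.integers(1, 500),
                            st.integers(1, 500), st.integers(1, 500)) \
    .map(lambda t: ContingencyTable(*t))


class TestContingencyTable:
    def test_build_from_id_sets(self):
        t = build_table({1, 2}, {2, 3}, {1, 2, 3, 4})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            build_table(set(), set(), set())

    def test_margins(self):
        assert VCM_ARF.drug_total == 2318
        assert VCM_ARF.n == 955177

    def test_brute_force_set_algebra_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            universe = set(range(rng.integers(4, 50)))
            eligible = {i for i in universe if rng.random() < 0.4}
            event = {i for i in universe if rng.random() < 0.4}
            t = build_table(eligible, event, universe)
            assert t.a == len(eligible & event)
            assert t.b == len(eligible - event)
            assert t.c == len(event - eligible)
            assert t.d == len(universe - eligible - event)
            assert t.n == len(universe)


class TestPRR:
    def test_reference_value(self):
        assert round(prr(VCM_ARF), 2) == 6.66

    def test_proportional_table_gives_one(self):
        assert prr(ContingencyTable(10, 90, 100, 900)) == pytest.approx(1.0)

    def test_zero_background_not_evaluable(self):
        assert math.isnan(prr(ContingencyTable(5, 10, 0, 100)))


class TestYatesChi2:
    def test_small_count_reference_value(self):
        # discriminates the continuity-corrected statistic (19.19) from the
        # uncorrected Pearson value (~23.1)
        assert round(yates_chi2(ContingencyTable(7, 32, 34376, 920762)), 2) == 19.19

    def test_proportional_table_gives_zero(self):
        assert yates_chi2(ContingencyTable(10, 90, 100, 900)) == 0.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            yates_chi2(ContingencyTable(0, 0, 5, 5))

    def test_closed_form_equivalence(self):
        # N(|ad-bc|-N/2)^2 / product-of-marginals whenever |ad-bc| >= N/2
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(1, 400, size=4))
            t = ContingencyTable(a, b, c, d)
            n = t.n
            cross = abs(a * d - b * c)
            if cross >= n / 2:
                closed = (n * (cross - n / 2) ** 2
                          / ((a + b) * (c + d) * (a + c) * (b + d)))
                assert yates_chi2(t) == pytest.approx(closed, abs=1e-9)

    @given(positive_tables)
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_row_and_column_swap(self, t):
        swapped = ContingencyTable(t.d, t.c, t.b, t.a)
        assert yates_chi2(t) == pytest.approx(yates_chi2(swapped), rel=1e-12)


class TestROR:
    def test_reference_values(self):
        point, low, high = ror_with_ci(VCM_ARF)
        assert round(point, 2) == 8.25
        assert low < point < high
        assert round(ror_with_ci(ContingencyTable(305, 533, 98880, 855459))[0],
                     2) == 4.95

    def test_symmetric_table_gives_one(self):
        point, low, high = ror_with_ci(ContingencyTable(30, 20, 30, 20))
        assert point == pytest.approx(1.0)

    def test_zero_cell_not_evaluable(self):
        point, low, high = ror_with_ci(ContingencyTable(0, 10, 20, 30))
        assert math.isnan(high) and math.isnan(low)

    @given(positive_tables)
    @settings(max_examples=200, deadline=None)
    def test_ror_prr_identity(self, t):
        # ROR = PRR * [(a+b)/b] * [d/(c+d)]
        lhs = ror_with_ci(t)[0]
        rhs = prr(t) * (t.drug_total / t.b) * (t.d / t.nondrug_total)
        assert lhs == pytest.approx(rhs, rel=1e-12)
        if t.a / t.drug_total > t.c / t.nondrug_total:
            assert lhs > prr(t)


class TestInformationComponent:
    def test_zero_count_limit(self):
        # a=0 with vanishing expectation: log2(0.5/0.5) = 0
        t = ContingencyTable(0, 1, 0, 10_000_000)
        ic, _ = ic_with_ic025(t)
        assert ic == pytest.approx(0.0, abs=1e-3)

    def test_reference_pair(self):
        ic, ic025 = ic_with_ic025(VCM_ARF)
        assert ic == pytest.approx(2.71, abs=0.01)
        assert ic025 == pytest.approx(2.58, abs=0.01)

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_lower_bound_below_point(self, t):
        ic, ic025 = ic_with_ic025(t)
        assert ic025 < ic


class TestLogScaleP:
    def test_five_percent_point(self):
        assert log_p_from_chi2(3.841459) == pytest.approx(math.log(0.05),
                                                          abs=1e-4)

    def test_no_underflow_at_extreme_statistics(self):
        # asymptotically ln p ~ -x/2 - 0.5*ln(pi*x/2)
        value = log_p_from_chi2(5000)
        assert math.isfinite(value)
        assert value == pytest.approx(-2500 - 0.5 * math.log(math.pi * 2500),
                                      rel=1e-3)

    def test_zero_statistic(self):
        assert log_p_from_chi2(0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_p_from_chi2(-1)


class TestLogSpaceBH:
    def test_single_test_unchanged(self):
        assert bh_adjust_log([-3.0]) == [-3.0]

    def test_hand_oracle(self):
        raw = [math.log(p) for p in (0.01, 0.02, 0.03, 0.04)]
        adjusted = [math.exp(v) for v in bh_adjust_log(raw)]
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        assert bh_adjust_log([]) == []

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(1)
        raw = np.log(rng.random(50)).tolist()
        adjusted = bh_adjust_log(raw)
        assert all(a >= r for a, r in zip(adjusted, raw))
        assert all(a <= 0 for a in adjusted)


def _result(prr_value=5.0, chi2=50.0, a=10, log_fdr_p=-10.0):
    t = ContingencyTable(a, max(100 - a, 1), 50, 10_000)
    r = SignalResult(drug="d", term_id="t", level="PT", table=t,
                     prr=prr_value, chi2=chi2, ror=1.0, ror_ci=(1, 1),
                     ic=0, ic025=0, log_p=log_fdr_p, log_fdr_p=log_fdr_p)
    return r


class TestSignalRule:
    def test_all_conditions_met(self):
        assert detect_signal(_result())

    @pytest.mark.parametrize("kwargs", [
        {"a": 2},                    # case-count floor
        {"prr_value": 1.99},         # PRR threshold boundary
        {"chi2": 3.9},
        {"log_fdr_p": math.log(0.06)},
    ])
    def test_each_condition_individually_fails(self, kwargs):
        assert not detect_signal(_result(**kwargs))

    def test_monotone_under_table_scaling(self):
        # scaling all cells up (same proportions) never unflags a signal
        base = ContingencyTable(6, 94, 50, 9850)
        for scale in (1, 2, 5, 10):
            t = ContingencyTable(base.a * scale, base.b * scale,
                                 base.c * scale, base.d * scale)
            r = compute_pair("d", "t", "PT", t)
            r.log_fdr_p = r.log_p
            if scale == 1:
                first = detect_signal(r)
                assert first
            else:
                assert detect_signal(r)


class TestScreen:
    def test_degenerate_single_pair_family(self, small_report_set):
        from pvsignal.meddra import build_event_matrix
        from pvsignal.srs_store import deduplicate
        rs = deduplicate(small_report_set)
        matrix = build_event_matrix(rs, level="PT")
        results = run_screen(rs, matrix, {"vancomycin": ["oral"]})
        tested = [r for r in results if r.drug == "vancomycin" and r.a >= 1]
        assert len(tested) == 1
        # single-member BH family: adjusted equals raw
        assert tested[0].log_fdr_p == pytest.approx(tested[0].log_p)

    def test_results_sorted_by_chi2_within_drug(self):
        from conftest import make_report_set
        from pvsignal.meddra import build_event_matrix
        drug_rows = [(f"C{i}", "drugx", "suspected", "intravenous",
                      "2020-01-01", "") for i in range(30)]
        reac_rows = [(f"C{i}", "pt_a", "2020-01-05") for i in range(25)] \
            + [(f"C{i}", "pt_b", "2020-01-05") for i in range(3)] \
            + [("F0000", "pt_a", "2020-01-05"), ("F0001", "pt_b", "2020-01-05")]
        rs = make_report_set(drug_rows, reac_rows, n_extra_reports=200)
        matrix = build_event_matrix(rs, level="PT")
        results = [r for r in run_screen(rs, matrix, ["drugx"])]
        chis = [r.chi2 for r in results]
        assert chis == sorted(chis, reverse=True)


class TestVolcano:
    def test_prr_one_maps_to_origin(self):
        r = _result(prr_value=1.0)
        (x, y, size, label), = volcano_data([r])
        assert x == 0.0 and y == r.chi2

    def test_reference_coordinates(self):
        r = compute_pair("vancomycin", "arf", "SMQ", VCM_ARF)
        (x, y, size, _), = volcano_data([r])
        assert x == pytest.approx(math.log2(6.66), abs=0.01)
        assert y == pytest.approx(2490.21, abs=0.01)

    def test_non_evaluable_rows_omitted_and_size_monotone(self):
        rng = np.random.default_rng(3)
        results = [compute_pair("d", f"t{i}",
                                "PT", ContingencyTable(*map(int, rng.integers(1, 80, 4))))
                   for i in range(20)]
        results.append(_result(prr_value=math.nan))
        points = volcano_data(results)
        assert len(points) == 20
        sizes = [p[2] for p in points]
        ratios = [r.reporting_ratio for r in results[:20]]
        assert np.argsort(sizes).tolist() == np.argsort(ratios).tolist()
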
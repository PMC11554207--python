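import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from floodcontam.metrics import (
    AssemblageSummary,
    aggregate_series,
    biomass_density,
    ci_additive,
    ci_multiplicative,
    contamination_indices,
    kempton_q,
    kempton_q_campaign,
    round_half_away,
    spearman_rho,
    summarize_unit,
    unit_profile_table,
)

from conftest import make_survey


# ---------------------------------------------------------------------------
# independent oracles

def oracle_quantile_type7(values, q):
    """Brute-force linear-interpolation quantile from first principles."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def oracle_midranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def oracle_pearson(a, b):
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    den = math.sqrt(sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b))
    return num / den


class TestBiomassDensity:
    @pytest.mark.parametrize(
        "weight, area, expected",
        [(368.0, 368.0, 1.0), (0.0, 247.69, 0.0), (175.0, 250.0, 0.7)],
    )
    def test_values(self, weight, area, expected):
        assert biomass_density(weight, area) == pytest.approx(expected)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            biomass_density(10.0, 0.0)


class TestSummarizeUnit:
    def test_splits_richness_and_biomass_by_origin(self, small_survey):
        s = summarize_unit(small_survey, "u1")
        assert (s.r_n, s.r_nn) == (2, 1)
        assert s.b_n == pytest.approx(300.0 / 368.0)
        assert s.b_nn == pytest.approx(68.0 / 368.0)

    def test_unit_without_catches_is_all_zero(self, small_registry_rows):
        survey = make_survey(
            [("u1", "lgar", "lake", "gillnet", "2005-05-15", 368.0)], [], small_registry_rows
        )
        s = summarize_unit(survey, "u1")
        assert (s.r_n, s.r_nn, s.b_n, s.b_nn) == (0, 0, 0.0, 0.0)

    def test_unknown_unit_raises(self, small_survey):
        with pytest.raises(KeyError):
            summarize_unit(small_survey, "nope")

    def test_unclassified_species_excluded(self, small_registry_rows):
        survey = make_survey(
            [("u1", "lgar", "lake", "gillnet", "2005-05-15", 368.0)],
            [("u1", "unc1", 5, 100.0), ("u1", "nat1", 1, 50.0)],
            small_registry_rows,
        )
        s = summarize_unit(survey, "u1")
        assert (s.r_n, s.r_nn) == (1, 0)
        assert s.b_n == pytest.approx(50.0 / 368.0)


class TestContaminationIndices:
    def test_initial_pool_ratio_worked_example(self):
        # 26 non-native vs 42 native species, unit biomasses
        prof = contamination_indices(AssemblageSummary("s", 42, 26, 1.0, 1.0))
        assert prof.ci_r == pytest.approx(26 / 68)
        assert prof.ci_b == pytest.approx(0.5)
        assert prof.ci_e == pytest.approx(26 / 68)
        assert prof.ci_a == pytest.approx((0.5 + 26 / 68) / 2)
        assert prof.ci_sq == pytest.approx(math.sqrt(0.5 * 26 / 68))
        assert round(prof.ci_r, 5) == 0.38235
        assert round(prof.ci_a, 5) == 0.44118
        assert round(prof.ci_sq, 5) == 0.43724

    def test_no_nonnatives_gives_zero_everywhere(self):
        prof = contamination_indices(AssemblageSummary("s", 5, 0, 2.0, 0.0))
        assert (prof.ci_r, prof.ci_b, prof.ci_e, prof.ci_a, prof.ci_sq) == (0, 0, 0, 0, 0)

    def test_perfect_symmetry_gives_half(self):
        prof = contamination_indices(AssemblageSummary("s", 3, 3, 1.5, 1.5))
        for v in (prof.ci_r, prof.ci_b, prof.ci_e, prof.ci_a, prof.ci_sq):
            assert v == pytest.approx(0.5)

    def test_empty_assemblage_is_undefined_not_zero(self):
        prof = contamination_indices(AssemblageSummary("s", 0, 0, 0.0, 0.0))
        assert all(math.isnan(v) for v in (prof.ci_r, prof.ci_b, prof.ci_e, prof.ci_a, prof.ci_sq))

    def test_locality_mean_additive_index_by_linearity(self):
        # group-average CI_a follows from averaged CI_b and CI_r exactly
        assert round_half_away(ci_additive(0.61, 0.55)) == 0.58

    def test_multiplicative_form_switch(self):
        assert ci_multiplicative(0.64, 0.55, "geometric") == pytest.approx(math.sqrt(0.352))
        assert ci_multiplicative(0.64, 0.55, "product") == pytest.approx(0.352)
        with pytest.raises(ValueError):
            ci_multiplicative(0.5, 0.5, "nope")

    @given(
        r_n=st.integers(0, 40),
        r_nn=st.integers(0, 40),
        b_n=st.floats(0, 100, allow_nan=False),
        b_nn=st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounds_and_am_gm_property(self, r_n, r_nn, b_n, b_nn):
        prof = contamination_indices(AssemblageSummary("s", r_n, r_nn, b_n, b_nn))
        for v in (prof.ci_r, prof.ci_b, prof.ci_e, prof.ci_a, prof.ci_sq):
            assert math.isnan(v) or 0.0 <= v <= 1.0
        if not math.isnan(prof.ci_a):
            assert prof.ci_sq <= prof.ci_a + 1e-12
        # CI_e defined exactly when CI_b is, given any species present
        assert math.isnan(prof.ci_e) == (r_n * b_n + r_nn * b_nn == 0)

    @given(r_n=st.integers(1, 30), r_nn=st.integers(1, 30), b=st.floats(0.01, 50, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_equal_per_species_biomass_limit(self, r_n, r_nn, b):
        # every species weighing the same makes CI_b equal CI_r, and CI_e an
        # amplified version of CI_r on the same side of 1/2
        prof = contamination_indices(AssemblageSummary("s", r_n, r_nn, b * r_n, b * r_nn))
        assert prof.ci_b == pytest.approx(prof.ci_r)
        assert abs(prof.ci_e - 0.5) >= abs(prof.ci_r - 0.5) - 1e-12
        assert (prof.ci_e - 0.5) * (prof.ci_r - 0.5) >= -1e-12

    def test_ci_e_monotone_in_nonnative_biomass(self):
        vals = [
            contamination_indices(AssemblageSummary("s", 5, 3, 2.0, b_nn)).ci_e
            for b_nn in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        expected = oracle_pearson(oracle_midranks(x), oracle_midranks(y))
        assert spearman_rho(x, y).rho == pytest.approx(expected)

    def test_constant_vector_is_undefined(self):
        res = spearman_rho([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert not res.defined

    @pytest.mark.parametrize("seed", range(20))
    def test_rho_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 12).astype(float)
        y = rng.integers(0, 5, 12).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert spearman_rho(x, y).rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_exact_p_at_n4_matches_full_enumeration(self):
        import itertools

        x = [1.0, 2.0, 3.0, 4.0]
        for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0]):
            res = spearman_rho(x, list(perm))
            rho_obs = abs(res.rho)
            count = 0
            for q in itertools.permutations(perm):
                r = oracle_pearson(oracle_midranks(x), oracle_midranks(list(q)))
                if abs(r) >= rho_obs - 1e-9:
                    count += 1
            assert res.p == pytest.approx(count / 24)


class TestKemptonQ:
    def test_worked_example_two_plateaus(self):
        b = [1.0] * 5 + [math.e] * 5
        # quartiles fall on the plateaus: Q = (10/2) / ln(e/1)
        assert kempton_q(b) == pytest.approx(5.0)

    @given(
        st.lists(st.floats(0.01, 1e4, allow_nan=False), min_size=4, max_size=20),
        st.floats(0.001, 1e3),
    )
    @settings(max_examples=150, deadline=None)
    def test_scale_invariance(self, b, c):
        q1 = kempton_q(b)
        q2 = kempton_q([c * v for v in b])
        assert (math.isnan(q1) and math.isnan(q2)) or q1 == pytest.approx(q2, rel=1e-6)

    def test_equal_biomasses_undefined(self):
        assert math.isnan(kempton_q([2.0] * 8))

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError):
            kempton_q([1.0, 0.0, 2.0])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_quantile_oracle(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.lognormal(0, 1, rng.integers(4, 13)).tolist()
        b4 = oracle_quantile_type7(b, 0.75)
        b2 = oracle_quantile_type7(b, 0.25)
        expected = (len(b) / 2) / math.log(b4 / b2) if b4 > b2 else math.nan
        got = kempton_q(b)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_campaign_mean_and_skip_rule(self):
        five = [1.0] * 5 + [math.e] * 5  # Q = 5
        qk = kempton_q_campaign([five, [1.0] * 4])
        assert qk.q == pytest.approx(5.0)
        assert (qk.k, qk.n_skipped) == (1, 1)
        both = kempton_q_campaign([five, [v * 2 for v in five]])
        assert both.q == pytest.approx(5.0)
        assert (both.k, both.n_skipped) == (2, 0)


class TestAggregateSeries:
    def test_single_unit_groups_reproduce_unit_values(self, small_survey):
        series = aggregate_series(small_survey, group_by="locality")
        row = series[(series.locality == "lgar") & (series.origin == "native")].iloc[0]
        assert row["mean_biomass"] == pytest.approx(300.0 / 368.0)
        assert row["mean_richness"] == 2.0
        assert math.isnan(row["sd_biomass"])

    def test_mean_additive_equals_half_sum_of_means(self, small_registry_rows):
        rng = np.random.default_rng(5)
        units, catches = [], []
        for i in range(6):
            uid = f"u{i}"
            units.append((uid, "lgar", "lake", "gillnet", f"200{i}-05-15", 368.0))
            catches += [
                (uid, "nat1", 1, float(rng.integers(50, 500))),
                (uid, "nnv1", 1, float(rng.integers(50, 500))),
            ]
        survey = make_survey(units, catches, small_registry_rows)
        series = aggregate_series(survey, group_by="locality")
        row = series.iloc[0]
        assert row["CIa"] == pytest.approx((row["CIb"] + row["CIr"]) / 2)

    def test_group_means_match_spreadsheet_recomputation(self, small_registry_rows):
        units = [
            (f"u{i}", "lgua", "lake", "gillnet", "2010-08-15", 368.0) for i in range(3)
        ] + [
            (f"v{i}", "lgua", "lake", "seine", "2010-08-15", 200.0) for i in range(3)
        ]
        catches = []
        weights = {"u0": (100, 50), "u1": (300, 100), "u2": (200, 0), "v0": (80, 20), "v1": (60, 60), "v2": (40, 10)}
        for uid, (wn, wnn) in weights.items():
            catches.append((uid, "nat1", 2, float(wn)))
            if wnn:
                catches.append((uid, "nnv1", 1, float(wnn)))
        survey = make_survey(units, catches, small_registry_rows)
        series = aggregate_series(survey, group_by="locality")
        gill_nn = series[(series.gear == "gillnet") & (series.origin == "non_native")].iloc[0]
        # brute-force: per-unit non-native biomass densities for gillnet units
        expected = (50 / 368 + 100 / 368 + 0 / 368) / 3
        assert gill_nn["mean_biomass"] == pytest.approx(expected)
        # CI_b per unit then averaged, undefined never coerced
        cib = [50 / 150, 100 / 400, 0 / 200]
        assert gill_nn["CIb"] == pytest.approx(sum(cib) / 3)

    def test_undefined_units_excluded_from_ci_means(self, small_registry_rows):
        units = [
            ("u1", "lgar", "lake", "gillnet", "2005-05-15", 368.0),
            ("u2", "lgar", "lake", "gillnet", "2006-05-15", 368.0),
        ]
        catches = [("u1", "nat1", 1, 100.0), ("u1", "nnv1", 1, 100.0)]  # u2 empty
        survey = make_survey(units, catches, small_registry_rows)
        series = aggregate_series(survey, group_by="locality")
        assert series.iloc[0]["CIr"] == pytest.approx(0.5)

    def test_unit_profile_table_has_ci_columns(self, small_survey):
        per = unit_profile_table(small_survey)
        assert {"CIr", "CIb", "CIe", "CIa", "CIsq"} <= set(per.columns)
        u1 = per[per.unit_id == "u1"].iloc[0]
        assert u1["CIr"] == pytest.approx(1 / 3)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.5800000000000001, 0.58), (0.5932958789676531, 0.59), (-1.2551, -1.26), (2.675000001, 2.68)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value, 2) == expected
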
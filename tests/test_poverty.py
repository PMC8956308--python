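"""Poverty and impoverishment metrics: examples, identities, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from impovmap import (
    GeneratorConfig,
    NATIONAL_LINE,
    PovertyLine,
    binary_impoverishment_flag,
    compute_metrics,
    generate,
    impoverishment,
    impoverishment_by_group,
    per_capita_expenditure,
)
from impovmap.poverty import (
    ImpoverishmentTable,
    PovertyMetrics,
    ses_dichotomy,
    validate_households,
    weighted_quintiles,
)

from conftest import random_households


def make_households(exp, oop, size, weight, district=None):
    n = len(exp)
    return pd.DataFrame(
        {
            "household_id": [f"H{k}" for k in range(n)],
            "district_id": district if district is not None else ["A"] * n,
            "total_expenditure": exp,
            "oop_payment": oop,
            "household_size": size,
            "survey_weight": weight,
        }
    )


class TestPerCapitaExpenditure:
    def test_gross_and_net(self):
        assert per_capita_expenditure(400_000, 50_000, 4) == 100_000
        assert per_capita_expenditure(400_000, 50_000, 4, deduct_oop=True) == 87_500

    def test_net_floored_at_zero(self):
        assert per_capita_expenditure(30_000, 40_000, 2, deduct_oop=True) == 0.0

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            per_capita_expenditure(1000, 0, 0)


class TestComputeMetrics:
    def test_two_household_hand_calculation(self):
        df = make_households([50, 150], [0, 0], [1, 1], [1.0, 1.0])
        m = compute_metrics(df, PovertyLine("toy", 100.0))
        assert m.head_count_pct == 50.0
        assert m.poverty_gap == 25.0
        assert m.normalized_gap_pct == 25.0
        assert m.mean_positive_gap_pct == 50.0

    def test_per_day_line_converts_by_365(self):
        df = make_households([300 * 365, 500 * 365], [0, 0], [1, 1], [1.0, 1.0])
        m = compute_metrics(df, PovertyLine("day", 400.0, period="per_day"))
        assert m.head_count_pct == 50.0

    def test_normalized_gap_from_printed_national_gap(self):
        # G = 23101.75 MWK against the MWK 137,425 national line -> NG 16.81%
        ng = 23101.75 / NATIONAL_LINE.per_year * 100.0
        assert round(ng, 2) == 16.81

    def test_head_count_matches_lognormal_closed_form(self):
        cfg = GeneratorConfig(
            n_districts=4,
            households_per_district=250,
            island=False,
            mode="expenditure_first",
            seed=5,
        )
        df, _, truth = generate(cfg)
        m = compute_metrics(df, cfg.line, deduct_oop=False)
        # person-weighted MC error on 1000 households; analytic rate is exact
        assert abs(m.head_count_pct / 100 - truth["analytic_head_count"]) < 0.05

    def test_empty_and_bad_line_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(make_households([], [], [], []), NATIONAL_LINE)
        with pytest.raises(ValueError):
            PovertyLine("bad", -5.0)

    def test_zero_head_count_flags_undefined_mpg(self):
        df = make_households([1e9], [0], [1], [1.0])
        with pytest.warns(UserWarning, match="mean positive gap"):
            m = compute_metrics(df, NATIONAL_LINE)
        assert np.isnan(m.mean_positive_gap_pct)


class TestImpoverishment:
    def test_zero_oop_is_identity(self):
        rng = np.random.default_rng(3)
        df = random_households(rng, 200)
        df["oop_payment"] = 0.0
        tab = impoverishment(df, NATIONAL_LINE)
        assert tab.pre == tab.post
        assert all(v == 0 for v in tab.absolute_diff.values())

    def test_difference_columns_from_printed_head_counts(self):
        tab = ImpoverishmentTable(
            PovertyMetrics(51.53, 23101.75, 16.81, 32.62),
            PovertyMetrics(53.13, 24167.55, 17.59, 33.10),
        )
        rep = tab.to_report_frame().set_index("metric")
        assert rep.loc["head_count_pct", "absolute"] == 1.60
        assert rep.loc["head_count_pct", "relative_pct"] == 3.10
        assert rep.loc["poverty_gap", "absolute"] == 1065.80

    def test_post_never_below_pre(self):
        rng = np.random.default_rng(8)
        df = random_households(rng, 300)
        tab = impoverishment(df, NATIONAL_LINE)
        assert tab.post.head_count_pct >= tab.pre.head_count_pct
        assert tab.post.poverty_gap >= tab.pre.poverty_gap

    def test_mpg_times_h_equals_ng(self):
        rng = np.random.default_rng(9)
        df = random_households(rng, 300)
        tab = impoverishment(df, NATIONAL_LINE)
        for m in (tab.pre, tab.post):
            assert m.mean_positive_gap_pct * m.head_count_pct == pytest.approx(
                m.normalized_gap_pct * 100.0, rel=1e-12
            )


class TestGrouping:
    def test_single_group_equals_overall(self):
        rng = np.random.default_rng(10)
        df = random_households(rng, 150)
        df["district_id"] = "X"
        by = impoverishment_by_group(df, NATIONAL_LINE, "district_id")
        assert by["X"].pre == impoverishment(df, NATIONAL_LINE).pre

    def test_oop_free_group_shows_no_difference(self):
        rng = np.random.default_rng(12)
        df = random_households(rng, 400)
        df.loc[df["district_id"] == "A", "oop_payment"] = 0.0
        # make sure the other groups do pay something that bites
        df.loc[df["district_id"] != "A", "oop_payment"] += 1e5
        by = impoverishment_by_group(df, NATIONAL_LINE, "district_id")
        assert by["A"].absolute_diff["head_count_pct"] == 0.0
        assert any(
            by[g].absolute_diff["head_count_pct"] > 0 for g in ("B", "C")
        )

    def test_unknown_grouping_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(KeyError):
            impoverishment_by_group(random_households(rng, 20), NATIONAL_LINE, "nope")

    def test_weighted_quintiles_cut_and_ties(self):
        # five one-person households with 20% person-weight each
        df = make_households([10, 20, 30, 40, 50], [0] * 5, [1] * 5, [1.0] * 5)
        assert weighted_quintiles(df).tolist() == [1, 2, 3, 4, 5]
        # a tie straddling a cut goes entirely to the lower quintile
        df2 = make_households([10, 20, 20, 40, 50], [0] * 5, [1] * 5, [1.0] * 5)
        assert weighted_quintiles(df2).tolist() == [1, 2, 2, 4, 5]

    def test_ses_dichotomy_splits_population(self):
        rng = np.random.default_rng(14)
        df = random_households(rng, 100)
        ses = ses_dichotomy(df)
        assert set(ses) == {"lower", "higher"}
        pw = df["survey_weight"] * df["household_size"]
        lower_share = pw[ses == "lower"].sum() / pw.sum()
        assert 0.35 < lower_share < 0.65


class TestBinaryFlag:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(140_000, 130_000, 1), (120_000, 110_000, 0), (200_000, 150_000, 0)],
    )
    def test_crossing_cases(self, pre, post, expected):
        df = make_households([pre], [pre - post], [1], [1.0])
        assert binary_impoverishment_flag(df, NATIONAL_LINE)[0] == expected

    def test_deepening_variant_counts_already_poor(self):
        df = make_households([120_000], [10_000], [1], [1.0])
        assert binary_impoverishment_flag(df, NATIONAL_LINE)[0] == 0
        assert (
            binary_impoverishment_flag(df, NATIONAL_LINE, include_deepening=True)[0]
            == 1
        )

    def test_flag_share_equals_head_count_change(self):
        """The person-weighted crossing share IS the head-count rise; the
        poverty-gap rise additionally carries the already-poor deepening."""
        rng = np.random.default_rng(21)
        df = random_households(rng, 500)
        flags = binary_impoverishment_flag(df, NATIONAL_LINE)
        pw = (df["survey_weight"] * df["household_size"]).to_numpy()
        share = 100.0 * (pw * flags).sum() / pw.sum()
        tab = impoverishment(df, NATIONAL_LINE)
        assert share == pytest.approx(tab.absolute_diff["head_count_pct"], abs=1e-10)


class TestProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1.5, 4.0))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        df = random_households(rng, 60)
        m1 = compute_metrics(df, NATIONAL_LINE, deduct_oop=True)
        df2 = df.assign(
            total_expenditure=df.total_expenditure * c, oop_payment=df.oop_payment * c
        )
        m2 = compute_metrics(
            df2, PovertyLine("scaled", NATIONAL_LINE.amount * c), deduct_oop=True
        )
        assert m2.head_count_pct == pytest.approx(m1.head_count_pct, abs=1e-9)
        assert m2.poverty_gap == pytest.approx(c * m1.poverty_gap, rel=1e-9)
        assert m2.normalized_gap_pct == pytest.approx(m1.normalized_gap_pct, rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_raising_oop_never_lowers_post_metrics(self, seed):
        rng = np.random.default_rng(seed)
        df = random_households(rng, 60)
        m1 = compute_metrics(df, NATIONAL_LINE, deduct_oop=True)
        bumped = df.copy()
        k = int(rng.integers(len(df)))
        bumped.loc[bumped.index[k], "oop_payment"] += float(rng.uniform(0, 2e5))
        m2 = compute_metrics(bumped, NATIONAL_LINE, deduct_oop=True)
        assert m2.head_count_pct >= m1.head_count_pct
        assert m2.poverty_gap >= m1.poverty_gap - 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equal_weights_reduce_to_unweighted_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        df = random_households(rng, 40)
        df["survey_weight"] = 1.0
        z = NATIONAL_LINE.per_year
        m = compute_metrics(df, NATIONAL_LINE)
        # brute force over persons: each household contributes `size` persons
        persons = []
        for _, r in df.iterrows():
            persons += [r.total_expenditure / r.household_size] * int(r.household_size)
        persons = np.array(persons)
        H = 100.0 * (persons < z).mean()
        G = ((z - persons) * (persons < z)).mean()
        assert m.head_count_pct == pytest.approx(H, abs=1e-9)
        assert m.poverty_gap == pytest.approx(G, rel=1e-9)


def test_validation_rejects_bad_records():
    df = make_households([100.0], [0.0], [1], [1.0])
    for col, bad in [
        ("household_size", 0),
        ("survey_weight", 0.0),
        ("total_expenditure", -1.0),
        ("oop_payment", -1.0),
    ]:
        broken = df.copy()
        broken[col] = bad
        with pytest.raises(ValueError):
            validate_households(broken)
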
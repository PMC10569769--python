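"""Data-cleaning and labelling rule tests."""

import numpy as np
import pandas as pd
import pytest

from navfair.preprocessing import (
    active_window,
    average_adi,
    build_model_table,
    build_weekly_rows,
    drop_sparse_features,
    evaluate_proxies,
    impute_numeric,
    label_target,
    map_insurance,
    split_by_patient,
)


class TestDropSparse:
    def test_boundary_at_80_percent(self):
        n = 1000
        df = pd.DataFrame(
            {
                "exactly80": [None] * 800 + [1.0] * 200,
                "just_below": [None] * 799 + [1.0] * 201,
                "all_null": [None] * n,
                "full": np.arange(n),
            }
        )
        out = drop_sparse_features(df)
        assert list(out.columns) == ["just_below", "full"]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            drop_sparse_features(pd.DataFrame({"a": [1]}), 0.0)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("MEDICARE PART B", "Medicare"),
        ("Medicaid Managed Care", "Medicaid"),
        ("SELF PAY", "Self-pay"),
        ("BCBS PPO", "Blue Cross/Blue Shield"),
        ("BLUE CROSS COMMUNITY", "Blue Cross/Blue Shield"),
        ("AETNA CHOICE POS", "Commercial"),
        ("TRICARE EAST", "Others"),
        (None, "Others"),
        (float("nan"), "Others"),
        ("", "Others"),
    ],
)
def test_insurance_keyword_mapping(raw, expected):
    assert map_insurance(raw) == expected


class TestImpute:
    def test_training_mean_fills_test_nulls(self):
        train = pd.DataFrame({"adi": [10.0, 20.0, None], "rucc": [1.0, 1.0, 1.0]})
        test = pd.DataFrame({"adi": [None], "rucc": [None]})
        out = impute_numeric(train, test)
        assert out["adi"].iloc[0] == 15.0
        assert out["rucc"].iloc[0] == 1.0

    def test_no_nulls_is_identity(self):
        train = pd.DataFrame({"adi": [1.0, 3.0], "rucc": [2.0, 4.0]})
        out = impute_numeric(train, train)
        pd.testing.assert_frame_equal(out, train)

    def test_test_values_never_affect_the_constant(self):
        train = pd.DataFrame({"adi": [10.0, 20.0], "rucc": [1.0, 2.0]})
        test_a = pd.DataFrame({"adi": [None, 0.0], "rucc": [None, 9.0]})
        test_b = pd.DataFrame({"adi": [None, 999.0], "rucc": [None, -5.0]})
        assert impute_numeric(train, test_a)["adi"].iloc[0] == impute_numeric(
            train, test_b
        )["adi"].iloc[0]

    def test_all_null_training_column_errors(self):
        train = pd.DataFrame({"adi": [None, None], "rucc": [1.0, 2.0]})
        with pytest.raises(ValueError):
            impute_numeric(train, train)


@pytest.mark.parametrize(
    "vals,expected", [([40, 60], 50.0), ([77], 77.0), ([1, 2, 3, 4], 2.5)]
)
def test_average_adi(vals, expected):
    assert average_adi(vals) == expected


def test_average_adi_empty_flows_to_imputation():
    assert average_adi([]) is None
    assert average_adi([float("nan")]) is None


class TestActiveWindow:
    def test_single_interaction(self):
        log = pd.DataFrame({"patient_id": ["p"], "day": [5]})
        w = active_window(log)
        assert (w["start_day"].iloc[0], w["end_day"].iloc[0]) == (5, 95)

    def test_two_interactions(self):
        log = pd.DataFrame({"patient_id": ["p", "p"], "day": [0, 10]})
        w = active_window(log)
        assert (w["start_day"].iloc[0], w["end_day"].iloc[0]) == (0, 100)

    def test_interaction_in_tail_extends_it(self):
        log = pd.DataFrame({"patient_id": ["p", "p"], "day": [0, 85]})
        w = active_window(log)
        assert w["end_day"].iloc[0] == 175

    def test_no_interactions_error(self):
        with pytest.raises(ValueError):
            active_window(pd.DataFrame({"patient_id": [], "day": []}))


class TestWeeklyRows:
    def test_mondays_inside_window_only(self):
        windows = pd.DataFrame({"patient_id": ["p"], "start_day": [1], "end_day": [20]})
        rows = build_weekly_rows(windows, n_weeks=10)
        assert list(rows["week"]) == [1, 2]  # Mondays at days 7 and 14

    def test_window_starting_on_monday_includes_it(self):
        windows = pd.DataFrame({"patient_id": ["p"], "start_day": [0], "end_day": [8]})
        rows = build_weekly_rows(windows, n_weeks=10)
        assert list(rows["week"]) == [0, 1]

    def test_inactive_patient_has_no_rows(self):
        windows = pd.DataFrame({"patient_id": ["p"], "start_day": [1], "end_day": [5]})
        assert len(build_weekly_rows(windows, n_weeks=10)) == 0

    def test_idempotent_for_fixed_inputs(self):
        windows = pd.DataFrame(
            {"patient_id": ["p", "q"], "start_day": [0, 3], "end_day": [30, 40]}
        )
        a = build_weekly_rows(windows, 8)
        b = build_weekly_rows(windows, 8)
        pd.testing.assert_frame_equal(a, b)


class TestLabelTarget:
    def test_half_open_week_window(self):
        rows = pd.DataFrame({"patient_id": ["p", "p"], "week": [0, 1]})
        # Tuesday (1) and Friday (4) count for week 0; day 7 (next Monday) for week 1
        enc = pd.DataFrame({"patient_id": ["p", "p", "p"], "day": [1, 4, 7]})
        out = label_target(rows, enc, max_covered_day=14)
        assert list(out["target"]) == [2, 1]

    def test_no_encounters_is_zero(self):
        rows = pd.DataFrame({"patient_id": ["p"], "week": [0]})
        enc = pd.DataFrame({"patient_id": ["q"], "day": [3]})
        out = label_target(rows, enc, max_covered_day=7)
        assert list(out["target"]) == [0]

    def test_trailing_uncovered_rows_dropped(self):
        rows = pd.DataFrame({"patient_id": ["p", "p"], "week": [0, 1]})
        enc = pd.DataFrame({"patient_id": ["p"], "day": [2]})
        out = label_target(rows, enc)  # coverage ends at day 2 -> week 0 needs day 7
        assert len(out) == 0


class TestSplit:
    def test_8_2_split(self):
        train, test = split_by_patient([f"p{i}" for i in range(10)], seed=0)
        assert len(train) == 8 and len(test) == 2
        assert set(train) | set(test) == {f"p{i}" for i in range(10)}
        assert not set(train) & set(test)

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(25)]
        assert np.array_equal(split_by_patient(ids, seed=3)[0], split_by_patient(ids, seed=3)[0])

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_by_patient(["only"])


def _proxy_fixture():
    """Two navigators, four months; encounter volume tracks panel size while
    note edits are pure noise."""
    rng = np.random.default_rng(0)
    rows = []
    panels = []
    for nav, base in (("n1", 10), ("n2", 20)):
        for month in range(4):
            size = base + 6 * month
            panels.append({"navigator_id": nav, "month": month, "panel_size": size})
            for day in range(month * 30, month * 30 + 30):
                for k in range(rng.poisson(size / 10)):
                    rows.append(
                        {
                            "patient_id": f"{nav}pt{day}_{k}",
                            "navigator_id": nav,
                            "day": day,
                            "interaction_kind": "encounter",
                        }
                    )
                for _ in range(rng.poisson(3)):  # size-independent note churn
                    rows.append(
                        {
                            "patient_id": f"{nav}note{day}",
                            "navigator_id": nav,
                            "day": day,
                            "interaction_kind": rng.choice(["note_create", "note_edit"]),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(panels)


class TestProxies:
    def test_enct_outranks_note_churn(self):
        log, panels = _proxy_fixture()
        result = evaluate_proxies(log, panels)
        ranks = {r.metric_name: i for i, r in result.iterrows()}
        assert ranks["enct"] < ranks["notct2"]
        assert result.iloc[0]["metric_name"] == "enct"

    def test_one_encounter_per_patient_per_day(self):
        log = pd.DataFrame(
            {
                "patient_id": ["p", "p", "q"],
                "navigator_id": ["n", "n", "n"],
                "day": [0, 0, 40],
                "interaction_kind": ["encounter"] * 3,
            }
        )
        panels = pd.DataFrame(
            {"navigator_id": ["n", "n"], "month": [0, 1], "panel_size": [1, 1]}
        )
        from navfair.preprocessing import _daily_proxy_values

        daily = _daily_proxy_values(log)
        # two same-day encounters for one patient contribute 1
        assert daily[daily.day == 0]["enct"].iloc[0] == 1

    def test_constant_series_reports_nan(self):
        log = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "navigator_id": ["n", "n"],
                "day": [0, 40],
                "interaction_kind": ["encounter", "encounter"],
            }
        )
        panels = pd.DataFrame(
            {"navigator_id": ["n", "n"], "month": [0, 1], "panel_size": [5, 5]}
        )
        result = evaluate_proxies(log, panels)
        assert result["pearson_r"].isna().all()  # constant panel size

    def test_needs_two_months(self):
        log = pd.DataFrame(
            {
                "patient_id": ["a"],
                "navigator_id": ["n"],
                "day": [0],
                "interaction_kind": ["encounter"],
            }
        )
        with pytest.raises(ValueError):
            evaluate_proxies(log, pd.DataFrame({"navigator_id": [], "month": [], "panel_size": []}))


class TestModelTable:
    def test_schema_and_invariants(self, small_cohort, small_table):
        t = small_table
        assert not t.duplicated(["patient_id", "week"]).any()
        assert (t["target"] >= 0).all()
        assert (t["weeks_since_enrollment"] >= 1).all()
        assert t["adi"].notna().all() and t["rucc"].notna().all()  # imputed
        assert set(t["insurance"]) <= {
            "Medicare",
            "Medicaid",
            "Self-pay",
            "Commercial",
            "Blue Cross/Blue Shield",
            "Others",
        }
        # excluded-by-design columns exist in the table but not in the feature set
        from navfair.predictor import EXCLUDED_FEATURES, NUMERIC_FEATURES

        for col in EXCLUDED_FEATURES:
            assert col in t.columns
            assert col not in NUMERIC_FEATURES

    def test_imputation_uses_training_means_only(self, small_cohort):
        """Mutating test patients' ADI must not change imputed training rows."""
        import navfair as nf

        ds = small_cohort
        mutated = ds.patients.copy()
        test_mask = mutated["patient_id"].isin(ds.test_ids)
        mutated.loc[test_mask, "adi"] = 999.0
        ds2 = nf.CohortDataset(
            config=ds.config,
            patients=mutated,
            encounters=ds.encounters,
            arrivals=ds.arrivals,
            latents=ds.latents,
            train_ids=ds.train_ids,
            test_ids=ds.test_ids,
        )
        t1 = build_model_table(ds)
        t2 = build_model_table(ds2)
        train_rows1 = t1[t1.patient_id.isin(ds.train_ids)]["adi"]
        train_rows2 = t2[t2.patient_id.isin(ds.train_ids)]["adi"]
        assert np.allclose(train_rows1.to_numpy(), train_rows2.to_numpy())
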
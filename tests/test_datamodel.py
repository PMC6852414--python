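import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathmed as pm
from pathmed.datamodel import DataValidationError


class TestVisitSchedule:
    def test_floor_visit_brackets_the_schedule(self):
        sched = pm.VisitSchedule((3.0, 9.0, 15.0))
        assert sched.floor_visit(1.0) == 0
        assert sched.floor_visit(3.0) == 1  # a visit time belongs to its own visit
        assert sched.floor_visit(8.99) == 1
        assert sched.floor_visit(100.0) == 3

    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=6, unique=True),
           st.floats(0, 120))
    def test_floor_visit_is_count_of_elapsed_visits(self, times, t):
        sched = pm.VisitSchedule(tuple(sorted(times)))
        k = sched.floor_visit(t)
        assert k == sum(tau <= t for tau in sched.times)
        if k:
            assert sched.tau(k) <= t

    @pytest.mark.parametrize("times", [(), (0.0, 3.0), (3.0, 3.0), (9.0, 3.0)])
    def test_invalid_schedules_rejected(self, times):
        with pytest.raises(ValueError):
            pm.VisitSchedule(times)


class TestRiskSets:
    def test_worked_example_control_risk_set(self, worked_example):
        ds, _ = worked_example
        # patient 2 fails at 0.65 < tau_1 = 3 and is excluded
        ids = ds.ids[pm.risk_set(ds, 1, 0)]
        assert list(ids) == [1, 3, 7, 9]

    def test_worked_example_treated_risk_set(self, worked_example):
        ds, _ = worked_example
        assert list(ds.ids[pm.risk_set(ds, 1, 1)]) == [4, 5, 6, 8, 10]

    def test_visit_zero_is_everyone(self, worked_example):
        ds, _ = worked_example
        assert len(pm.risk_set(ds, 0, "both")) == 10

    def test_risk_sets_are_nested(self, small_trial):
        for arm in (0, 1, "both"):
            prev = set(pm.risk_set(small_trial, 0, arm))
            for k in range(1, small_trial.K + 1):
                cur = set(pm.risk_set(small_trial, k, arm))
                assert cur <= prev
                prev = cur

    def test_visit_out_of_range(self, worked_example):
        ds, _ = worked_example
        with pytest.raises(ValueError):
            pm.risk_set(ds, ds.K + 1, 0)


class TestBuildHistory:
    def test_worked_example_design(self, worked_example):
        ds, _ = worked_example
        idx = pm.risk_set(ds, 1, 0)
        design = pm.build_history(ds, idx, confounder_depth=1, mediator_depth=0)
        assert design.X.shape == (4, 2)
        assert design.names == ["l0", "l1"]

    def test_baseline_only_and_full_depth(self, worked_example):
        ds, _ = worked_example
        idx = pm.risk_set(ds, 1, "both")
        assert pm.build_history(ds, idx, 0, 0).names == ["l0"]
        full = pm.build_history(ds, idx, 1, 1)
        assert full.names == ["l0", "l1", "m1"]
        assert full.X.shape == (9, 3)

    def test_column_order_is_stable(self, small_trial):
        idx = pm.risk_set(small_trial, 2, "both")
        a = pm.build_history(small_trial, idx, 2, 1)
        b = pm.build_history(small_trial, idx, 2, 1)
        assert a.names == b.names
        np.testing.assert_array_equal(a.X, b.X)

    def test_incomplete_history_rejected(self, worked_example):
        import dataclasses

        ds, _ = worked_example
        M = [m.copy() for m in ds.M]
        M[0][1, 0] = np.nan  # blank patient 2's visit-1 mediator
        ds2 = dataclasses.replace(ds, M=M)
        with pytest.raises(DataValidationError):
            pm.build_history(ds2, np.arange(10), 1, 1)
        # excluding the incomplete patient makes the request valid again
        keep = np.array([i for i in range(10) if i != 1])
        assert pm.build_history(ds2, keep, 1, 1).X.shape == (9, 3)

    def test_depth_beyond_schedule_rejected(self, worked_example):
        ds, _ = worked_example
        with pytest.raises(ValueError):
            pm.build_history(ds, np.array([0]), 2, 0)


class TestIO:
    def test_round_trip_is_exact(self, small_trial, tmp_path):
        path = tmp_path / "trial.csv"
        schema = pm.write_longitudinal_table(small_trial, path)
        back = pm.read_longitudinal_table(path, schema)
        np.testing.assert_array_equal(small_trial.T, back.T)
        np.testing.assert_array_equal(small_trial.arm, back.arm)
        np.testing.assert_array_equal(small_trial.E, back.E)
        np.testing.assert_array_equal(small_trial.L0, back.L0)
        for k in range(small_trial.K):
            np.testing.assert_array_equal(small_trial.M[k], back.M[k])
            np.testing.assert_array_equal(small_trial.V[k], back.V[k])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("patient,visit,arm,time,event,l0\n")
        schema = {**pm.datamodel.DEFAULT_SCHEMA, "baseline": ["l0"],
                  "confounders": [], "mediators": [], "visit_times": [3.0]}
        with pytest.raises(DataValidationError, match="no patients"):
            pm.read_longitudinal_table(path, schema)

    def test_missing_mandatory_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient,visit,time,event,l0\n1,0,5.0,1,60\n")
        schema = {**pm.datamodel.DEFAULT_SCHEMA, "baseline": ["l0"],
                  "confounders": [], "mediators": [], "visit_times": [3.0]}
        with pytest.raises(DataValidationError, match="arm"):
            pm.read_longitudinal_table(path, schema)

    def test_value_after_event_rejected_in_strict_mode(self, tmp_path):
        path = tmp_path / "anachronistic.csv"
        path.write_text(
            "patient,visit,arm,time,event,l0,m1\n"
            "1,0,0,1.5,1,60,\n"
            "1,1,,,,,70\n"   # mediator recorded after the event at t=1.5 < 3
            "2,0,1,10,0,61,\n"
            "2,1,,,,,68\n"
        )
        schema = {**pm.datamodel.DEFAULT_SCHEMA, "baseline": ["l0"],
                  "confounders": [], "mediators": ["m1"], "visit_times": [3.0]}
        with pytest.raises(DataValidationError):
            pm.read_longitudinal_table(path, schema)
        lenient = pm.read_longitudinal_table(path, schema, strict=False)
        assert np.isnan(lenient.M[0][0, 0])
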
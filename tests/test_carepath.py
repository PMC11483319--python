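"""Care-path arithmetic: staff time, machine slots, staff cost."""

import pytest
from hypothesis import given, settings, strategies as st

import rtcost as rc
from rtcost.carepath import (
    CarePath,
    StaffRateTable,
    Task,
    calibrated_carepath,
    occurrences,
)
from rtcost.cohort import ValidationError


@pytest.fixture(scope="module")
def regimen_26_5(registry):
    return registry.get("26-5")


class TestHourlyRate:
    def test_division(self):
        rates = StaffRateTable(
            annual_salaries={"radiation_therapist": 58812.0},
            annual_working_hours=1956.0,
        )
        assert rc.hourly_rate("radiation_therapist", rates) == pytest.approx(
            30.07, abs=0.005
        )

    def test_zero_salary_gives_zero_rate(self):
        rates = StaffRateTable(
            annual_salaries={"other": 0.0}, annual_working_hours=1956.0
        )
        assert rc.hourly_rate("other", rates) == 0.0

    def test_unknown_role_raises(self, staff_rates):
        with pytest.raises(KeyError, match="nurse"):
            rc.hourly_rate("nurse", staff_rates)


class TestTreatmentCalendar:
    @pytest.mark.parametrize("regimen_id,weeks", [
        ("26-5", 1),        # one chart check in the one-week pathway
        ("40-15", 3),
        ("40-15_boost", 4),  # 15 + 5 boost fractions span four weeks
        ("50-25", 5),
    ])
    def test_treatment_weeks(self, registry, regimen_id, weeks):
        assert rc.treatment_weeks(registry.get(regimen_id)) == weeks

    def test_occurrences_by_frequency(self, registry, regimen_26_5):
        per_course = Task("a", 10, "physician")
        per_fx = Task("b", 15, "radiation_therapist", frequency="per_fraction")
        weekly = Task("c", 20, "radiation_therapist",
                      frequency="per_treatment_week")
        assert occurrences(per_course, regimen_26_5) == 1
        assert occurrences(per_fx, regimen_26_5) == 5
        assert occurrences(weekly, registry.get("40-15_boost")) == 4


class TestStaffMinutes:
    def test_documented_one_week_pathway(self, verbatim_26_5, regimen_26_5):
        linac, non_linac = rc.staff_minutes(verbatim_26_5, regimen_26_5)
        # 30 + 45x2 + 40 + 20 + 90 + 35 + 35 + 20 = 360 off the machine;
        # 15 min x 2 therapists x 5 fractions = 150 on it
        assert non_linac == 360
        assert linac == 150

    def test_empty_task_list(self, regimen_26_5):
        empty = CarePath(regimen_id="26-5", tasks=[])
        assert rc.staff_minutes(empty, regimen_26_5) == (0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        minutes=st.lists(
            st.floats(min_value=0, max_value=240, allow_nan=False),
            min_size=0, max_size=8,
        ),
        split=st.integers(min_value=0, max_value=8),
    )
    def test_additive_over_concatenation_and_linear(self, minutes, split):
        registry = rc.default_registry()
        regimen = registry.get("40-15")
        tasks = [
            Task(f"t{i}", m, "radiation_therapist",
                 location="linac" if i % 2 else "non_linac",
                 frequency="per_fraction" if i % 3 == 0 else "per_course")
            for i, m in enumerate(minutes)
        ]
        split = min(split, len(tasks))
        whole = CarePath("40-15", tasks)
        left = CarePath("40-15", tasks[:split])
        right = CarePath("40-15", tasks[split:])
        w = rc.staff_minutes(whole, regimen)
        l, r = rc.staff_minutes(left, regimen), rc.staff_minutes(right, regimen)
        assert w[0] == pytest.approx(l[0] + r[0])
        assert w[1] == pytest.approx(l[1] + r[1])
        doubled = CarePath("40-15", [
            Task(t.name, t.minutes * 2, t.role, t.n_staff, t.location,
                 t.frequency) for t in tasks
        ])
        d = rc.staff_minutes(doubled, regimen)
        assert d[0] == pytest.approx(2 * w[0])
        assert d[1] == pytest.approx(2 * w[1])


class TestMachineMinutes:
    def test_slot_model_reproduces_every_calibrated_value(
        self, registry, slot_table, calibration
    ):
        # the audited per-patient linac minutes are slot x fractions for all
        # sixteen audited regimens and both one-week schedules
        for row in calibration.itertuples(index=False):
            regimen = registry.get(row.regimen_id)
            expected = row.machine_min_total / row.n_2019
            assert rc.machine_minutes(regimen, slot_table) == expected, \
                row.regimen_id

    @pytest.mark.parametrize("regimen_id,minutes", [
        ("40-15", 225),                   # 15 fx x 15 min
        ("40-15_boost_dibh", 400),        # 15 x 20 + 5 x 20
        ("40-15_scaximn_boost_dibh", 625),  # 15 x 35 + 5 x 20
    ])
    def test_worked_examples(self, registry, slot_table, regimen_id, minutes):
        assert rc.machine_minutes(registry.get(regimen_id), slot_table) \
            == minutes

    def test_missing_slot_entry_raises(self, registry):
        sparse = rc.SlotTimeTable(slots={("none", False): 15.0})
        with pytest.raises(KeyError):
            rc.machine_minutes(registry.get("40-15_dibh"), sparse)

    def test_dibh_slot_shorter_than_free_breathing_rejected(self):
        table = rc.SlotTimeTable(
            slots={("none", False): 15.0, ("none", True): 10.0}
        )
        with pytest.raises(ValidationError):
            table.validate()


class TestStaffCost:
    def test_unit_case(self, registry):
        rates = StaffRateTable(
            annual_salaries={"physician": 30.0 * 1956},
            annual_working_hours=1956.0,
        )
        path = CarePath("40-15", [Task("consult", 60, "physician")])
        assert rc.staff_cost(path, registry.get("40-15"), rates) \
            == pytest.approx(30.0)

    def test_empty_path_costs_nothing(self, registry, staff_rates):
        assert rc.staff_cost(CarePath("40-15", []), registry.get("40-15"),
                             staff_rates) == 0.0

    def test_matches_task_by_task_sum(self, verbatim_26_5, regimen_26_5,
                                      staff_rates):
        # independent brute-force oracle over the documented pathway
        expected = 0.0
        for task in verbatim_26_5.tasks:
            if task.frequency == "per_course":
                times = 1
            elif task.frequency == "per_fraction":
                times = regimen_26_5.total_fractions
            else:
                times = -(-regimen_26_5.total_fractions // 5)
            rate = (staff_rates.annual_salaries[task.role]
                    / staff_rates.annual_working_hours)
            expected += task.minutes / 60 * rate * task.n_staff * times
        actual = rc.staff_cost(verbatim_26_5, regimen_26_5, staff_rates)
        assert actual == pytest.approx(expected)


class TestCalibratedPathways:
    def test_reproduce_calibrated_non_linac_minutes(
        self, registry, slot_table, profiles
    ):
        for regimen in registry:
            profile = profiles[regimen.regimen_id]
            path = calibrated_carepath(
                regimen, profile.non_linac_min, slot_table
            )
            _, non_linac = rc.staff_minutes(path, regimen)
            assert non_linac == pytest.approx(profile.non_linac_min)

    def test_target_below_fixed_floor_rejected(self, registry, slot_table):
        with pytest.raises(ValidationError):
            calibrated_carepath(registry.get("40-15"), 100.0, slot_table)
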
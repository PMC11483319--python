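"""Protocol-change predicates and sequential assignment rewrites."""

import pytest

import rtcost as rc
from rtcost.rules import apply_change, baseline_assignment, get_changes


def _patient(**overrides):
    base = dict(
        patient_id="P1", age=55, sex="female", t_stage="T1", n_stage="N0",
        chemotherapy=False, surgery="WLE", reconstruction=False,
        nodal_surgery="SLNB", laterality="left", central_or_medial=False,
        histology="ductal", molecular_subtype="luminalA", grade=2,
        lvi=False, margin_positive=False, margin_le_2mm=False,
        fb_plan_unsatisfactory=False, baseline_regimen_id="40-15",
    )
    base.update(overrides)
    return rc.PatientRecord(**base)


def _dcis_patient(age=60, **features):
    profile_fields = dict(
        nuclear_grade="low", comedonecrosis=False, central_necrosis=False,
        symptomatic=False, size_mm=10.0, multifocal=False,
        radial_margin_mm=12.0,
    )
    profile_fields.update(features)
    return _patient(
        age=age, histology="DCIS", t_stage="Tis", grade=1,
        dcis_features=rc.DcisProfile(**profile_fields),
    )


class TestBoostIndication:
    def test_under_50_always_indicated(self):
        assert rc.boost_indicated(_patient(age=45))

    @pytest.mark.parametrize("risk", [
        dict(grade=3),
        dict(lvi=True),
        dict(margin_positive=True, margin_le_2mm=True),
    ])
    def test_50_plus_with_one_risk_factor(self, risk):
        assert rc.boost_indicated(_patient(age=55, **risk))

    def test_50_plus_without_risk_factors(self):
        assert not rc.boost_indicated(_patient(age=55))

    def test_extensive_intraductal_component_counts_for_invasive(self):
        profile = rc.DcisProfile(
            nuclear_grade="low", comedonecrosis=False,
            central_necrosis=False, symptomatic=False, size_mm=0.0,
            multifocal=False, radial_margin_mm=20.0,
            extensive_intraductal_component=True,
        )
        assert rc.boost_indicated(_patient(age=60, dcis_features=profile))

    def test_rejects_in_situ_disease(self):
        with pytest.raises(ValueError):
            rc.boost_indicated(_dcis_patient())


class TestDcisBoostIndication:
    def test_low_risk_profile_not_indicated(self):
        assert not rc.dcis_boost_indicated(_dcis_patient())

    @pytest.mark.parametrize("kwargs", [
        dict(age=45),
        dict(size_mm=20.0),
        dict(symptomatic=True),
        dict(multifocal=True),
        dict(nuclear_grade="intermediate"),
        dict(nuclear_grade="high"),
        dict(comedonecrosis=True),
        dict(radial_margin_mm=5.0),
    ])
    def test_any_single_criterion_indicates(self, kwargs):
        age = kwargs.pop("age", 60)
        assert rc.dcis_boost_indicated(_dcis_patient(age=age, **kwargs))

    def test_rejects_invasive_disease(self):
        with pytest.raises(ValueError):
            rc.dcis_boost_indicated(_patient())


class TestImnIndication:
    def test_n2_disease(self):
        assert rc.imn_indicated(_patient(n_stage="N2"))

    @pytest.mark.parametrize("risk", [
        dict(grade=3),
        dict(lvi=True),
        dict(molecular_subtype="triple_negative"),
        dict(age=35),
        dict(central_or_medial=True),
    ])
    def test_n1_with_adverse_factor(self, risk):
        assert rc.imn_indicated(_patient(n_stage="N1", **risk))

    def test_n1_without_adverse_factor(self):
        assert not rc.imn_indicated(_patient(n_stage="N1"))

    def test_n0_never_indicated(self):
        assert not rc.imn_indicated(_patient(n_stage="N0", grade=3, lvi=True))


class TestDibhIndication:
    def test_under_60_left_sided(self, registry):
        regimen = registry.get("40-15")
        assert rc.dibh_indicated(_patient(age=50), regimen)

    def test_under_60_right_sided_needs_imn(self, registry):
        patient = _patient(age=50, laterality="right")
        assert not rc.dibh_indicated(patient, registry.get("40-15"))
        assert rc.dibh_indicated(patient, registry.get("40-15_scaximn"))

    def test_60_plus_depends_on_plan_quality(self, registry):
        regimen = registry.get("40-15")
        assert not rc.dibh_indicated(_patient(age=70), regimen)
        assert rc.dibh_indicated(
            _patient(age=70, fb_plan_unsatisfactory=True), regimen
        )

    def test_bilateral_meets_no_laterality_criterion(self, registry):
        patient = _patient(age=50, laterality="bilateral")
        assert not rc.dibh_indicated(patient, registry.get("40-15"))


class TestUltraEligibility:
    def test_invasive_breast_only_no_boost(self, registry):
        assert rc.ultra_eligible(_patient(), registry.get("40-15"))

    def test_dcis_excluded(self, registry):
        assert not rc.ultra_eligible(_dcis_patient(), registry.get("40-15"))

    @pytest.mark.parametrize("regimen_id",
                             ["40-15_scax", "40-15_boost", "40-15_scaximn"])
    def test_nodes_or_boost_exclude(self, registry, regimen_id):
        assert not rc.ultra_eligible(_patient(), registry.get(regimen_id))


def _counts(assignment):
    out = {}
    for rid in assignment.values():
        out[rid] = out.get(rid, 0) + 1
    return out


def _run_through(cohort, registry, last_change):
    assignment = baseline_assignment(cohort)
    states = [assignment]
    for change in get_changes():
        if change.change_id > last_change:
            break
        assignment = apply_change(cohort, assignment, change, registry)
        states.append(assignment)
    return states


class TestApplyChange:
    def test_change_1_is_identity_without_conventional_fractionation(
        self, registry
    ):
        cohort = [_patient(patient_id=f"P{i}") for i in range(5)]
        assignment = baseline_assignment(cohort)
        after = apply_change(cohort, assignment, get_changes([1])[0],
                             registry)
        assert after == assignment

    def test_patient_records_never_mutated(self, cohort, registry):
        snapshot = list(cohort)
        assignment = baseline_assignment(cohort)
        for change in get_changes():
            assignment = apply_change(cohort, assignment, change, registry)
        assert cohort == snapshot  # frozen records, same objects and values

    @pytest.mark.parametrize("change_id", [1, 2, 3, 4, 5, 6])
    def test_each_change_is_idempotent(self, cohort, registry, change_id):
        states = _run_through(cohort, registry, change_id)
        change = get_changes([change_id])[0]
        again = apply_change(cohort, states[-1], change, registry)
        assert again == states[-1]

    def test_missing_rewrite_target_raises(self, registry):
        # an in-breath-hold one-week patient with N2 disease would need a
        # 26/5 locoregional schedule, which is not a registered regimen
        patient = _patient(n_stage="N2", baseline_regimen_id="26-5")
        with pytest.raises(KeyError):
            apply_change([patient], baseline_assignment([patient]),
                         get_changes([5])[0], registry)


class TestSequentialTransitions:
    """Frozen intermediate assignment counts along the packaged trajectory."""

    def test_change_1_reassigns_the_ten_conventional_courses(
        self, cohort, registry
    ):
        counts = _counts(_run_through(cohort, registry, 1)[-1])
        assert counts["40-15"] == 39
        assert counts["40-15_dibh"] == 8
        assert counts["40-15_scax_dibh"] == 11
        assert counts["40-15_scaximn_dibh"] == 9
        assert all(not rid.startswith("50-25") for rid in counts)

    def test_change_2_withdraws_34_boosts_and_adds_none(
        self, cohort, registry
    ):
        states = _run_through(cohort, registry, 2)
        before, after = states[1], states[2]
        removed = sum(
            1 for pid in before
            if registry.get(before[pid]).boost
            and not registry.get(after[pid]).boost
        )
        added = sum(
            1 for pid in before
            if not registry.get(before[pid]).boost
            and registry.get(after[pid]).boost
        )
        assert (removed, added) == (34, 0)
        assert _counts(after)["40-15"] == 56

    def test_change_3_moves_68_to_one_week_schedules(self, cohort, registry):
        counts = _counts(_run_through(cohort, registry, 3)[-1])
        assert counts["26-5"] == 50
        assert counts["26-5_dibh"] == 18
        # the whole-breast patients left behind are the in-situ cases
        assert counts["40-15"] == 6
        assert counts["40-15_dibh"] == 2

    def test_change_4_boosts_five_high_risk_dcis(self, cohort, registry):
        states = _run_through(cohort, registry, 4)
        added = sum(
            1 for pid in states[3]
            if not registry.get(states[3][pid]).boost
            and registry.get(states[4][pid]).boost
        )
        assert added == 5
        counts = _counts(states[4])
        assert counts["40-15"] == 2 and counts["40-15_dibh"] == 1

    def test_change_5_adds_imn_for_42_reaching_71(self, cohort, registry):
        states = _run_through(cohort, registry, 5)
        gained = sum(
            1 for pid in states[4]
            if registry.get(states[4][pid]).nodal_class != "scax_imn"
            and registry.get(states[5][pid]).nodal_class == "scax_imn"
        )
        total = sum(
            1 for rid in states[5].values()
            if registry.get(rid).nodal_class == "scax_imn"
        )
        assert (gained, total) == (42, 71)

    def test_change_6_only_ever_adds_breath_hold(self, cohort, registry):
        states = _run_through(cohort, registry, 6)
        lost = sum(
            1 for pid in states[5]
            if registry.get(states[5][pid]).dibh
            and not registry.get(states[6][pid]).dibh
        )
        assert lost == 0
        counts = _counts(states[6])
        assert counts["26-5_dibh"] == 21 and counts["26-5"] == 47
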
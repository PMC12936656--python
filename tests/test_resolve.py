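import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxsupply.dose import FormGroup
from rxsupply.model import Component
from rxsupply.resolve import (DEFAULT_RULES, FormRuleSet, Method,
                              MissingQuantity, build_mode_table,
                              calculate_ds, impute_from_mode, mode_key,
                              reconcile, resolve_baseline, resolve_ds,
                              small_group_policy, total_dispensed_units)
from rxsupply.simulate import example_prescription

from conftest import make_record


# ---------------------------------------------------------------------------
# quantity and calculation

def test_total_units_multiplies_packages():
    assert total_dispensed_units(make_record(n_packages=2, units_per_package=30)) == 60
    assert total_dispensed_units(make_record(n_packages=1, units_per_package=100)) == 100


def test_measured_total_uses_item_size():
    rec = make_record(units_per_package=None, item_size_value=30.0, item_size_unit="g")
    assert total_dispensed_units(rec, prefer="measured") == 30.0


def test_missing_quantity_raises():
    rec = make_record(units_per_package=None)
    with pytest.raises(MissingQuantity):
        total_dispensed_units(rec)


@pytest.mark.parametrize("total, per_day, expected", [
    (60, 2, 30),
    (100, 3, 33),          # floor: full days of coverage
    (12, 4 / 7, 21),       # weekly frequency normalised upstream
    (1, 2, 1),             # minimum one day
])
def test_ds_calculation_floor_rule(total, per_day, expected):
    assert calculate_ds(total, per_day) == expected


def test_rounding_configurable():
    assert calculate_ds(100, 3, rounding="ceil") == 34
    assert calculate_ds(100, 3, rounding="round") == 33


# ---------------------------------------------------------------------------
# reconciliation: the smaller of calculated and provided wins

@pytest.mark.parametrize("calc, provided, ds, method", [
    (30, 28, 28, Method.MIN_OF_CALCULATED_AND_PROVIDED),
    (28, 30, 28, Method.MIN_OF_CALCULATED_AND_PROVIDED),
    (30, None, 30, Method.CALCULATED),
    (None, 28, 28, Method.PROVIDED),
    (None, None, None, None),
])
def test_reconcile_prefers_smaller(calc, provided, ds, method):
    got_ds, got_method, _ = reconcile(calc, provided)
    assert (got_ds, got_method) == (ds, method)


@settings(deadline=None, max_examples=200)
@given(calc=st.integers(1, 400), provided=st.integers(1, 400))
def test_reconciled_value_bounded_by_both(calc, provided):
    ds, _, _ = reconcile(calc, provided)
    assert ds <= calc and ds <= provided


# ---------------------------------------------------------------------------
# mode table

def _dose_record(i, substance, strength, per_day):
    return make_record(
        prescription_id=f"RX{i}",
        components=(Component(substance, strength, "mass"),),
        dose_times=per_day, dose_period="day",
        dose_amount=1.0, dose_amount_unit="unit")


def test_strict_mode_recovered():
    records = [_dose_record(i, "a", 10, 1.0) for i in range(5)]
    records += [_dose_record(i + 10, "a", 10, 2.0) for i in range(3)]
    table = build_mode_table(records)
    entry = table.lookup(records[0])
    assert entry.modal_daily_dose == 1.0
    assert entry.support == 8


def test_tied_key_excluded_from_imputation():
    records = [_dose_record(i, "a", 10, 1.0) for i in range(4)]
    records += [_dose_record(i + 10, "a", 10, 2.0) for i in range(4)]
    table = build_mode_table(records)
    assert len(table.entries) == 0
    key = mode_key(records[0])
    assert table.excluded_keys[key] == "tie"
    # and a record on that key stays unimputed
    bare = make_record(prescription_id="RXq",
                       components=(Component("a", 10, "mass"),))
    ds, why = impute_from_mode(bare, table)
    assert ds is None and "excluded" in why


def test_same_substance_different_strength_is_different_key():
    a5 = make_record(components=(Component("a", 5, "mass"),))
    a10 = make_record(components=(Component("a", 10, "mass"),))
    assert mode_key(a5) != mode_key(a10)


def test_mode_table_order_invariant():
    records = [_dose_record(i, s, st_, d)
               for i, (s, st_, d) in enumerate(
                   [("a", 10, 1.0)] * 5 + [("a", 10, 2.0)] * 2
                   + [("b", 5, 2.0)] * 4 + [("b", 5, 1.0)] * 4)]
    t1 = build_mode_table(records)
    shuffled = records[:]
    random.Random(5).shuffle(shuffled)
    t2 = build_mode_table(shuffled)
    assert t1.entries == t2.entries
    assert t1.excluded_keys == t2.excluded_keys


def test_min_support_excludes_sparse_keys():
    records = [_dose_record(0, "a", 10, 1.0)]
    table = build_mode_table(records, min_support=2)
    assert not table.entries
    assert list(table.excluded_keys.values()) == ["low_support"]


def test_mode_imputation_computes_ds_from_modal_dose():
    records = [_dose_record(i, "a", 10, 2.0) for i in range(5)]
    table = build_mode_table(records)
    bare = make_record(prescription_id="RXq", units_per_package=60,
                       components=(Component("a", 10, "mass"),))
    ds, _ = impute_from_mode(bare, table)
    assert ds == 30


# ---------------------------------------------------------------------------
# drug-form rule chains (constants checked in test_acceptance)

def test_provided_ds_precedes_form_constant():
    rec = example_prescription("ear_drops", provided_ds=10)
    res = resolve_ds(rec)
    assert (res.ds_days, res.method) == (10, Method.PROVIDED)


def test_implant_rule_ignores_provided_ds():
    rec = example_prescription("vaccine", provided_ds=200)
    res = resolve_ds(rec)
    assert (res.ds_days, res.method) == (1, Method.FORM_IMPUTED)


def test_hormonal_patch_counts_patches_plus_patch_free_week():
    rec = example_prescription("patch_hormonal", units_per_package=3)
    res = resolve_ds(rec)
    assert res.ds_days == 7 * 3 + 7


def test_semisolid_scales_with_package_count():
    rec = example_prescription("semisolid", n_packages=3)
    assert resolve_ds(rec).ds_days == 90


def test_nail_polish_package_type_mapping():
    large = example_prescription("nail_polish")  # 3 mL bottle
    assert resolve_ds(large).ds_days == 210
    import dataclasses
    small = dataclasses.replace(large, item_size_value=2.5)
    assert resolve_ds(small).ds_days == 180


def test_chain_reconciles_calculated_against_provided():
    # inhalation chain both calculates and consults the provided DS
    rec = example_prescription(
        "inhalation", provided_ds=25,
        dose_fields=dict(dose_times=2.0, dose_period="day",
                         dose_amount=1.0, dose_amount_unit="unit"))
    res = resolve_ds(rec)  # calculated 60/2 = 30 vs provided 25
    assert (res.ds_days, res.method) == (25, Method.MIN_OF_CALCULATED_AND_PROVIDED)


def test_other_group_without_provided_is_unresolved():
    rec = example_prescription("other")
    res = resolve_ds(rec)
    assert res.method is Method.UNRESOLVED and res.ds_days is None


def test_unresolved_oral_drops_fall_to_constant():
    rec = example_prescription("oral_drops")
    res = resolve_ds(rec)
    assert (res.ds_days, res.method) == (30, Method.FORM_IMPUTED)


def test_oral_drops_calculated_from_drop_count():
    rec = example_prescription(
        "oral_drops",
        dose_fields=dict(dose_times=1.0, dose_period="day",
                         dose_amount=20.0, dose_amount_unit="drops"))
    # 20 drops/day at 20 drops/mL = 1 mL/day over a 30 mL bottle
    assert resolve_ds(rec).ds_days == 30


def test_rules_yaml_round_trip(tmp_path):
    path = tmp_path / "rules.yaml"
    DEFAULT_RULES.to_yaml(path)
    loaded = FormRuleSet.from_yaml(path)
    assert loaded.chains == DEFAULT_RULES.chains


# ---------------------------------------------------------------------------
# full resolution precedence

def test_single_dose_full_information_reconciles():
    rec = make_record(dose_times=2.0, dose_period="day", dose_amount=1.0,
                      dose_amount_unit="unit", units_per_package=60,
                      provided_ds=28)
    res = resolve_ds(rec)  # calculated 30 vs provided 28
    assert (res.ds_days, res.method) == (28, Method.MIN_OF_CALCULATED_AND_PROVIDED)


def test_single_dose_without_dose_info_uses_mode_table():
    donors = [_dose_record(i, "tensoprel", 10, 2.0) for i in range(6)]
    table = build_mode_table(donors)
    bare = make_record(units_per_package=60)
    res = resolve_ds(bare, mode_table=table)
    assert (res.ds_days, res.method) == (30, Method.MODE_IMPUTED)


def test_single_dose_without_any_route_is_unresolved():
    res = resolve_ds(make_record())
    assert res.method is Method.UNRESOLVED


def test_resolution_always_returns_a_result(small_cohort):
    for rec in small_cohort.records[:500]:
        res = resolve_ds(rec)
        assert (res.ds_days is not None) == (res.method is not Method.UNRESOLVED)
        if res.ds_days is not None:
            assert res.ds_days >= 1


# ---------------------------------------------------------------------------
# small-group policy

def test_small_groups_restricted_to_provided_ds():
    records = [make_record(prescription_id=f"T{i}") for i in range(12)]
    records += [example_prescription("ear_drops", prescription_id="E1",
                                     provided_ds=9),
                example_prescription("ear_drops", prescription_id="E2")]
    small = small_group_policy(records, threshold=10)
    assert small == {FormGroup.EAR_DROPS}
    with_ds = resolve_ds(records[-2], provided_only_groups=small)
    without = resolve_ds(records[-1], provided_only_groups=small)
    assert (with_ds.ds_days, with_ds.method) == (9, Method.PROVIDED)
    assert without.method is Method.UNRESOLVED  # constant rule suppressed


def test_threshold_boundary_inclusive():
    records = [make_record(prescription_id=f"T{i}") for i in range(10)]
    assert small_group_policy(records, threshold=10) == set()
    assert small_group_policy(records[:-1], threshold=10) == {FormGroup.SINGLE_DOSE}


# ---------------------------------------------------------------------------
# baseline comparator

def test_baseline_calculates_when_daily_dose_present():
    rec = make_record(dose_times=2.0, dose_period="day", dose_amount=1.0,
                      dose_amount_unit="unit", units_per_package=60)
    res = resolve_baseline(rec)
    assert (res.ds_days, res.method) == (30, Method.CALCULATED)


def test_baseline_imputes_flat_default_otherwise():
    for rec in (make_record(),  # tablet without dose info
                example_prescription("eye_multi_dose")):  # qualitative form
        res = resolve_baseline(rec)
        assert (res.ds_days, res.method) == (30, Method.BASELINE_IMPUTED)
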
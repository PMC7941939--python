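"""Study-ID construction, check characters, NHS validation and stripping."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from eprlink.bundle import IDENTIFIER_COLUMNS
from eprlink.nhs import generate_nhs_numbers, is_valid_nhs_number, nhs_check_digit
from eprlink.pseudonym import (
    NeedsManualID,
    age_at_delivery,
    derive_and_strip,
    drop_off_spine,
    generate_identifiers,
    is_automated_id,
    make_manual_id,
    make_study_id,
    normalise_postcode,
    simulate_collisions,
    verify_check_char,
)

DOB_RANGE = (dt.date(1989, 1, 1), dt.date(1990, 12, 31))
DOD_RANGE = (dt.date(2017, 1, 1), dt.date(2018, 11, 30))


def _mod11_oracle(number: str) -> bool:
    # independent re-implementation of the national modulus-11 scheme
    if len(number) != 10 or not number.isdigit():
        return False
    total = sum(int(d) * w for d, w in zip(number[:9], range(10, 1, -1)))
    check = 11 - total % 11
    if check == 11:
        check = 0
    return check != 10 and check == int(number[9])


class TestNHSNumbers:
    def test_generated_numbers_satisfy_independent_mod11_oracle(self):
        rng = np.random.default_rng(0)
        numbers = generate_nhs_numbers(500, rng)
        assert len(set(numbers)) == 500
        assert all(_mod11_oracle(n) for n in numbers)
        assert all(is_valid_nhs_number(n) for n in numbers)

    def test_corrupted_digit_fails_validation(self):
        rng = np.random.default_rng(1)
        for n in generate_nhs_numbers(50, rng):
            flipped = n[:9] + str((int(n[9]) + 1) % 10)
            assert not is_valid_nhs_number(flipped)

    @pytest.mark.parametrize("bad", ["", "12345", "abcdefghij", "12345678901"])
    def test_malformed_input_rejected(self, bad):
        assert not is_valid_nhs_number(bad)
        assert nhs_check_digit(bad[:9]) is None or len(bad) != 10


class TestIdentifierGeneration:
    def test_empty_request_gives_empty_list(self):
        assert generate_identifiers(0, DOB_RANGE, seed=1) == []

    def test_identifiers_distinct_valid_and_in_range(self):
        records = generate_identifiers(2000, DOB_RANGE, seed=1)
        nhs = [r["nhs_number"] for r in records]
        assert len(set(nhs)) == 2000
        assert all(is_valid_nhs_number(n) for n in nhs)
        assert all(DOB_RANGE[0] <= r["dob"] <= DOB_RANGE[1] for r in records)

    def test_deterministic_under_fixed_seed(self):
        a = generate_identifiers(100, DOB_RANGE, seed=7)
        b = generate_identifiers(100, DOB_RANGE, seed=7)
        assert a == b


class TestStudyID:
    def test_same_inputs_always_give_same_id(self):
        sid1 = make_study_id("9434765919", dt.date(1990, 6, 15), "salt")
        sid2 = make_study_id("9434765919", dt.date(1990, 6, 15), "salt")
        assert sid1.value == sid2.value

    def test_format_is_19_digits_plus_check_letter(self):
        for rec in generate_identifiers(50, DOB_RANGE, seed=2):
            sid = make_study_id(rec["nhs_number"], rec["dob"], "salt").value
            assert len(sid) == 20
            assert sid[:19].isdigit() and sid[19].isalpha()
            assert is_automated_id(sid)

    def test_only_nhs_number_and_dob_enter_the_function(self):
        base = make_study_id("9434765919", dt.date(1990, 6, 15), "salt").value
        for hosp in ("H1", "H2", "ZZZ"):
            for pc in ("AB1 2CD", "XY9 8ZZ"):
                # hospital number and postcode are not arguments at all:
                # the same (NHS, DOB) pair must reproduce the ID regardless
                assert make_study_id("9434765919", dt.date(1990, 6, 15), "salt").value == base

    def test_salt_changes_the_id(self):
        a = make_study_id("9434765919", dt.date(1990, 6, 15), "salt-a").value
        b = make_study_id("9434765919", dt.date(1990, 6, 15), "salt-b").value
        assert a != b

    def test_missing_inputs_signal_manual_id(self):
        with pytest.raises(NeedsManualID):
            make_study_id(None, dt.date(1990, 6, 15), "salt")
        with pytest.raises(NeedsManualID):
            make_study_id("9434765919", None, "salt")
        with pytest.raises(NeedsManualID):
            make_study_id("1234567890", dt.date(1990, 6, 15), "salt")  # bad check digit

    def test_identifier_substrings_never_appear_in_id(self):
        for rec in generate_identifiers(200, DOB_RANGE, seed=3):
            sid = make_study_id(rec["nhs_number"], rec["dob"], "salt").value
            assert rec["nhs_number"] not in sid
            assert rec["dob"].strftime("%Y%m%d") not in sid


class TestCheckCharacter:
    def test_round_trip_verifies(self):
        for rec in generate_identifiers(100, DOB_RANGE, seed=4):
            assert verify_check_char(make_study_id(rec["nhs_number"], rec["dob"], "s").value)

    def test_every_single_digit_substitution_is_detected(self):
        ids = [
            make_study_id(r["nhs_number"], r["dob"], "s").value
            for r in generate_identifiers(100, DOB_RANGE, seed=5)
        ]
        for sid in ids:
            for pos in range(19):
                for repl in "0123456789":
                    if repl == sid[pos]:
                        continue
                    mutated = sid[:pos] + repl + sid[pos + 1 :]
                    assert not verify_check_char(mutated)

    @pytest.mark.parametrize("bad", ["", "123", "1" * 19, "1" * 20, "1" * 19 + "a"])
    def test_malformed_strings_are_false(self, bad):
        assert verify_check_char(bad) in (False,)


class TestManualID:
    def test_format_and_check_character(self):
        sid = make_manual_id("S01", 1)
        assert len(sid.value) == 20
        assert sid.value.startswith("M")
        assert verify_check_char(sid.value)

    def test_two_pregnancies_get_two_different_ids(self):
        assert make_manual_id("S01", 1).value != make_manual_id("S01", 2).value

    def test_namespace_disjoint_from_automated(self):
        manual = {make_manual_id("S01", i).value for i in range(1, 200)}
        automated = {
            make_study_id(r["nhs_number"], r["dob"], "s").value
            for r in generate_identifiers(200, DOB_RANGE, seed=6)
        }
        assert manual.isdisjoint(automated)
        assert not any(is_automated_id(v) for v in manual)

    def test_counter_overflow_raises(self):
        with pytest.raises(ValueError):
            make_manual_id("S01", 10**14)


class TestCollisionSimulation:
    def test_single_record_has_no_duplicates(self):
        assert simulate_collisions(1, DOB_RANGE, DOD_RANGE, seed=1) == 0

    def test_lossy_truncation_matches_group_and_count_oracle(self):
        n = 20_000
        records = generate_identifiers(n, DOB_RANGE, seed=8)

        def lossy(nhs, dob, dod):  # deliberately collision-prone 6-char key
            return nhs[:4] + dob.strftime("%m")

        engine = simulate_collisions(n, DOB_RANGE, DOD_RANGE, seed=8, scheme=lossy)
        keys = pd.Series([lossy(r["nhs_number"], r["dob"], None) for r in records])
        oracle = int(len(keys) - keys.nunique())
        assert engine == oracle
        assert engine > 0  # the truncation really is lossy at this n


class TestDeriveAndStrip:
    def test_age_at_delivery_is_completed_years(self):
        assert age_at_delivery(dt.date(1990, 6, 15), dt.date(2017, 10, 10)) == 27
        assert age_at_delivery(dt.date(1990, 6, 15), dt.date(2017, 6, 14)) == 26
        assert age_at_delivery(dt.date(1990, 6, 15), dt.date(2017, 6, 15)) == 27

    def test_postcode_normalisation(self):
        assert normalise_postcode(" ab12  3cd ") == "AB12 3CD"
        assert normalise_postcode(None) is None

    def test_identifiers_absent_from_every_output_table(self, clean_pseudonymised):
        for name, df in clean_pseudonymised.tables().items():
            for col in IDENTIFIER_COLUMNS:
                assert col not in df.columns, f"{col} leaked into {name}"
            if not df.empty:
                assert "study_id" in df.columns

    def test_missing_identifiers_route_through_manual_ids(self, defect_site, defect_config):
        bundle, truth = defect_site
        from tests.conftest import pseudonymise  # reuse the fixture helper

        from eprlink.synthetic import DIALECTS, make_postcode_lookup

        lookup = make_postcode_lookup([truth], 1, coverage=1.0).set_index("postcode")
        result = derive_and_strip(
            bundle,
            "salt",
            lookup,
            dod_column=DIALECTS[defect_config.dialect].maternity_columns["dod"],
        )
        n_manual_women = int(truth.women["missing_identifiers"].sum())
        assert n_manual_women > 0
        assert result.n_manual >= n_manual_women
        manual_ids = [
            v for v in result.bundle.maternity["study_id"] if v.startswith("M")
        ]
        assert len(manual_ids) > 0

    def test_key_file_never_in_bundle_and_maps_ids(self, clean_site, clean_config):
        bundle, truth = clean_site
        from eprlink.synthetic import DIALECTS, make_postcode_lookup

        lookup = make_postcode_lookup([truth], 1, coverage=1.0).set_index("postcode")
        result = derive_and_strip(
            bundle,
            "salt",
            lookup,
            dod_column=DIALECTS[clean_config.dialect].maternity_columns["dod"],
        )
        assert set(result.key_file.columns) >= {"study_id", "nhs_number", "dob", "site_code"}
        assert result.key_file["study_id"].is_unique
        # one key row per distinct woman
        assert len(result.key_file) == result.n_automated


class TestDropOffSpine:
    def test_off_spine_rows_removed_by_set_difference(self):
        mat = pd.DataFrame({"study_id": [f"W{i}" for i in range(7)]})
        sat = pd.DataFrame({"study_id": [f"W{i}" for i in range(10)]})
        from eprlink.bundle import RecordBundle

        bundle = RecordBundle(
            site_code="S", stage="pseudonymised", maternity=mat,
            neonatal=sat.copy(), ultrasound=sat.copy(), activity=pd.DataFrame(),
        )
        out, removed = drop_off_spine(bundle)
        assert removed == {"neonatal": 3, "ultrasound": 3, "activity": 0}
        assert set(out.neonatal["study_id"]) <= set(mat["study_id"])

    def test_all_on_spine_unchanged(self, clean_pseudonymised):
        out, removed = drop_off_spine(clean_pseudonymised)
        assert removed == {"neonatal": 0, "ultrasound": 0, "activity": 0}

    def test_empty_spine_removes_everything(self):
        from eprlink.bundle import RecordBundle

        sat = pd.DataFrame({"study_id": ["A", "B"]})
        bundle = RecordBundle(
            site_code="S", stage="pseudonymised",
            maternity=pd.DataFrame({"study_id": []}),
            neonatal=sat.copy(), ultrasound=pd.DataFrame(), activity=pd.DataFrame(),
        )
        out, removed = drop_off_spine(bundle)
        assert removed["neonatal"] == 2 and out.neonatal.empty
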
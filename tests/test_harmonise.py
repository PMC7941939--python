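"""Unit conversion, recoding, binary rules, the engine and its audit trail."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eprlink.bundle import ConfigurationError
from eprlink.harmonise import (
    DataDictionary,
    DictionaryError,
    apply_binary_rule,
    calculate_bmi,
    convert_units,
    harmonise_bundle,
    load_dictionary,
    merge_multisource,
    recode_categorical,
    replay_trail,
)


class TestConvertUnits:
    @pytest.mark.parametrize(
        "value,rule,expected",
        [
            ("5ft 4in", "ft_in->m", 64 * 0.0254),
            ("6ft 0in", "ft_in->m", 72 * 0.0254),
            ("40+2", "ga_string->days", 282.0),
            ("37+0", "ga_string->days", 259.0),
            (40.29, "ga_string->days", 282.0),  # decimal weeks
            (282, "ga_string->days", 282.0),    # already days
            (164, "cm->m", 1.64),
            ("10st 4lb", "st_lb->kg", 144 * 0.45359237),
            (150, "lb->kg", 150 * 0.45359237),
            (3400, "g->g", 3400.0),
            (2.5, "identity", 2.5),
        ],
    )
    def test_known_conversions(self, value, rule, expected):
        result, ok = convert_units(value, rule)
        assert ok
        assert result == pytest.approx(expected, abs=1e-12)

    def test_missing_passes_through_as_missing(self):
        for rule in ("identity", "cm->m", "ga_string->days"):
            value, ok = convert_units(None, rule)
            assert np.isnan(value) and ok

    def test_unparseable_flags_failure(self):
        value, ok = convert_units("tall-ish", "cm->m")
        assert np.isnan(value) and not ok

    def test_unknown_rule_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            convert_units(1.0, "furlongs->m")


class TestBMI:
    def test_reference_values(self):
        assert calculate_bmi(66.0, 1.64)[0] == pytest.approx(24.54, abs=0.005)
        assert calculate_bmi(30.0, 1.20)[0] == pytest.approx(20.83, abs=0.005)

    def test_missing_or_nonpositive_height_gives_missing(self):
        assert np.isnan(calculate_bmi(66.0, np.nan)[0])
        assert np.isnan(calculate_bmi(66.0, 0.0)[0])
        assert np.isnan(calculate_bmi(np.nan, 1.64)[0])


class TestRecode:
    def test_site_map_merges_vocabulary(self):
        s = pd.Series(["Em LSCS", "El LSCS", "SVD", None])
        out, unmapped = recode_categorical(
            s, {"Em LSCS": "caesarean", "El LSCS": "caesarean", "SVD": "unassisted_vaginal"}
        )
        assert list(out[:3]) == ["caesarean", "caesarean", "unassisted_vaginal"]
        assert pd.isna(out[3])
        assert unmapped == {}

    def test_unmapped_values_distinct_from_true_missing(self):
        s = pd.Series(["water birth", "water birth", "breech extraction", None])
        out, unmapped = recode_categorical(s, {"SVD": "unassisted_vaginal"})
        assert out.isna().all()
        assert unmapped == {"water birth": 2, "breech extraction": 1}


class TestBinaryRule:
    def test_affirmative_only_turns_missing_into_negative(self):
        s = pd.Series(["yes", np.nan, "yes"])
        assert list(apply_binary_rule(s, "affirmative_only")) == ["yes", "no", "yes"]

    def test_full_mode_preserves_missing(self):
        s = pd.Series(["yes", "no", np.nan])
        out = apply_binary_rule(s, "full")
        assert list(out[:2]) == ["yes", "no"] and pd.isna(out[2])

    def test_all_missing_affirmative_only_becomes_all_no(self):
        out = apply_binary_rule(pd.Series([np.nan] * 5), "affirmative_only")
        assert (out == "no").all()

    def test_non_binary_values_raise(self):
        with pytest.raises(ConfigurationError):
            apply_binary_rule(pd.Series(["yes", "maybe"]), "full")


class TestMergeMultisource:
    def _oracle(self, values):
        if "yes" in values:
            return "yes"
        if "no" in values:
            return "no"
        return np.nan

    def test_epidural_example(self):
        merged = merge_multisource(pd.Series(["yes"]), pd.Series([np.nan]))
        assert merged[0] == "yes"

    def test_double_negative(self):
        assert merge_multisource(pd.Series(["no"]), pd.Series(["no"]))[0] == "no"

    def test_all_27_three_column_combinations_match_truth_table_oracle(self):
        cases = list(itertools.product(["yes", "no", np.nan], repeat=3))
        cols = [pd.Series([c[i] for c in cases]) for i in range(3)]
        merged = merge_multisource(*cols)
        for row, case in enumerate(cases):
            expected = self._oracle([v for v in case if isinstance(v, str)])
            if isinstance(expected, str):
                assert merged[row] == expected, case
            else:
                assert pd.isna(merged[row]), case

    def test_needs_at_least_two_columns(self):
        with pytest.raises(ConfigurationError):
            merge_multisource(pd.Series(["yes"]))


class TestDictionaryValidation:
    def _doc(self, name="mat_h_modebirth", recode_target="caesarean"):
        return {
            name: {
                "source": "mat",
                "stage": "h",
                "dtype": "categorical",
                "categories": ["unassisted_vaginal", "assisted_vaginal", "caesarean"],
                "sites": {
                    "S01": {"raw_name": "DeliveryMethod", "recode_map": {"LSCS": recode_target}}
                },
            }
        }

    def test_conforming_entry_accepted(self, tmp_path):
        import yaml

        path = tmp_path / "dict.yaml"
        path.write_text(yaml.safe_dump(self._doc()))
        d = load_dictionary(path, known_sites=["S01"])
        assert "mat_h_modebirth" in d.entries

    def test_name_without_source_stage_tags_rejected(self):
        with pytest.raises(DictionaryError, match="birthmode"):
            DataDictionary.from_dict(
                {"birthmode": {"source": "mat", "stage": "h", "dtype": "categorical"}}
            ).validate()

    def test_recode_target_outside_categories_names_the_entry(self):
        with pytest.raises(DictionaryError, match="mat_h_modebirth"):
            DataDictionary.from_dict(self._doc(recode_target="water birth")).validate()

    def test_unknown_site_rejected(self):
        with pytest.raises(DictionaryError, match="S01"):
            DataDictionary.from_dict(self._doc()).validate(known_sites=["S99"])

    def test_round_trip_through_yaml(self, dictionary, tmp_path):
        path = tmp_path / "full.yaml"
        dictionary.to_yaml(path)
        loaded = load_dictionary(path)
        assert set(loaded.entries) == set(dictionary.entries)


class TestEngine:
    def test_no_defect_site_reproduces_truth_exactly(self, clean_harmonised, clean_site):
        harmonised, _ = clean_harmonised
        _, truth = clean_site
        mat = harmonised.maternity.set_index("row_id")
        tb = truth.babies.set_index("row_id").loc[mat.index]
        assert np.allclose(mat["mat_h_ga"], tb["ga_days"])
        assert np.allclose(mat["mat_h_bw"], tb["birthweight_g"])
        assert np.allclose(mat["mat_h_height"], tb["height_m"])
        assert np.allclose(mat["mat_h_weight"], tb["weight_kg"])
        assert (mat["mat_h_sex"] == tb["sex"]).all()
        assert (mat["mat_h_modebirth"] == tb["mode_of_birth"]).all()
        assert (mat["mat_h_ethnicity"] == tb["ethnicity"]).all()
        assert (pd.to_datetime(mat["mat_h_dod"]).dt.date == tb["dod"]).all()

    def test_idempotent_on_its_own_output(self, clean_harmonised, dictionary):
        harmonised, _ = clean_harmonised
        again, _ = harmonise_bundle(harmonised, dictionary)
        for name, df in harmonised.tables().items():
            pd.testing.assert_frame_equal(df, getattr(again, name))

    def test_raw_columns_retained_untouched(self, clean_pseudonymised, clean_harmonised):
        harmonised, _ = clean_harmonised
        raw = clean_pseudonymised.maternity
        out = harmonised.maternity
        # the raw delivery-method column survives, renamed, byte-identical
        assert out["mat_r_modebirth"].equals(raw["DeliveryMethod"])
        assert out["mat_r_height"].equals(raw["HeightCm"])

    def test_audit_replay_is_bit_identical(self, clean_pseudonymised, clean_harmonised):
        harmonised, trail = clean_harmonised
        replayed = replay_trail(clean_pseudonymised, trail)
        for name, df in harmonised.tables().items():
            pd.testing.assert_frame_equal(df, getattr(replayed, name))

    def test_missing_source_column_emits_fully_missing_variable(
        self, clean_pseudonymised, dictionary
    ):
        bundle = clean_pseudonymised.copy()
        bundle.maternity = bundle.maternity.drop(columns=["HeightCm"])
        harmonised, trail = harmonise_bundle(bundle, dictionary)
        assert harmonised.maternity["mat_h_height"].isna().all()
        notes = [r for r in trail.notes("missing_source") if r.column == "mat_h_height"]
        assert len(notes) == 1

    def test_affirmative_only_site_fills_negatives(self, defect_harmonised, defect_site):
        harmonised, _ = defect_harmonised
        _, truth = defect_site
        assert "chronic_htn" in truth.affirmative_only
        assert harmonised.maternity["mat_h_htn"].notna().all()

    def test_unmapped_audit_records_on_binary_parity_site(self, all_dialect_configs, dictionary):
        from eprlink.synthetic import generate_bundle
        from tests.conftest import pseudonymise

        config = all_dialect_configs[1]  # euroking site reporting parity as binary
        bundle, truth = generate_bundle(config, 99)
        pseud = pseudonymise(bundle, truth, config)
        harmonised, trail = harmonise_bundle(pseud, dictionary)
        parity = harmonised.maternity["mat_h_parity"]
        multip = harmonised.maternity["mat_h_multip"]
        # nulliparous converts to 0; multiparous cannot convert and is missing
        assert (parity.dropna() == 0).all()
        assert parity.isna().equals(multip == "yes")
        # the unconvertible multiparous token is audited, distinct from true missing
        notes = [r for r in trail.notes() if r.column == "mat_h_parity"]
        assert len(notes) == 1 and notes[0].detail == "Multiparous"
        assert notes[0].rows_affected == int((multip == "yes").sum())
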
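"""Checklists, duplicate classification, distribution summaries and the
outlier policy."""

import numpy as np
import pandas as pd
import pytest

from eprlink.bundle import ConfigurationError, RecordBundle
from eprlink.quality import (
    OutlierLimit,
    OutlierPolicy,
    apply_outlier_policy,
    classify_duplicates,
    distribution_summary,
    drop_true_duplicates,
    first_download_checks,
    flag_outlier_candidates,
    second_download_checks,
)


class TestDistributionSummary:
    def test_1_to_100_under_linear_interpolation(self):
        s = distribution_summary(range(1, 101))
        assert s["median"] == 50.5
        assert s["p5"] == pytest.approx(5.95)
        assert s["p95"] == pytest.approx(95.05)
        assert s["min"] == 1 and s["max"] == 100

    def test_constant_column(self):
        s = distribution_summary([7.0] * 20)
        assert s["min"] == s["max"] == s["median"] == 7.0

    def test_all_missing_flagged_empty(self):
        assert distribution_summary([np.nan, np.nan]) == {"n": 0, "empty": True}

    def test_matches_sortbased_oracle_on_random_columns(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x = rng.normal(size=rng.integers(10, 80))
            s = distribution_summary(x)
            xs = np.sort(x)

            def oracle(p):
                # linear interpolation between order statistics
                h = (len(xs) - 1) * p / 100
                lo = int(np.floor(h))
                hi = min(lo + 1, len(xs) - 1)
                return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

            for key, p in (("p5", 5), ("p25", 25), ("median", 50), ("p75", 75), ("p95", 95)):
                assert s[key] == pytest.approx(oracle(p), rel=1e-12)


class TestOutlierScreening:
    def test_normal_tail_mass_beyond_3sd(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10_000)
        flags = flag_outlier_candidates(x)
        frac = len(flags["beyond_3sd"]) / len(x)
        assert 0.0005 < frac < 0.007  # ~0.27% expected, generous Monte-Carlo band

    def test_constant_column_has_no_candidates(self):
        flags = flag_outlier_candidates([5.0] * 50)
        assert all(len(v) == 0 for k, v in flags.items() if k.startswith("beyond"))

    def test_centile_lists_are_about_one_percent(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=5_000)
        flags = flag_outlier_candidates(x)
        assert 0.005 < len(flags["below_p1"]) / len(x) <= 0.011
        assert 0.005 < len(flags["above_p99"]) / len(x) <= 0.011

    def test_small_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            flag_outlier_candidates([1.0] * 5)


class TestClassifyDuplicates:
    def _mat(self, rows):
        return pd.DataFrame(rows)

    def test_identical_rows_are_true_duplicates(self):
        mat = self._mat(
            [
                {"study_id": "W1", "dod": "2017-01-01", "sex": "male", "birthweight": 3400},
                {"study_id": "W1", "dod": "2017-01-01", "sex": "male", "birthweight": 3400},
            ]
        )
        assert list(classify_duplicates(mat)) == ["true_duplicate", "true_duplicate"]

    def test_differing_baby_fields_look_like_multiple_birth(self):
        mat = self._mat(
            [
                {"study_id": "W1", "dod": "2017-01-01", "sex": "male", "birthweight": 3400},
                {"study_id": "W1", "dod": "2017-01-01", "sex": "female", "birthweight": 2900},
            ]
        )
        assert list(classify_duplicates(mat)) == ["multiple_birth", "multiple_birth"]

    def test_singleton_scan_overrides_to_true_duplicate(self):
        mat = self._mat(
            [
                {"study_id": "W1", "dod": "2017-06-01", "sex": "male", "birthweight": 3400},
                {"study_id": "W1", "dod": "2017-06-01", "sex": "male", "birthweight": 3300},
            ]
        )
        uss = pd.DataFrame(
            {"study_id": ["W1"], "scan_date": ["2017-03-01"], "fetal_count": [1]}
        )
        assert list(classify_duplicates(mat, uss)) == ["true_duplicate", "true_duplicate"]

    def test_twin_scan_keeps_multiple_birth(self):
        mat = self._mat(
            [
                {"study_id": "W1", "dod": "2017-06-01", "sex": "male", "birthweight": 3400},
                {"study_id": "W1", "dod": "2017-06-01", "sex": "male", "birthweight": 3300},
            ]
        )
        uss = pd.DataFrame(
            {"study_id": ["W1"], "scan_date": ["2017-03-01"], "fetal_count": [2]}
        )
        assert list(classify_duplicates(mat, uss)) == ["multiple_birth", "multiple_birth"]

    def test_injected_duplicates_recovered_on_synthetic_site(self, defect_site, defect_config):
        bundle, truth = defect_site
        # canonical view straight from the emitted raw bundle via truth row ids
        from eprlink.synthetic import DIALECTS

        cols = DIALECTS[defect_config.dialect].maternity_columns
        mat = pd.DataFrame(
            {
                "study_id": bundle.maternity["nhs_number"],
                "dod": bundle.maternity[cols["dod"]].map(
                    lambda v: pd.to_datetime(v, dayfirst=True)
                ),
                "sex": bundle.maternity[cols["sex"]],
                "birthweight": bundle.maternity[cols["bw"]],
                "birth_order": bundle.maternity[cols["birthorder"]],
            }
        )
        classes = classify_duplicates(mat)
        n_true_dup_pairs = int((classes == "true_duplicate").sum())
        # every injected duplicate makes (at least) one identical pair
        assert n_true_dup_pairs >= 2 * len(truth.duplicated_rows) > 0
        deduped, n_removed = drop_true_duplicates(mat, classes)
        assert n_removed >= len(truth.duplicated_rows)


class TestOutlierPolicy:
    def _bundle(self, mat):
        return RecordBundle(
            site_code="S", stage="linked", maternity=mat,
            neonatal=pd.DataFrame(), ultrasound=pd.DataFrame(), activity=pd.DataFrame(),
        )

    def test_boundary_values_retained_strict_outside_removed(self):
        mat = pd.DataFrame(
            {
                "mat_c_agedel": [13, 12, 60, 61],
                "mat_h_height": [1.20, 1.19, 2.00, 2.01],
                "mat_h_weight": [30, 29.9, 200, 200.1],
                "mat_c_bmi": [13, 12.9, 70, 70.1],
                "mat_h_ebl": [1, 0, 15000, 15001],
                "mat_h_bw": [100, 99, 6000, 6001],
            }
        )
        cleaned, counts = apply_outlier_policy(self._bundle(mat), OutlierPolicy.consensus_defaults())
        out = cleaned.maternity
        for col in mat.columns:
            assert out[col].notna().iloc[0] and out[col].notna().iloc[2], col  # limits kept
            assert out[col].isna().iloc[1] and out[col].isna().iloc[3], col    # outside removed
        assert (counts["removed"] == 2).all()

    def test_idempotent_and_only_converts_to_missing(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            {
                "mat_c_agedel": rng.integers(14, 45, 200).astype(float),
                "mat_h_height": rng.normal(1.64, 0.07, 200),
                "mat_h_weight": rng.normal(68, 12, 200),
                "mat_c_bmi": rng.normal(25, 4, 200),
                "mat_h_ebl": rng.integers(50, 900, 200).astype(float),
                "mat_h_bw": rng.normal(3400, 400, 200),
            }
        )
        mat.loc[0, "mat_h_height"] = 2.5
        policy = OutlierPolicy.consensus_defaults()
        once, counts1 = apply_outlier_policy(self._bundle(mat), policy)
        twice, counts2 = apply_outlier_policy(once, policy)
        pd.testing.assert_frame_equal(once.maternity, twice.maternity)
        assert counts2["removed"].sum() == 0
        retained = once.maternity["mat_h_weight"]
        assert retained.equals(mat["mat_h_weight"])  # untouched variable identical

    def test_injected_implausible_counts_match_removals_exactly(self):
        from eprlink.harmonise import harmonise_bundle
        from eprlink.synthetic import SiteConfig, build_dictionary, generate_bundle
        from tests.conftest import pseudonymise

        config = SiteConfig(
            site_code="S09", n_women=600, dialect="medway", missing_id_rate=0.0,
            defect_rates={"implausible_value": 0.01},
        )
        bundle, truth = generate_bundle(config, 17)
        pseud = pseudonymise(bundle, truth, config)
        harmonised, _ = harmonise_bundle(pseud, build_dictionary([config]))
        cleaned, counts = apply_outlier_policy(harmonised, OutlierPolicy.consensus_defaults())
        injected = truth.implausible.groupby("column").size()
        col_map = {"height_m": "height", "weight_kg": "weight",
                   "ebl_ml": "ebl", "birthweight_g": "birthweight"}
        by_var = counts.set_index("variable")["removed"]
        assert len(truth.implausible) > 0
        for truth_col, var in col_map.items():
            assert by_var[var] == injected.get(truth_col, 0), var
        assert by_var["maternal_age"] == 0

    def test_missing_policy_column_is_configuration_error(self):
        policy = OutlierPolicy({"x": OutlierLimit("nope", 0, 1)})
        with pytest.raises(ConfigurationError):
            apply_outlier_policy(self._bundle(pd.DataFrame({"a": [1]})), policy)

    def test_invalid_limits_rejected(self):
        with pytest.raises(ConfigurationError):
            OutlierLimit("x", 10, 10)


class TestFirstDownloadChecklist:
    def test_clean_bundle_passes_all_seven(self, clean_pseudonymised, dictionary, clean_config):
        report = first_download_checks(
            clean_pseudonymised, dictionary, clean_config.date_window
        )
        assert len(report.checks) == 7
        assert all(c.status == "pass" for c in report.checks), report.statuses()

    def test_missing_activity_dataset_fails_check_one(
        self, clean_pseudonymised, dictionary, clean_config
    ):
        bundle = clean_pseudonymised.copy()
        bundle.activity = pd.DataFrame()
        report = first_download_checks(bundle, dictionary, clean_config.date_window)
        check = report.check("datasets_present")
        assert check.status == "fail"
        assert "activity" in check.evidence["missing_datasets"]

    def test_injected_mcar_shows_in_completeness(
        self, defect_pseudonymised, dictionary, defect_config, defect_site
    ):
        from scipy.stats import binom

        report = first_download_checks(
            defect_pseudonymised, dictionary, defect_config.date_window
        )
        pct = report.check("completeness").evidence["percent_complete"][
            "maternity.Maternal_Height"
        ]
        _, truth = defect_site
        n = len(defect_pseudonymised.maternity)
        lo = 100 * binom.ppf(0.005, n, 0.78) / n  # 20% MCAR, duplicates shift slightly
        hi = 100 * binom.ppf(0.995, n, 0.82) / n
        assert lo <= pct <= hi

    def test_out_of_window_defects_flagged_in_date_range(
        self, defect_pseudonymised, dictionary, defect_config
    ):
        report = first_download_checks(
            defect_pseudonymised, dictionary, defect_config.date_window
        )
        assert report.check("duplicate_ids").evidence["true_duplicate_rows"] > 0

    def test_report_serialises_to_json(self, clean_pseudonymised, dictionary, clean_config, tmp_path):
        report = first_download_checks(clean_pseudonymised, dictionary, clean_config.date_window)
        path = tmp_path / "qc.json"
        report.to_json(path)
        import json

        doc = json.loads(path.read_text())
        assert len(doc["checks"]) == 7


class TestSecondDownloadChecklist:
    KEY_VARS = ["mat_h_weight", "mat_h_height", "mat_h_ethnicity", "mat_h_parity",
                "mat_h_sex", "mat_h_ga", "mat_h_bw"]

    def test_no_prior_issues_gives_five_checks(
        self, clean_pseudonymised, dictionary, clean_config
    ):
        prior = first_download_checks(clean_pseudonymised, dictionary, clean_config.date_window)
        report = second_download_checks(
            clean_pseudonymised, prior, self.KEY_VARS, dictionary, clean_config.date_window
        )
        assert len(report.checks) == 5
        assert all(c.status == "pass" for c in report.checks)

    def test_prior_failure_resolved_in_better_extract(
        self, clean_pseudonymised, dictionary, clean_config
    ):
        broken = clean_pseudonymised.copy()
        broken.activity = pd.DataFrame()
        prior = first_download_checks(broken, dictionary, clean_config.date_window)
        report = second_download_checks(
            clean_pseudonymised, prior, self.KEY_VARS, dictionary, clean_config.date_window
        )
        assert report.check("prior_issues").evidence["resolution"]["datasets_present"] == "resolved"

    def test_key_variable_completely_missing_is_flagged(
        self, clean_pseudonymised, dictionary, clean_config
    ):
        bundle = clean_pseudonymised.copy()
        bundle.maternity = bundle.maternity.drop(columns=["BookingWeightKg"])
        prior = first_download_checks(bundle, dictionary, clean_config.date_window)
        report = second_download_checks(
            bundle, prior, self.KEY_VARS, dictionary, clean_config.date_window
        )
        check = report.check("key_completeness")
        assert check.status == "fail"
        assert "mat_h_weight" in check.evidence["completely_missing"]
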
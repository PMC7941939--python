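"""Shared fixtures: generated site bundles at several defect settings.

Session-scoped because generation is the expensive step and every module
exercises the same bundles read-only (tests copy before mutating).
"""

from __future__ import annotations

import numpy as np
import pytest

from eprlink.harmonise import harmonise_bundle
from eprlink.pseudonym import derive_and_strip, drop_off_spine
from eprlink.synthetic import (
    MissingnessSpec,
    SiteConfig,
    build_dictionary,
    generate_bundle,
    make_postcode_lookup,
)

SEED = 20170101


def canonical_from_truth(truth, site="S01"):
    """Analysis-ready maternity table built from ground truth with the
    logged missing cells blanked — bypasses rendering for imputation tests."""
    tab = truth.babies.copy()
    for r in truth.missing_cells.itertuples():
        tab.loc[tab.row_id == r.row_id, r.column] = np.nan
    tab = tab.rename(
        columns={
            "height_m": "mat_h_height",
            "weight_kg": "mat_h_weight",
            "parity": "mat_h_parity",
            "ethnicity": "mat_h_ethnicity",
            "ga_days": "mat_h_ga",
            "sex": "mat_h_sex",
            "birthweight_g": "mat_h_bw",
        }
    )
    tab["site"] = site
    tab["phase"] = "pre_randomisation"
    tab["mat_c_agedel"] = [
        d.year - b.year - ((d.month, d.day) < (b.month, b.day))
        for b, d in zip(tab["dob"], tab["dod"])
    ]
    return tab


@pytest.fixture(scope="session")
def clean_config():
    return SiteConfig(
        site_code="S01",
        n_women=400,
        dialect="medway",
        twin_rate=0.03,
        neonatal_admission_rate=0.12,
        missing_id_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_site(clean_config):
    """Defect-free, missingness-free bundle plus truth."""
    return generate_bundle(clean_config, SEED)


@pytest.fixture(scope="session")
def defect_config():
    return SiteConfig(
        site_code="S02",
        n_women=500,
        dialect="euroking",
        twin_rate=0.04,
        missing_id_rate=0.01,
        defect_rates={
            "duplicate_row": 0.02,
            "per_pregnancy_multiple": 0.3,
            "out_of_window_date": 0.03,
            "implausible_value": 0.01,
            "affirmative_only_binary": 1.0,
        },
        missingness={
            "height_m": MissingnessSpec("MCAR", 0.2),
            "weight_kg": MissingnessSpec("MAR", 0.15, driver="height_m"),
        },
    )


@pytest.fixture(scope="session")
def defect_site(defect_config):
    return generate_bundle(defect_config, SEED + 1)


@pytest.fixture(scope="session")
def all_dialect_configs():
    return [
        SiteConfig(site_code="D01", n_women=150, dialect="medway"),
        SiteConfig(site_code="D02", n_women=150, dialect="euroking", parity_binary=True),
        SiteConfig(site_code="D03", n_women=150, dialect="badgernet"),
    ]


@pytest.fixture(scope="session")
def dictionary(clean_config, defect_config, all_dialect_configs):
    return build_dictionary([clean_config, defect_config] + list(all_dialect_configs))


def pseudonymise(bundle, truth, config):
    lookup = make_postcode_lookup([truth], 99, coverage=1.0).set_index("postcode")
    from eprlink.synthetic import DIALECTS

    dod_col = DIALECTS[config.dialect].maternity_columns["dod"]
    result = derive_and_strip(bundle, "fixture-salt", lookup, dod_column=dod_col)
    pseud, _ = drop_off_spine(result.bundle)
    return pseud


@pytest.fixture(scope="session")
def clean_pseudonymised(clean_site, clean_config):
    bundle, truth = clean_site
    return pseudonymise(bundle, truth, clean_config)


@pytest.fixture(scope="session")
def clean_harmonised(clean_pseudonymised, dictionary):
    harmonised, trail = harmonise_bundle(clean_pseudonymised, dictionary)
    return harmonised, trail


@pytest.fixture(scope="session")
def defect_pseudonymised(defect_site, defect_config):
    bundle, truth = defect_site
    return pseudonymise(bundle, truth, defect_config)


@pytest.fixture(scope="session")
def defect_harmonised(defect_pseudonymised, dictionary):
    harmonised, trail = harmonise_bundle(defect_pseudonymised, dictionary)
    return harmonised, trail
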
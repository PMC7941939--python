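"""Data-dictionary construction for the bundled synthetic dialects.

A real study writes its dictionary by hand after inspecting each site's
extract; here the dictionary is derived from the same dialect profiles the
generator renders with, which is exactly the knowledge a data-management
team would have assembled. The harmonisation engine itself never sees the
dialect objects — only this dictionary.
"""

from __future__ import annotations

from ..harmonise import DataDictionary, DictEntry, SiteRule
from .dialects import (
    ACTIVITY_COLUMNS,
    DIALECTS,
    ETHNICITY_CATEGORIES,
    MODE_BIRTH_CATEGORIES,
    NEONATAL_COLUMNS,
    NEONATAL_SEX_MAP,
    SEX_CATEGORIES,
    ULTRASOUND_COLUMNS,
)
from .generator import SiteConfig

BINARY = ("yes", "no")


def _invert(synonyms: dict[str, tuple[str, ...]]) -> dict[str, str]:
    return {raw: canonical for canonical, raws in synonyms.items() for raw in raws}


def build_dictionary(configs: list[SiteConfig]) -> DataDictionary:
    """Dictionary covering every site in ``configs``, one rule set per site."""
    entries: dict[str, DictEntry] = {}

    def entry(name, dtype, description, unit="", categories=(), calc=None, inputs=()):
        source, stage, _ = name.split("_", 2)
        e = DictEntry(
            name=name,
            source=source,
            stage=stage,
            dtype=dtype,
            description=description,
            unit=unit,
            categories=tuple(categories),
            calc=calc,
            inputs=tuple(inputs),
        )
        entries[name] = e
        return e

    mat = {
        "mat_h_dod": entry("mat_h_dod", "date", "date of delivery"),
        "mat_h_ga": entry(
            "mat_h_ga", "continuous", "gestational age at birth", unit="completed days"
        ),
        "mat_h_sex": entry("mat_h_sex", "categorical", "infant sex", categories=SEX_CATEGORIES),
        "mat_h_bw": entry("mat_h_bw", "continuous", "birthweight", unit="g"),
        "mat_h_modebirth": entry(
            "mat_h_modebirth", "categorical", "mode of birth", categories=MODE_BIRTH_CATEGORIES
        ),
        "mat_h_height": entry("mat_h_height", "continuous", "maternal height", unit="m"),
        "mat_h_weight": entry("mat_h_weight", "continuous", "maternal booking weight", unit="kg"),
        "mat_h_parity": entry("mat_h_parity", "continuous", "parity (previous births)", unit="count"),
        "mat_h_multip": entry("mat_h_multip", "binary", "multiparous", categories=BINARY),
        "mat_h_ethnicity": entry(
            "mat_h_ethnicity", "categorical", "maternal ethnicity", categories=ETHNICITY_CATEGORIES
        ),
        "mat_h_htn": entry("mat_h_htn", "binary", "chronic hypertension", categories=BINARY),
        "mat_h_epidurallab": entry(
            "mat_h_epidurallab", "binary", "epidural recorded in labour analgesia",
            categories=BINARY,
        ),
        "mat_h_epiduralbirth": entry(
            "mat_h_epiduralbirth", "binary", "epidural recorded in birth analgesia",
            categories=BINARY,
        ),
        "mat_h_trauma3": entry(
            "mat_h_trauma3", "binary", "severe (3rd/4th degree) perineal trauma",
            categories=BINARY,
        ),
        "mat_h_ebl": entry("mat_h_ebl", "continuous", "estimated blood loss", unit="mL"),
        "mat_h_birthorder": entry("mat_h_birthorder", "continuous", "birth order within pregnancy"),
        "mat_c_agedel": entry(
            "mat_c_agedel", "continuous", "maternal age at delivery", unit="completed years"
        ),
    }
    entry(
        "mat_c_bmi", "continuous", "body mass index", unit="kg/m2",
        calc="bmi", inputs=("mat_h_weight", "mat_h_height"),
    )
    entry(
        "mat_c_epidural", "binary", "epidural from any anaesthesia source",
        categories=BINARY, calc="multisource",
        inputs=("mat_h_epidurallab", "mat_h_epiduralbirth"),
    )

    neo = {
        "neo_h_dob": entry("neo_h_dob", "date", "neonatal date of birth"),
        "neo_h_sex": entry("neo_h_sex", "categorical", "infant sex", categories=SEX_CATEGORIES),
        "neo_h_bw": entry("neo_h_bw", "continuous", "birthweight", unit="g"),
        "neo_h_admreason": entry("neo_h_admreason", "text", "neonatal admission reason"),
    }
    uss = {
        "uss_h_scandate": entry("uss_h_scandate", "date", "ultrasound scan date"),
        "uss_h_fetalcount": entry("uss_h_fetalcount", "continuous", "fetal count at scan"),
        "uss_h_efw": entry("uss_h_efw", "continuous", "estimated fetal weight", unit="g"),
        "uss_h_sgaflag": entry(
            "uss_h_sgaflag", "binary", "small-for-dates suspected at scan", categories=BINARY
        ),
    }
    act = {
        "act_h_eventdate": entry("act_h_eventdate", "date", "appointment/admission date"),
        "act_h_eventtype": entry("act_h_eventtype", "text", "activity type"),
    }

    for config in configs:
        site = config.site_code
        d = DIALECTS[config.dialect]
        cols = d.maternity_columns
        date_fmt = d.date_format
        yes, no = d.binary_map["yes"], d.binary_map["no"]
        binary_recode = {yes: "yes", no: "no"}
        gated = config.defect_rates.get("affirmative_only_binary", 0.0) > 0
        gate_mode = "affirmative_only" if gated else "full"

        mat["mat_h_dod"].sites[site] = SiteRule(raw_name=cols["dod"], date_format=date_fmt)
        mat["mat_h_ga"].sites[site] = SiteRule(raw_name=cols["ga"], unit_rule="ga_string->days")
        mat["mat_h_sex"].sites[site] = SiteRule(
            raw_name=cols["sex"], recode_map={v: k for k, v in d.sex_map.items()}
        )
        mat["mat_h_bw"].sites[site] = SiteRule(raw_name=cols["bw"], unit_rule="g->g")
        mat["mat_h_modebirth"].sites[site] = SiteRule(
            raw_name=cols["modebirth"], recode_map=_invert(d.mode_birth_synonyms)
        )
        height_rule = {"cm": "cm->m", "ft_in": "ft_in->m", "m": "identity"}[d.height_unit]
        mat["mat_h_height"].sites[site] = SiteRule(raw_name=cols["height"], unit_rule=height_rule)
        weight_rule = {"kg": "identity", "lb": "lb->kg", "st_lb": "st_lb->kg"}[d.weight_unit]
        mat["mat_h_weight"].sites[site] = SiteRule(raw_name=cols["weight"], unit_rule=weight_rule)
        if config.parity_binary:
            # Site supplies parity only as nulliparous/multiparous; nulliparity
            # converts to 0, multiparity cannot be converted and stays missing.
            mat["mat_h_parity"].sites[site] = SiteRule(
                raw_name=cols["parity"],
                recode_map={d.parity_binary_map["nulliparous"]: "0"},
            )
            mat["mat_h_multip"].sites[site] = SiteRule(
                raw_name=cols["multip"],
                recode_map=binary_recode,
            )
        else:
            mat["mat_h_parity"].sites[site] = SiteRule(raw_name=cols["parity"])
            mat["mat_h_multip"].sites[site] = SiteRule(
                raw_name=cols["multip"], recode_map=binary_recode
            )
        mat["mat_h_ethnicity"].sites[site] = SiteRule(
            raw_name=cols["ethnicity"], recode_map=_invert(d.ethnicity_synonyms)
        )
        mat["mat_h_htn"].sites[site] = SiteRule(
            raw_name=cols["htn"], recode_map=binary_recode, binary_mode=gate_mode
        )
        mat["mat_h_epidurallab"].sites[site] = SiteRule(
            raw_name=cols["epidurallab"], recode_map=binary_recode
        )
        mat["mat_h_epiduralbirth"].sites[site] = SiteRule(
            raw_name=cols["epiduralbirth"], recode_map=binary_recode
        )
        mat["mat_h_trauma3"].sites[site] = SiteRule(
            raw_name=cols["trauma3"], recode_map=binary_recode, binary_mode=gate_mode
        )
        mat["mat_h_ebl"].sites[site] = SiteRule(raw_name=cols["ebl"])
        mat["mat_h_birthorder"].sites[site] = SiteRule(raw_name=cols["birthorder"])
        mat["mat_c_agedel"].sites[site] = SiteRule(raw_name="age_at_delivery")

        neo["neo_h_dob"].sites[site] = SiteRule(raw_name=NEONATAL_COLUMNS["dob"])
        neo["neo_h_sex"].sites[site] = SiteRule(
            raw_name=NEONATAL_COLUMNS["sex"],
            recode_map={v: k for k, v in NEONATAL_SEX_MAP.items()},
        )
        neo["neo_h_bw"].sites[site] = SiteRule(raw_name=NEONATAL_COLUMNS["bw"], unit_rule="g->g")
        neo["neo_h_admreason"].sites[site] = SiteRule(raw_name=NEONATAL_COLUMNS["admreason"])

        uss["uss_h_scandate"].sites[site] = SiteRule(
            raw_name=ULTRASOUND_COLUMNS["scandate"], date_format=date_fmt
        )
        uss["uss_h_fetalcount"].sites[site] = SiteRule(raw_name=ULTRASOUND_COLUMNS["fetalcount"])
        uss["uss_h_efw"].sites[site] = SiteRule(
            raw_name=ULTRASOUND_COLUMNS["efw"], unit_rule="g->g"
        )
        uss["uss_h_sgaflag"].sites[site] = SiteRule(
            raw_name=ULTRASOUND_COLUMNS["sgaflag"], recode_map={"Y": "yes", "N": "no"}
        )
        act["act_h_eventdate"].sites[site] = SiteRule(
            raw_name=ACTIVITY_COLUMNS["eventdate"], date_format=date_fmt
        )
        act["act_h_eventtype"].sites[site] = SiteRule(raw_name=ACTIVITY_COLUMNS["eventtype"])

    dictionary = DataDictionary(entries)
    dictionary.validate([c.site_code for c in configs])
    return dictionary
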
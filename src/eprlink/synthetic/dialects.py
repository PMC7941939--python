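"""Source-system dialect profiles for the synthetic EPR generator.

Real multi-site maternity extracts arrive in the vocabulary of whichever
record system each hospital runs: different column names, category
wordings, date renderings and measurement units. Three maternity dialects
are defined here, loosely styled on common UK systems, purely as invented
vocabularies that exercise harmonisation:

* ``medway``  — ISO dates, height in cm, weight in kg, gestation as "40+2".
* ``euroking`` — DD/MM/YYYY dates, height in feet+inches, weight in pounds,
  gestation as decimal weeks.
* ``badgernet`` — spreadsheet serial dates, height in metres, weight in
  stones+pounds, gestation in completed days, numeric-coded categories.

Neonatal extracts come from a single national system, so their layout is
identical at every site; ultrasound and activity extracts share the site's
date rendering but keep fixed column names.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from ..bundle import to_excel_serial

MODE_BIRTH_CATEGORIES = ("unassisted_vaginal", "assisted_vaginal", "caesarean")
ETHNICITY_CATEGORIES = ("white", "black", "asian", "mixed", "other")
SEX_CATEGORIES = ("male", "female")
BINARY_CATEGORIES = ("yes", "no")


@dataclass(frozen=True)
class Dialect:
    name: str
    date_format: str  # iso | dmy | serial
    height_unit: str  # cm | ft_in | m
    weight_unit: str  # kg | lb | st_lb
    ga_format: str    # wd | weeks | days
    binary_map: dict[str, str]            # canonical yes/no -> raw token
    sex_map: dict[str, str]
    mode_birth_synonyms: dict[str, tuple[str, ...]]
    ethnicity_synonyms: dict[str, tuple[str, ...]]
    parity_binary_map: dict[str, str] = field(
        default_factory=lambda: {"nulliparous": "Nulliparous", "multiparous": "Multiparous"}
    )
    maternity_columns: dict[str, str] = field(default_factory=dict)

    # ---- value rendering -------------------------------------------------
    def render_date(self, date: dt.date):
        if self.date_format == "iso":
            return date.isoformat()
        if self.date_format == "dmy":
            return date.strftime("%d/%m/%Y")
        return to_excel_serial(date)

    def quantise_height(self, metres: float) -> float:
        """Snap a true height to the precision this system records at,
        returning the canonical-metre value that rendering will preserve."""
        if self.height_unit == "cm":
            return round(metres * 100, 1) / 100
        if self.height_unit == "ft_in":
            return round(metres / 0.0254) * 0.0254
        return round(metres, 2)

    def render_height(self, metres: float):
        if self.height_unit == "cm":
            return round(metres * 100, 1)
        if self.height_unit == "ft_in":
            inches = round(metres / 0.0254)
            return f"{inches // 12}ft {inches % 12}in"
        return round(metres, 2)

    def quantise_weight(self, kg: float) -> float:
        if self.weight_unit == "kg":
            return round(kg, 1)
        return round(kg / 0.45359237) * 0.45359237

    def render_weight(self, kg: float):
        if self.weight_unit == "kg":
            return round(kg, 1)
        pounds = round(kg / 0.45359237)
        if self.weight_unit == "lb":
            return float(pounds)
        return f"{pounds // 14}st {pounds % 14}lb"

    def render_ga(self, ga_days: int):
        if self.ga_format == "wd":
            return f"{ga_days // 7}+{ga_days % 7}"
        if self.ga_format == "weeks":
            return round(ga_days / 7, 2)
        return int(ga_days)

    def render_binary(self, value: bool | None, affirmative_only: bool = False):
        if value is None:
            return None
        if value:
            return self.binary_map["yes"]
        return None if affirmative_only else self.binary_map["no"]


MEDWAY = Dialect(
    name="medway",
    date_format="iso",
    height_unit="cm",
    weight_unit="kg",
    ga_format="wd",
    binary_map={"yes": "Y", "no": "N"},
    sex_map={"male": "M", "female": "F"},
    mode_birth_synonyms={
        "unassisted_vaginal": ("SVD", "NVD"),
        "assisted_vaginal": ("Forceps", "Ventouse"),
        "caesarean": ("Em LSCS", "El LSCS"),
    },
    ethnicity_synonyms={
        "white": ("White British", "White Other"),
        "black": ("Black African", "Black Caribbean"),
        "asian": ("Asian Indian", "Asian Pakistani"),
        "mixed": ("Mixed",),
        "other": ("Any Other",),
    },
    maternity_columns={
        "dod": "DeliveryDate",
        "ga": "Gestation",
        "sex": "InfantSex",
        "bw": "BirthWeight",
        "modebirth": "DeliveryMethod",
        "height": "HeightCm",
        "weight": "BookingWeightKg",
        "parity": "Parity",
        "multip": "PreviousBirths",
        "ethnicity": "EthnicOrigin",
        "htn": "ChronicHypertension",
        "epidurallab": "LabourAnalgesia",
        "epiduralbirth": "BirthAnalgesia",
        "trauma3": "ThirdDegreeTear",
        "ebl": "EstBloodLossMl",
        "birthorder": "BirthOrder",
    },
)

EUROKING = Dialect(
    name="euroking",
    date_format="dmy",
    height_unit="ft_in",
    weight_unit="lb",
    ga_format="weeks",
    binary_map={"yes": "Yes", "no": "No"},
    sex_map={"male": "Male", "female": "Female"},
    mode_birth_synonyms={
        "unassisted_vaginal": ("Normal delivery", "Spontaneous vertex"),
        "assisted_vaginal": ("Assisted - forceps", "Assisted - ventouse"),
        "caesarean": ("Caesarean - emergency", "Caesarean - elective"),
    },
    ethnicity_synonyms={
        "white": ("British European", "Other European"),
        "black": ("Central African", "Afro-Caribbean"),
        "asian": ("Indian", "Chinese"),
        "mixed": ("Mixed Asian-European", "Mixed other"),
        "other": ("Other ethnic group",),
    },
    maternity_columns={
        "dod": "Date_of_Delivery",
        "ga": "Gest_Weeks",
        "sex": "Baby_Sex",
        "bw": "Weight_at_Birth_g",
        "modebirth": "Mode_of_Delivery",
        "height": "Maternal_Height",
        "weight": "Maternal_Weight",
        "parity": "Para",
        "multip": "Multiparous_Flag",
        "ethnicity": "Ethnicity",
        "htn": "Essential_HTN",
        "epidurallab": "Labour_Anaesthesia",
        "epiduralbirth": "Delivery_Anaesthesia",
        "trauma3": "OASI",
        "ebl": "EBL",
        "birthorder": "Birth_Order",
    },
)

BADGERNET_MAT = Dialect(
    name="badgernet",
    date_format="serial",
    height_unit="m",
    weight_unit="st_lb",
    ga_format="days",
    binary_map={"yes": "1", "no": "0"},
    sex_map={"male": "1", "female": "2"},
    mode_birth_synonyms={
        "unassisted_vaginal": ("svd",),
        "assisted_vaginal": ("instrumental",),
        "caesarean": ("cs",),
    },
    ethnicity_synonyms={
        "white": ("1",),
        "black": ("2",),
        "asian": ("3",),
        "mixed": ("4",),
        "other": ("5", "9"),
    },
    maternity_columns={
        "dod": "del_date",
        "ga": "ga_days",
        "sex": "baby_sex",
        "bw": "bw_grams",
        "modebirth": "del_mode",
        "height": "mat_height_m",
        "weight": "mat_weight",
        "parity": "parity_n",
        "multip": "multip",
        "ethnicity": "eth_code",
        "htn": "chr_htn",
        "epidurallab": "lab_anaes",
        "epiduralbirth": "del_anaes",
        "trauma3": "tear_34",
        "ebl": "ebl_ml",
        "birthorder": "birth_no",
    },
)

DIALECTS: dict[str, Dialect] = {d.name: d for d in (MEDWAY, EUROKING, BADGERNET_MAT)}

# Single national neonatal system: identical layout everywhere.
NEONATAL_COLUMNS = {
    "dob": "BabyDateOfBirth",
    "sex": "BabySex",
    "bw": "BirthWeightGrams",
    "admreason": "AdmissionReason",
}
NEONATAL_SEX_MAP = {"male": "Male", "female": "Female"}

ULTRASOUND_COLUMNS = {
    "scandate": "ScanDate",
    "fetalcount": "FetalCount",
    "efw": "EFW_g",
    "sgaflag": "SGA_Suspected",
}
ACTIVITY_COLUMNS = {"eventdate": "EventDate", "eventtype": "EventType"}
ACTIVITY_TYPES = ("antenatal_clinic", "triage", "day_assessment", "admission")
ADMISSION_REASONS = ("prematurity", "respiratory", "hypoglycaemia", "jaundice", "observation")
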
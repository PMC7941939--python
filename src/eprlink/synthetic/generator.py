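"""Multi-site synthetic maternity EPR generator with ground truth.

Every downstream stage of the pipeline (pseudonymisation, harmonisation,
linkage, quality checks, imputation) is tested against bundles produced
here, because real hospital extracts cannot be shared. The generator
produces the four per-site datasets — a wide maternity spine (one row per
baby born), a wide neonatal table (rows only for babies admitted to
neonatal care), and long ultrasound / hospital-activity tables (one row
per scan or appointment) — rendered in a per-site source-system dialect,
together with a :class:`TruthTable` recording every true value and every
injected defect.

Injectable defects mirror those seen in real extracts: duplicated rows,
per-pregnancy (rather than per-baby) reporting of multiple births,
event dates outside the pregnancy window, implausible measurement values,
and binary variables recorded affirmative-only. Missingness is injected
under MCAR or MAR (logistic in site and one continuous covariate, with
coefficients logged so tests can recompute expected blanking rates).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..bundle import ConfigurationError, RecordBundle
from ..centiles import BW_SIGMA, birthweight_mean, is_sga
from ..pseudonym import generate_identifiers
from .dialects import (
    ACTIVITY_COLUMNS,
    ACTIVITY_TYPES,
    ADMISSION_REASONS,
    DIALECTS,
    ETHNICITY_CATEGORIES,
    MODE_BIRTH_CATEGORIES,
    NEONATAL_COLUMNS,
    NEONATAL_SEX_MAP,
    ULTRASOUND_COLUMNS,
    Dialect,
)

DEFECT_KINDS = (
    "duplicate_row",
    "per_pregnancy_multiple",
    "out_of_window_date",
    "implausible_value",
    "affirmative_only_binary",
)

#: Canonical columns eligible for implausible-value injection, with values
#: strictly outside the clinical-consensus plausibility limits.
IMPLAUSIBLE_VALUES = {
    "height_m": (0.50, 2.50, 3.00),
    "weight_kg": (8.0, 260.0, 500.0),
    "ebl_ml": (0.0, 20000.0, 50000.0),
    "birthweight_g": (50.0, 6500.0, 9000.0),
}

#: Canonical columns a missingness spec may target.
MISSABLE_COLUMNS = (
    "height_m",
    "weight_kg",
    "parity",
    "ethnicity",
    "ga_days",
    "sex",
    "birthweight_g",
    "ebl_ml",
    "mode_of_birth",
)


@dataclass(frozen=True)
class MissingnessSpec:
    mechanism: str  # "MCAR" | "MAR"
    rate: float
    driver: str | None = None  # continuous covariate driving MAR blanking
    beta: float = 0.8          # logit-scale effect of one SD of the driver

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ConfigurationError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigurationError("missingness rate must be in [0, 1]")
        if self.mechanism == "MAR" and not self.driver:
            raise ConfigurationError("MAR missingness requires a driver covariate")


@dataclass
class SiteConfig:
    site_code: str
    n_women: int
    dialect: str = "medway"
    twin_rate: float = 0.015
    neonatal_admission_rate: float = 0.10
    repeat_pregnancy_rate: float = 0.06
    missing_id_rate: float = 0.004
    parity_binary: bool = False
    mar_site_effect: float = 0.0
    missingness: dict[str, MissingnessSpec] = field(default_factory=dict)
    defect_rates: dict[str, float] = field(default_factory=dict)
    date_window: tuple[dt.date, dt.date] = (dt.date(2017, 1, 1), dt.date(2018, 6, 30))
    maternal_dob_range: tuple[dt.date, dt.date] = (dt.date(1975, 1, 1), dt.date(2003, 6, 30))

    def __post_init__(self) -> None:
        if self.n_women < 0:
            raise ConfigurationError("n_women must be non-negative")
        if self.dialect not in DIALECTS:
            raise ConfigurationError(f"unknown dialect {self.dialect!r}")
        for name, value in (
            ("twin_rate", self.twin_rate),
            ("neonatal_admission_rate", self.neonatal_admission_rate),
            ("repeat_pregnancy_rate", self.repeat_pregnancy_rate),
            ("missing_id_rate", self.missing_id_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for kind, rate in self.defect_rates.items():
            if kind not in DEFECT_KINDS:
                raise ConfigurationError(f"unknown defect kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"defect rate for {kind} must be in [0, 1]")
        for var in self.missingness:
            if var not in MISSABLE_COLUMNS:
                raise ConfigurationError(f"missingness target {var!r} is not a known variable")
        if self.date_window[0] >= self.date_window[1]:
            raise ConfigurationError("date_window start must precede end")
        if self.maternal_dob_range[0] >= self.maternal_dob_range[1]:
            raise ConfigurationError("maternal DOB range start must precede end")

    @property
    def dialect_profile(self) -> Dialect:
        return DIALECTS[self.dialect]

    def rate(self, kind: str) -> float:
        return self.defect_rates.get(kind, 0.0)


@dataclass
class TruthTable:
    """Per-woman and per-baby ground truth plus a log of every injected defect."""

    site_code: str
    women: pd.DataFrame
    babies: pd.DataFrame
    neonatal: pd.DataFrame
    ultrasound: pd.DataFrame
    activity: pd.DataFrame
    missing_cells: pd.DataFrame
    duplicated_rows: pd.DataFrame
    dropped_rows: pd.DataFrame
    implausible: pd.DataFrame
    out_of_window: pd.DataFrame
    affirmative_only: tuple[str, ...]
    mar_models: dict[str, dict]

    def write_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = {
            "women": self.women,
            "babies": self.babies,
            "neonatal": self.neonatal,
            "ultrasound": self.ultrasound,
            "activity": self.activity,
            "missing_cells": self.missing_cells,
            "duplicated_rows": self.duplicated_rows,
            "dropped_rows": self.dropped_rows,
            "implausible": self.implausible,
            "out_of_window": self.out_of_window,
        }
        for name, df in frames.items():
            df.to_csv(directory / f"{self.site_code}_truth_{name}.csv", index=False)


_EMPTY_LOGS = {
    "missing_cells": ["table", "row_id", "column", "mechanism", "true_value"],
    "duplicated_rows": ["table", "row_id"],
    "dropped_rows": ["table", "row_id", "reason"],
    "implausible": ["table", "row_id", "column", "true_value", "injected_value"],
    "out_of_window": ["table", "row_id", "true_date", "injected_date"],
}


def _empty_log(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_EMPTY_LOGS[name])


# ---------------------------------------------------------------------------
# Truth generation

def _draw_truth(config: SiteConfig, rng: np.random.Generator):
    dialect = config.dialect_profile
    site = config.site_code
    idents = generate_identifiers(
        config.n_women, config.maternal_dob_range, int(rng.integers(0, 2**31 - 1))
    )
    window_days = (config.date_window[1] - config.date_window[0]).days

    n = config.n_women
    heights = np.clip(rng.normal(1.645, 0.068, n), 1.30, 1.95)
    weights = np.clip(rng.normal(68.0, 13.5, n), 38.0, 150.0)
    heights = np.array([dialect.quantise_height(h) for h in heights])
    weights = np.array([dialect.quantise_weight(w) for w in weights])
    base_parity = np.minimum(rng.poisson(0.85, n), 8)
    eth = rng.choice(len(ETHNICITY_CATEGORIES), size=n, p=[0.55, 0.14, 0.19, 0.03, 0.09])
    htn = rng.random(n) < 0.02
    missing_ids = rng.random(n) < config.missing_id_rate

    women = pd.DataFrame(
        {
            "woman_id": [f"{site}-W-{i:05d}" for i in range(n)],
            "nhs_number": [r["nhs_number"] for r in idents],
            "hospital_number": [f"{site}{i:06d}" for i in range(n)],
            "dob": [r["dob"] for r in idents],
            "postcode": [r["postcode"] for r in idents],
            "height_m": heights,
            "weight_kg": weights,
            "base_parity": base_parity,
            "ethnicity": [ETHNICITY_CATEGORIES[i] for i in eth],
            "chronic_htn": htn,
            "missing_identifiers": missing_ids,
        }
    )

    baby_rows, scan_rows, act_rows, neo_rows = [], [], [], []
    for w in women.itertuples(index=False):
        n_pregs = 1
        if config.repeat_pregnancy_rate and rng.random() < config.repeat_pregnancy_rate:
            n_pregs = 2
        first_dod = config.date_window[0] + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
        dods = [first_dod]
        if n_pregs == 2:
            second = first_dod + dt.timedelta(days=int(rng.integers(280, 451)))
            if second <= config.date_window[1]:
                dods.append(second)
        for preg_idx, dod in enumerate(sorted(dods), start=1):
            twin = rng.random() < config.twin_rate
            n_babies = 2 if twin else 1
            if twin:
                ga = int(np.clip(rng.normal(258, 14), 161, 293))
            else:
                ga = int(np.clip(rng.normal(279.5, 11), 161, 300))
            edc = dod - dt.timedelta(days=ga) + dt.timedelta(days=14)
            parity = int(w.base_parity + (preg_idx - 1))
            mode = MODE_BIRTH_CATEGORIES[rng.choice(3, p=[0.58, 0.12, 0.30])]
            ebl = float(int(np.clip(np.exp(rng.normal(np.log(300.0), 0.5)), 50, 2400)))
            epidural = rng.random() < 0.30
            if epidural:
                lab_rec = "yes" if rng.random() < 0.92 else None
                birth_rec = "yes" if rng.random() < 0.50 else None
            else:
                lab_rec = "no" if rng.random() < 0.95 else None
                birth_rec = "no" if rng.random() < 0.40 else None
            trauma = rng.random() < 0.035

            babies = []
            for b in range(1, n_babies + 1):
                male = rng.random() < 0.514
                mu = birthweight_mean(ga, male, twin=twin)
                bw = float(int(np.clip(rng.normal(mu, BW_SIGMA), 300, 5800)))
                babies.append((b, male, bw))
            sga_flags = [bool(is_sga(bw, ga, male)) for _, male, bw in babies]
            any_sga = any(sga_flags)

            # antenatal ultrasound scans (absent when care was elsewhere)
            detected = False
            if not w.missing_identifiers and rng.random() < 0.90:
                n_scans = 1 + int(rng.poisson(2))
                offsets = np.sort(rng.integers(40, ga - 14 + 1, size=n_scans))
                for s_i, off in enumerate(offsets):
                    scan_date = edc + dt.timedelta(days=int(off))
                    frac = off / max(ga - 14, 1)
                    efw = float(
                        int(max(80, babies[0][2] * (0.25 + 0.75 * frac) + rng.normal(0, 50)))
                    )
                    last = s_i == n_scans - 1
                    flag = (last and any_sga and rng.random() < 0.55) or (
                        not last and rng.random() < 0.02
                    )
                    detected = detected or flag
                    scan_rows.append(
                        {
                            "woman_id": w.woman_id,
                            "pregnancy_index": preg_idx,
                            "nhs_number": w.nhs_number,
                            "hospital_number": w.hospital_number,
                            "dob": w.dob,
                            "postcode": w.postcode,
                            "scan_date": scan_date,
                            "fetal_count": n_babies,
                            "efw_g": efw,
                            "sga_flag": flag,
                        }
                    )

            if not w.missing_identifiers and rng.random() < 0.95:
                for _ in range(1 + int(rng.poisson(3))):
                    act_rows.append(
                        {
                            "woman_id": w.woman_id,
                            "pregnancy_index": preg_idx,
                            "nhs_number": w.nhs_number,
                            "hospital_number": w.hospital_number,
                            "dob": w.dob,
                            "postcode": w.postcode,
                            "event_date": edc + dt.timedelta(days=int(rng.integers(0, ga - 14 + 1))),
                            "event_type": ACTIVITY_TYPES[rng.integers(0, len(ACTIVITY_TYPES))],
                        }
                    )

            for (b, male, bw), sga in zip(babies, sga_flags):
                baby_rows.append(
                    {
                        "woman_id": w.woman_id,
                        "pregnancy_index": preg_idx,
                        "baby_index": b,
                        "nhs_number": w.nhs_number,
                        "hospital_number": w.hospital_number,
                        "dob": w.dob,
                        "postcode": w.postcode,
                        "dod": dod,
                        "edc": edc,
                        "ga_days": float(ga),
                        "twin": twin,
                        "sex": "male" if male else "female",
                        "birthweight_g": bw,
                        "mode_of_birth": mode,
                        "height_m": w.height_m,
                        "weight_kg": w.weight_kg,
                        "parity": float(parity),
                        "multiparous": parity >= 1,
                        "ethnicity": w.ethnicity,
                        "chronic_htn": bool(w.chronic_htn),
                        "epidural": epidural,
                        "epidural_labour_rec": lab_rec,
                        "epidural_birth_rec": birth_rec,
                        "trauma3": trauma,
                        "ebl_ml": ebl,
                        "birth_order": b,
                        "sga": sga,
                        "sga_detected": sga and detected,
                        "missing_identifiers": bool(w.missing_identifiers),
                    }
                )
                if not w.missing_identifiers and rng.random() < config.neonatal_admission_rate:
                    neo_rows.append(
                        {
                            "woman_id": w.woman_id,
                            "pregnancy_index": preg_idx,
                            "baby_index": b,
                            "nhs_number": w.nhs_number,
                            "hospital_number": w.hospital_number,
                            "dob": w.dob,
                            "postcode": w.postcode,
                            "baby_dob": dod,
                            "sex": "male" if male else "female",
                            "birthweight_g": bw,
                            "admission_reason": ADMISSION_REASONS[
                                rng.integers(0, len(ADMISSION_REASONS))
                            ],
                        }
                    )

    babies = pd.DataFrame(baby_rows)
    babies.insert(0, "row_id", [f"{site}-M-{i:05d}" for i in range(len(babies))])
    neonatal = pd.DataFrame(neo_rows, columns=list(neo_rows[0].keys()) if neo_rows else
                            ["woman_id", "pregnancy_index", "baby_index", "nhs_number",
                             "hospital_number", "dob", "postcode", "baby_dob", "sex",
                             "birthweight_g", "admission_reason"])
    neonatal.insert(0, "row_id", [f"{site}-N-{i:05d}" for i in range(len(neonatal))])
    ultrasound = pd.DataFrame(scan_rows, columns=list(scan_rows[0].keys()) if scan_rows else
                              ["woman_id", "pregnancy_index", "nhs_number", "hospital_number",
                               "dob", "postcode", "scan_date", "fetal_count", "efw_g", "sga_flag"])
    ultrasound.insert(0, "row_id", [f"{site}-U-{i:05d}" for i in range(len(ultrasound))])
    activity = pd.DataFrame(act_rows, columns=list(act_rows[0].keys()) if act_rows else
                            ["woman_id", "pregnancy_index", "nhs_number", "hospital_number",
                             "dob", "postcode", "event_date", "event_type"])
    activity.insert(0, "row_id", [f"{site}-A-{i:05d}" for i in range(len(activity))])
    return women, babies, neonatal, ultrasound, activity


# ---------------------------------------------------------------------------
# Missingness injection

def inject_missingness(
    table: pd.DataFrame,
    spec: dict[str, MissingnessSpec],
    seed: int,
    site_effect: float = 0.0,
    protected: set[tuple[str, str]] | None = None,
    table_name: str = "maternity",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict]]:
    """Blank cells per the missingness spec, returning the table, a log of
    blanked cells and the MAR model coefficients used.

    MCAR blanks each cell independently of all values. MAR blanks with
    probability ``expit(logit(rate) + site_effect + beta * z(driver))``
    where ``z(driver)`` is the within-table standardised driver covariate.
    Cells listed in ``protected`` (row_id, column) are never blanked, so
    other injected defects survive.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    protected = protected or set()
    log_rows = []
    mar_models: dict[str, dict] = {}
    for var, m in spec.items():
        if var not in out.columns:
            raise ConfigurationError(f"missingness target {var!r} not in table")
        if m.rate == 0.0:
            continue
        n = len(out)
        if m.mechanism == "MCAR":
            p = np.full(n, m.rate)
        else:
            driver = pd.to_numeric(out[m.driver], errors="coerce")
            mu, sd = float(driver.mean()), float(driver.std(ddof=0)) or 1.0
            z = ((driver - mu) / sd).fillna(0.0).to_numpy()
            logit = np.log(m.rate / (1.0 - m.rate)) + site_effect + m.beta * z
            p = 1.0 / (1.0 + np.exp(-logit))
            mar_models[var] = {
                "driver": m.driver,
                "intercept": float(np.log(m.rate / (1.0 - m.rate))),
                "site_effect": float(site_effect),
                "beta": float(m.beta),
                "driver_mean": mu,
                "driver_sd": sd,
            }
        blank = rng.random(n) < p
        for i in np.nonzero(blank)[0]:
            row_id = out.iloc[i].get("row_id", str(i))
            if (row_id, var) in protected:
                continue
            true_value = out.iat[i, out.columns.get_loc(var)]
            if pd.isna(true_value):
                continue
            log_rows.append(
                {
                    "table": table_name,
                    "row_id": row_id,
                    "column": var,
                    "mechanism": m.mechanism,
                    "true_value": true_value,
                }
            )
            out.iat[i, out.columns.get_loc(var)] = np.nan
    return out, pd.DataFrame(log_rows, columns=_EMPTY_LOGS["missing_cells"]), mar_models


# ---------------------------------------------------------------------------
# Defect injection + rendering

def _inject_defects(config, babies, ultrasound, activity, rng):
    dropped, dup_rows, implausible, out_window = [], [], [], []

    emitted = babies.copy()
    rate = config.rate("per_pregnancy_multiple")
    if rate:
        mask = (emitted["baby_index"] == 2) & (rng.random(len(emitted)) < rate)
        for rid in emitted.loc[mask, "row_id"]:
            dropped.append({"table": "maternity", "row_id": rid, "reason": "per_pregnancy_multiple"})
        emitted = emitted[~mask].reset_index(drop=True)

    rate = config.rate("implausible_value")
    if rate:
        for col, choices in IMPLAUSIBLE_VALUES.items():
            mask = rng.random(len(emitted)) < rate
            for i in np.nonzero(mask)[0]:
                true_value = emitted.iat[i, emitted.columns.get_loc(col)]
                injected = float(choices[rng.integers(0, len(choices))])
                implausible.append(
                    {
                        "table": "maternity",
                        "row_id": emitted.iat[i, emitted.columns.get_loc("row_id")],
                        "column": col,
                        "true_value": true_value,
                        "injected_value": injected,
                    }
                )
                emitted.iat[i, emitted.columns.get_loc(col)] = injected

    uss = ultrasound.copy()
    act = activity.copy()
    rate = config.rate("out_of_window_date")
    if rate:
        edc_by_preg = babies.drop_duplicates(["woman_id", "pregnancy_index"]).set_index(
            ["woman_id", "pregnancy_index"]
        )[["edc", "dod"]]
        for df, date_col, name in ((uss, "scan_date", "ultrasound"), (act, "event_date", "activity")):
            mask = rng.random(len(df)) < rate
            for i in np.nonzero(mask)[0]:
                key = (df.iat[i, df.columns.get_loc("woman_id")],
                       df.iat[i, df.columns.get_loc("pregnancy_index")])
                dod = edc_by_preg.loc[key, "dod"]
                edc = edc_by_preg.loc[key, "edc"]
                old = df.iat[i, df.columns.get_loc(date_col)]
                if rng.random() < 0.5:
                    new = dod + dt.timedelta(days=int(rng.integers(8, 121)))
                else:
                    new = edc - dt.timedelta(days=int(rng.integers(5, 101)))
                out_window.append(
                    {"table": name, "row_id": df.iat[i, df.columns.get_loc("row_id")],
                     "true_date": old, "injected_date": new}
                )
                df.iat[i, df.columns.get_loc(date_col)] = new
    return emitted, uss, act, dropped, dup_rows, implausible, out_window


def _render_maternity(emitted: pd.DataFrame, config: SiteConfig, rng, affirmative_only):
    d = config.dialect_profile
    cols = d.maternity_columns
    out = pd.DataFrame()
    out["row_id"] = emitted["row_id"]
    out["nhs_number"] = [
        "" if m else v for m, v in zip(emitted["missing_identifiers"], emitted["nhs_number"])
    ]
    out["hospital_number"] = emitted["hospital_number"]
    out["dob"] = [
        "" if m else d.render_date(v) for m, v in zip(emitted["missing_identifiers"], emitted["dob"])
    ]
    out["postcode"] = emitted["postcode"]

    def render(col, fn):
        return [None if pd.isna(v) else fn(v) for v in emitted[col]]

    def pick(synonyms_by_cat, values):
        rendered = []
        for v in values:
            if pd.isna(v):
                rendered.append(None)
            else:
                opts = synonyms_by_cat[v]
                rendered.append(opts[rng.integers(0, len(opts))])
        return rendered

    out[cols["dod"]] = render("dod", d.render_date)
    out[cols["ga"]] = render("ga_days", lambda v: d.render_ga(int(v)))
    out[cols["sex"]] = render("sex", lambda v: d.sex_map[v])
    out[cols["bw"]] = render("birthweight_g", lambda v: float(v))
    out[cols["modebirth"]] = pick(d.mode_birth_synonyms, emitted["mode_of_birth"])
    out[cols["height"]] = render("height_m", d.render_height)
    out[cols["weight"]] = render("weight_kg", d.render_weight)
    if config.parity_binary:
        out[cols["parity"]] = render(
            "parity",
            lambda v: d.parity_binary_map["nulliparous" if v == 0 else "multiparous"],
        )
    else:
        out[cols["parity"]] = render("parity", lambda v: float(v))
    out[cols["multip"]] = render("multiparous", lambda v: d.render_binary(bool(v)))
    out[cols["ethnicity"]] = pick(d.ethnicity_synonyms, emitted["ethnicity"])
    out[cols["htn"]] = render(
        "chronic_htn", lambda v: d.render_binary(bool(v), "chronic_htn" in affirmative_only)
    )
    out[cols["epidurallab"]] = render(
        "epidural_labour_rec", lambda v: d.binary_map[v] if v in ("yes", "no") else None
    )
    out[cols["epiduralbirth"]] = render(
        "epidural_birth_rec", lambda v: d.binary_map[v] if v in ("yes", "no") else None
    )
    out[cols["trauma3"]] = render(
        "trauma3", lambda v: d.render_binary(bool(v), "trauma3" in affirmative_only)
    )
    out[cols["ebl"]] = render("ebl_ml", lambda v: float(v))
    out[cols["birthorder"]] = render("birth_order", lambda v: int(v))
    return out


def generate_bundle(config: SiteConfig, seed: int) -> tuple[RecordBundle, TruthTable]:
    """Generate one site's raw four-table bundle and its ground truth."""
    rng = np.random.default_rng(seed)
    women, babies, neonatal, ultrasound, activity = _draw_truth(config, rng)

    emitted, uss, act, dropped, dup_log, implausible, out_window = _inject_defects(
        config, babies, ultrasound, activity, rng
    )

    affirmative_only: tuple[str, ...] = ()
    if config.rate("affirmative_only_binary") > 0:
        affirmative_only = ("chronic_htn", "trauma3")

    protected = {(r["row_id"], r["column"]) for r in implausible}
    emitted, missing_log, mar_models = inject_missingness(
        emitted,
        config.missingness,
        seed=int(rng.integers(0, 2**31 - 1)),
        site_effect=config.mar_site_effect,
        protected=protected,
    )

    dup_rate = config.rate("duplicate_row")
    if dup_rate and len(emitted):
        mask = rng.random(len(emitted)) < dup_rate
        dups = emitted[mask]
        for rid in dups["row_id"]:
            dup_log.append({"table": "maternity", "row_id": rid})
        emitted = pd.concat([emitted, dups], ignore_index=True)

    mat_raw = _render_maternity(emitted, config, rng, affirmative_only)

    d = config.dialect_profile
    neo_raw = pd.DataFrame()
    neo_raw["row_id"] = neonatal["row_id"]
    neo_raw["nhs_number"] = neonatal["nhs_number"]
    neo_raw["hospital_number"] = neonatal["hospital_number"]
    neo_raw["dob"] = [v.isoformat() for v in neonatal["dob"]]
    neo_raw["postcode"] = neonatal["postcode"]
    neo_raw[NEONATAL_COLUMNS["dob"]] = [v.isoformat() for v in neonatal["baby_dob"]]
    neo_raw[NEONATAL_COLUMNS["sex"]] = [NEONATAL_SEX_MAP[v] for v in neonatal["sex"]]
    neo_raw[NEONATAL_COLUMNS["bw"]] = neonatal["birthweight_g"].astype(float)
    neo_raw[NEONATAL_COLUMNS["admreason"]] = neonatal["admission_reason"]

    uss_raw = pd.DataFrame()
    uss_raw["row_id"] = uss["row_id"]
    uss_raw["nhs_number"] = uss["nhs_number"]
    uss_raw["hospital_number"] = uss["hospital_number"]
    uss_raw["dob"] = [d.render_date(v) for v in uss["dob"]]
    uss_raw["postcode"] = uss["postcode"]
    uss_raw[ULTRASOUND_COLUMNS["scandate"]] = [d.render_date(v) for v in uss["scan_date"]]
    uss_raw[ULTRASOUND_COLUMNS["fetalcount"]] = uss["fetal_count"].astype(float)
    uss_raw[ULTRASOUND_COLUMNS["efw"]] = uss["efw_g"].astype(float)
    uss_raw[ULTRASOUND_COLUMNS["sgaflag"]] = ["Y" if v else "N" for v in uss["sga_flag"]]

    act_raw = pd.DataFrame()
    act_raw["row_id"] = act["row_id"]
    act_raw["nhs_number"] = act["nhs_number"]
    act_raw["hospital_number"] = act["hospital_number"]
    act_raw["dob"] = [d.render_date(v) for v in act["dob"]]
    act_raw["postcode"] = act["postcode"]
    act_raw[ACTIVITY_COLUMNS["eventdate"]] = [d.render_date(v) for v in act["event_date"]]
    act_raw[ACTIVITY_COLUMNS["eventtype"]] = act["event_type"]

    bundle = RecordBundle(
        site_code=config.site_code,
        stage="raw",
        maternity=mat_raw,
        neonatal=neo_raw,
        ultrasound=uss_raw,
        activity=act_raw,
    )
    truth = TruthTable(
        site_code=config.site_code,
        women=women,
        babies=babies,
        neonatal=neonatal,
        ultrasound=ultrasound,
        activity=activity,
        missing_cells=missing_log,
        duplicated_rows=pd.DataFrame(dup_log, columns=_EMPTY_LOGS["duplicated_rows"]),
        dropped_rows=pd.DataFrame(dropped, columns=_EMPTY_LOGS["dropped_rows"]),
        implausible=pd.DataFrame(implausible, columns=_EMPTY_LOGS["implausible"]),
        out_of_window=pd.DataFrame(out_window, columns=_EMPTY_LOGS["out_of_window"]),
        affirmative_only=affirmative_only,
        mar_models=mar_models,
    )
    return bundle, truth


def generate_run(configs: list[SiteConfig], seed: int) -> dict[str, tuple[RecordBundle, TruthTable]]:
    """Generate bundles for several sites with independent per-site streams."""
    codes = [c.site_code for c in configs]
    if len(set(codes)) != len(codes):
        raise ConfigurationError("site codes must be unique within a generation run")
    children = np.random.SeedSequence(seed).spawn(len(configs))
    return {
        c.site_code: generate_bundle(c, int(child.generate_state(1)[0] % (2**31 - 1)))
        for c, child in zip(configs, children)
    }


def make_postcode_lookup(
    bundles_or_truths, seed: int, coverage: float = 0.97
) -> pd.DataFrame:
    """Synthetic postcode -> deprivation lookup (stand-in for the national
    postcode directory) covering most postcodes seen in the given truths."""
    rng = np.random.default_rng(seed)
    postcodes: set[str] = set()
    for item in bundles_or_truths:
        women = item.women if isinstance(item, TruthTable) else item.maternity
        postcodes.update(str(p) for p in women["postcode"].dropna())
    postcodes = sorted(postcodes)
    keep = rng.random(len(postcodes)) < coverage
    rows = []
    for pc, k in zip(postcodes, keep):
        if not k:
            continue
        rows.append(
            {
                "postcode": pc,
                "imd": int(rng.integers(1, 32845)),
                "lsoa": f"E0{rng.integers(1000000, 2000000)}",
                "msoa": f"E0{rng.integers(2000000, 3000000)}",
            }
        )
    return pd.DataFrame(rows, columns=["postcode", "imd", "lsoa", "msoa"])
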
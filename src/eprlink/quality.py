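"""Staged data-quality auditing: download checklists, duplicate
classification and the two-stage outlier policy.

The first extract from each site runs a seven-item checklist (dataset
presence, duplicate study IDs, ID matching across datasets, variable
presence, completeness, continuous distributions, date ranges); the second
download runs a reduced six-item list focused on resolution of previously
raised issues and the variables key to the primary outcome.

Outlier handling is two-stage: distributional screening (3/4/5 SD limits
and the 1st/99th centiles) only ever *highlights* candidates, while the
clinical-consensus plausibility limits convert values strictly outside
them to missing. Default limits: maternal age 13–60 years, height
1.20–2.00 m, weight 30–200 kg, BMI 13–70 kg/m², estimated blood loss
1–15,000 mL, birthweight 100–6,000 g. The limits themselves are inclusive.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bundle import ConfigurationError, RecordBundle, parse_date_column
from .harmonise import DataDictionary, convert_units

PERCENTILE_CONVENTION = "linear interpolation between order statistics"


# ---------------------------------------------------------------------------
# Report containers

@dataclass
class CheckResult:
    id: str
    name: str
    status: str  # pass | warn | fail
    evidence: dict = field(default_factory=dict)


@dataclass
class QCReport:
    checklist_id: str  # first_download | second_download
    site_code: str
    checks: list[CheckResult] = field(default_factory=list)

    def check(self, check_id: str) -> CheckResult:
        for c in self.checks:
            if c.id == check_id:
                return c
        raise KeyError(check_id)

    def statuses(self) -> dict[str, str]:
        return {c.id: c.status for c in self.checks}

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if c.status != "pass"]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "checklist_id": self.checklist_id,
            "site_code": self.site_code,
            "percentile_convention": PERCENTILE_CONVENTION,
            "checks": [dataclasses.asdict(c) for c in self.checks],
        }
        text = json.dumps(doc, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"QC report [{self.checklist_id}] site {self.site_code}"]
        for c in self.checks:
            lines.append(f"  [{c.status.upper():4s}] {c.name}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Summaries and outlier screening

def distribution_summary(values) -> dict:
    """Range, median and 5th/25th/75th/95th centiles of a numeric column,
    missing values excluded; linear-interpolation percentile convention."""
    x = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(dtype=float)
    if x.size == 0:
        return {"n": 0, "empty": True}
    p5, p25, p50, p75, p95 = np.percentile(x, [5, 25, 50, 75, 95])
    return {
        "n": int(x.size),
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(p50),
        "p5": float(p5),
        "p25": float(p25),
        "p75": float(p75),
        "p95": float(p95),
    }


def flag_outlier_candidates(values) -> dict[str, list[float]]:
    """Advisory screening lists: values beyond ±3/4/5 sample SD and beyond
    the 1st/99th centiles. Never mutates data."""
    x = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(dtype=float)
    if x.size < 10:
        raise ConfigurationError("outlier screening needs at least 10 observed values")
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    p1, p99 = np.percentile(x, [1, 99])
    out: dict[str, list[float]] = {}
    for k in (3, 4, 5):
        mask = np.abs(x - mu) > k * sd if sd > 0 else np.zeros(x.size, bool)
        out[f"beyond_{k}sd"] = sorted(x[mask].tolist())
    out["below_p1"] = sorted(x[x < p1].tolist())
    out["above_p99"] = sorted(x[x > p99].tolist())
    return out


# ---------------------------------------------------------------------------
# Duplicate classification

def classify_duplicates(
    maternity: pd.DataFrame,
    ultrasound: pd.DataFrame | None = None,
    dod_column: str = "dod",
    baby_columns: tuple[str, ...] = ("sex", "birthweight", "birth_order"),
    scan_date_column: str = "scan_date",
    fetal_count_column: str = "fetal_count",
) -> pd.Series:
    """Classify each maternity row as unique / multiple_birth / true_duplicate.

    Rows sharing (study_id, DOD) but differing in baby-level fields look
    like a multiple birth; rows identical across all baby fields are true
    duplicates. Where ultrasound fetal count for the pregnancy is 1, a
    multiple-birth-looking pair is reclassified as true duplicates (the
    scan clarifies the pregnancy was a singleton).
    """
    cls = pd.Series("unique", index=maternity.index, dtype=object)
    baby_cols = [c for c in baby_columns if c in maternity.columns]
    dod = pd.to_datetime(maternity[dod_column])

    scans = None
    if ultrasound is not None and fetal_count_column in getattr(ultrasound, "columns", ()):
        scans = ultrasound.copy()
        scans["_scan_date"] = pd.to_datetime(scans[scan_date_column])

    for (sid, d), group in maternity.groupby(["study_id", dod], sort=False):
        if len(group) < 2:
            continue
        dup_of_other = pd.Series(False, index=group.index)
        values = group[baby_cols].astype(str)
        counts = values.groupby(list(baby_cols) if baby_cols else values.columns.tolist()).size()
        for idx in group.index:
            key = tuple(values.loc[idx])
            same = (values == values.loc[idx]).all(axis=1)
            dup_of_other.loc[idx] = int(same.sum()) >= 2
        for idx in group.index:
            cls.loc[idx] = "true_duplicate" if dup_of_other.loc[idx] else "multiple_birth"
        if scans is not None and (cls.loc[group.index] == "multiple_birth").any():
            window = scans[
                (scans["study_id"] == sid)
                & (scans["_scan_date"] <= d)
                & (scans["_scan_date"] >= d - pd.Timedelta(days=301))
            ]
            fc = pd.to_numeric(window[fetal_count_column], errors="coerce").dropna()
            if len(fc) and fc.max() == 1:
                cls.loc[group.index] = "true_duplicate"
    return cls


def drop_true_duplicates(
    maternity: pd.DataFrame, classes: pd.Series, dod_column: str = "dod"
) -> tuple[pd.DataFrame, int]:
    """Resolve true duplicates by keeping one row per identical set."""
    dup_idx = classes[classes == "true_duplicate"].index
    if len(dup_idx) == 0:
        return maternity, 0
    dups = maternity.loc[dup_idx]
    keep_first = ~dups.astype(str).duplicated()
    to_drop = dups.index[~keep_first]
    return maternity.drop(index=to_drop), int(len(to_drop))


# ---------------------------------------------------------------------------
# Outlier policy

@dataclass(frozen=True)
class OutlierLimit:
    column: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(f"outlier limits for {self.column}: lower must be < upper")


@dataclass
class OutlierPolicy:
    limits: dict[str, OutlierLimit]

    @classmethod
    def consensus_defaults(cls) -> "OutlierPolicy":
        """Clinical-consensus plausibility limits in canonical units
        (height applied in metres after harmonisation)."""
        return cls(
            {
                "maternal_age": OutlierLimit("mat_c_agedel", 13, 60),
                "height": OutlierLimit("mat_h_height", 1.20, 2.00),
                "weight": OutlierLimit("mat_h_weight", 30, 200),
                "bmi": OutlierLimit("mat_c_bmi", 13, 70),
                "ebl": OutlierLimit("mat_h_ebl", 1, 15000),
                "birthweight": OutlierLimit("mat_h_bw", 100, 6000),
            }
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {k: dataclasses.asdict(v) for k, v in self.limits.items()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OutlierPolicy":
        doc = yaml.safe_load(Path(path).read_text())
        return cls({k: OutlierLimit(**v) for k, v in doc.items()})


def apply_outlier_policy(
    bundle: RecordBundle, policy: OutlierPolicy
) -> tuple[RecordBundle, pd.DataFrame]:
    """Convert values strictly outside the consensus limits to missing.

    Values equal to a limit are retained (limits are inclusive). Idempotent;
    retained values are never altered. Returns the cleaned bundle and
    per-variable removal counts.
    """
    out = bundle.copy(stage="cleaned")
    mat = out.maternity
    rows = []
    for label, limit in policy.limits.items():
        if limit.column not in mat.columns:
            raise ConfigurationError(f"outlier policy column {limit.column!r} absent from bundle")
        values = pd.to_numeric(mat[limit.column], errors="coerce")
        outside = values.notna() & ((values < limit.lower) | (values > limit.upper))
        mat.loc[outside, limit.column] = np.nan
        rows.append(
            {
                "site": bundle.site_code,
                "variable": label,
                "column": limit.column,
                "lower": limit.lower,
                "upper": limit.upper,
                "removed": int(outside.sum()),
            }
        )
    out.maternity = mat
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checklists

def _site_rules(dictionary: DataDictionary, site: str, table: str):
    for entry in dictionary.for_table(table):
        rule = entry.sites.get(site)
        if rule is not None and rule.raw_name:
            yield entry, rule


def _canonical_numeric(df: pd.DataFrame, rule, entry) -> pd.Series:
    raw = df[rule.raw_name]
    return pd.Series(
        [convert_units(v, rule.unit_rule)[0] for v in raw], index=df.index, dtype=float
    )


def _completeness(df: pd.DataFrame, column: str) -> float:
    col = df[column]
    blank = col.isna() | (col.astype(str).str.strip().isin(["", "nan", "None"]))
    return float(100.0 * (1 - blank.mean())) if len(col) else float("nan")


def _date_range_check(bundle, dictionary, expected_window):
    start, end = expected_window
    event_start = start - dt.timedelta(days=301)  # conception precedes the birth window
    violations: dict[str, int] = {}
    ranges: dict[str, dict] = {}
    windows = {
        "maternity": (start, end),
        "neonatal": (start, end),
        "ultrasound": (event_start, end),
        "activity": (event_start, end),
    }
    for table, df in bundle.tables().items():
        if df.empty:
            continue
        for entry, rule in _site_rules(dictionary, bundle.site_code, table):
            if entry.dtype != "date":
                continue
            dates = parse_date_column(df[rule.raw_name]).dropna()
            if dates.empty:
                continue
            lo, hi = windows[table]
            bad = int(((dates < pd.Timestamp(lo)) | (dates > pd.Timestamp(hi))).sum())
            ranges[f"{table}.{rule.raw_name}"] = {
                "min": str(dates.min().date()),
                "max": str(dates.max().date()),
                "expected": [str(lo), str(hi)],
            }
            if bad:
                violations[f"{table}.{rule.raw_name}"] = bad
    return violations, ranges


def _duplicate_check(bundle, dictionary):
    site = bundle.site_code
    mat = bundle.maternity
    view = pd.DataFrame(index=mat.index)
    view["study_id"] = mat["study_id"]
    names = {e.name: r for e, r in _site_rules(dictionary, site, "maternity")}
    if "mat_h_dod" in names:
        view["dod"] = parse_date_column(mat[names["mat_h_dod"].raw_name])
    for out_col, key in (("sex", "mat_h_sex"), ("birthweight", "mat_h_bw"),
                         ("birth_order", "mat_h_birthorder")):
        if key in names:
            view[out_col] = mat[names[key].raw_name]
    uss_view = None
    uss_names = {e.name: r for e, r in _site_rules(dictionary, site, "ultrasound")}
    if not bundle.ultrasound.empty and "uss_h_fetalcount" in uss_names:
        uss_view = pd.DataFrame(index=bundle.ultrasound.index)
        uss_view["study_id"] = bundle.ultrasound["study_id"]
        uss_view["scan_date"] = parse_date_column(
            bundle.ultrasound[uss_names["uss_h_scandate"].raw_name]
        )
        uss_view["fetal_count"] = pd.to_numeric(
            bundle.ultrasound[uss_names["uss_h_fetalcount"].raw_name], errors="coerce"
        )
    classes = classify_duplicates(view, uss_view)
    return classes


def first_download_checks(
    bundle: RecordBundle,
    dictionary: DataDictionary,
    expected_window: tuple[dt.date, dt.date],
) -> QCReport:
    """Seven-item completeness/plausibility checklist for a first extract."""
    site = bundle.site_code
    report = QCReport(checklist_id="first_download", site_code=site)

    # 1. presence of all four requested datasets
    missing = [name for name, df in bundle.tables().items() if df is None or df.empty]
    report.checks.append(
        CheckResult(
            "datasets_present",
            "Presence of all four requested datasets",
            "fail" if missing else "pass",
            {"missing_datasets": missing},
        )
    )

    # 2. duplicate study IDs, classified against multiple births
    classes = _duplicate_check(bundle, dictionary)
    n_true = int((classes == "true_duplicate").sum())
    n_multi = int((classes == "multiple_birth").sum())
    report.checks.append(
        CheckResult(
            "duplicate_ids",
            "Duplication of study IDs (true duplicates vs multiple births)",
            "warn" if n_true else "pass",
            {"true_duplicate_rows": n_true, "multiple_birth_rows": n_multi},
        )
    )

    # 3. matching of study IDs across the four datasets
    spine = set(bundle.maternity.get("study_id", pd.Series(dtype=object)))
    match_rates = {}
    broken = []
    for name in ("neonatal", "ultrasound", "activity"):
        df = getattr(bundle, name)
        if df.empty or "study_id" not in df.columns:
            continue
        frac = float(df["study_id"].isin(spine).mean())
        match_rates[name] = round(100 * frac, 2)
        if frac == 0:
            broken.append(name)
    report.checks.append(
        CheckResult(
            "id_matching",
            "Matching of study IDs across the 4 datasets",
            "fail" if broken else "pass",
            {"percent_matching_spine": match_rates, "no_overlap": broken},
        )
    )

    # 4. presence of the requested variables
    absent: dict[str, list[str]] = {}
    for table, df in bundle.tables().items():
        if df.empty:
            continue
        missing_vars = [
            rule.raw_name
            for _, rule in _site_rules(dictionary, site, table)
            if rule.raw_name not in df.columns
        ]
        if missing_vars:
            absent[table] = missing_vars
    report.checks.append(
        CheckResult(
            "variables_present",
            "Presence of the requested variables",
            "fail" if absent else "pass",
            {"absent_variables": absent},
        )
    )

    # 5. completeness of the requested variables
    completeness: dict[str, float] = {}
    for table, df in bundle.tables().items():
        if df.empty:
            continue
        for _, rule in _site_rules(dictionary, site, table):
            if rule.raw_name in df.columns:
                completeness[f"{table}.{rule.raw_name}"] = round(
                    _completeness(df, rule.raw_name), 2
                )
    report.checks.append(
        CheckResult(
            "completeness",
            "Level of completeness of the requested variables",
            "pass",
            {"percent_complete": completeness},
        )
    )

    # 6. distribution of continuously reported variables
    distributions = {}
    for table, df in bundle.tables().items():
        if df.empty:
            continue
        for entry, rule in _site_rules(dictionary, site, table):
            if entry.dtype == "continuous" and rule.raw_name in df.columns:
                distributions[entry.name] = distribution_summary(
                    _canonical_numeric(df, rule, entry)
                )
    report.checks.append(
        CheckResult(
            "distributions",
            "Range, median, 5th/25th/75th/95th centiles of continuous variables",
            "pass",
            {"summaries": distributions, "convention": PERCENTILE_CONVENTION},
        )
    )

    # 7. date range of reported births and hospital activities
    violations, ranges = _date_range_check(bundle, dictionary, expected_window)
    report.checks.append(
        CheckResult(
            "date_range",
            "Date range of all reported births and hospital activities",
            "warn" if violations else "pass",
            {"out_of_range_counts": violations, "observed_ranges": ranges},
        )
    )
    return report


def second_download_checks(
    bundle: RecordBundle,
    prior_report: QCReport,
    key_vars: list[str],
    dictionary: DataDictionary,
    expected_window: tuple[dt.date, dt.date],
) -> QCReport:
    """Reduced checklist for the second download: resolution of prior issues
    plus checks on the variables key to the primary outcome.

    ``key_vars`` are harmonised entry names (e.g. ``mat_h_height``).
    """
    site = bundle.site_code
    report = QCReport(checklist_id="second_download", site_code=site)
    fresh = first_download_checks(bundle, dictionary, expected_window)

    # 1. resolution of issues raised at the first download (omitted when none)
    prior_failures = prior_report.failures()
    if prior_failures:
        resolution = {
            c.id: ("resolved" if fresh.check(c.id).status == "pass" else "unresolved")
            for c in prior_failures
        }
        status = "pass" if all(v == "resolved" for v in resolution.values()) else "warn"
        report.checks.append(
            CheckResult(
                "prior_issues",
                "Resolution of data quality issues raised at the first download",
                status,
                {"resolution": resolution},
            )
        )

    # 2. duplicate study IDs
    report.checks.append(fresh.check("duplicate_ids"))

    rules = {e.name: (e, r) for t in bundle.tables() for e, r in _site_rules(dictionary, site, t)}

    # 3. completeness of key variables (with completely-missing flags)
    key_completeness: dict[str, float] = {}
    completely_missing: list[str] = []
    for name in key_vars:
        if name not in rules:
            completely_missing.append(name)
            key_completeness[name] = 0.0
            continue
        entry, rule = rules[name]
        df = getattr(bundle, entry.table)
        if df.empty or rule.raw_name not in df.columns:
            completely_missing.append(name)
            key_completeness[name] = 0.0
            continue
        pct = _completeness(df, rule.raw_name)
        key_completeness[name] = round(pct, 2)
        if pct == 0.0:
            completely_missing.append(name)
    report.checks.append(
        CheckResult(
            "key_completeness",
            "Completeness of variables key to the primary outcome",
            "fail" if completely_missing else "pass",
            {
                "percent_complete": key_completeness,
                "completely_missing": completely_missing,
            },
        )
    )

    # 4. distribution of key continuous variables
    key_distributions = {}
    for name in key_vars:
        if name in rules:
            entry, rule = rules[name]
            df = getattr(bundle, entry.table)
            if entry.dtype == "continuous" and not df.empty and rule.raw_name in df.columns:
                key_distributions[name] = distribution_summary(_canonical_numeric(df, rule, entry))
    report.checks.append(
        CheckResult(
            "key_distributions",
            "Distribution of continuous variables required for the primary outcome",
            "pass",
            {"summaries": key_distributions},
        )
    )

    # 5. value responses of key categorical variables
    unexpected: dict[str, list[str]] = {}
    for name in key_vars:
        if name in rules:
            entry, rule = rules[name]
            df = getattr(bundle, entry.table)
            if entry.dtype in ("categorical", "binary") and not df.empty and rule.raw_name in df.columns:
                observed = set(
                    str(v).strip() for v in df[rule.raw_name].dropna() if str(v).strip()
                )
                known = set((rule.recode_map or {}).keys())
                extra = sorted(observed - known)
                if extra:
                    unexpected[name] = extra
    report.checks.append(
        CheckResult(
            "key_categorical_values",
            "Value responses to categorical variables required for the primary outcome",
            "warn" if unexpected else "pass",
            {"unexpected_values": unexpected},
        )
    )

    # 6. date ranges
    report.checks.append(fresh.check("date_range"))
    return report
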
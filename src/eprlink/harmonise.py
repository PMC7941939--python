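"""Dictionary-driven harmonisation of heterogeneous per-site EPR extracts.

Each variable is described once in a :class:`DataDictionary` under a
standardised name ``<source>_<stage>_<short>`` where source identifies the
originating dataset (``mat``/``neo``/``uss``/``act``) and stage records the
degree of data management applied: ``r`` raw, ``h`` harmonised, ``c``
calculated. Per-site rules give the raw column name, a unit-conversion
rule, a recode map for categorical vocabularies and the binary-missingness
mode. The engine realises every entry, always retaining the untouched raw
column under its ``_r_`` name, and emits an audit trail whose replay on the
raw input reproduces the harmonised output bit-identically.

Binary variables follow two rules observed in source systems: where a site
records only the affirmative option (``affirmative_only``), missing values
are treated as explicit negatives; where negatives are recorded too
(``full``), missing values are left missing. When the same clinical fact is
recorded in several source columns, any affirmative record wins
(:func:`merge_multisource`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bundle import ConfigurationError, RecordBundle, parse_date_column

SOURCES = {"mat": "maternity", "neo": "neonatal", "uss": "ultrasound", "act": "activity"}
STAGE_TAGS = ("r", "h", "c")
DTYPES = ("continuous", "categorical", "binary", "date", "text")
BINARY_MODES = ("affirmative_only", "full")
SUPPORTED_UNIT_RULES = (
    "identity",
    "cm->m",
    "ft_in->m",
    "lb->kg",
    "st_lb->kg",
    "g->g",
    "ga_string->days",
)

_NAME_RE = re.compile(r"^(mat|neo|uss|act)_(r|h|c)_[a-z][a-z0-9]*$")
_LB_PER_KG = 0.45359237


class DictionaryError(ConfigurationError):
    """Dictionary failed validation; message lists the offending entries."""


# ---------------------------------------------------------------------------
# Elementary transforms

def convert_units(value, unit_rule: str):
    """Convert one raw value to canonical units.

    Returns ``(canonical_value, ok)``; unparseable input yields
    ``(nan, False)`` so the caller can log an audit entry.
    """
    if unit_rule not in SUPPORTED_UNIT_RULES:
        raise ConfigurationError(f"unknown unit rule {unit_rule!r}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan, True
    text = str(value).strip()
    if not text or text.lower() in ("nan", "none"):
        return np.nan, True

    def as_float(t):
        try:
            return float(t)
        except ValueError:
            return None

    if unit_rule == "ft_in->m":
        m = re.fullmatch(r"(\d+)\s*(?:ft|')\s*(\d+(?:\.\d+)?)?\s*(?:in|\")?", text)
        if not m:
            return np.nan, False
        inches = int(m.group(1)) * 12 + (float(m.group(2)) if m.group(2) else 0.0)
        return inches * 0.0254, True
    if unit_rule == "st_lb->kg":
        m = re.fullmatch(r"(\d+)\s*st\s*(\d+(?:\.\d+)?)?\s*(?:lb|lbs)?", text)
        if not m:
            return np.nan, False
        pounds = int(m.group(1)) * 14 + (float(m.group(2)) if m.group(2) else 0.0)
        return pounds * _LB_PER_KG, True
    if unit_rule == "ga_string->days":
        m = re.fullmatch(r"(\d+)\s*\+\s*(\d)", text)
        if m:
            return float(int(m.group(1)) * 7 + int(m.group(2))), True
        x = as_float(text)
        if x is None or x < 0:
            return np.nan, False
        return float(round(x * 7)) if x <= 45 else float(round(x)), True

    x = as_float(text)
    if x is None:
        return np.nan, False
    if unit_rule == "cm->m":
        return x / 100.0, True
    if unit_rule == "lb->kg":
        return x * _LB_PER_KG, True
    return x, True  # identity, g->g


def calculate_bmi(weight_kg, height_m):
    """BMI in kg/m^2; missing or non-positive inputs give missing output."""
    w = pd.to_numeric(pd.Series(np.asarray(weight_kg, dtype=object).ravel()), errors="coerce")
    h = pd.to_numeric(pd.Series(np.asarray(height_m, dtype=object).ravel()), errors="coerce")
    bmi = w / (h**2)
    bmi[(h <= 0) | (w <= 0)] = np.nan
    return bmi.to_numpy()


def recode_categorical(series: pd.Series, recode_map: dict[str, str]):
    """Map raw category strings to harmonised categories.

    Unmapped non-missing values become missing and are reported separately
    from true missing: returns ``(recoded, unmapped_value_counts)``.
    """
    norm_map = {str(k): v for k, v in recode_map.items()}
    out, unmapped = [], {}
    for v in series:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(np.nan)
            continue
        key = str(v).strip()
        if not key or key.lower() == "nan":
            out.append(np.nan)
        elif key in norm_map:
            out.append(norm_map[key])
        else:
            unmapped[key] = unmapped.get(key, 0) + 1
            out.append(np.nan)
    return pd.Series(out, index=series.index, dtype=object), unmapped


def apply_binary_rule(series: pd.Series, binary_mode: str) -> pd.Series:
    """Resolve missingness for a recoded yes/no column.

    ``affirmative_only``: the source form offered only the affirmative
    option, so missing means the event did not happen — missing becomes
    ``no``. ``full``: negatives were recorded too, so missing stays missing.
    """
    if binary_mode not in BINARY_MODES:
        raise ConfigurationError(f"unknown binary mode {binary_mode!r}")
    bad = series.dropna()[~series.dropna().isin(["yes", "no"])]
    if len(bad):
        raise ConfigurationError(
            f"binary column contains non-binary values after recoding: {sorted(set(bad))[:5]}"
        )
    if binary_mode == "affirmative_only":
        return series.fillna("no")
    return series.copy()


def merge_multisource(*columns: pd.Series) -> pd.Series:
    """Combine >=2 yes/no/missing columns recording the same clinical fact.

    Any affirmative record wins; negative requires at least one recorded
    negative and no affirmative; missing only when every source is missing.
    """
    if len(columns) < 2:
        raise ConfigurationError("merge_multisource needs at least two columns")
    stacked = pd.concat(columns, axis=1)
    any_yes = (stacked == "yes").any(axis=1)
    any_no = (stacked == "no").any(axis=1)
    out = pd.Series(np.nan, index=stacked.index, dtype=object)
    out[any_no] = "no"
    out[any_yes] = "yes"
    return out


# ---------------------------------------------------------------------------
# Dictionary

@dataclass
class SiteRule:
    raw_name: str | None = None
    unit_rule: str = "identity"
    recode_map: dict[str, str] | None = None
    binary_mode: str = "full"
    date_format: str = "iso"


@dataclass
class DictEntry:
    name: str
    source: str
    stage: str
    dtype: str
    description: str = ""
    unit: str = ""
    categories: tuple[str, ...] = ()
    calc: str | None = None           # "bmi" | "multisource" for calculated entries
    inputs: tuple[str, ...] = ()
    sites: dict[str, SiteRule] = field(default_factory=dict)

    @property
    def short(self) -> str:
        return self.name.split("_", 2)[2]

    @property
    def table(self) -> str:
        return SOURCES[self.source]


@dataclass
class DataDictionary:
    entries: dict[str, DictEntry]

    def validate(self, known_sites: list[str] | None = None) -> None:
        errors = []
        for name, entry in self.entries.items():
            if not _NAME_RE.match(name):
                errors.append(f"{name}: violates nomenclature <source>_<r|h|c>_<name>")
                continue
            src, stage, _ = name.split("_", 2)
            if entry.source != src or entry.stage != stage:
                errors.append(f"{name}: source/stage fields disagree with the name")
            if entry.dtype not in DTYPES:
                errors.append(f"{name}: unknown dtype {entry.dtype!r}")
            for site, rule in entry.sites.items():
                if known_sites is not None and site not in known_sites:
                    errors.append(f"{name}: references unknown site {site!r}")
                if rule.unit_rule not in SUPPORTED_UNIT_RULES:
                    errors.append(f"{name}/{site}: unknown unit rule {rule.unit_rule!r}")
                if rule.binary_mode not in BINARY_MODES:
                    errors.append(f"{name}/{site}: unknown binary mode {rule.binary_mode!r}")
                if rule.recode_map and entry.categories and entry.dtype in ("categorical", "binary"):
                    targets = set(entry.categories)
                    for raw, cat in rule.recode_map.items():
                        if cat not in targets:
                            errors.append(
                                f"{name}/{site}: recode target {cat!r} for {raw!r} "
                                f"outside declared categories"
                            )
            if entry.calc and not entry.inputs:
                errors.append(f"{name}: calculated entry without inputs")
        if errors:
            raise DictionaryError("dictionary validation failed:\n" + "\n".join(errors))

    def for_table(self, table: str) -> list[DictEntry]:
        return [e for e in self.entries.values() if e.table == table and e.stage in ("h", "c")]

    def sites(self) -> list[str]:
        seen: list[str] = []
        for entry in self.entries.values():
            for site in entry.sites:
                if site not in seen:
                    seen.append(site)
        return seen

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {}
        for name, e in self.entries.items():
            doc[name] = {
                "source": e.source,
                "stage": e.stage,
                "dtype": e.dtype,
                "description": e.description,
                "unit": e.unit,
                "categories": list(e.categories),
                "calc": e.calc,
                "inputs": list(e.inputs),
                "sites": {s: asdict(r) for s, r in e.sites.items()},
            }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_dict(cls, doc: dict) -> "DataDictionary":
        entries = {}
        for name, raw in doc.items():
            if name in entries:
                raise DictionaryError(f"duplicate harmonised name {name}")
            sites = {
                s: SiteRule(**{k: v for k, v in r.items()})
                for s, r in (raw.get("sites") or {}).items()
            }
            entries[name] = DictEntry(
                name=name,
                source=raw.get("source", name.split("_", 1)[0]),
                stage=raw.get("stage", name.split("_", 2)[1] if "_" in name else ""),
                dtype=raw.get("dtype", "text"),
                description=raw.get("description", ""),
                unit=raw.get("unit", ""),
                categories=tuple(raw.get("categories") or ()),
                calc=raw.get("calc"),
                inputs=tuple(raw.get("inputs") or ()),
                sites=sites,
            )
        return cls(entries)


def load_dictionary(path: str | Path, known_sites: list[str] | None = None) -> DataDictionary:
    """Load and validate a YAML data dictionary."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise DictionaryError("dictionary file must be a mapping of entries")
    dictionary = DataDictionary.from_dict(doc)
    dictionary.validate(known_sites)
    return dictionary


# ---------------------------------------------------------------------------
# Audit trail

@dataclass
class AuditRecord:
    seq: int
    site: str
    table: str
    column: str
    op: str            # "transform" records are replayable; others informational
    rows_affected: int
    params: dict = field(default_factory=dict)
    detail: str = ""


@dataclass
class AuditTrail:
    records: list[AuditRecord] = field(default_factory=list)

    def transforms(self) -> list[AuditRecord]:
        return [r for r in self.records if r.op == "transform"]

    def notes(self, op: str | None = None) -> list[AuditRecord]:
        out = [r for r in self.records if r.op != "transform"]
        return [r for r in out if r.op == op] if op else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seq": r.seq,
                    "site": r.site,
                    "table": r.table,
                    "column": r.column,
                    "op": r.op,
                    "rows_affected": r.rows_affected,
                    "detail": r.detail,
                    "params": json.dumps(r.params, default=str),
                }
                for r in self.records
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Engine

def _entry_params(entry: DictEntry, rule: SiteRule | None) -> dict:
    return {
        "name": entry.name,
        "source": entry.source,
        "dtype": entry.dtype,
        "categories": list(entry.categories),
        "calc": entry.calc,
        "inputs": list(entry.inputs),
        "raw_name": rule.raw_name if rule else None,
        "unit_rule": rule.unit_rule if rule else "identity",
        "recode_map": dict(rule.recode_map) if (rule and rule.recode_map) else None,
        "binary_mode": rule.binary_mode if rule else "full",
    }


def _apply_params(df: pd.DataFrame, params: dict):
    """Apply one dictionary entry to a table. Returns (df, rows_affected, notes).

    Used identically by the engine and by audit replay, which is what makes
    replay bit-identical by construction.
    """
    name = params["name"]
    notes: list[tuple[str, str, int]] = []  # (op, detail, count)

    if params["calc"] == "bmi":
        w_col, h_col = params["inputs"]
        if w_col not in df.columns or h_col not in df.columns:
            df[name] = np.nan
            return df, 0, [("missing_source", f"inputs {params['inputs']} absent", 0)]
        values = calculate_bmi(df[w_col].to_numpy(), df[h_col].to_numpy())
        n_bad = int(((pd.to_numeric(df[h_col], errors="coerce") <= 0)).sum())
        if n_bad:
            notes.append(("unparseable", "non-positive height set missing in BMI", n_bad))
        df[name] = values
        return df, int(np.isfinite(values).sum()), notes

    if params["calc"] == "multisource":
        cols = [c for c in params["inputs"] if c in df.columns]
        if len(cols) < 2:
            df[name] = np.nan
            return df, 0, [("missing_source", f"inputs {params['inputs']} absent", 0)]
        merged = merge_multisource(*[df[c] for c in cols])
        df[name] = merged
        return df, int(merged.notna().sum()), notes

    short = name.split("_", 2)[2]
    raw_kept = f"{params['source']}_r_{short}"
    src = None
    if params["raw_name"] and params["raw_name"] in df.columns:
        src = params["raw_name"]
    elif raw_kept in df.columns:
        src = raw_kept
    if src is None:
        df[name] = np.nan
        return df, 0, [("missing_source", f"raw column {params['raw_name']!r} absent", 0)]
    if src != raw_kept:
        df.rename(columns={src: raw_kept}, inplace=True)
    series = df[raw_kept]

    dtype = params["dtype"]
    if dtype == "date":
        values = parse_date_column(series)
    elif dtype == "text":
        values = series.map(lambda v: np.nan if pd.isna(v) else str(v))
    elif dtype in ("categorical", "binary"):
        recoded, unmapped = recode_categorical(series, params["recode_map"] or {})
        for raw_value, count in sorted(unmapped.items()):
            notes.append(("unmapped_value", raw_value, count))
        if dtype == "binary":
            recoded = apply_binary_rule(recoded, params["binary_mode"])
        values = recoded
    else:  # continuous
        work = series
        if params["recode_map"]:
            mapped = []
            for v in work:
                key = None if pd.isna(v) else str(v).strip()
                mapped.append(params["recode_map"].get(key, v) if key else v)
            work = pd.Series(mapped, index=series.index, dtype=object)
        converted, n_fail, fails = [], 0, {}
        for v in work:
            value, ok = convert_units(v, params["unit_rule"])
            converted.append(value)
            if not ok:
                n_fail += 1
                key = str(v).strip()
                fails[key] = fails.get(key, 0) + 1
        for raw_value, count in sorted(fails.items()):
            notes.append(("unparseable", raw_value, count))
        values = pd.Series(converted, index=series.index, dtype=float)

    df[name] = values
    return df, int(pd.Series(values).notna().sum()), notes


def harmonise_bundle(
    bundle: RecordBundle, dictionary: DataDictionary
) -> tuple[RecordBundle, AuditTrail]:
    """Realise every dictionary entry for this site's bundle.

    Harmonised (``h``) entries run before calculated (``c``) entries so that
    calculations see canonical inputs. Raw columns are retained under their
    ``_r_`` names, untouched; re-running on the output is a fixed point.
    """
    site = bundle.site_code
    out = bundle.copy(stage="harmonised")
    trail = AuditTrail()
    seq = 0
    for table_name, df in out.tables().items():
        if df.empty:
            continue
        entries = dictionary.for_table(table_name)
        ordered = [e for e in entries if not e.calc] + [e for e in entries if e.calc]
        for entry in ordered:
            rule = entry.sites.get(site)
            if rule is None and not entry.calc:
                rule = SiteRule(raw_name=None)
            params = _entry_params(entry, rule)
            df, rows, notes = _apply_params(df, params)
            seq += 1
            trail.records.append(
                AuditRecord(
                    seq=seq,
                    site=site,
                    table=table_name,
                    column=entry.name,
                    op="transform",
                    rows_affected=rows,
                    params=params,
                )
            )
            for op, detail, count in notes:
                seq += 1
                trail.records.append(
                    AuditRecord(
                        seq=seq,
                        site=site,
                        table=table_name,
                        column=entry.name,
                        op=op,
                        rows_affected=count,
                        detail=detail,
                    )
                )
        setattr(out, table_name, df)
    return out, trail


def replay_trail(raw_bundle: RecordBundle, trail: AuditTrail) -> RecordBundle:
    """Re-apply a recorded audit trail to a raw bundle.

    The transform records embed their full rule parameters, so replay needs
    no dictionary and reproduces the engine output exactly.
    """
    out = raw_bundle.copy(stage="harmonised")
    for record in sorted(trail.transforms(), key=lambda r: r.seq):
        df = getattr(out, record.table)
        if df.empty:
            continue
        df, _, _ = _apply_params(df, record.params)
        setattr(out, record.table, df)
    return out
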
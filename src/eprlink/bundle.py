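"""Record bundle: the four per-site EPR extracts at a named pipeline stage.

A bundle carries the maternity spine (wide, one row per baby) and the three
satellite datasets (neonatal wide; ultrasound and hospital-activity long,
one row per scan / appointment / admission) for a single maternity site.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

STAGES = ("raw", "pseudonymised", "harmonised", "linked", "cleaned", "imputed")
TABLE_NAMES = ("maternity", "neonatal", "ultrasound", "activity")

#: The identifiable quadruple collected on site and destroyed at pseudonymisation.
IDENTIFIER_COLUMNS = ("nhs_number", "hospital_number", "dob", "postcode")

_EXCEL_EPOCH = dt.date(1899, 12, 30)


class ConfigurationError(ValueError):
    """Raised when a configuration object or file fails validation."""


@dataclass
class RecordBundle:
    site_code: str
    stage: str
    maternity: pd.DataFrame
    neonatal: pd.DataFrame
    ultrasound: pd.DataFrame
    activity: pd.DataFrame

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def copy(self, stage: str | None = None) -> "RecordBundle":
        return replace(
            self,
            stage=stage or self.stage,
            **{name: df.copy() for name, df in self.tables().items()},
        )

    def write_csv(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in self.tables().items():
            path = directory / f"{self.site_code}_{name}.csv"
            df.to_csv(path, index=False)
            paths.append(path)
        return paths

    def write_xlsx(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, df in self.tables().items():
                df.to_excel(writer, sheet_name=name, index=False)
        return path

    @classmethod
    def read_csv(cls, directory: str | Path, site_code: str, stage: str) -> "RecordBundle":
        directory = Path(directory)
        tables = {}
        for name in TABLE_NAMES:
            path = directory / f"{site_code}_{name}.csv"
            tables[name] = pd.read_csv(path) if path.exists() else pd.DataFrame()
        return cls(site_code=site_code, stage=stage, **tables)


def parse_date_any(value) -> dt.date | None:
    """Parse a date rendered in any of the source-system styles.

    Accepts ISO (``2017-10-10``), day-first (``10/10/2017``), spreadsheet
    serial numbers (days since 1899-12-30) and native date objects. Returns
    ``None`` for missing or unparseable input.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, (int, float)):
        serial = int(value)
        if 20000 <= serial <= 80000:  # 1954..2118: plausible spreadsheet serials
            return _EXCEL_EPOCH + dt.timedelta(days=serial)
        return None
    text = str(value).strip()
    if not text:
        return None
    if re.fullmatch(r"\d{4}-\d{2}-\d{2}", text):
        try:
            return dt.date.fromisoformat(text)
        except ValueError:
            return None
    m = re.fullmatch(r"(\d{1,2})/(\d{1,2})/(\d{4})", text)
    if m:
        day, month, year = int(m.group(1)), int(m.group(2)), int(m.group(3))
        try:
            return dt.date(year, month, day)
        except ValueError:
            return None
    if re.fullmatch(r"\d{5}", text):
        return _EXCEL_EPOCH + dt.timedelta(days=int(text))
    return None


def parse_date_column(series: pd.Series) -> pd.Series:
    """Vectorised :func:`parse_date_any`, returning datetime64[ns]."""
    return pd.to_datetime(series.map(parse_date_any))


def to_excel_serial(date: dt.date) -> int:
    return (date - _EXCEL_EPOCH).days
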
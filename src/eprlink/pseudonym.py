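"""Study-ID pseudonymisation, demographic derivation and identifier stripping.

The automated study ID is a 20-character string: 19 decimal digits followed
by one alphabetic check character. The digits are the decimal rendering of a
salt-keyed cryptographic digest of the woman's NHS number and date of birth,
so the same woman always receives the same ID (across pregnancies, because
the delivery date does not enter the function) while the salt acts as the
seeded random component. The check character is a weighted checksum
(weights 1..19, sum modulo 26, mapped to A-Z) over the 19 body characters.

Women missing either input are routed to a manually issued ID occupying a
disjoint namespace (first character ``M``); one manual ID denotes one
pregnancy and is never reused across a woman's births.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import IDENTIFIER_COLUMNS, ConfigurationError, RecordBundle, parse_date_any
from .nhs import generate_nhs_numbers, is_valid_nhs_number

logger = logging.getLogger(__name__)

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_BODY_LEN = 19
# Positional weights for the check character: 19 distinct values all coprime
# to 26 (odd, not divisible by 13), so any single-digit substitution shifts
# the checksum by weight*delta != 0 (mod 26) and is always detected.
_CHECK_WEIGHTS = [w for w in range(1, 44, 2) if w % 13 != 0][:19]
_MANUAL_COUNTER_WIDTH = 14
_AUTOMATED_RE = re.compile(r"^\d{19}[A-Z]$")


class NeedsManualID(ValueError):
    """Signals that a record lacks the identifiers needed for an automated ID."""


@dataclasses.dataclass(frozen=True)
class StudyID:
    value: str
    origin: str  # "automated" | "manual"

    def __post_init__(self) -> None:
        if len(self.value) != 20:
            raise ValueError(f"study ID must be 20 characters, got {len(self.value)}")

    def __str__(self) -> str:
        return self.value


def _char_value(c: str) -> int:
    if c.isdigit():
        return int(c)
    if "A" <= c <= "Z":
        return 10 + ord(c) - ord("A")
    raise ValueError(f"invalid study-ID character {c!r}")


def compute_check_char(body: str) -> str:
    """Check letter over a 19-character body: position-weighted sum mod 26."""
    if len(body) != _BODY_LEN:
        raise ValueError("check character is defined over exactly 19 characters")
    total = sum(w * _char_value(c) for w, c in zip(_CHECK_WEIGHTS, body))
    return _ALPHABET[total % 26]


def verify_check_char(candidate: str) -> bool:
    """True iff ``candidate`` is 20 characters and its check letter verifies."""
    if not isinstance(candidate, str) or len(candidate) != 20:
        return False
    body, check = candidate[:19], candidate[19]
    if check not in _ALPHABET:
        return False
    try:
        return compute_check_char(body) == check
    except ValueError:
        return False


def make_study_id(nhs_number: str | None, dob, site_salt: str) -> StudyID:
    """Deterministic automated study ID from (NHS number, DOB, salt).

    Hospital number and postcode deliberately never enter the function. The
    raised :class:`NeedsManualID` must be handled by issuing a manual ID —
    the function never fabricates an ID from partial identifiers.
    """
    dob_date = parse_date_any(dob)
    if not nhs_number or not isinstance(nhs_number, str) or dob_date is None:
        raise NeedsManualID("NHS number and DOB are both required for an automated ID")
    if not is_valid_nhs_number(nhs_number):
        raise NeedsManualID(f"NHS number {nhs_number!r} fails modulus-11 validation")
    digest = hashlib.blake2b(
        f"{nhs_number}|{dob_date.isoformat()}".encode(),
        key=site_salt.encode()[:64],
        digest_size=16,
    ).digest()
    body = f"{int.from_bytes(digest, 'big') % 10**_BODY_LEN:0{_BODY_LEN}d}"
    return StudyID(body + compute_check_char(body), origin="automated")


def make_manual_id(site_code: str, counter: int) -> StudyID:
    """Manual study ID: ``M`` + 4-char site tag + 14-digit counter + check letter."""
    if counter < 1 or counter >= 10**_MANUAL_COUNTER_WIDTH:
        raise ValueError(f"manual counter {counter} outside fixed width")
    site_tag = re.sub(r"[^A-Z0-9]", "", site_code.upper())[:4].ljust(4, "0")
    body = f"M{site_tag}{counter:0{_MANUAL_COUNTER_WIDTH}d}"
    return StudyID(body + compute_check_char(body), origin="manual")


def is_automated_id(value: str) -> bool:
    return bool(_AUTOMATED_RE.match(value)) and verify_check_char(value)


# ---------------------------------------------------------------------------
# Collision simulation

def simulate_collisions(
    n: int,
    dob_range: tuple[dt.date, dt.date],
    dod_range: tuple[dt.date, dt.date],
    seed: int,
    site_salt: str = "collision-simulation",
    scheme=None,
) -> int:
    """Count duplicate study IDs over ``n`` simulated (NHS, DOB, DOD) records.

    Narrow date ranges concentrate duplicate dates and so stress the risk
    that two women share an ID. Returns the number of extra occurrences
    (n minus distinct IDs). ``scheme`` may replace the production ID function
    with a deliberately lossy one for oracle cross-checks.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    ids = generate_identifiers(n, dob_range, seed)
    dod_start, dod_end = dod_range
    if dod_start > dod_end:
        raise ConfigurationError("invalid DOD interval")
    rng = np.random.default_rng(seed + 1)
    offsets = rng.integers(0, (dod_end - dod_start).days + 1, size=n)
    dods = [dod_start + dt.timedelta(days=int(o)) for o in offsets]
    fn = scheme or (lambda nhs, dob, dod: make_study_id(nhs, dob, site_salt).value)
    values = [fn(rec["nhs_number"], rec["dob"], dod) for rec, dod in zip(ids, dods)]
    return len(values) - len(set(values))


def generate_identifiers(n: int, dob_range: tuple[dt.date, dt.date], seed: int) -> list[dict]:
    """n simulated identifier quadruples with distinct valid NHS numbers."""
    start, end = dob_range
    if n < 0 or start > end:
        raise ConfigurationError("invalid count or DOB interval")
    rng = np.random.default_rng(seed)
    numbers = generate_nhs_numbers(n, rng)
    span = (end - start).days + 1
    offsets = rng.integers(0, span, size=n)
    letters = np.array(list("ABCDEFGHJKLMNPRSTUVWXY"))
    records = []
    for i in range(n):
        postcode = (
            f"{rng.choice(letters)}{rng.choice(letters)}{rng.integers(1, 99)}"
            f" {rng.integers(0, 9)}{rng.choice(letters)}{rng.choice(letters)}"
        )
        records.append(
            {
                "nhs_number": numbers[i],
                "hospital_number": f"H{i:07d}",
                "dob": start + dt.timedelta(days=int(offsets[i])),
                "postcode": postcode,
            }
        )
    return records


# ---------------------------------------------------------------------------
# Derivation and stripping

def normalise_postcode(postcode) -> str | None:
    if postcode is None or (isinstance(postcode, float) and pd.isna(postcode)):
        return None
    text = re.sub(r"\s+", "", str(postcode).upper())
    if len(text) < 5:
        return text or None
    return f"{text[:-3]} {text[-3:]}"


def load_postcode_lookup(path: str | Path) -> pd.DataFrame:
    """Postcode -> deprivation lookup (columns postcode, imd, lsoa, msoa)."""
    lookup = pd.read_csv(path, dtype={"postcode": str})
    required = {"postcode", "imd", "lsoa", "msoa"}
    missing = required - set(lookup.columns)
    if missing:
        raise ConfigurationError(f"postcode lookup missing columns {sorted(missing)}")
    lookup["postcode"] = lookup["postcode"].map(normalise_postcode)
    return lookup.drop_duplicates("postcode").set_index("postcode")


def age_at_delivery(dob: dt.date, dod: dt.date) -> int:
    """Completed years between maternal DOB and the neonate's delivery date."""
    years = dod.year - dob.year
    if (dod.month, dod.day) < (dob.month, dob.day):
        years -= 1
    return years


@dataclasses.dataclass
class PseudonymisationResult:
    bundle: RecordBundle
    key_file: pd.DataFrame
    n_automated: int
    n_manual: int
    warnings: list[str]


def derive_and_strip(
    bundle: RecordBundle,
    site_salt: str,
    postcode_lookup: pd.DataFrame,
    key_sink: str | Path | None = None,
    dod_column: str = "dod",
    created_at: str = "",
) -> PseudonymisationResult:
    """Pseudonymise a raw bundle: assign study IDs, derive age/deprivation,
    and remove all four identifier columns from every table.

    The key file (study ID against the identifiable quadruple) is written
    only to ``key_sink`` and must never travel with the de-identified bundle.
    Rows lacking NHS number or DOB are routed through manual IDs, one per
    pregnancy (hospital number + delivery date group).
    """
    out = bundle.copy(stage="pseudonymised")
    warnings: list[str] = []
    manual_counter = 0
    manual_cache: dict[tuple, str] = {}
    auto_cache: dict[tuple, str] = {}
    key_rows: list[dict] = []
    n_manual_ids = 0

    def assign(row, pregnancy_key) -> str:
        nonlocal manual_counter, n_manual_ids
        nhs = row.get("nhs_number")
        nhs = None if (not isinstance(nhs, str) or not nhs) else nhs
        dob = parse_date_any(row.get("dob"))
        if nhs is not None and dob is not None:
            cache_key = (nhs, dob)
            if cache_key not in auto_cache:
                sid = make_study_id(nhs, dob, site_salt).value
                auto_cache[cache_key] = sid
                key_rows.append(
                    {
                        "study_id": sid,
                        "nhs_number": nhs,
                        "hospital_number": row.get("hospital_number"),
                        "dob": dob.isoformat(),
                        "postcode": row.get("postcode"),
                        "site_code": bundle.site_code,
                        "created_at": created_at,
                    }
                )
            return auto_cache[cache_key]
        if pregnancy_key not in manual_cache:
            manual_counter += 1
            n_manual_ids += 1
            manual_cache[pregnancy_key] = make_manual_id(bundle.site_code, manual_counter).value
        return manual_cache[pregnancy_key]

    for name, df in out.tables().items():
        if df.empty:
            continue
        present = [c for c in IDENTIFIER_COLUMNS if c in df.columns]
        if "nhs_number" not in df.columns:
            raise ConfigurationError(f"{name} table carries no identifiers to pseudonymise")
        preg_dates = df[dod_column] if (name == "maternity" and dod_column in df.columns) else None
        study_ids = []
        for idx, row in df.iterrows():
            preg_key = (
                ("mat", row.get("hospital_number"), str(preg_dates.loc[idx]))
                if preg_dates is not None
                else (name, idx)
            )
            study_ids.append(assign(row, preg_key))
        df.insert(0, "study_id", study_ids)

        if name == "maternity":
            dobs = df["dob"].map(parse_date_any) if "dob" in df.columns else None
            dods = df[dod_column].map(parse_date_any) if dod_column in df.columns else None
            if dobs is not None and dods is not None:
                df["age_at_delivery"] = [
                    age_at_delivery(b, d) if (b and d) else np.nan for b, d in zip(dobs, dods)
                ]
            pcs = df["postcode"].map(normalise_postcode) if "postcode" in df.columns else None
            if pcs is not None:
                hits = pcs.map(lambda p: p in postcode_lookup.index if p else False)
                for col in ("imd", "lsoa", "msoa"):
                    df[col] = [
                        postcode_lookup.at[p, col] if hit else np.nan
                        for p, hit in zip(pcs, hits)
                    ]
                n_miss = int((~hits & pcs.notna()).sum())
                if n_miss:
                    msg = f"{n_miss} postcodes absent from lookup; deprivation left missing"
                    warnings.append(msg)
                    logger.warning(msg)
        df.drop(columns=present, inplace=True)
        setattr(out, name, df)

    key_file = pd.DataFrame(
        key_rows,
        columns=["study_id", "nhs_number", "hospital_number", "dob", "postcode", "site_code", "created_at"],
    )
    if key_sink is not None:
        sink = Path(key_sink)
        sink.mkdir(parents=True, exist_ok=True)
        key_file.to_csv(sink / f"{bundle.site_code}_keyfile.csv", index=False)
    return PseudonymisationResult(
        bundle=out,
        key_file=key_file,
        n_automated=len(auto_cache),
        n_manual=n_manual_ids,
        warnings=warnings,
    )


def drop_off_spine(bundle: RecordBundle) -> tuple[RecordBundle, dict[str, int]]:
    """Remove satellite rows whose study ID has no birth on the maternity spine."""
    out = bundle.copy()
    spine = set(out.maternity["study_id"]) if "study_id" in out.maternity.columns else set()
    if not spine:
        logger.warning("maternity spine is empty; all satellite rows will be removed")
    removed = {}
    for name in ("neonatal", "ultrasound", "activity"):
        df = getattr(out, name)
        if df.empty or "study_id" not in df.columns:
            removed[name] = 0
            continue
        keep = df["study_id"].isin(spine)
        removed[name] = int((~keep).sum())
        setattr(out, name, df[keep].reset_index(drop=True))
    return out, removed
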
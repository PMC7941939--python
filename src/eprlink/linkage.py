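"""Deterministic linkage of pregnancy episodes across the four datasets.

Women may have more than one pregnancy at a site during the study, so the
study ID alone does not identify a pregnancy. Episodes are numbered by
appending ``_n`` to the study ID, where n counts a woman's distinct
delivery dates at the site in ascending order; babies of one pregnancy
(multiple births) share an episode.

Satellite rows attach to episodes by three date rules:

* neonatal rows — same study ID and neonatal date of birth within 7 days
  of the mother's date of delivery;
* ultrasound scans and hospital-activity events — same study ID and event
  date inside the closed pregnancy window [EDC, DOD], where the estimated
  date of conception is EDC = date of delivery − gestational age at birth
  + 14 days. Postnatal events are never linked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import ConfigurationError, RecordBundle

logger = logging.getLogger(__name__)

NEONATAL_WINDOW_DAYS = 7


@dataclass
class LinkReport:
    """Per-satellite linkage outcome counts and per-site linkage rates."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for table, c in self.counts.items():
            rows.append({"table": table, **c, "linkage_rate": self.rates.get(table, np.nan)})
        return pd.DataFrame(rows)


def assign_episodes(maternity: pd.DataFrame, dod_column: str = "mat_h_dod") -> pd.DataFrame:
    """Number each woman's pregnancies by ascending delivery date.

    Rows sharing (study_id, DOD) — multiple births — share an episode.
    Rows with missing DOD are flagged unlinkable (``episode_id`` missing)
    and excluded from numbering. Assignment is invariant to input row order.
    """
    if "study_id" not in maternity.columns or dod_column not in maternity.columns:
        raise ConfigurationError("maternity table needs study_id and a DOD column")
    out = maternity.copy()
    dod = pd.to_datetime(out[dod_column])
    n = pd.Series(np.nan, index=out.index)
    for sid, group in out.groupby("study_id", sort=False):
        dates = dod.loc[group.index]
        distinct = sorted(dates.dropna().unique())
        rank = {d: i + 1 for i, d in enumerate(distinct)}
        n.loc[group.index] = [rank.get(d, np.nan) for d in dates]
    out["episode_n"] = n
    out["episode_id"] = [
        f"{sid}_{int(k)}" if not np.isnan(k) else np.nan
        for sid, k in zip(out["study_id"], n)
    ]
    n_unlinkable = int(out["episode_id"].isna().sum())
    if n_unlinkable:
        logger.warning("%d maternity rows lack a delivery date and are unlinkable", n_unlinkable)
    return out


def compute_edc(dod, ga_days):
    """Estimated date of conception: DOD − GA(days) + 14 days, exact calendar
    arithmetic. Missing GA gives missing EDC (row excluded from window linkage)."""
    dod = pd.to_datetime(pd.Series(dod))
    ga = pd.to_numeric(pd.Series(ga_days), errors="coerce")
    bad = ga.notna() & ((ga < 0) | (ga > 330))
    if bad.any():
        raise ConfigurationError("gestational age outside 0..330 days")
    return dod - pd.to_timedelta(ga, unit="D") + pd.Timedelta(days=14)


def _episode_frame(maternity: pd.DataFrame, dod_column: str, ga_column: str | None):
    episodes = (
        maternity.dropna(subset=["episode_id"])
        .drop_duplicates("episode_id")[
            ["study_id", "episode_id", dod_column] + ([ga_column] if ga_column else [])
        ]
        .copy()
    )
    episodes["dod"] = pd.to_datetime(episodes[dod_column])
    if ga_column:
        episodes["edc"] = compute_edc(episodes["dod"], episodes[ga_column]).values
    return episodes


def link_neonatal(
    maternity: pd.DataFrame,
    neonatal: pd.DataFrame,
    dod_column: str = "mat_h_dod",
    neo_dob_column: str = "neo_h_dob",
) -> tuple[pd.DataFrame, LinkReport]:
    """Attach each neonatal row to the episode whose delivery date is within
    7 days of the neonatal date of birth.

    Ties (two candidate episodes — only possible through data error) break
    to the smaller date difference, then the earlier episode, and are
    logged ambiguous.
    """
    episodes = _episode_frame(maternity, dod_column, None)
    out = neonatal.copy()
    out["episode_id"] = pd.Series(np.nan, index=out.index, dtype=object)
    out["link_status"] = "unmatched"
    n_ambiguous = 0
    dob = pd.to_datetime(out[neo_dob_column]) if neo_dob_column in out.columns else None
    ep_by_sid: dict = (
        {sid: g for sid, g in episodes.groupby("study_id", sort=False)} if len(episodes) else {}
    )
    for i in out.index:
        sid = out.at[i, "study_id"]
        d = dob.loc[i] if dob is not None else pd.NaT
        if pd.isna(d) or sid not in ep_by_sid:
            continue
        cands = ep_by_sid[sid]
        diffs = (cands["dod"] - d).abs().dt.days
        ok = diffs <= NEONATAL_WINDOW_DAYS
        if not ok.any():
            continue
        hits = cands[ok]
        if len(hits) > 1:
            n_ambiguous += 1
            order = hits.assign(absdiff=diffs[ok]).sort_values(["absdiff", "dod"])
            chosen = order.iloc[0]
            out.at[i, "link_status"] = "ambiguous"
        else:
            chosen = hits.iloc[0]
            out.at[i, "link_status"] = "matched"
        out.at[i, "episode_id"] = chosen["episode_id"]
    report = _report("neonatal", out, maternity, n_ambiguous)
    return out, report


def link_window(
    maternity: pd.DataFrame,
    events: pd.DataFrame,
    kind: str,
    date_column: str,
    dod_column: str = "mat_h_dod",
    ga_column: str = "mat_h_ga",
) -> tuple[pd.DataFrame, LinkReport]:
    """Attach long-format events to the episode whose closed [EDC, DOD]
    window contains the event date.

    An event inside two windows (a data error) goes to the episode with the
    latest EDC and is logged ambiguous; postnatal events stay unmatched.
    """
    if kind not in ("ultrasound", "activity"):
        raise ConfigurationError("kind must be 'ultrasound' or 'activity'")
    episodes = _episode_frame(maternity, dod_column, ga_column)
    episodes = episodes.dropna(subset=["edc"])
    out = events.copy()
    out["episode_id"] = pd.Series(np.nan, index=out.index, dtype=object)
    out["link_status"] = "unmatched"
    n_ambiguous = 0
    dates = pd.to_datetime(out[date_column]) if date_column in out.columns else None
    ep_by_sid: dict = (
        {sid: g for sid, g in episodes.groupby("study_id", sort=False)} if len(episodes) else {}
    )
    for i in out.index:
        sid = out.at[i, "study_id"]
        d = dates.loc[i] if dates is not None else pd.NaT
        if pd.isna(d) or sid not in ep_by_sid:
            continue
        cands = ep_by_sid[sid]
        ok = (cands["edc"] <= d) & (d <= cands["dod"])
        if not ok.any():
            continue
        hits = cands[ok]
        if len(hits) > 1:
            n_ambiguous += 1
            chosen = hits.sort_values("edc", ascending=False).iloc[0]
            out.at[i, "link_status"] = "ambiguous"
        else:
            chosen = hits.iloc[0]
            out.at[i, "link_status"] = "matched"
        out.at[i, "episode_id"] = chosen["episode_id"]
    report = _report(kind, out, maternity, n_ambiguous)
    return out, report


def _report(table: str, linked: pd.DataFrame, maternity: pd.DataFrame, n_ambiguous: int):
    report = LinkReport()
    n_matched = int((linked["link_status"] == "matched").sum())
    n_unmatched = int((linked["link_status"] == "unmatched").sum())
    report.counts[table] = {
        "matched": n_matched,
        "unmatched": n_unmatched,
        "ambiguous": n_ambiguous,
    }
    spine_eps = maternity["episode_id"].dropna().nunique() if "episode_id" in maternity else 0
    linked_eps = linked.loc[linked["episode_id"].notna(), "episode_id"].nunique()
    report.rates[table] = linked_eps / spine_eps if spine_eps else 0.0
    return report


def assign_neonatal_to_babies(
    maternity: pd.DataFrame,
    neonatal: pd.DataFrame,
    sex_columns: tuple[str, str] = ("mat_h_sex", "neo_h_sex"),
    bw_columns: tuple[str, str] = ("mat_h_bw", "neo_h_bw"),
    order_column: str = "mat_h_birthorder",
) -> pd.DataFrame:
    """Within an episode, pair neonatal rows one-to-one with baby rows.

    Pairing prefers matching sex, then nearest birthweight, then registered
    birth order; residual ambiguity (identical candidates) is logged.
    """
    out = neonatal.copy()
    out["baby_row"] = pd.Series(np.nan, index=out.index, dtype=object)
    mat_sex, neo_sex = sex_columns
    mat_bw, neo_bw = bw_columns
    for ep, neo_group in out.dropna(subset=["episode_id"]).groupby("episode_id"):
        babies = maternity[maternity["episode_id"] == ep]
        taken: set = set()
        for i in neo_group.index:
            best, best_key = None, None
            for j in babies.index:
                if j in taken:
                    continue
                sex_penalty = int(
                    pd.notna(out.at[i, neo_sex])
                    and pd.notna(babies.at[j, mat_sex])
                    and out.at[i, neo_sex] != babies.at[j, mat_sex]
                )
                bw_diff = abs(
                    (out.at[i, neo_bw] if pd.notna(out.at[i, neo_bw]) else 0)
                    - (babies.at[j, mat_bw] if pd.notna(babies.at[j, mat_bw]) else 0)
                )
                order = babies.at[j, order_column] if order_column in babies.columns else 0
                key = (sex_penalty, bw_diff, order if pd.notna(order) else 99)
                if best_key is None or key < best_key:
                    best, best_key = j, key
            if best is not None:
                taken.add(best)
                out.at[i, "baby_row"] = best
    return out


def link_bundle(
    bundle: RecordBundle,
    dod_column: str = "mat_h_dod",
    ga_column: str = "mat_h_ga",
    neo_dob_column: str = "neo_h_dob",
    scan_date_column: str = "uss_h_scandate",
    event_date_column: str = "act_h_eventdate",
) -> tuple[RecordBundle, LinkReport]:
    """Episode assignment plus all three linkage rules over one bundle."""
    out = bundle.copy(stage="linked")
    out.maternity = assign_episodes(out.maternity, dod_column)
    report = LinkReport()
    if not out.neonatal.empty:
        out.neonatal, r = link_neonatal(out.maternity, out.neonatal, dod_column, neo_dob_column)
        out.neonatal = assign_neonatal_to_babies(out.maternity, out.neonatal)
        report.counts.update(r.counts)
        report.rates.update(r.rates)
    if not out.ultrasound.empty:
        out.ultrasound, r = link_window(
            out.maternity, out.ultrasound, "ultrasound", scan_date_column, dod_column, ga_column
        )
        report.counts.update(r.counts)
        report.rates.update(r.rates)
    if not out.activity.empty:
        out.activity, r = link_window(
            out.maternity, out.activity, "activity", event_date_column, dod_column, ga_column
        )
        report.counts.update(r.counts)
        report.rates.update(r.rates)
    else:
        report.counts["activity"] = {"matched": 0, "unmatched": 0, "ambiguous": 0}
        report.rates["activity"] = 0.0
        report.flags.append("no activity extract supplied for this site")
    return out, report


def linkage_report(bundle: RecordBundle, report: LinkReport) -> pd.DataFrame:
    """Human-readable per-table linkage summary for one site."""
    df = report.to_frame()
    df.insert(0, "site", bundle.site_code)
    return df
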
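"""End-to-end orchestration: pseudonymise → QC → harmonise → link →
outliers → impute, with run provenance.

A run is configured by :class:`RunConfig` (sites, trial-phase windows,
paths, seed). The de-identified outputs are written per stage under the
output directory; the key files linking study IDs back to identifiers are
written only to a separate key sink, which must lie outside the output
directory. The two-download workflow is modelled as two runs sharing a key
sink: passing the first run's QC reports to the second run switches the QC
stage to the reduced second-download checklist.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bundle import ConfigurationError
from .harmonise import harmonise_bundle
from .impute import (
    ImputationSpec,
    VarSpec,
    apply_parity_rule,
    compute_outcome_triple,
    impute_outcome_triple,
)
from .linkage import link_bundle, linkage_report
from .pseudonym import derive_and_strip, drop_off_spine, load_postcode_lookup
from .quality import (
    OutlierPolicy,
    QCReport,
    apply_outlier_policy,
    classify_duplicates,
    drop_true_duplicates,
    first_download_checks,
    second_download_checks,
)
from .synthetic import DIALECTS, SiteConfig, build_dictionary, generate_run, make_postcode_lookup

logger = logging.getLogger(__name__)

DEFAULT_KEY_VARS = (
    "mat_h_weight",
    "mat_h_height",
    "mat_h_ethnicity",
    "mat_h_parity",
    "mat_h_sex",
    "mat_h_ga",
    "mat_h_bw",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    sites: list[SiteConfig]
    seed: int
    output_dir: Path
    key_sink: Path
    salt: str = "trial-salt"
    phases: dict[str, tuple[dt.date, dt.date]] = field(default_factory=dict)
    expected_window: tuple[dt.date, dt.date] | None = None
    key_vars: tuple[str, ...] = DEFAULT_KEY_VARS
    impute_m: int = 10
    impute_cycles: int = 5
    lookup_coverage: float = 0.97
    created_at: str = "run"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.key_sink = Path(self.key_sink)
        out = self.output_dir.resolve()
        sink = self.key_sink.resolve()
        if sink == out or out in sink.parents or sink in out.parents:
            raise ConfigurationError("key sink must lie outside the output directory")
        if not self.sites:
            raise ConfigurationError("at least one site is required")
        window = (
            min(c.date_window[0] for c in self.sites),
            max(c.date_window[1] for c in self.sites),
        )
        if self.expected_window is None:
            self.expected_window = window
        if not self.phases:
            # three consecutive phases partitioning the study window
            start, end = window
            third = (end - start) // 3
            self.phases = {
                "pre_randomisation": (start, start + third),
                "washout": (start + third + dt.timedelta(days=1), start + 2 * third),
                "comparison": (start + 2 * third + dt.timedelta(days=1), end),
            }
        _check_phase_windows(self.phases)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())

        def d(x):
            return dt.date.fromisoformat(x)

        sites = []
        for s in doc["sites"]:
            kwargs = dict(s)
            if "date_window" in kwargs:
                kwargs["date_window"] = tuple(d(x) for x in kwargs["date_window"])
            sites.append(SiteConfig(**kwargs))
        phases = {
            name: (d(lo), d(hi)) for name, (lo, hi) in (doc.get("phases") or {}).items()
        }
        return cls(
            sites=sites,
            seed=int(doc["seed"]),
            output_dir=Path(doc["output_dir"]),
            key_sink=Path(doc["key_sink"]),
            salt=doc.get("salt", "trial-salt"),
            phases=phases,
            impute_m=int(doc.get("impute_m", 10)),
            impute_cycles=int(doc.get("impute_cycles", 5)),
        )


def _check_phase_windows(phases: dict[str, tuple[dt.date, dt.date]]) -> None:
    items = sorted(phases.items(), key=lambda kv: kv[1][0])
    for (_, (lo, hi)) in items:
        if lo > hi:
            raise ConfigurationError("phase window start must not exceed end")
    for (_, (_, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
        if lo2 <= hi1:
            raise ConfigurationError("phase windows must not overlap")


def phase_tag(
    records: pd.DataFrame,
    phase_windows: dict[str, tuple[dt.date, dt.date]],
    dod_column: str = "mat_h_dod",
) -> tuple[pd.DataFrame, int]:
    """Label each birth with the trial phase containing its delivery date.

    Births outside every window are excluded; the exclusion count is
    returned alongside the labelled table.
    """
    _check_phase_windows(phase_windows)
    out = records.copy()
    dod = pd.to_datetime(out[dod_column])
    label = pd.Series(None, index=out.index, dtype=object)
    for name, (lo, hi) in phase_windows.items():
        mask = (dod >= pd.Timestamp(lo)) & (dod <= pd.Timestamp(hi))
        label[mask] = name
    out["phase"] = label
    excluded = int(label.isna().sum())
    return out[label.notna()].copy(), excluded


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, prior_qc: dict[str, QCReport] | None = None) -> dict:
    """Execute the full flow on generated site bundles; returns the manifest.

    With ``prior_qc`` supplied (the first run's QC reports keyed by site),
    the QC stage runs the reduced second-download checklist instead.
    """
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "created_at": config.created_at,
        "sites": [c.site_code for c in config.sites],
        "stages": [],
        "files": {},
    }

    def record(stage: str, paths) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["files"][str(Path(p).relative_to(out_dir))] = _sha256(Path(p))

    stage = "generate"
    try:
        generated = generate_run(config.sites, config.seed)
        dictionary = build_dictionary(config.sites)
        lookup_df = make_postcode_lookup(
            [t for _, t in generated.values()], config.seed, config.lookup_coverage
        )
        lookup_path = out_dir / "postcode_lookup.csv"
        lookup_df.to_csv(lookup_path, index=False)
        dict_path = out_dir / "dictionary.yaml"
        dictionary.to_yaml(dict_path)
        paths = [lookup_path, dict_path]
        for site, (bundle, truth) in generated.items():
            paths += bundle.write_csv(out_dir / "raw")
        record(stage, paths)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    lookup = load_postcode_lookup(lookup_path)
    qc_reports: dict[str, QCReport] = {}
    cleaned_sites: list[pd.DataFrame] = []
    qc_stage = "qc_second" if prior_qc else "qc_first"

    for site_config in config.sites:
        site = site_config.site_code
        bundle, truth = generated[site]
        dialect = DIALECTS[site_config.dialect]

        stage = "pseudonymise"
        try:
            result = derive_and_strip(
                bundle,
                site_salt=config.salt,
                postcode_lookup=lookup,
                key_sink=config.key_sink,
                dod_column=dialect.maternity_columns["dod"],
                created_at=config.created_at,
            )
            pseud, removed = drop_off_spine(result.bundle)
            record(stage, pseud.write_csv(out_dir / "pseudonymised"))
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = qc_stage
        try:
            if prior_qc:
                report = second_download_checks(
                    pseud, prior_qc[site], list(config.key_vars), dictionary,
                    config.expected_window,
                )
            else:
                report = first_download_checks(pseud, dictionary, config.expected_window)
            qc_reports[site] = report
            qc_path = out_dir / "qc" / f"{site}_{report.checklist_id}.json"
            qc_path.parent.mkdir(parents=True, exist_ok=True)
            report.to_json(qc_path)
            record(stage, [qc_path])
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = "harmonise"
        try:
            harmonised, trail = harmonise_bundle(pseud, dictionary)
            trail_path = out_dir / "harmonised" / f"{site}_audit_trail.csv"
            trail_path.parent.mkdir(parents=True, exist_ok=True)
            trail.write_csv(trail_path)
            record(stage, harmonised.write_csv(out_dir / "harmonised") + [trail_path])
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = "link"
        try:
            linked, link_rep = link_bundle(harmonised)
            rep_path = out_dir / "linked" / f"{site}_link_report.csv"
            rep_path.parent.mkdir(parents=True, exist_ok=True)
            linkage_report(linked, link_rep).to_csv(rep_path, index=False)
            record(stage, linked.write_csv(out_dir / "linked") + [rep_path])
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = "clean"
        try:
            mat = linked.maternity
            classes = classify_duplicates(
                mat.rename(columns={"mat_h_sex": "sex", "mat_h_bw": "birthweight",
                                    "mat_h_birthorder": "birth_order"}),
                linked.ultrasound.rename(
                    columns={"uss_h_scandate": "scan_date", "uss_h_fetalcount": "fetal_count"}
                ),
                dod_column="mat_h_dod",
            )
            mat, n_dropped = drop_true_duplicates(mat, classes, dod_column="mat_h_dod")
            linked.maternity = mat.reset_index(drop=True)
            cleaned, removals = apply_outlier_policy(linked, OutlierPolicy.consensus_defaults())
            removals_path = out_dir / "cleaned" / f"{site}_outlier_removals.csv"
            removals_path.parent.mkdir(parents=True, exist_ok=True)
            removals.to_csv(removals_path, index=False)
            record(stage, cleaned.write_csv(out_dir / "cleaned") + [removals_path])
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        # per-episode antenatal detection flag for the outcome triple
        mat = cleaned.maternity.copy()
        uss = cleaned.ultrasound
        flagged: set = set()
        if not uss.empty and "uss_h_sgaflag" in uss.columns:
            flagged = set(
                uss.loc[
                    (uss["uss_h_sgaflag"] == "yes") & uss["episode_id"].notna(), "episode_id"
                ]
            )
        mat["sga_scan_flag"] = mat["episode_id"].isin(flagged)
        mat["site"] = site
        mat, n_excluded = phase_tag(mat, config.phases)
        manifest.setdefault("phase_exclusions", {})[site] = n_excluded
        cleaned_sites.append(mat)

    stage = "impute"
    try:
        pooled = pd.concat(cleaned_sites, ignore_index=True)
        pooled["outcome_triple"] = compute_outcome_triple(pooled)
        spec = ImputationSpec(
            variables=[
                VarSpec("mat_h_bw", "continuous", "within_cluster"),
                VarSpec("mat_h_ga", "continuous", "within_cluster"),
                VarSpec("mat_h_sex", "binary", "within_cluster"),
                VarSpec("mat_h_height", "continuous", "across_clusters"),
                VarSpec("mat_h_weight", "continuous", "across_clusters"),
                VarSpec("mat_h_parity", "ordinal", "across_clusters"),
                VarSpec("mat_h_ethnicity", "multinomial", "within_cluster"),
                VarSpec("outcome_triple", "multinomial", "within_cluster"),
            ],
            m=config.impute_m,
            cycles=config.impute_cycles,
        )
        completed = impute_outcome_triple(pooled, spec, seed=config.seed)
        completed = [apply_parity_rule(t) for t in completed]
        long = pd.concat(
            [t.assign(imputation=i + 1) for i, t in enumerate(completed)], ignore_index=True
        )
        imp_dir = out_dir / "imputed"
        imp_dir.mkdir(parents=True, exist_ok=True)
        imp_path = imp_dir / "maternity_imputed_long.csv"
        long.to_csv(imp_path, index=False)
        record(stage, [imp_path])
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["qc_reports"] = qc_reports
    return manifest
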
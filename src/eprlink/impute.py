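"""Multiple imputation by chained equations with trial-specific structure.

The engine produces m completed datasets (default m=10) under the
missing-at-random assumption. Each variable is imputed by a conditional
model given a common predictor set: continuous and ordinal-count variables
by Bayesian linear regression with predictive mean matching (k=5 donors,
so imputed values are always observed values), binary variables by
logistic regression draws, and multi-category variables by multinomial
logistic draws.

Three bespoke behaviours mirror how multi-site perinatal data must be
handled:

* scoping — variables are imputed within cluster (site) wherever possible,
  because case mix and clinical process vary between maternity units;
  variables with sites that recorded nothing at all (classically parity,
  height and weight) must be configured ``across_clusters`` or the engine
  raises, naming the variable and site;
* the three-category primary-outcome variable (SGA detected / SGA not
  detected / not SGA) participates in the chains like any other variable,
  but the analysis outcome is recomputed afterwards from each completed
  dataset's components via a pluggable centile function;
* the parity floor — at a site that records parity only as
  nulliparous/multiparous, an imputed parity of 0 for a woman known to be
  multiparous is replaced by the pre-specified value 1.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .bundle import ConfigurationError
from .centiles import is_sga

FAMILIES = ("continuous", "binary", "multinomial", "ordinal")
SCOPES = ("within_cluster", "across_clusters")

#: Default common predictor set: site, trial phase, the outcome triple and
#: the main maternal/neonatal characteristics.
DEFAULT_PREDICTORS = (
    "site",
    "phase",
    "outcome_triple",
    "mat_c_agedel",
    "mat_h_parity",
    "mat_h_height",
    "mat_h_weight",
    "mat_h_ethnicity",
    "mat_h_ga",
    "mat_h_sex",
)


@dataclass(frozen=True)
class VarSpec:
    name: str
    family: str
    scope: str = "within_cluster"
    predictors: tuple[str, ...] | None = None  # None -> common set minus self

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.scope not in SCOPES:
            raise ConfigurationError(f"unknown scope {self.scope!r}")


@dataclass
class ImputationSpec:
    variables: list[VarSpec]
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    m: int = 10
    cycles: int = 10
    pmm_donors: int = 5
    cluster_col: str = "site"

    def predictors_for(self, var: VarSpec) -> tuple[str, ...]:
        preds = var.predictors if var.predictors is not None else self.predictors
        out = tuple(p for p in preds if p != var.name)
        if not out:
            raise ConfigurationError(f"variable {var.name} has no predictors")
        return out

    def validate(self, table: pd.DataFrame) -> None:
        for var in self.variables:
            if var.name not in table.columns:
                raise ConfigurationError(f"imputation variable {var.name!r} not in table")
            for p in self.predictors_for(var):
                if p not in table.columns:
                    raise ConfigurationError(f"predictor {p!r} (for {var.name}) not in table")
        if self.cluster_col not in table.columns and any(
            v.scope == "within_cluster" for v in self.variables
        ):
            raise ConfigurationError(f"cluster column {self.cluster_col!r} not in table")
        for var in self.variables:
            if var.scope != "within_cluster":
                continue
            for cluster, group in table.groupby(self.cluster_col):
                if group[var.name].isna().all() and len(group):
                    raise ConfigurationError(
                        f"variable {var.name!r} is 100% missing in cluster {cluster!r} "
                        f"but scoped within_cluster; configure it across_clusters"
                    )


# ---------------------------------------------------------------------------
# Design-matrix helpers

def _design(df: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    cols = []
    for p in predictors:
        s = df[p]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(pd.DataFrame({p: pd.to_numeric(s, errors="coerce").fillna(0.0)}))
        else:
            d = pd.get_dummies(s.astype(str), prefix=p, dtype=float)
            if d.shape[1] > 1:
                d = d.iloc[:, 1:]  # reference category
            cols.append(d)
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _drop_constant(X_train: np.ndarray, X_test: np.ndarray):
    keep = np.ptp(X_train, axis=0) > 0
    keep[0] = True
    return X_train[:, keep], X_test[:, keep]


def _bayes_linear_pmm(y, X_train, X_test, rng, donors: int):
    """Draw from an approximate posterior of a linear model and match each
    prediction to the observed value of one of its k nearest neighbours."""
    n, p = X_train.shape
    ridge = 1e-8 * np.eye(p)
    xtx = X_train.T @ X_train + ridge
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (X_train.T @ y)
    resid = y - X_train @ beta_hat
    df_resid = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / df_resid
    sigma2_star = sigma2_hat * df_resid / max(rng.chisquare(df_resid), 1e-9)
    cov = sigma2_star * xtx_inv
    cov = (cov + cov.T) / 2
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        L = np.zeros((p, p))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    pred_train = X_train @ beta_hat
    pred_test = X_test @ beta_star
    k = min(donors, n)
    diffs = np.abs(pred_test[:, None] - pred_train[None, :])
    nearest = np.argpartition(diffs, k - 1, axis=1)[:, :k]
    chosen = nearest[np.arange(len(pred_test)), rng.integers(0, k, size=len(pred_test))]
    return y[chosen]


def _categorical_draw(y, X_train, X_test, rng):
    classes = pd.unique(y)
    if len(classes) == 1:
        return np.repeat(classes[0], len(X_test))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LogisticRegression(max_iter=300)
        model.fit(X_train[:, 1:], y)
        proba = model.predict_proba(X_test[:, 1:])
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(X_test))[:, None]
    idx = (u > cum).sum(axis=1)
    return model.classes_[np.minimum(idx, len(model.classes_) - 1)]


# ---------------------------------------------------------------------------
# Chained-equations engine

def _group_rng(seed: int, imputation: int, cycle: int, var_idx: int, group_key) -> np.random.Generator:
    """Independent stream per (imputation, cycle, variable, cluster).

    Keying streams by cluster identity (not draw order) makes each site's
    within-cluster imputations invariant to how other sites' rows are
    arranged or permuted.
    """
    key = zlib.crc32(str(group_key).encode())
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, imputation, cycle, var_idx, key])
    )


def _var_groups(work: pd.DataFrame, spec: ImputationSpec, var: VarSpec):
    if var.scope == "within_cluster":
        return [(key, g.index) for key, g in work.groupby(spec.cluster_col, sort=False)]
    return [("__all__", work.index)]


def _impute_one(table, spec, masks, seed: int, imputation: int) -> pd.DataFrame:
    work = table.copy()
    # initial fill: random draws from the observed marginal, scope-respecting
    for vi, var in enumerate(spec.variables):
        mask = masks[var.name]
        if not mask.any():
            continue
        for key, idx in _var_groups(work, spec, var):
            g_mask = mask.loc[idx]
            if not g_mask.any():
                continue
            observed = work.loc[idx[~g_mask.to_numpy()], var.name].dropna().to_numpy()
            rng = _group_rng(seed, imputation, 0, vi, key)
            work.loc[idx[g_mask.to_numpy()], var.name] = rng.choice(
                observed, size=int(g_mask.sum()), replace=True
            )

    for cycle in range(1, spec.cycles + 1):
        for vi, var in enumerate(spec.variables):
            mask = masks[var.name]
            if not mask.any():
                continue
            preds = spec.predictors_for(var)
            for key, idx in _var_groups(work, spec, var):
                g_mask = mask.loc[idx]
                if not g_mask.any():
                    continue
                rng = _group_rng(seed, imputation, cycle, vi, key)
                g = work.loc[idx]
                X = _design(g, preds)
                X_train, X_test = X[~g_mask.to_numpy()], X[g_mask.to_numpy()]
                X_train, X_test = _drop_constant(X_train, X_test)
                if var.family in ("continuous", "ordinal"):
                    y = pd.to_numeric(g.loc[~g_mask, var.name], errors="coerce").to_numpy(float)
                    drawn = _bayes_linear_pmm(y, X_train, X_test, rng, spec.pmm_donors)
                else:
                    y = g.loc[~g_mask, var.name].astype(str).to_numpy()
                    drawn = _categorical_draw(y, X_train, X_test, rng)
                work.loc[idx[g_mask.to_numpy()], var.name] = drawn
    return work


def mice_impute(table: pd.DataFrame, spec: ImputationSpec, seed: int) -> list[pd.DataFrame]:
    """m completed copies of ``table``; observed cells identical across all m."""
    spec.validate(table)
    masks = {v.name: table[v.name].isna() for v in spec.variables}
    for var in spec.variables:
        if masks[var.name].all() and len(table):
            raise ConfigurationError(f"variable {var.name!r} has no observed values at all")
    if not any(m.any() for m in masks.values()):
        return [table.copy() for _ in range(spec.m)]
    completed = []
    for k in range(1, spec.m + 1):
        done = _impute_one(table, spec, masks, seed, k)
        for var in spec.variables:  # observed-cell immutability, enforced
            observed = ~masks[var.name]
            done.loc[observed, var.name] = table.loc[observed, var.name]
        completed.append(done)
    return completed


# ---------------------------------------------------------------------------
# Outcome triple and parity rule

OUTCOME_CATEGORIES = ("SGA_detected", "SGA_not_detected", "not_SGA")


def compute_outcome_triple(
    table: pd.DataFrame,
    centile_fn=None,
    bw_col: str = "mat_h_bw",
    ga_col: str = "mat_h_ga",
    sex_col: str = "mat_h_sex",
    detected_col: str = "sga_scan_flag",
) -> pd.Series:
    """Three-category primary outcome from its components.

    ``centile_fn(birthweight_g, ga_days, male) -> bool`` classifies SGA;
    the default is the synthetic stand-in centile model. A baby is
    ``SGA_detected`` when SGA at birth and flagged on an antenatal scan.
    Rows with a missing component give a missing outcome.
    """
    centile_fn = centile_fn or is_sga
    bw = pd.to_numeric(table[bw_col], errors="coerce")
    ga = pd.to_numeric(table[ga_col], errors="coerce")
    male = table[sex_col].astype(str) == "male"
    detected = (
        table[detected_col].fillna(False).astype(bool)
        if detected_col in table.columns
        else pd.Series(False, index=table.index)
    )
    sga = pd.Series(
        np.asarray(centile_fn(bw.fillna(0).to_numpy(), ga.fillna(280).to_numpy(),
                              male.to_numpy())),
        index=table.index,
    )
    out = pd.Series(np.nan, index=table.index, dtype=object)
    ok = bw.notna() & ga.notna() & table[sex_col].notna()
    out[ok & ~sga] = "not_SGA"
    out[ok & sga & detected] = "SGA_detected"
    out[ok & sga & ~detected] = "SGA_not_detected"
    return out


def impute_outcome_triple(
    table: pd.DataFrame,
    spec: ImputationSpec,
    seed: int,
    centile_fn=None,
    bw_col: str = "mat_h_bw",
    ga_col: str = "mat_h_ga",
    sex_col: str = "mat_h_sex",
    detected_col: str = "sga_scan_flag",
) -> list[pd.DataFrame]:
    """Run the chains with the outcome triple as participant, then recompute
    the analysis outcome from each completed dataset's components.

    The chained triple serves as a predictor during imputation; the final
    ``outcome_triple`` column in each returned table is recomputed via
    ``centile_fn`` and overwrites the chained draw.
    """
    if centile_fn is None:
        centile_fn = is_sga
    if "outcome_triple" not in table.columns:
        table = table.copy()
        table["outcome_triple"] = compute_outcome_triple(
            table, centile_fn, bw_col, ga_col, sex_col, detected_col
        )
    completed = mice_impute(table, spec, seed)
    out = []
    for done in completed:
        for col in (bw_col, ga_col, sex_col):
            if done[col].isna().any():
                raise AssertionError(
                    f"outcome component {col} still missing after imputation; "
                    f"add it to the imputation spec"
                )
        done = done.copy()
        done["outcome_triple"] = compute_outcome_triple(
            done, centile_fn, bw_col, ga_col, sex_col, detected_col
        )
        out.append(done)
    return out


def apply_parity_rule(
    completed: pd.DataFrame,
    parity_col: str = "mat_h_parity",
    multip_col: str = "mat_h_multip",
) -> pd.DataFrame:
    """Replace imputed parity 0 with the pre-specified value 1 for women
    known to be multiparous; all other rows untouched."""
    out = completed.copy()
    multip = out[multip_col].astype(str) == "yes"
    parity = pd.to_numeric(out[parity_col], errors="coerce")
    out.loc[multip & (parity == 0), parity_col] = 1.0
    return out


# ---------------------------------------------------------------------------
# Observed vs imputed comparison

def compare_observed_imputed(
    observed: pd.DataFrame,
    completed_tables: list[pd.DataFrame],
    grouping: list[str],
    continuous: list[str] = (),
    categorical: list[str] = (),
) -> pd.DataFrame:
    """Side-by-side summary statistics of observed and pooled imputed data.

    Continuous variables report median [IQR]; categorical variables report
    per-category percentages. Imputed statistics are computed per completed
    dataset and averaged over the m imputations.
    """
    rows = []
    group_iter = observed.groupby(grouping) if grouping else [((), observed)]
    for key, obs_group in group_iter:
        key = key if isinstance(key, tuple) else (key,)
        imp_groups = [
            (t.groupby(grouping).get_group(key) if grouping else t) for t in completed_tables
        ]
        for var in continuous:
            obs = pd.to_numeric(obs_group[var], errors="coerce").dropna()
            obs_stats = np.percentile(obs, [50, 25, 75]) if len(obs) else [np.nan] * 3
            imp_stats = np.mean(
                [
                    np.percentile(pd.to_numeric(g[var], errors="coerce").dropna(), [50, 25, 75])
                    for g in imp_groups
                ],
                axis=0,
            )
            rows.append(
                {
                    **dict(zip(grouping, key)),
                    "variable": var,
                    "category": "",
                    "observed": f"{obs_stats[0]:.2f} [{obs_stats[1]:.2f}, {obs_stats[2]:.2f}]",
                    "imputed": f"{imp_stats[0]:.2f} [{imp_stats[1]:.2f}, {imp_stats[2]:.2f}]",
                    "observed_median": float(obs_stats[0]),
                    "imputed_median": float(imp_stats[0]),
                }
            )
        for var in categorical:
            cats = sorted(set(obs_group[var].dropna().astype(str)))
            for cat in cats:
                obs_pct = 100 * (obs_group[var].astype(str) == cat).sum() / max(
                    obs_group[var].notna().sum(), 1
                )
                imp_pct = np.mean(
                    [100 * (g[var].astype(str) == cat).mean() for g in imp_groups]
                )
                rows.append(
                    {
                        **dict(zip(grouping, key)),
                        "variable": var,
                        "category": cat,
                        "observed": f"{obs_pct:.1f}%",
                        "imputed": f"{imp_pct:.1f}%",
                        "observed_median": float(obs_pct),
                        "imputed_median": float(imp_pct),
                    }
                )
    return pd.DataFrame(rows)
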
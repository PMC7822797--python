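"""Difference-in-differences estimators with cluster-robust inference.

Two estimators share this module:

* ``fit_did_fe`` — the panel fixed-effects DiD over all waves,
  y_it = a + b*policy_it + year dummies + facility effect + e_it,
  estimated by the within transformation (facility demeaning).
* ``fit_did_2period`` — the two-period covariate-adjusted DiD,
  y_it = a + b*acc_i + g*d_post + delta*(acc_i x d_post) + covariates + e_it,
  where delta is the effect of interest.

Standard errors are cluster-robust (sandwich with within-cluster score
outer products) with the G/(G-1) x (N-1)/(N-K) small-sample factor;
p-values use a t reference with G-1 degrees of freedom, G = number of
clusters. Clustering defaults to the district, the level at which the
rollout was targeted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .errors import NoIdentifyingVariation
from .synthetic_data import INDICATOR_COLUMNS, STAFF_CATEGORIES

#: reference levels for categorical covariates, so coefficients are
#: comparable across runs
REFERENCE_LEVELS = {"building_condition": "bad", "region": "fully-urban"}


@dataclass
class EffectEstimate:
    """A treatment-effect result in percentage points."""

    outcome: str
    estimator: str
    estimate: float
    se: float
    t_stat: float
    p_value: float
    n_obs: int
    n_clusters: int
    period: str = ""
    covariate_set: str = ""
    detail: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("outcome", "estimator", "estimate", "se", "t_stat", "p_value",
              "n_obs", "n_clusters", "period", "covariate_set")}
        return d


def _drop_collinear(X: np.ndarray, names: list[str], keep_first: int = 0,
                    warnings_out: list | None = None) -> tuple[np.ndarray, list[str]]:
    """Remove linearly dependent columns via pivoted QR, never touching the
    first ``keep_first`` columns (the terms of interest)."""
    n, k = X.shape
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank == k:
        return X, names
    keep = sorted(piv[:rank])
    protected = [i for i in range(keep_first) if i not in keep]
    if protected:
        raise NoIdentifyingVariation(
            f"term(s) of interest collinear with the rest of the design: {[names[i] for i in protected]}"
        )
    dropped = [names[i] for i in range(k) if i not in keep]
    if warnings_out is not None:
        warnings_out.extend(dropped)
    return X[:, keep], [names[i] for i in keep]


def cluster_robust_cov(X: np.ndarray, resid: np.ndarray, cluster_ids: np.ndarray,
                       k_params: int | None = None) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of OLS coefficients.

    Sums score outer products within clusters; applies the small-sample
    factor G/(G-1) x (N-1)/(N-K). ``k_params`` overrides K when the design
    absorbs additional parameters (e.g. demeaned fixed effects)."""
    cluster_ids = np.asarray(cluster_ids)
    groups = pd.unique(cluster_ids)
    G = len(groups)
    if G < 2:
        raise ValueError("need >= 2 clusters for cluster-robust covariance")
    n, k = X.shape
    K = k if k_params is None else k_params
    XtX_inv = np.linalg.pinv(X.T @ X)
    meat = np.zeros((k, k))
    order = np.argsort(cluster_ids, kind="stable")
    Xs, us, cs = X[order], resid[order], cluster_ids[order]
    boundaries = np.flatnonzero(np.r_[True, cs[1:] != cs[:-1], True])
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        s = Xs[a:b].T @ us[a:b]
        meat += np.outer(s, s)
    c = (G / (G - 1)) * ((n - 1) / max(n - K, 1))
    return c * XtX_inv @ meat @ XtX_inv


def _ols_cluster(X: np.ndarray, y: np.ndarray, clusters: np.ndarray,
                 k_params: int | None = None) -> tuple[np.ndarray, np.ndarray, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    V = cluster_robust_cov(X, resid, clusters, k_params=k_params)
    return beta, V, len(pd.unique(clusters))


def _demean_by(df: pd.DataFrame, cols: list[str], by: str) -> pd.DataFrame:
    out = df.copy()
    out[cols] = df[cols] - df.groupby(by)[cols].transform("mean")
    return out


def fit_did_fe(panel: pd.DataFrame, outcome: str,
               cluster_col: str = "district_id") -> EffectEstimate:
    """Panel fixed-effects DiD: coefficient on ``policy`` after facility
    demeaning, with year dummies.

    Uses every (facility, wave) cell with a non-missing outcome (unbalanced
    within-estimator). Raises :class:`NoIdentifyingVariation` when no
    facility changes treatment status over the sample.
    """
    pc = f"pct_{outcome}" if f"pct_{outcome}" in panel.columns else outcome
    cols = ["facility_id", "wave", "policy", pc]
    if cluster_col in panel.columns:
        cols.append(cluster_col)
    df = panel[cols].dropna(subset=[pc]).copy()
    if df["facility_id"].nunique() < 2 or df["wave"].nunique() < 2:
        raise ValueError("panel must cover >= 2 facilities and >= 2 waves with data")
    if not (df.groupby("facility_id")["policy"].nunique() > 1).any():
        raise NoIdentifyingVariation("policy has no within-facility variation: effect not identified")

    waves = sorted(df["wave"].unique())
    year_cols = []
    for w in waves[1:]:
        cname = f"year_{w}"
        df[cname] = (df["wave"] == w).astype(float)
        year_cols.append(cname)
    df["policy"] = df["policy"].astype(float)
    dm = _demean_by(df, ["policy", pc, *year_cols], "facility_id")

    names = ["policy", *year_cols]
    X = dm[names].to_numpy()
    y = dm[pc].to_numpy()
    X, names = _drop_collinear(X, names, keep_first=1)
    clusters = df[cluster_col].to_numpy() if cluster_col in df.columns else df["facility_id"].to_numpy()
    # absorbed facility effects are not counted in K: the cluster correction
    # follows the within-estimator convention (scores are cluster-level)
    beta, V, G = _ols_cluster(X, y, clusters, k_params=X.shape[1])

    est, se = float(beta[0]), float(np.sqrt(V[0, 0]))
    t = est / se if se > 0 else np.nan
    p = 2 * scipy.stats.t.sf(abs(t), G - 1) if np.isfinite(t) else np.nan
    waves_span = f"{waves[0]}-{waves[-1]}"
    return EffectEstimate(
        outcome=outcome, estimator="did_fe", estimate=est, se=se, t_stat=t,
        p_value=float(p), n_obs=len(df), n_clusters=G, period=waves_span,
        covariate_set="year dummies + facility FE",
        detail={"year_coefficients": {n: float(b) for n, b in zip(names[1:], beta[1:])}},
    )


def _covariate_design(df: pd.DataFrame, facility_covariates: bool,
                      district_covariates: bool) -> tuple[np.ndarray, list[str]]:
    blocks, names = [], []

    def add_numeric(col):
        blocks.append(df[col].to_numpy(dtype=float)[:, None])
        names.append(col)

    def add_categorical(col):
        ref = REFERENCE_LEVELS.get(col)
        for level in sorted(df[col].dropna().unique()):
            if level == ref:
                continue
            blocks.append((df[col] == level).to_numpy(dtype=float)[:, None])
            names.append(f"{col}[{level}]")

    if facility_covariates:
        for c in STAFF_CATEGORIES:
            col = f"staff_{c}"
            if col in df.columns:
                add_numeric(col)
        if "catchment_population" in df.columns:
            add_numeric("catchment_population")
        if "building_condition" in df.columns:
            add_categorical("building_condition")
    if district_covariates:
        for col in INDICATOR_COLUMNS:
            if col in df.columns:
                add_numeric(col)
        if "region" in df.columns:
            add_categorical("region")
    if not blocks:
        return np.empty((len(df), 0)), []
    return np.hstack(blocks), names


def fit_did_2period(
    panel: pd.DataFrame,
    baseline_wave: int,
    followup_wave: int,
    outcome: str,
    facility_covariates: bool = True,
    district_covariates: bool = True,
    cluster_col: str = "district_id",
) -> EffectEstimate:
    """Two-period DiD with covariate adjustment.

    Restricts to facilities with a non-missing outcome in both waves,
    regresses the outcome on the treated-group indicator, the post-period
    indicator, their interaction (the effect of interest), and the facility
    and district covariates; categorical covariates expand against fixed
    reference levels. Collinear covariates are dropped with a warning
    recorded in the result detail.
    """
    if followup_wave <= baseline_wave:
        raise ValueError("followup_wave must be after baseline_wave")
    pc = f"pct_{outcome}" if f"pct_{outcome}" in panel.columns else outcome
    df = panel[panel["wave"].isin([baseline_wave, followup_wave])].dropna(subset=[pc]).copy()
    both = df.groupby("facility_id")["wave"].nunique()
    keep = both.index[both == 2]
    n_dropped = df["facility_id"].nunique() - len(keep)
    df = df[df["facility_id"].isin(keep)].copy()
    if df.empty:
        raise ValueError("no facility observed in both waves with a non-missing outcome")

    # treated group = accredited by the follow-up wave
    acc = df.groupby("facility_id")["policy"].max()
    df["acc"] = df["facility_id"].map(acc).astype(float)
    df["d_post"] = (df["wave"] == followup_wave).astype(float)
    df["acc_post"] = df["acc"] * df["d_post"]
    if df["acc"].nunique() < 2:
        raise NoIdentifyingVariation("all facilities share the same treatment status")

    core = np.column_stack([df["acc_post"], df["acc"], df["d_post"], np.ones(len(df))])
    core_names = ["acc_x_post", "acc", "d_post", "intercept"]
    Z, z_names = _covariate_design(df, facility_covariates, district_covariates)
    dropped: list[str] = []
    X, names = _drop_collinear(np.hstack([core, Z]), core_names + z_names,
                               keep_first=1, warnings_out=dropped)
    clusters = df[cluster_col].to_numpy() if cluster_col in df.columns else df["facility_id"].to_numpy()
    beta, V, G = _ols_cluster(X, df[pc].to_numpy(), clusters)

    est, se = float(beta[0]), float(np.sqrt(V[0, 0]))
    t = est / se if se > 0 else np.nan
    p = 2 * scipy.stats.t.sf(abs(t), G - 1) if np.isfinite(t) else np.nan
    covset = []
    if facility_covariates:
        covset.append("facility")
    if district_covariates:
        covset.append("district+region")
    return EffectEstimate(
        outcome=outcome, estimator="did_2period", estimate=est, se=se, t_stat=t,
        p_value=float(p), n_obs=len(df), n_clusters=G,
        period=f"{baseline_wave}-{followup_wave}",
        covariate_set="+".join(covset) or "none",
        detail={
            "coefficients": {n: float(b) for n, b in zip(names, beta)},
            "dropped_collinear": dropped,
            "n_facilities": int(df["facility_id"].nunique()),
            "n_facilities_dropped_missing_period": int(n_dropped),
        },
    )
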
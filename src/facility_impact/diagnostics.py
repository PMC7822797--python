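"""Robustness suite: parallel-trends pre-test, placebo experiments, and an
end-to-end pipeline runner driven by a config mapping."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import panel_builder, spatial_linkage, synthetic_data
from .did_core import _demean_by, _drop_collinear, _ols_cluster, fit_did_2period, fit_did_fe
from .psm_did import run_psm_did, balance_tests, _propensity_design
from .synthetic_data import OUTCOMES, TruthConfig

log = logging.getLogger(__name__)


@dataclass
class DiagnosticResult:
    name: str  # "parallel_trends" | "placebo"
    outcome: str
    statistic: float
    p_value: float
    n_reps: int | None = None
    rejection_rate: float | None = None


def parallel_trends_test(panel: pd.DataFrame, outcome: str, pre_waves: list[int],
                         cluster_col: str = "district_id") -> DiagnosticResult:
    """Group-specific linear pre-trend test.

    Restricted to pre-treatment waves, regresses the outcome on facility
    effects, wave dummies, and (eventually treated) x (linear wave trend);
    a significant interaction flags divergent pre-trends, i.e. evidence
    against the parallel-trends assumption. With a staggered rollout a
    listed wave can already be post-treatment for an early cohort, so
    cells with policy = 1 are excluded — only genuinely untreated
    observations identify the pre-trend.
    """
    if len(pre_waves) < 2:
        raise ValueError("need >= 2 pre-treatment waves")
    pc = f"pct_{outcome}" if f"pct_{outcome}" in panel.columns else outcome
    df = panel[panel["wave"].isin(pre_waves)].dropna(subset=[pc]).copy()
    if "policy" in df.columns:
        df = df[df["policy"] == 0].copy()
    if df.empty:
        raise ValueError("no pre-treatment observations for this outcome")
    if "accreditation_status" in df.columns:
        ever = df["accreditation_status"].isin(["provisional", "full"])
    else:
        ever = df["facility_id"].map(panel.groupby("facility_id")["policy"].max()).astype(bool)
    rank = {w: i for i, w in enumerate(sorted(pre_waves))}
    df["trend_x_treated"] = df["wave"].map(rank).astype(float) * ever.astype(float)
    year_cols = []
    for w in sorted(pre_waves)[1:]:
        cname = f"year_{w}"
        df[cname] = (df["wave"] == w).astype(float)
        year_cols.append(cname)

    dm = _demean_by(df, ["trend_x_treated", pc, *year_cols], "facility_id")
    names = ["trend_x_treated", *year_cols]
    X, names = _drop_collinear(dm[names].to_numpy(), names, keep_first=1)
    clusters = df[cluster_col].to_numpy() if cluster_col in df.columns else df["facility_id"].to_numpy()
    beta, V, G = _ols_cluster(X, dm[pc].to_numpy(), clusters, k_params=X.shape[1])
    t = float(beta[0] / np.sqrt(V[0, 0]))
    p = float(2 * scipy.stats.t.sf(abs(t), G - 1))
    return DiagnosticResult(name="parallel_trends", outcome=outcome, statistic=t, p_value=p)


def placebo_test(panel: pd.DataFrame, outcome: str, estimator: str = "did_fe",
                 n_reps: int = 200, seed: int = 0, alpha: float = 0.05,
                 baseline_wave: int | None = None, followup_wave: int | None = None,
                 cluster_col: str = "district_id") -> DiagnosticResult:
    """Fake-group placebo experiment.

    Repeatedly assigns pseudo-treatment among never-treated facilities —
    at the district level, preserving the treated-district share and a
    pseudo rollout wave drawn from the real rollout distribution — and
    re-estimates. Returns the empirical rejection rate at nominal ``alpha``;
    a calibrated design rejects at about the nominal rate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ever = panel.groupby("facility_id")["policy"].max()
    never_ids = ever.index[ever == 0]
    ctrl = panel[panel["facility_id"].isin(never_ids)].copy()
    districts = ctrl[cluster_col].dropna().unique() if cluster_col in ctrl.columns else never_ids.to_numpy()

    all_districts = panel[cluster_col].dropna().unique() if cluster_col in panel.columns else ever.index
    treated_fac = ever.index[ever == 1]
    treated_districts = panel[panel["facility_id"].isin(treated_fac)][cluster_col].dropna().unique() \
        if cluster_col in panel.columns else treated_fac
    share = max(len(treated_districts) / max(len(all_districts), 1), 1 / max(len(districts), 1))
    n_pseudo = max(1, round(share * len(districts)))
    n_ctrl_fac = ctrl["facility_id"].nunique()
    pseudo_fac_per_district = n_ctrl_fac / max(len(districts), 1)
    if n_ctrl_fac < 2 * n_pseudo * pseudo_fac_per_district * share and len(districts) < 2 * n_pseudo:
        raise ValueError("insufficient never-treated districts for the requested placebo share")

    real_waves = panel.loc[panel["policy"] == 1, "wave"]
    candidate_waves = sorted(real_waves.unique()) if len(real_waves) else sorted(panel["wave"].unique())[1:]
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        pseudo_d = rng.choice(districts, size=n_pseudo, replace=False)
        pseudo_wave = {d: int(rng.choice(candidate_waves)) for d in pseudo_d}
        rep = ctrl.copy()
        w0 = rep[cluster_col].map(pseudo_wave)
        rep["policy"] = (rep["wave"] >= w0).fillna(False).astype(int)
        try:
            if estimator == "did_fe":
                est = fit_did_fe(rep, outcome, cluster_col=cluster_col)
            elif estimator == "did_2period":
                est = fit_did_2period(rep, baseline_wave, followup_wave, outcome,
                                      cluster_col=cluster_col)
            else:
                raise ValueError(f"unknown placebo estimator {estimator!r}")
        except Exception:
            continue
        if est.p_value < alpha:
            rejections += 1
    rate = rejections / n_reps
    return DiagnosticResult(name="placebo", outcome=outcome, statistic=float(rate),
                            p_value=float("nan"), n_reps=n_reps, rejection_rate=float(rate))


DEFAULT_CONFIG: dict = {
    "n_districts": 60,
    "n_facilities": 600,
    "waves": list(synthetic_data.DEFAULT_WAVES),
    "rollout_waves": list(synthetic_data.DEFAULT_ROLLOUT_WAVES),
    "truth": {},
    "outcomes": list(OUTCOMES),
    "period_pairs": [[2000, 2005], [2005, 2008], [2008, 2014]],
    "min_denominator": 5,
    "max_distance_km": None,
    "kernel": "epanechnikov",
    "bandwidth": 0.06,
    "n_boot": 0,
    "placebo_reps": 0,
    "pre_waves": [1992, 1995, 2000],
    "seed": 0,
    "outdir": None,
}


def _validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}
    if not set(cfg["rollout_waves"]) <= set(cfg["waves"]):
        raise ValueError("rollout_waves must be a subset of waves")
    if not set(cfg["outcomes"]) <= set(OUTCOMES):
        raise ValueError("unknown outcome names in config")
    return cfg


def build_analysis_panel(data: dict, min_denominator: int = 5,
                         max_distance_km: float | None = None,
                         use_truth_links: bool = False) -> tuple[pd.DataFrame, dict]:
    """Link -> collapse every wave -> sample rules -> long panel.

    ``use_truth_links`` bypasses the spatial search with the generator's
    ground-truth assignment (exact by construction) — used by Monte-Carlo
    studies where the linkage stage is not under test."""
    women, facilities, districts = data["women"], data["facilities"], data["districts"]
    if use_truth_links:
        links = women[["woman_id", "true_facility_id", "wave"]].rename(
            columns={"true_facility_id": "facility_id"})
        links = links.assign(distance_km=0.0)
        summary = {"n_women": len(women), "n_linked": len(links), "mode": "truth"}
    else:
        links, summary = spatial_linkage.link_cohort(women, facilities,
                                                     max_distance_km=max_distance_km)
    rows = pd.concat(
        [panel_builder.collapse_outcomes(links, women, w) for w in sorted(women["wave"].unique())],
        ignore_index=True,
    )
    panel = panel_builder.build_panel(rows, sorted(women["wave"].unique()), facilities, districts)
    panel = panel_builder.apply_sample_rules(panel, facilities, min_denominator=min_denominator)
    accounting = {
        "women_generated": int(len(women)),
        "women_linked": int(summary["n_linked"]),
        "women_dropped_distance": int(summary.get("n_dropped_distance", 0)),
        "panel_rows": int(len(panel)),
    }
    return panel, {"linkage": summary, "accounting": accounting}


def run_pipeline(config: dict) -> dict:
    """Execute the full evaluation from a config mapping.

    generate -> link -> build panel -> estimate (panel FE DiD for every
    outcome; two-period DiD and kernel PSM-DiD for every configured period
    pair) -> diagnostics. Returns (and optionally writes) a machine-readable
    report; reruns with the same config are byte-identical.
    """
    cfg = _validate_config(config)
    hashed = {k: v for k, v in cfg.items() if k != "outdir"}  # output path is not identity
    cfg_hash = hashlib.sha256(json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()[:12]
    t0 = time.time()
    stage = "generate"
    try:
        truth_cfg = TruthConfig(seed=cfg["seed"], **cfg["truth"])
        data = synthetic_data.generate_dataset(
            n_districts=cfg["n_districts"], n_facilities=cfg["n_facilities"],
            waves=cfg["waves"], rollout_waves=cfg["rollout_waves"], cfg=truth_cfg)
        log.info("[%s] generated %d women, %d facilities (%.1fs)",
                 stage, len(data["women"]), len(data["facilities"]), time.time() - t0)

        stage = "link+panel"
        panel, meta = build_analysis_panel(data, min_denominator=cfg["min_denominator"],
                                           max_distance_km=cfg["max_distance_km"])
        stage = "estimate"
        estimates = []
        for outcome in cfg["outcomes"]:
            try:
                estimates.append(fit_did_fe(panel, outcome).to_row())
            except Exception as exc:
                log.warning("did_fe failed for %s: %s", outcome, exc)
            for pre, post in cfg["period_pairs"]:
                try:
                    estimates.append(fit_did_2period(panel, pre, post, outcome).to_row())
                    est, model, weights = run_psm_did(
                        panel, data["districts"], pre, post, outcome,
                        kernel=cfg["kernel"], bandwidth=cfg["bandwidth"])
                    estimates.append(est.to_row())
                except Exception as exc:
                    log.warning("two-period estimators failed for %s %s-%s: %s", outcome, pre, post, exc)

        stage = "diagnostics"
        diags = []
        pre_waves = [w for w in cfg["pre_waves"] if w in cfg["waves"]]
        for outcome in cfg["outcomes"]:
            try:
                d = parallel_trends_test(panel, outcome, pre_waves)
                diags.append({"name": d.name, "outcome": d.outcome,
                              "statistic": d.statistic, "p_value": d.p_value})
            except Exception as exc:
                log.warning("parallel-trends test failed for %s: %s", outcome, exc)
            if cfg["placebo_reps"]:
                d = placebo_test(panel, outcome, n_reps=cfg["placebo_reps"], seed=cfg["seed"])
                diags.append({"name": d.name, "outcome": d.outcome,
                              "rejection_rate": d.rejection_rate, "n_reps": d.n_reps})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed (config {cfg_hash}): {exc}") from exc

    report = {
        "config_hash": cfg_hash,
        "truth": data["truth"],
        "linkage": {k: v for k, v in meta["linkage"].items() if k != "women_per_facility"},
        "accounting": meta["accounting"],
        "estimates": estimates,
        "diagnostics": diags,
    }
    if cfg["outdir"]:
        outdir = Path(cfg["outdir"])
        outdir.mkdir(parents=True, exist_ok=True)
        synthetic_data.write_dataset(data, outdir, cfg=truth_cfg)
        panel.to_csv(outdir / "panel.csv", index=False)
        pd.DataFrame(estimates).to_csv(outdir / "estimates.csv", index=False)
        with open(outdir / "results.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
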
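"""Kernel propensity-score-matching difference-in-differences.

The estimator matches treated to control facilities on the estimated
probability of being targeted by the rollout (a logit on district
socio-economic indicators), enforces common support by the min-max rule,
weights each control by a kernel in propensity-score distance, and for each
treated facility i contrasts its pre-to-post outcome change against the
kernel-weighted average control change:

    delta_i = (y_i,post - y_i,pre) - sum_j w(i,j) (y_j,post - y_j,pre)

The overall estimate averages delta_i over treated facilities on support.
Inference comes from a district-level cluster bootstrap that re-runs the
whole matching pipeline each draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .did_core import EffectEstimate
from .errors import NoOverlapError, SeparationError
from .synthetic_data import INDICATOR_COLUMNS

log = logging.getLogger(__name__)

DEFAULT_KERNEL = "epanechnikov"
DEFAULT_BANDWIDTH = 0.06


@dataclass
class PropensityModel:
    """Fitted logistic treatment-assignment model."""

    coefficients: dict[str, float]
    scores: pd.Series  # facility_id -> probability in (0, 1)
    treated: pd.Series  # facility_id -> 0/1
    converged: bool
    n_iterations: int
    standard_errors: dict[str, float] = field(default_factory=dict)


@dataclass
class MatchWeights:
    """Kernel matching weights: rows = treated on support, cols = controls."""

    treated_ids: list
    control_ids: list
    matrix: np.ndarray  # shape (n_treated, n_controls), rows sum to 1
    support_flags: pd.Series  # facility_id -> bool (on support)
    support_interval: tuple[float, float]
    dropped_no_match: list = field(default_factory=list)

    def weights_for(self, treated_id) -> pd.Series:
        i = self.treated_ids.index(treated_id)
        return pd.Series(self.matrix[i], index=self.control_ids)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def fit_propensity(
    covariates: pd.DataFrame,
    treatment_labels: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PropensityModel:
    """Logistic regression of treatment on covariates via IRLS.

    ``covariates`` is indexed by facility_id (or carries a facility_id
    column); zero-variance columns are dropped with a warning. Convergence
    is declared when the largest coefficient change falls below ``tol``;
    perfect separation raises :class:`SeparationError` naming the covariate
    with the most extreme coefficient.
    """
    cov = covariates.copy()
    if "facility_id" in cov.columns:
        cov = cov.set_index("facility_id")
    y = np.asarray(treatment_labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both treated and control facilities are required")

    cols = []
    for c in cov.columns:
        x = cov[c].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            log.warning("fit_propensity: dropping zero-variance covariate %r", c)
            continue
        # a dummy level that perfectly predicts treatment has no finite MLE;
        # drop it (the affected units keep their other covariates)
        levels = np.unique(x)
        if len(levels) == 2:
            sep = any(len(np.unique(y[x == lv])) == 1 for lv in levels)
            if sep:
                log.warning("fit_propensity: dropping covariate %r (a level perfectly "
                            "predicts treatment status)", c)
                continue
        cols.append(c)
    X = np.column_stack([np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in cols])
    names = ["intercept", *cols]
    # linearly dependent covariates have no separate finite MLE: drop them
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = sorted(set(piv[:rank]) | {0})
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        log.warning("fit_propensity: dropping collinear covariate(s) %s", dropped)
        X, names = X[:, keep], [names[i] for i in keep]

    beta = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"IRLS normal equations singular at iteration {n_iter}") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(f"perfect separation suspected (diverging coefficient on {worst!r})")
        if step < tol:
            converged = True
            break
    if not converged and np.max(np.abs(beta)) > 30:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise SeparationError(f"perfect separation suspected (coefficient on {worst!r} did not stabilize)")

    scores = pd.Series(np.clip(_expit(X @ beta), 1e-12, 1 - 1e-12), index=cov.index, name="pscore")
    mu = _expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov_beta = np.linalg.pinv(X.T @ (X * w[:, None]))
    return PropensityModel(
        coefficients=dict(zip(names, map(float, beta))),
        scores=scores,
        treated=pd.Series(y.astype(int), index=cov.index, name="treated"),
        converged=converged,
        n_iterations=n_iter,
        standard_errors=dict(zip(names, map(float, np.sqrt(np.diag(cov_beta))))),
    )


def common_support(model: PropensityModel, n_hist_bins: int = 20) -> dict:
    """Min-max common-support rule on the fitted scores.

    Support is [max(min_T, min_C), min(max_T, max_C)]; facilities outside
    are flagged off-support. Returns flags, the interval, exclusion counts,
    and histogram data for overlap plots. Raises :class:`NoOverlapError`
    when the interval is empty.
    """
    if not model.converged:
        raise ValueError("propensity model did not converge; refusing downstream use")
    s, t = model.scores, model.treated.astype(bool)
    lo = max(s[t].min(), s[~t].min())
    hi = min(s[t].max(), s[~t].max())
    if lo > hi:
        raise NoOverlapError(f"treated scores [{s[t].min():.3f}, {s[t].max():.3f}] and control "
                             f"scores [{s[~t].min():.3f}, {s[~t].max():.3f}] do not overlap")
    flags = (s >= lo) & (s <= hi)
    edges = np.linspace(lo, hi, n_hist_bins + 1)
    hist_t, _ = np.histogram(s[t & flags], bins=edges)
    hist_c, _ = np.histogram(s[~t & flags], bins=edges)
    n_off = int((~flags).sum())
    if n_off:
        log.info("common_support: %d facilities off support [%.4f, %.4f]", n_off, lo, hi)
    return {
        "support_flags": flags,
        "interval": (float(lo), float(hi)),
        "n_off_support_treated": int((~flags & t).sum()),
        "n_off_support_control": int((~flags & ~t).sum()),
        "histogram": {"edges": edges, "treated": hist_t, "control": hist_c},
    }


def _kernel_values(u: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "epanechnikov":
        return np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u ** 2), 0.0)
    if kernel == "gaussian":
        return np.exp(-0.5 * u ** 2) / np.sqrt(2 * np.pi)
    raise ValueError(f"unknown kernel {kernel!r}; use 'epanechnikov' or 'gaussian'")


def kernel_weights(score_i: float, control_scores: np.ndarray,
                   kernel: str = DEFAULT_KERNEL, bandwidth: float = DEFAULT_BANDWIDTH) -> np.ndarray:
    """Normalized kernel weights of every control for one treated score.

    w(i,j) = K((p_j - p_i)/h) / sum_k K((p_k - p_i)/h). Raises ValueError
    when no control falls within the kernel's effective window."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    u = (np.asarray(control_scores, dtype=float) - score_i) / bandwidth
    k = _kernel_values(u, kernel)
    total = k.sum()
    if total <= 0.0:
        raise ValueError(f"no control within bandwidth of score {score_i:.4f}")
    return k / total


def build_match_weights(model: PropensityModel, kernel: str = DEFAULT_KERNEL,
                        bandwidth: float = DEFAULT_BANDWIDTH) -> MatchWeights:
    """Common support + per-treated kernel weights over on-support controls.

    Treated facilities with no control inside the bandwidth are dropped
    with a logged warning (never silently)."""
    sup = common_support(model)
    flags = sup["support_flags"]
    t = model.treated.astype(bool)
    treated_ids = list(model.scores.index[t & flags])
    control_ids = list(model.scores.index[~t & flags])
    if not treated_ids:
        raise NoOverlapError("no treated facility on common support")
    c_scores = model.scores[control_ids].to_numpy()
    rows, kept, dropped = [], [], []
    for tid in treated_ids:
        try:
            rows.append(kernel_weights(float(model.scores[tid]), c_scores, kernel, bandwidth))
            kept.append(tid)
        except ValueError:
            dropped.append(tid)
    if dropped:
        log.warning("build_match_weights: dropped %d treated facilities with no control "
                    "within bandwidth %.3f: %s", len(dropped), bandwidth, dropped[:5])
    if not kept:
        raise NoOverlapError("every treated facility lost all matches within the bandwidth")
    return MatchWeights(
        treated_ids=kept, control_ids=control_ids,
        matrix=np.vstack(rows), support_flags=flags,
        support_interval=sup["interval"], dropped_no_match=dropped,
    )


def psm_did_estimate(panel: pd.DataFrame, pre_wave: int, post_wave: int,
                     outcome: str, weights: MatchWeights) -> EffectEstimate:
    """Kernel-matched DiD over the pre/post waves.

    Facilities missing either period are dropped (logged); control columns
    lost this way are renormalized within each treated row. The reported SE
    is the naive treated-level SD of delta_i / sqrt(n_T) — bootstrap_se is
    the supported inference route since it propagates matching uncertainty.
    """
    pc = f"pct_{outcome}" if f"pct_{outcome}" in panel.columns else outcome
    wide = panel.pivot_table(index="facility_id", columns="wave", values=pc, aggfunc="first")
    if pre_wave not in wide.columns or post_wave not in wide.columns:
        raise ValueError(f"panel lacks wave {pre_wave} or {post_wave}")
    change = (wide[post_wave] - wide[pre_wave]).dropna()

    t_ids = [i for i in weights.treated_ids if i in change.index]
    n_t_dropped = len(weights.treated_ids) - len(t_ids)
    c_mask = np.array([j in change.index for j in weights.control_ids])
    if n_t_dropped or (~c_mask).any():
        log.info("psm_did_estimate: dropped %d treated / %d controls missing a period",
                 n_t_dropped, int((~c_mask).sum()))
    if not t_ids:
        raise ValueError("no treated facility on support observed in both waves")
    if not c_mask.any():
        raise ValueError("no matched control observed in both waves")

    rows = [weights.treated_ids.index(i) for i in t_ids]
    W = weights.matrix[np.ix_(rows, np.flatnonzero(c_mask))]
    row_sums = W.sum(axis=1)
    ok = row_sums > 0
    if not ok.all():
        log.info("psm_did_estimate: %d treated lost all matched controls", int((~ok).sum()))
        t_ids = [i for i, o in zip(t_ids, ok) if o]
        W = W[ok]
        row_sums = row_sums[ok]
    W = W / row_sums[:, None]

    d_t = change[t_ids].to_numpy()
    d_c = change[np.array(weights.control_ids)[c_mask]].to_numpy()
    delta_i = d_t - W @ d_c
    est = float(delta_i.mean())
    se = float(delta_i.std(ddof=1) / np.sqrt(len(delta_i))) if len(delta_i) > 1 else np.nan
    t_stat = est / se if se and se > 0 else np.nan
    p = 2 * scipy.stats.t.sf(abs(t_stat), len(delta_i) - 1) if np.isfinite(t_stat) else np.nan
    return EffectEstimate(
        outcome=outcome, estimator="psm_did", estimate=est, se=se, t_stat=t_stat,
        p_value=float(p) if np.isfinite(t_stat) else np.nan,
        n_obs=len(delta_i) + int(c_mask.sum()), n_clusters=len(delta_i),
        period=f"{pre_wave}-{post_wave}", covariate_set="district indicators (propensity)",
        detail={"per_treated_delta": dict(zip(t_ids, map(float, delta_i))),
                "se_kind": "naive treated-level; use bootstrap_se for inference"},
    )


def run_psm_did(panel: pd.DataFrame, districts: pd.DataFrame, pre_wave: int, post_wave: int,
                outcome: str, kernel: str = DEFAULT_KERNEL, bandwidth: float = DEFAULT_BANDWIDTH,
                propensity_covariates: list[str] | None = None,
                include_region_dummies: bool = False) -> tuple[EffectEstimate, PropensityModel, MatchWeights]:
    """Convenience pipeline: propensity fit -> support -> weights -> estimate.

    Treatment is defined at the facility level as accredited by the
    follow-up wave. Propensity covariates default to the eight district
    indicators that compose the vulnerability index; region dummies can be
    added but are off by default since assignment is district-level and the
    extra parameters invite quasi-separation in modest district counts
    (regions still enter the outcome-equation estimators)."""
    fac = panel.drop_duplicates("facility_id").set_index("facility_id")
    treated = panel[panel["wave"] == post_wave].set_index("facility_id")["policy"]
    treated = treated.reindex(fac.index).fillna(0).astype(int)
    covs = _propensity_design(fac, districts, propensity_covariates, include_region_dummies)
    model = fit_propensity(covs, treated)
    weights = build_match_weights(model, kernel=kernel, bandwidth=bandwidth)
    est = psm_did_estimate(panel, pre_wave, post_wave, outcome, weights)
    return est, model, weights


def _propensity_design(fac: pd.DataFrame, districts: pd.DataFrame | None,
                       covariate_names: list[str] | None,
                       include_region_dummies: bool) -> pd.DataFrame:
    names = list(covariate_names or INDICATOR_COLUMNS)
    if all(c in fac.columns for c in names):
        covs = fac[names].copy()
        region = fac["region"] if "region" in fac.columns else None
    else:
        if districts is None:
            raise ValueError("district table required when panel lacks district indicators")
        d = districts.set_index("district_id")
        covs = d.loc[fac["district_id"], names].set_axis(fac.index)
        region = d.loc[fac["district_id"], "region"].set_axis(fac.index) if "region" in d.columns else None
    if include_region_dummies and region is not None:
        for level in sorted(region.dropna().unique()):
            if level == "fully-urban":
                continue
            covs[f"region[{level}]"] = (region == level).astype(float)
    return covs


def bootstrap_se(panel: pd.DataFrame, districts: pd.DataFrame, pre_wave: int, post_wave: int,
                 outcome: str, n_boot: int = 199, seed: int = 0,
                 kernel: str = DEFAULT_KERNEL, bandwidth: float = DEFAULT_BANDWIDTH,
                 cluster_col: str = "district_id", max_failure_rate: float = 0.20,
                 propensity_covariates: list[str] | None = None,
                 include_region_dummies: bool = False) -> dict:
    """District-level cluster bootstrap of the full PSM-DiD pipeline.

    Each draw resamples districts with replacement (their facilities ride
    along, duplicates treated as distinct clusters), re-fits the propensity
    model, re-enforces support, rebuilds kernel weights, and re-estimates.
    Returns the bootstrap SD and the 2.5/97.5 percentile interval. Errors
    if more than ``max_failure_rate`` of the draws fail (e.g. no overlap).
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)
    cluster_ids = panel[cluster_col].dropna().unique()
    estimates, failures = [], 0
    for _ in range(n_boot):
        drawn = rng.choice(cluster_ids, size=len(cluster_ids), replace=True)
        parts = []
        for rep, cid in enumerate(drawn):
            sub = panel[panel[cluster_col] == cid].copy()
            sub["facility_id"] = sub["facility_id"].astype(str) + f"~b{rep}"
            parts.append(sub)
        bpanel = pd.concat(parts, ignore_index=True)
        try:
            est, _, _ = run_psm_did(bpanel, districts, pre_wave, post_wave, outcome,
                                    kernel=kernel, bandwidth=bandwidth,
                                    propensity_covariates=propensity_covariates,
                                    include_region_dummies=include_region_dummies)
            estimates.append(est.estimate)
        except (NoOverlapError, SeparationError, ValueError):
            failures += 1
    fail_rate = failures / n_boot
    if fail_rate > max_failure_rate:
        raise RuntimeError(f"bootstrap failure rate {fail_rate:.1%} exceeds {max_failure_rate:.0%}")
    arr = np.asarray(estimates)
    return {
        "se": float(arr.std(ddof=1)),
        "ci_lower": float(np.percentile(arr, 2.5)),
        "ci_upper": float(np.percentile(arr, 97.5)),
        "n_successful": len(arr),
        "failure_rate": fail_rate,
    }


def balance_tests(covariates: pd.DataFrame, treatment_labels: pd.Series,
                  weights: MatchWeights) -> pd.DataFrame:
    """Covariate balance before and after matching.

    Per covariate: treated/control raw means, kernel-weighted control mean,
    two-sample t statistics and p-values before and after matching, and
    standardized mean differences (denominator = pre-matching pooled SD).
    Zero-variance covariates report SMD 0 with a warning."""
    cov = covariates.copy()
    if "facility_id" in cov.columns:
        cov = cov.set_index("facility_id")
    t = np.asarray(treatment_labels, dtype=bool)
    # aggregate control weight: average over treated rows, sums to 1
    w_c = pd.Series(weights.matrix.mean(axis=0), index=weights.control_ids)
    rows = []
    for c in cov.columns:
        x = cov[c].to_numpy(dtype=float)
        xt, xc = x[t], x[~t]
        pooled_sd = np.sqrt((xt.var(ddof=1) + xc.var(ddof=1)) / 2.0)
        xt_s = cov.loc[weights.treated_ids, c].to_numpy(dtype=float)
        xc_s = cov.loc[weights.control_ids, c].to_numpy(dtype=float)
        wc = w_c.to_numpy()
        mean_c_w = float(np.sum(wc * xc_s))
        if pooled_sd == 0.0 or not np.isfinite(pooled_sd):
            log.warning("balance_tests: covariate %r has zero variance; SMD set to 0", c)
            smd_before = smd_after = 0.0
            t_before = p_before = t_after = p_after = np.nan
        else:
            smd_before = (xt.mean() - xc.mean()) / pooled_sd
            smd_after = (xt_s.mean() - mean_c_w) / pooled_sd
            t_before, p_before = scipy.stats.ttest_ind(xt, xc, equal_var=False)
            # Welch-type t with kernel-weighted control moments and
            # effective control sample size (Kish)
            n_eff = (wc.sum() ** 2) / np.sum(wc ** 2)
            var_c_w = float(np.sum(wc * (xc_s - mean_c_w) ** 2) / max(1e-12, 1 - np.sum(wc ** 2)))
            num = xt_s.mean() - mean_c_w
            den = np.sqrt(xt_s.var(ddof=1) / len(xt_s) + var_c_w / n_eff)
            t_after = num / den if den > 0 else np.nan
            df_w = max(2.0, len(xt_s) + n_eff - 2)
            p_after = 2 * scipy.stats.t.sf(abs(t_after), df_w) if np.isfinite(t_after) else np.nan
        rows.append({
            "covariate": c,
            "mean_treated": float(xt.mean()), "mean_control": float(xc.mean()),
            "mean_control_weighted": mean_c_w,
            "smd_before": float(smd_before), "smd_after": float(smd_after),
            "t_before": float(t_before) if np.isfinite(t_before) else np.nan,
            "p_before": float(p_before) if np.isfinite(p_before) else np.nan,
            "t_after": float(t_after) if np.isfinite(t_after) else np.nan,
            "p_after": float(p_after) if np.isfinite(p_after) else np.nan,
        })
    return pd.DataFrame(rows)
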
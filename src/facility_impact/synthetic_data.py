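"""Synthetic DHS-style data generator with known ground truth.

Emulates the statistical structure a facility-accreditation evaluation
assumes: districts carrying socio-economic deprivation indicators, a
vulnerability index that drives staggered district-level targeting of the
accreditation rollout, facilities with staffing/building/catchment
covariates, and woman-level binary health outcomes with facility
heterogeneity and binomial noise.

Treatment effects are planted in percentage points: for each treated
facility-wave cell the success probability is lifted by ``effect_ppts/100``
relative to its counterfactual, implemented as the equivalent log-odds
shift at that cell's no-treatment probability. The infinite-n
difference-in-differences of the generative model therefore equals the
configured effect exactly (up to clipping at the probability boundaries).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

OUTCOMES: tuple[str, ...] = (
    "knowledge_side_effects",
    "knowledge_other_methods",
    "anc_4plus_visits",
    "informed_complications",
    "weight_measured",
    "blood_pressure_measured",
    "urine_sample_taken",
    "institutional_delivery",
    "skilled_delivery",
    "child_ari",
    "child_fever",
    "child_diarrhea",
)

REGIONS: tuple[str, ...] = (
    "fully-urban",
    "urban-lower",
    "rural-lower",
    "urban-upper",
    "rural-upper",
    "frontier",
)

STAFF_CATEGORIES: tuple[str, ...] = (
    "practitioners",
    "specialists",
    "pharmacists",
    "nurses",
    "lab_technicians",
    "xray_technicians",
    "health_observers",
    "social_workers",
)

#: district deprivation indicators entering the vulnerability index.
INDICATOR_COLUMNS: tuple[str, ...] = (
    "illiteracy_ratio",
    "unemployment_ratio",
    "income_dependency_ratio",
    "no_electricity",
    "no_potable_water",
    "avg_family_size",
    "crowding_factor",
    "population_size",
)

#: sign with which each indicator enters the index (+1 = more is more
#: vulnerable). Larger population is treated as less vulnerable.
INDICATOR_SIGNS: dict[str, int] = {
    "illiteracy_ratio": +1,
    "unemployment_ratio": +1,
    "income_dependency_ratio": +1,
    "no_electricity": +1,
    "no_potable_water": +1,
    "avg_family_size": +1,
    "crowding_factor": +1,
    "population_size": -1,
}

# Beta/Gamma parameters for district indicator draws. Means roughly match
# census-style national figures (e.g. illiteracy mean 3/8 = 0.375).
DISTRICT_DISTRIBUTIONS: dict[str, tuple] = {
    "illiteracy_ratio": ("beta", 3.0, 5.0),
    "unemployment_ratio": ("beta", 2.0, 8.0),
    "income_dependency_ratio": ("beta", 3.0, 4.0),
    "no_electricity": ("beta", 1.5, 8.0),
    "no_potable_water": ("beta", 2.0, 6.0),
}

DEFAULT_WAVES: tuple[int, ...] = (1992, 1995, 2000, 2005, 2008, 2014)
DEFAULT_ROLLOUT_WAVES: tuple[int, ...] = (2000, 2005, 2008)

# National averages where the descriptive statistics print them; the two
# family-planning knowledge outcomes and urine collection use mid-range
# values of the same order as the printed constants.
DEFAULT_BASELINE_RATES: dict[str, float] = {
    "knowledge_side_effects": 0.45,
    "knowledge_other_methods": 0.40,
    "anc_4plus_visits": 0.56,
    "informed_complications": 0.34,
    "weight_measured": 0.82,
    "blood_pressure_measured": 0.82,
    "urine_sample_taken": 0.47,
    "institutional_delivery": 0.60,
    "skilled_delivery": 0.70,
    "child_ari": 0.14,
    "child_fever": 0.23,
    "child_diarrhea": 0.13,
}

# Probability a woman enters an outcome's denominator (current contraceptive
# users, recent mothers, mothers of under-5 children respectively).
DEFAULT_ELIGIBILITY_RATES: dict[str, float] = {
    "knowledge_side_effects": 0.55,
    "knowledge_other_methods": 0.55,
    "anc_4plus_visits": 0.65,
    "informed_complications": 0.65,
    "weight_measured": 0.65,
    "blood_pressure_measured": 0.65,
    "urine_sample_taken": 0.65,
    "institutional_delivery": 0.70,
    "skilled_delivery": 0.70,
    "child_ari": 0.75,
    "child_fever": 0.75,
    "child_diarrhea": 0.75,
}

DEFAULT_WAVE_EFFECTS: dict[int, float] = {
    1992: 0.0,
    1995: 0.10,
    2000: 0.25,
    2005: 0.45,
    2008: 0.55,
    2014: 0.70,
}

_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON_EQ = 111.320

# substream labels -> spawn keys, so stages can be re-run independently
_STREAMS = {"districts": 0, "facilities": 1, "treatment": 2, "women": 3, "scores": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class TruthConfig:
    """Ground-truth configuration for the generator.

    effect_ppts
        True treatment effect per outcome, in percentage points on the
        outcome percentage (e.g. ``{"child_diarrhea": -5.0}``).
    baseline_rates
        Pre-period success probability per outcome at the reference wave.
    wave_effects
        Additive secular shift per survey wave, on the log-odds scale.
    facility_sd
        SD of facility random intercepts on the log-odds scale.
    targeting_strength
        Logistic slope linking the district vulnerability index to the
        district's probability of being selected for the rollout.
    confounding_strength
        Log-odds penalty on outcomes per unit of district vulnerability
        (time-invariant, so removed by differencing but biasing naive
        cross-sectional contrasts).
    pretrend_ppts_per_wave
        Divergent pre-accreditation drift (ppts per survey wave) planted for
        eventually treated facilities; 0 = parallel trends hold.
    """

    effect_ppts: dict[str, float] = field(default_factory=dict)
    baseline_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    wave_effects: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_WAVE_EFFECTS))
    facility_sd: float = 0.3
    targeting_strength: float = 1.0
    confounding_strength: float = 0.5
    target_treated_share: float = 0.45
    other_interventions_frac: float = 0.10
    pretrend_ppts_per_wave: float = 0.0
    eligibility_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ELIGIBILITY_RATES))
    women_per_facility_per_wave: int = 25
    gps_jitter_km: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.women_per_facility_per_wave < 1:
            raise ValueError("women_per_facility_per_wave must be >= 1")
        for k, v in self.baseline_rates.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"baseline rate for {k!r} must be in (0, 1), got {v}")
        unknown = set(self.effect_ppts) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"effect_ppts names unknown outcomes: {sorted(unknown)}")


def gen_districts(n_districts: int, seed: int) -> pd.DataFrame:
    """Draw ``n_districts`` district profiles with socio-economic indicators.

    Proportions come from Beta distributions, family size and crowding from
    shifted Gammas, population from a lognormal; regions are drawn uniformly.
    """
    if n_districts < 2:
        raise ValueError("n_districts must be >= 2 (need treated and control pools)")
    rng = _rng(seed, "districts")
    df = pd.DataFrame({"district_id": [f"D{i:04d}" for i in range(n_districts)]})
    for col, (kind, a, b) in DISTRICT_DISTRIBUTIONS.items():
        assert kind == "beta"
        df[col] = rng.beta(a, b, size=n_districts)
    df["avg_family_size"] = 3.0 + rng.gamma(2.0, 0.6, size=n_districts)
    df["crowding_factor"] = 0.8 + rng.gamma(2.0, 0.35, size=n_districts)
    df["population_size"] = np.maximum(1, rng.lognormal(10.5, 0.6, size=n_districts)).astype(int)
    df["region"] = rng.choice(REGIONS, size=n_districts)
    return df


def vulnerability_index(districts: pd.DataFrame) -> pd.Series:
    """Composite deprivation score per district: mean of the eight indicators
    after z-standardization across the district set, signed so that higher
    means more vulnerable (population size enters negatively).

    An indicator with zero variance across districts contributes 0 and is
    reported with a warning.
    """
    parts = []
    for col in INDICATOR_COLUMNS:
        x = districts[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        # tolerance guards against 1-ulp "variance" in identical columns
        if sd <= 1e-12 * max(1.0, abs(x.mean())) or not np.isfinite(sd):
            log.warning("vulnerability_index: indicator %r has zero variance; contributes 0", col)
            parts.append(np.zeros_like(x))
        else:
            parts.append(INDICATOR_SIGNS[col] * (x - x.mean()) / sd)
    idx = np.mean(parts, axis=0)
    return pd.Series(idx, index=districts.index, name="vulnerability_index")


def classify_accreditation(survey_score: float) -> str:
    """Three-tier accreditation decision from the total survey score.

    >= 0.80 -> "full"; [0.50, 0.80) -> "provisional"; < 0.50 -> "denied".
    """
    if not 0.0 <= survey_score <= 1.0:
        raise ValueError(f"survey_score must be in [0, 1], got {survey_score}")
    if survey_score >= 0.80:
        return "full"
    if survey_score >= 0.50:
        return "provisional"
    return "denied"


def gen_facilities(districts: pd.DataFrame, n_facilities: int, seed: int) -> pd.DataFrame:
    """Place facilities on a jittered lattice and attach covariates.

    The lattice guarantees inter-facility spacing large relative to the
    woman GPS jitter, so nearest-facility linkage recovers the generating
    facility for nearly all women. Lattice cells are chunked row-major into
    districts, giving districts spatial coherence.
    """
    if n_facilities < 2:
        raise ValueError("n_facilities must be >= 2")
    rng = _rng(seed, "facilities")
    n_districts = len(districts)

    # Egypt-sized bounding box, ~1000 km per side.
    lat_lo, lat_hi, lon_lo, lon_hi = 22.0, 31.0, 25.0, 35.0
    side = math.ceil(math.sqrt(n_facilities))
    cell_lat = (lat_hi - lat_lo) / side
    cell_lon = (lon_hi - lon_lo) / side
    idx = np.arange(n_facilities)
    row, col = idx // side, idx % side
    lat = lat_lo + (row + 0.5) * cell_lat + rng.uniform(-0.25, 0.25, n_facilities) * cell_lat
    lon = lon_lo + (col + 0.5) * cell_lon + rng.uniform(-0.25, 0.25, n_facilities) * cell_lon

    district_of = np.minimum((idx * n_districts) // n_facilities, n_districts - 1)
    df = pd.DataFrame(
        {
            "facility_id": [f"F{i:05d}" for i in idx],
            "district_id": districts["district_id"].to_numpy()[district_of],
            "lat": lat,
            "lon": lon,
        }
    )
    staff_rates = {
        "practitioners": 2.0,
        "specialists": 1.0,
        "pharmacists": 1.0,
        "nurses": 4.0,
        "lab_technicians": 1.0,
        "xray_technicians": 0.5,
        "health_observers": 1.0,
        "social_workers": 1.0,
    }
    for cat in STAFF_CATEGORIES:
        df[f"staff_{cat}"] = rng.poisson(staff_rates[cat], n_facilities)
    df["building_condition"] = rng.choice(["bad", "average", "good"], size=n_facilities, p=[0.2, 0.5, 0.3])
    df["catchment_population"] = np.maximum(1, rng.lognormal(9.0, 0.5, n_facilities)).astype(int)
    df["accreditation_wave"] = pd.array([pd.NA] * n_facilities, dtype="Int64")
    df["accreditation_status"] = "none"
    df["other_interventions"] = 0
    return df


def assign_treatment(
    districts: pd.DataFrame,
    facilities: pd.DataFrame,
    rollout_waves: list[int],
    cfg: TruthConfig,
) -> pd.DataFrame:
    """Stagger accreditation across districts, targeting by vulnerability.

    District selection probability follows a logistic link in the
    vulnerability index scaled by ``cfg.targeting_strength``; selected
    districts receive one of ``rollout_waves``. Facilities in selected
    districts sit an accreditation survey: scores >= 0.5 are accredited
    (full or provisional) from the district's rollout wave, scores below 0.5
    are denied and stay untreated. A fraction of accredited facilities is
    flagged for other concurrent interventions.
    """
    if not rollout_waves:
        raise ValueError("rollout_waves must be non-empty")
    rng = _rng(cfg.seed, "treatment")
    vidx = vulnerability_index(districts)
    logit_base = math.log(cfg.target_treated_share / (1 - cfg.target_treated_share))
    p_select = 1.0 / (1.0 + np.exp(-(logit_base + cfg.targeting_strength * vidx.to_numpy())))
    selected = rng.random(len(districts)) < p_select
    district_wave = {
        d: int(rng.choice(rollout_waves))
        for d, sel in zip(districts["district_id"], selected)
        if sel
    }

    fac = facilities.copy()
    fac["district_vulnerability"] = vidx.set_axis(districts["district_id"]).reindex(
        fac["district_id"]
    ).to_numpy()

    in_selected = fac["district_id"].map(district_wave).notna()
    scores = rng.beta(5.0, 2.0, size=len(fac))  # mean ~0.71: most pass, some denied
    status = np.array(["none"] * len(fac), dtype=object)
    acc_wave = pd.array([pd.NA] * len(fac), dtype="Int64")
    for i in np.flatnonzero(in_selected.to_numpy()):
        decision = classify_accreditation(float(scores[i]))
        if decision != "denied":
            status[i] = decision
            acc_wave[i] = district_wave[fac["district_id"].iloc[i]]
    fac["accreditation_status"] = status
    fac["accreditation_wave"] = acc_wave
    fac["survey_score"] = np.where(in_selected, scores, np.nan)

    treated = fac["accreditation_status"].ne("none").to_numpy()
    flags = np.zeros(len(fac), dtype=int)
    flags[treated] = rng.random(treated.sum()) < cfg.other_interventions_frac
    # a few never-accredited facilities carry the flag too; the exclusion
    # rule must not drop those
    flags[~treated] = rng.random((~treated).sum()) < 0.02
    fac["other_interventions"] = flags
    return fac


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_women(facilities: pd.DataFrame, waves: list[int], cfg: TruthConfig) -> pd.DataFrame:
    """Draw woman-level records around each facility for each wave.

    Women are placed with isotropic Gaussian GPS jitter (SD
    ``cfg.gps_jitter_km``) around their facility. Each of the twelve binary
    indicators is Bernoulli with log-odds = logit(baseline) + wave effect +
    facility intercept − confounding x district vulnerability, plus, for
    treated facility-waves, the log-odds shift equivalent to the configured
    effect in percentage points at that cell's counterfactual probability.
    Eligibility flags are drawn per outcome so denominators differ; the
    indicator is NaN where the woman is not in the denominator.

    The returned frame keeps ``true_facility_id`` (the generating facility)
    as ground truth for linkage diagnostics; it is excluded from the
    women.csv export.
    """
    if facilities.empty:
        raise ValueError("facilities must be non-empty")
    if list(waves) != sorted(waves):
        raise ValueError("waves must be sorted ascending")
    rng = _rng(cfg.seed, "women")
    n_fac = len(facilities)
    n_w = cfg.women_per_facility_per_wave
    n_waves = len(waves)
    total = n_fac * n_waves * n_w

    fac_idx = np.repeat(np.arange(n_fac), n_waves * n_w)
    wave_arr = np.tile(np.repeat(np.asarray(waves), n_w), n_fac)

    flat = facilities["lat"].to_numpy()[fac_idx]
    flon = facilities["lon"].to_numpy()[fac_idx]
    dlat = rng.normal(0.0, cfg.gps_jitter_km / _KM_PER_DEG_LAT, total)
    dlon = rng.normal(0.0, cfg.gps_jitter_km / (_KM_PER_DEG_LON_EQ * np.cos(np.radians(flat))), total)

    acc_wave = facilities["accreditation_wave"].to_numpy(dtype="float64", na_value=np.nan)[fac_idx]
    treated_cell = ~np.isnan(acc_wave) & (wave_arr >= acc_wave)
    ever_treated = ~np.isnan(acc_wave)
    wave_rank = np.searchsorted(np.asarray(waves), wave_arr).astype(float)

    if "district_vulnerability" in facilities.columns:
        dvuln = facilities["district_vulnerability"].to_numpy(dtype=float)[fac_idx]
    else:
        dvuln = np.zeros(total)

    wave_eff = np.vectorize(lambda w: cfg.wave_effects.get(int(w), 0.0))(wave_arr)

    eps = 1e-6
    out = {}
    for k, name in enumerate(OUTCOMES):
        base = cfg.baseline_rates[name]
        b_i = rng.normal(0.0, cfg.facility_sd, n_fac)[fac_idx]
        eta0 = _logit(np.full(total, base)) + wave_eff + b_i - cfg.confounding_strength * dvuln
        p0 = _expit(eta0)
        if cfg.pretrend_ppts_per_wave:
            drift = (cfg.pretrend_ppts_per_wave / 100.0) * wave_rank
            p0 = np.where(ever_treated & ~treated_cell, np.clip(p0 + drift, eps, 1 - eps), p0)
        eff = cfg.effect_ppts.get(name, 0.0) / 100.0
        p1 = np.clip(p0 + eff, eps, 1 - eps)
        p = np.where(treated_cell, p1, p0)
        eligible = rng.random(total) < cfg.eligibility_rates[name]
        draws = (rng.random(total) < p).astype(float)
        out[name] = np.where(eligible, draws, np.nan)

    women = pd.DataFrame(
        {
            "woman_id": [f"W{i:07d}" for i in range(total)],
            "wave": wave_arr.astype(int),
            "lat": flat + dlat,
            "lon": flon + dlon,
            "true_facility_id": facilities["facility_id"].to_numpy()[fac_idx],
        }
    )
    for name in OUTCOMES:
        women[name] = out[name]
    return women


def generate_dataset(
    n_districts: int = 60,
    n_facilities: int = 600,
    waves: list[int] | None = None,
    rollout_waves: list[int] | None = None,
    cfg: TruthConfig | None = None,
) -> dict:
    """Run the full generator: districts -> facilities -> treatment -> women.

    Returns a dict with the three tables plus a truth sidecar recording the
    planted configuration (for recovery tests)."""
    cfg = cfg or TruthConfig()
    waves = list(waves or DEFAULT_WAVES)
    rollout = list(rollout_waves or DEFAULT_ROLLOUT_WAVES)
    if not set(rollout) <= set(waves):
        raise ValueError("rollout_waves must be a subset of the survey waves")
    districts = gen_districts(n_districts, cfg.seed)
    facilities = gen_facilities(districts, n_facilities, cfg.seed)
    facilities = assign_treatment(districts, facilities, rollout, cfg)
    women = gen_women(facilities, waves, cfg)
    truth = {
        "effect_ppts": {k: cfg.effect_ppts.get(k, 0.0) for k in OUTCOMES},
        "baseline_rates": cfg.baseline_rates,
        "waves": waves,
        "rollout_waves": rollout,
        "seed": cfg.seed,
        "n_treated_facilities": int(facilities["accreditation_status"].ne("none").sum()),
        "women_per_facility_per_wave": cfg.women_per_facility_per_wave,
    }
    return {"districts": districts, "facilities": facilities, "women": women, "truth": truth}


def write_dataset(data: dict, outdir: str | Path, cfg: TruthConfig | None = None) -> None:
    """Write districts/facilities/women CSVs, truth sidecar JSON, and config YAML.

    The women table is exported without the ``true_facility_id`` ground-truth
    column; that mapping lives in the sidecar domain only."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data["districts"].to_csv(outdir / "districts.csv", index=False)
    data["facilities"].to_csv(outdir / "facilities.csv", index=False)
    data["women"].drop(columns=["true_facility_id"]).to_csv(outdir / "women.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(data["truth"], fh, indent=2, default=str)
    if cfg is not None:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(cfg), fh)
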
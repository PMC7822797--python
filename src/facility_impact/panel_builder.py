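"""Collapse linked woman-level outcomes into a facility x wave panel.

Each cell holds the percentage of eligible women with the indicator set,
its denominator, the treatment status of the facility in that wave, and the
facility and district covariates used downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .synthetic_data import OUTCOMES, INDICATOR_COLUMNS, STAFF_CATEGORIES

log = logging.getLogger(__name__)

DEFAULT_MIN_DENOMINATOR = 5


def collapse_outcomes(links: pd.DataFrame, women: pd.DataFrame, wave: int) -> pd.DataFrame:
    """Per facility, per outcome: percentage over eligible women in one wave.

    A woman contributes to an outcome's denominator only when her indicator
    is non-missing (eligible). Facilities with zero linked women in the wave
    are omitted and counted in the log. Cells with zero eligible women get a
    missing percentage and n_eligible = 0.
    """
    w = women[women["wave"] == wave]
    l = links[links["wave"] == wave]
    unknown_women = set(l["woman_id"]) - set(w["woman_id"])
    if unknown_women:
        raise DataIntegrityError(f"links reference unknown woman ids, e.g. {sorted(unknown_women)[:3]}")
    merged = l[["woman_id", "facility_id"]].merge(w, on="woman_id", how="inner")

    grouped = merged.groupby("facility_id", sort=True)[list(OUTCOMES)]
    counts = grouped.count()
    means = grouped.mean()  # NaN (not eligible) excluded from both
    out = pd.DataFrame({"facility_id": counts.index, "wave": wave})
    for name in OUTCOMES:
        out[f"pct_{name}"] = (100.0 * means[name]).to_numpy()
        out[f"n_{name}"] = counts[name].to_numpy().astype(int)
    out = out.reset_index(drop=True)
    n_linked_fac = links[links["wave"] == wave]["facility_id"].nunique()
    if len(out) < n_linked_fac:
        log.info("collapse_outcomes: wave %s, %d facilities had no linked women", wave, n_linked_fac - len(out))
    return out


def build_panel(
    rows: pd.DataFrame,
    waves: list[int],
    facilities: pd.DataFrame | None = None,
    districts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the long facility x wave panel and attach covariates.

    The panel is keyed on (facility_id, wave); duplicate keys are a data
    integrity error. Unbalanced panels (facilities absent in some wave) are
    allowed and logged. When facility and district tables are supplied, the
    treatment indicator ``policy`` (1 iff the facility is accredited —
    provisionally or fully — by that wave) and the covariates enter.
    """
    if len(waves) < 2:
        raise ValueError("need >= 2 waves for a panel")
    panel = rows.copy()
    dup = panel.duplicated(subset=["facility_id", "wave"])
    if dup.any():
        bad = panel.loc[dup, ["facility_id", "wave"]].iloc[0]
        raise DataIntegrityError(f"duplicate (facility, wave) key: {tuple(bad)}")

    if facilities is not None:
        unknown = set(panel["facility_id"]) - set(facilities["facility_id"])
        if unknown:
            raise DataIntegrityError(f"panel references unknown facility ids, e.g. {sorted(unknown)[:3]}")
        fac_cols = ["facility_id", "district_id", "building_condition", "catchment_population",
                    "accreditation_wave", "accreditation_status", "other_interventions"]
        fac_cols += [f"staff_{c}" for c in STAFF_CATEGORIES if f"staff_{c}" in facilities.columns]
        panel = panel.merge(facilities[fac_cols], on="facility_id", how="left")
        acc = panel["accreditation_wave"].to_numpy(dtype="float64", na_value=np.nan)
        treated_status = panel["accreditation_status"].isin(["provisional", "full"]).to_numpy()
        panel["policy"] = ((panel["wave"].to_numpy() >= acc) & treated_status).astype(int)
        if districts is not None:
            dist_cols = ["district_id", *INDICATOR_COLUMNS, "region"]
            panel = panel.merge(districts[dist_cols], on="district_id", how="left")

    counts = panel.groupby("facility_id")["wave"].nunique()
    n_unbalanced = int((counts < len(waves)).sum())
    if n_unbalanced:
        log.info("build_panel: %d facilities observed in fewer than %d waves (unbalanced)", n_unbalanced, len(waves))
    per_outcome = {name: int(panel[f"pct_{name}"].notna().sum()) for name in OUTCOMES if f"pct_{name}" in panel}
    log.debug("build_panel: per-outcome observation counts %s", per_outcome)
    return panel.sort_values(["facility_id", "wave"]).reset_index(drop=True)


def apply_sample_rules(
    panel: pd.DataFrame,
    facilities: pd.DataFrame,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
) -> pd.DataFrame:
    """Apply the analysis-sample exclusion rules.

    Drops every row of accredited facilities that were simultaneously
    subject to other interventions (performance-based financing or user
    fees), so the treatment contrast reflects accreditation alone; a flagged
    but never-accredited facility is retained. Percentages with a
    denominator below ``min_denominator`` are set missing. Counts dropped by
    each rule are logged.
    """
    fac = facilities.set_index("facility_id")
    flagged = fac.index[(fac["other_interventions"] == 1) & (fac["accreditation_status"] != "none")]
    out = panel[~panel["facility_id"].isin(flagged)].copy()
    n_dropped = len(panel) - len(out)
    if n_dropped:
        log.info("apply_sample_rules: dropped %d rows from %d co-intervention facilities", n_dropped, len(flagged))
    n_masked = 0
    for name in OUTCOMES:
        pc, nc = f"pct_{name}", f"n_{name}"
        if pc in out.columns:
            mask = out[nc] < min_denominator
            n_masked += int((mask & out[pc].notna()).sum())
            out.loc[mask, pc] = np.nan
    if n_masked:
        log.info("apply_sample_rules: masked %d cells below the %d-woman denominator floor", n_masked, min_denominator)
    return out.reset_index(drop=True)
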
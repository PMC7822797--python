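"""Catchment assignment: link each woman to her nearest facility.

Distances are great-circle (haversine) on a sphere of radius 6371.0088 km.
Ties are broken by lowest facility_id so assignment is invariant to the
order of the facility table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


def _validate_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of range: |lat| <= 90, |lon| <= 180 required")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays."""
    _validate_coords(lat1, lon1)
    _validate_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def nearest_facility(woman, facilities: pd.DataFrame) -> dict:
    """Return the facility minimizing great-circle distance to one woman.

    ``woman`` is any mapping with lat/lon (and optionally woman_id, wave).
    Ties are broken by lowest facility_id."""
    if len(facilities) == 0:
        raise ValueError("facilities must be non-empty")
    fac = facilities.sort_values("facility_id", kind="stable").reset_index(drop=True)
    d = haversine_km(woman["lat"], woman["lon"], fac["lat"].to_numpy(), fac["lon"].to_numpy())
    j = int(np.argmin(d))  # first occurrence -> lowest id after sort
    return {
        "woman_id": woman.get("woman_id") if hasattr(woman, "get") else woman["woman_id"],
        "facility_id": fac["facility_id"].iloc[j],
        "distance_km": float(d[j]),
        "wave": woman["wave"] if "wave" in woman else None,
    }


def link_cohort(
    women: pd.DataFrame,
    facilities: pd.DataFrame,
    max_distance_km: float | None = None,
    chunk_size: int = 4096,
) -> tuple[pd.DataFrame, dict]:
    """Link every woman to her nearest facility.

    Returns ``(links, summary)`` where links has one row per woman
    (woman_id, facility_id, distance_km, wave) and summary reports median
    and max link distance plus the women-per-facility distribution. With
    ``max_distance_km`` set, implausible links are dropped and counted.
    """
    if len(facilities) == 0:
        raise ValueError("facilities must be non-empty")
    fac = facilities.sort_values("facility_id", kind="stable").reset_index(drop=True)
    flat, flon = fac["lat"].to_numpy(), fac["lon"].to_numpy()
    wlat, wlon = women["lat"].to_numpy(dtype=float), women["lon"].to_numpy(dtype=float)
    _validate_coords(wlat, wlon)
    _validate_coords(flat, flon)

    n = len(women)
    best_j = np.empty(n, dtype=int)
    best_d = np.empty(n, dtype=float)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        d = haversine_km(wlat[sl, None], wlon[sl, None], flat[None, :], flon[None, :])
        best_j[sl] = np.argmin(d, axis=1)
        best_d[sl] = d[np.arange(d.shape[0]), best_j[sl]]

    links = pd.DataFrame(
        {
            "woman_id": women["woman_id"].to_numpy(),
            "facility_id": fac["facility_id"].to_numpy()[best_j] if n else np.array([], dtype=object),
            "distance_km": best_d,
            "wave": women["wave"].to_numpy() if "wave" in women.columns else np.full(n, np.nan),
        }
    )
    n_dropped = 0
    if max_distance_km is not None:
        keep = links["distance_km"] <= max_distance_km
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("link_cohort: dropped %d links beyond %.1f km", n_dropped, max_distance_km)
        links = links[keep].reset_index(drop=True)

    per_fac = links["facility_id"].value_counts()
    summary = {
        "n_women": int(n),
        "n_linked": int(len(links)),
        "n_dropped_distance": n_dropped,
        "median_distance_km": float(links["distance_km"].median()) if len(links) else 0.0,
        "max_distance_km": float(links["distance_km"].max()) if len(links) else 0.0,
        "women_per_facility": {
            "min": int(per_fac.min()) if len(per_fac) else 0,
            "median": float(per_fac.median()) if len(per_fac) else 0.0,
            "max": int(per_fac.max()) if len(per_fac) else 0,
            "n_facilities_with_links": int(len(per_fac)),
        },
    }
    return links, summary


def mislinkage_rate(links: pd.DataFrame, women: pd.DataFrame) -> float:
    """Fraction of women not linked to their generating facility.

    Requires the ground-truth ``true_facility_id`` column (synthetic data
    diagnostic)."""
    merged = links.merge(women[["woman_id", "true_facility_id"]], on="woman_id", how="inner")
    if merged.empty:
        return 0.0
    return float((merged["facility_id"] != merged["true_facility_id"]).mean())
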
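import numpy as np
import pandas as pd
import pytest

from facility_impact import synthetic_data as sd
from facility_impact.diagnostics import build_analysis_panel


@pytest.fixture(scope="session")
def small_dataset():
    """Two-wave synthetic dataset with a planted +10 ppt effect on ANC."""
    cfg = sd.TruthConfig(
        effect_ppts={"anc_4plus_visits": 10.0},
        targeting_strength=1.5,
        confounding_strength=1.0,
        women_per_facility_per_wave=20,
        seed=42,
    )
    return sd.generate_dataset(n_districts=20, n_facilities=150,
                               waves=[2000, 2005], rollout_waves=[2005], cfg=cfg), cfg


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    data, _ = small_dataset
    panel, meta = build_analysis_panel(data, use_truth_links=True)
    return panel, data, meta


@pytest.fixture()
def two_by_two_panel():
    """Minimal 2 facilities x 2 waves panel: treated changes +10, control +2."""
    return pd.DataFrame(
        {
            "facility_id": ["A", "A", "B", "B"],
            "district_id": ["d1", "d1", "d2", "d2"],
            "wave": [2000, 2005, 2000, 2005],
            "policy": [0, 1, 0, 0],
            "pct_anc_4plus_visits": [50.0, 60.0, 40.0, 42.0],
        }
    )


def make_random_panel(n_facilities=200, n_waves=4, seed=0, n_districts=25):
    """Unstructured random panel for estimator-equivalence checks."""
    rng = np.random.default_rng(seed)
    fids = [f"F{i:03d}" for i in range(n_facilities)]
    districts = rng.choice([f"d{j}" for j in range(n_districts)], n_facilities)
    waves = [2000 + 5 * k for k in range(n_waves)]
    treated = rng.random(n_facilities) < 0.4
    onset = rng.choice(waves[1:], n_facilities)
    rows = []
    for i, f in enumerate(fids):
        for w in waves:
            rows.append({
                "facility_id": f, "district_id": districts[i], "wave": w,
                "policy": int(treated[i] and w >= onset[i]),
                "pct_anc_4plus_visits": rng.normal(50, 10),
            })
    return pd.DataFrame(rows)
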
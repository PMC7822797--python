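"""Collapse linked woman-level outcomes into the facility x wave panel.

Per facility and wave, each outcome becomes the percentage of eligible
women with the indicator set (denominators recorded). Applies the analysis
sample rules: accredited facilities under concurrent interventions are
excluded, and cells with fewer than five eligible women are set missing.
Attaches the treatment indicator and facility/district covariates.
"""

from pathlib import Path

import pandas as pd

from facility_impact import panel_builder as pb
from facility_impact.synthetic_data import OUTCOMES

DEMO = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    links = pd.read_csv(DEMO / "links.csv")
    women = pd.read_csv(DEMO / "women.csv")
    facilities = pd.read_csv(DEMO / "facilities.csv")
    districts = pd.read_csv(DEMO / "districts.csv")
    waves = sorted(women["wave"].unique())
    rows = pd.concat([pb.collapse_outcomes(links, women, w) for w in waves], ignore_index=True)
    panel = pb.build_panel(rows, waves, facilities, districts)
    panel = pb.apply_sample_rules(panel, facilities)
    panel.to_csv(DEMO / "panel.csv", index=False)
    obs = {name: int(panel[f"pct_{name}"].notna().sum()) for name in OUTCOMES}
    print(f"panel: {len(panel)} facility-wave rows over waves {waves}")
    print("non-missing cells per outcome:", obs)
    print(f"treated share of rows: {panel['policy'].mean():.2f}")


if __name__ == "__main__":
    main()
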
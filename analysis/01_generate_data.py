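"""Generate the synthetic evaluation dataset.

Emulates a DHS-style setting: 60 districts with socio-economic indicators,
400 primary-care facilities on a jittered lattice, six survey waves
(1992-2014) with a staggered, vulnerability-targeted accreditation rollout,
and ~25 women per facility-wave with twelve binary outcomes. Plants
known effects (in ppts) on a subset of outcomes so downstream stages can be
judged against ground truth. Writes districts/facilities/women CSVs, the
config, and the truth sidecar under results/demo/.
"""

from pathlib import Path

from facility_impact import synthetic_data as sd

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "demo"

PLANTED = {
    "knowledge_side_effects": 16.0,
    "institutional_delivery": 7.0,
    "skilled_delivery": 11.0,
    "child_ari": -10.0,
    "child_fever": -10.0,
    "child_diarrhea": -4.0,
}


def main() -> None:
    cfg = sd.TruthConfig(effect_ppts=PLANTED, targeting_strength=1.5,
                         confounding_strength=0.8, seed=2026)
    data = sd.generate_dataset(n_districts=60, n_facilities=400, cfg=cfg)
    sd.write_dataset(data, OUTDIR, cfg=cfg)
    n_treated = data["truth"]["n_treated_facilities"]
    print(f"generated {len(data['women'])} women across {len(data['facilities'])} facilities "
          f"({n_treated} accredited) in {len(data['districts'])} districts")
    print(f"planted effects (ppts): {PLANTED}")
    print(f"wrote CSVs + truth sidecar to {OUTDIR}")


if __name__ == "__main__":
    main()
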
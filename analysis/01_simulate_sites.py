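#!/usr/bin/env python
"""Generate the two synthetic institutions used by the downstream analyses.

site_A is the reference institution (all six CDM dimensions recorded).
site_B is larger, carries negative institutional multipliers on all three
CVD outcomes (log ratios of the two sites' reported incidences), and lacks
hemoglobin and smoking data entirely.  After generation, realistic
column-level missingness is injected into the recorded labs/vitals: blood
pressure and white-cell counts are missing for over half of the baseline
records, HbA1c is missing at random conditional on age.

Cohort sizes here are scaled to roughly half the motivating study's
(6,000 / 8,000 patients) to keep the full analysis chain quick to re-run.

Writes results/cdm/<site>/ (CDM CSVs + manifest + planted truth).
"""

from pathlib import Path

from cvdadapt.cdm import write_cdm
from cvdadapt.simulate import (
    CovariateSpec,
    generate_institution,
    inject_missingness,
    site_profiles,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "cdm"
SEED = 20240710

MISSINGNESS = [
    CovariateSpec("sbp", "truncnormal", {"mean": 133, "sd": 16, "lower": 80,
                                         "upper": 220}, missing_fraction=0.55),
    CovariateSpec("dbp", "truncnormal", {"mean": 78, "sd": 11, "lower": 40,
                                         "upper": 130}, missing_fraction=0.55),
    CovariateSpec("wbc", "truncnormal", {"mean": 7.5, "sd": 2, "lower": 2,
                                         "upper": 30}, missing_fraction=0.50),
    CovariateSpec("hba1c", "truncnormal", {"mean": 7.8, "sd": 1.4, "lower": 4,
                                           "upper": 15}, missing_fraction=0.15,
                  missing_mechanism="MAR", missing_conditional="age"),
]


def main() -> None:
    profiles = site_profiles(n_a=6000, n_b=8000, seed=SEED)
    for i, (label, cfg) in enumerate(profiles.items()):
        cdm, truth = generate_institution(cfg, label, site_index=i)
        cdm = inject_missingness(cdm, MISSINGNESS, seed=SEED + i)
        write_cdm(cdm, OUT / label)
        truth.save(OUT / label)
        print(f"{label}: n={cfg.n_patients}, "
              f"multipliers={ {k: round(v, 3) for k, v in cfg.institution_multipliers.items()} }, "
              f"absent={list(cfg.absent_columns)} -> {OUT / label}")


if __name__ == "__main__":
    main()
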
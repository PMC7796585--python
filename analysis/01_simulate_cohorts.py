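#!/usr/bin/env python
"""Simulate the study cohorts: control urines/DUS, one patient per reported
disorder-matrix profile, and the mixed positive QC; write peak-area and
metadata TSVs under results/simulated/."""
from pathlib import Path

from oligoscreen.panels import load_panel_registry
from oligoscreen.quantify import write_peak_area_tables, write_sample_meta
from oligoscreen.synthetic_data import (SIGNATURES, SimulationConfig,
                                        gen_control_cohort, gen_patient, gen_qc_mix)

OUT = Path("results/simulated")
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    registry = load_panel_registry()
    config = SimulationConfig(seed=SEED)
    for matrix in ("urine", "dus"):
        controls = gen_control_cohort(config, matrix, None, registry)
        write_peak_area_tables([t for _, t in controls],
                               OUT / f"{matrix}_controls_areas.tsv")
        write_sample_meta([m for m, _ in controls], OUT / f"{matrix}_controls_meta.tsv")

        batch = []
        for disorder, sig in SIGNATURES.items():
            if matrix in sig.folds:
                batch.append(gen_patient(config, disorder, matrix, registry=registry))
        batch.append(gen_qc_mix(config, matrix, registry=registry))
        write_peak_area_tables([t for _, t in batch], OUT / f"{matrix}_batch_areas.tsv")
        write_sample_meta([m for m, _ in batch], OUT / f"{matrix}_batch_meta.tsv")
        print(f"{matrix}: {len(controls)} controls, {len(batch) - 1} patients + iQC "
              f"-> {OUT}")


if __name__ == "__main__":
    main()
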
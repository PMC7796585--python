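#!/usr/bin/env python
"""Scatter of control vs patient MoMs per disorder's most characteristic
transition (log scale), with the matrix positivity threshold; writes
results/figures/separation_<matrix>.png."""
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from oligoscreen.panels import load_panel_registry
from oligoscreen.quantify import (adjust_creatinine, compute_ratio_profile,
                                  read_peak_area_tables, read_sample_meta)
from oligoscreen.reference import compute_mom, read_reference
from oligoscreen.screen import ScreenThresholds

PANEL_DISORDER = {"SIAL": "sialidosis", "AMAN": "alpha_mannosidosis",
                  "BMAN": "beta_mannosidosis", "FUCO": "fucosidosis",
                  "AGU": "aspartylglucosaminuria", "GM1": "gm1_gangliosidosis",
                  "GM2": "gm2_sandhoff", "GLC4": "pompe"}


def moms_for(registry, ref, areas_path, meta_path):
    metas = read_sample_meta(meta_path)
    out = {}
    for tab in read_peak_area_tables(areas_path):
        meta = metas[tab.sample_id]
        prof = adjust_creatinine(compute_ratio_profile(tab, registry), meta)
        out[tab.sample_id] = compute_mom(prof, ref)
    return out


def main() -> None:
    registry = load_panel_registry()
    out_dir = Path("results/figures")
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = ScreenThresholds()
    for matrix in ("urine", "dus"):
        ref = read_reference(f"results/reference_{matrix}.tsv")
        controls = moms_for(registry, ref, f"results/simulated/{matrix}_controls_areas.tsv",
                            f"results/simulated/{matrix}_controls_meta.tsv")
        patients = moms_for(registry, ref, f"results/simulated/{matrix}_batch_areas.tsv",
                            f"results/simulated/{matrix}_batch_meta.tsv")
        fig, ax = plt.subplots(figsize=(9, 4.5))
        panels = list(registry.panels)
        for i, panel in enumerate(panels):
            key = panel.most_characteristic.key
            cvals = [m.moms.get(key) for m in controls.values() if m.moms.get(key)]
            ax.scatter(np.full(len(cvals), i) - 0.15 + 0.1 * np.random.default_rng(i).random(len(cvals)),
                       cvals, s=10, c="steelblue", alpha=0.6,
                       label="controls" if i == 0 else None)
            pid_patient = f"{matrix}_{PANEL_DISORDER[panel.panel_id]}_00"
            if pid_patient in patients:
                pv = patients[pid_patient].moms.get(key)
                if pv:
                    ax.scatter([i + 0.15], [pv], s=45, c="firebrick", marker="D",
                               label="patient" if i == 0 else None)
        ax.axhline(thresholds.for_matrix(matrix), color="gray", ls="--", lw=1,
                   label=f"threshold {thresholds.for_matrix(matrix):g}x")
        ax.set_yscale("log")
        ax.set_xticks(range(len(panels)), [p.panel_id for p in panels])
        ax.set_ylabel("MoM (log scale)")
        ax.set_title(f"Control vs patient MoMs, {matrix} (most characteristic transitions)")
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        path = out_dir / f"separation_{matrix}.png"
        fig.savefig(path, dpi=150)
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
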
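#!/usr/bin/env python
"""Build per-matrix control-median references from the simulated control
cohorts and audit the panel registry; write results/reference_<matrix>.tsv."""
from pathlib import Path

from oligoscreen.panels import load_panel_registry, validate_registry
from oligoscreen.quantify import (adjust_creatinine, compute_ratio_profile,
                                  read_peak_area_tables, read_sample_meta)
from oligoscreen.reference import build_reference, write_reference

SIM = Path("results/simulated")


def main() -> None:
    registry = load_panel_registry()
    audit = validate_registry(registry)
    print("registry audit:", "clean" if audit.clean else "; ".join(audit.flags))
    for pid, counts in audit.panel_counts.items():
        print(f"  {pid}: {counts}, quantifiers={audit.quantifier_counts[pid]}")

    for matrix in ("urine", "dus"):
        metas = read_sample_meta(SIM / f"{matrix}_controls_meta.tsv")
        profiles = [
            adjust_creatinine(compute_ratio_profile(t, registry), metas[t.sample_id])
            for t in read_peak_area_tables(SIM / f"{matrix}_controls_areas.tsv")]
        ref = build_reference(profiles, matrix)
        out = Path(f"results/reference_{matrix}.tsv")
        write_reference(ref, out)
        weak = ref.under_strength()
        print(f"{matrix}: median reference from n={ref.n_controls} controls, "
              f"{len(ref.medians)} transitions"
              + (f", {len(weak)} under-strength" if weak else "") + f" -> {out}")


if __name__ == "__main__":
    main()
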
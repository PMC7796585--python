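#!/usr/bin/env python
"""Screen the simulated patient batches against the control references and
summarize the per-disorder calls; write reports under results/screen_<matrix>/."""
from pathlib import Path

from oligoscreen.workflow import WorkflowConfig, run_screening


def main() -> None:
    for matrix in ("urine", "dus"):
        config = WorkflowConfig(
            areas_path=f"results/simulated/{matrix}_batch_areas.tsv",
            meta_path=f"results/simulated/{matrix}_batch_meta.tsv",
            reference_paths={matrix: f"results/reference_{matrix}.tsv"},
            qc_sample_ids=(f"{matrix}_iqc",),
            out_dir=f"results/screen_{matrix}", output_format="json_text")
        result = run_screening(config)
        print(f"== {matrix} batch ==")
        for line in result.log_lines:
            print(" ", line)
        for rep in result.reports:
            positives = [c.panel_id for c in rep.calls if c.positive]
            print(f"  {rep.sample_id:32s} {rep.interpretation:18s} "
                  f"{rep.disorder or '/'.join(rep.differential[:2]) + '...' if rep.differential else rep.disorder or '-':40s} "
                  f"positive panels: {','.join(positives) or '-'}")
        if result.sample_errors:
            print("  errors:", result.sample_errors)
        print(f"  QC: {'pass' if result.qc_passed else 'FAIL'}")


if __name__ == "__main__":
    main()
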
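"""End-to-end orchestration: files in, screening reports out.

The pipeline per sample is: (integrate chromatograms if supplied) ->
internal-standard ratios -> creatinine adjustment -> MoM against the
matrix-matched control reference -> panel calls and interpretation.  A batch
is gated, but not suppressed, by its internal-QC sample: QC failure flags the
run while individual reports are still written.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import OligoscreenError, WorkflowError
from .panels import PanelRegistry, load_panel_registry, validate_registry
from .chromatograms import RetentionWindow, integrate_peak, read_chromatogram_table
from .quantify import (PeakAreaTable, SampleMeta, adjust_creatinine,
                       compute_ratio_profile, read_peak_area_tables, read_sample_meta)
from .reference import (ControlReference, MoMProfile, build_reference, compute_mom,
                        read_reference)
from .screen import ScreenReport, ScreenThresholds, screen_sample
from .validate import QCResult, qc_check

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkflowConfig:
    """Paths, thresholds and flags for one screening run."""

    areas_path: str | None = None
    meta_path: str | None = None
    chromatograms_path: str | None = None
    panels_path: str | None = None
    reference_paths: Mapping[str, str] = field(default_factory=dict)
    controls_areas_path: str | None = None
    controls_meta_path: str | None = None
    out_dir: str | None = None
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    quantifier_only: bool = False
    qc_sample_ids: tuple[str, ...] = ()
    output_format: str = "tsv"


@dataclass(frozen=True)
class RunResult:
    reports: tuple[ScreenReport, ...]
    qc_results: Mapping[str, QCResult]
    sample_errors: Mapping[str, str]
    log_lines: tuple[str, ...]

    @property
    def qc_passed(self) -> bool | None:
        if not self.qc_results:
            return None
        return all(r.passed for r in self.qc_results.values())


def integrate_sample(traces, registry: PanelRegistry) -> PeakAreaTable:
    """Turn one sample's chromatogram traces into a peak-area table using the
    registry's configured retention windows."""
    defs = {t.key: t for t in registry.all_transitions()}
    entries = {}
    sample_id = None
    for tr in traces:
        sample_id = tr.sample_id
        tdef = defs.get(tr.key)
        if tdef is None or tdef.expected_rt_min is None or tdef.rt_window_min is None:
            log.warning("sample %s: no retention window for %s; skipped",
                        tr.sample_id, tr.key)
            continue
        area, _apex = integrate_peak(tr, RetentionWindow(tdef.expected_rt_min,
                                                         tdef.rt_window_min))
        entries[tr.key] = area
    if sample_id is None:
        raise WorkflowError("no traces to integrate")
    return PeakAreaTable(sample_id=sample_id, entries=entries)


def screen_batch(samples: Sequence[tuple[SampleMeta, PeakAreaTable]],
                 registry: PanelRegistry,
                 references: Mapping[str, ControlReference],
                 thresholds: ScreenThresholds | None = None,
                 quantifier_only: bool = False,
                 qc_sample_ids: Sequence[str] = (),
                 ) -> RunResult:
    """Pure in-memory batch screening; per-sample failures are recorded and do
    not abort the run."""
    thresholds = thresholds or ScreenThresholds()
    reports: list[ScreenReport] = []
    qc_results: dict[str, QCResult] = {}
    errors: dict[str, str] = {}
    lines: list[str] = []
    for meta, areas in samples:
        try:
            profile = adjust_creatinine(compute_ratio_profile(areas, registry), meta)
            ref = references.get(meta.matrix)
            if ref is None:
                raise WorkflowError(f"no reference for matrix {meta.matrix!r}")
            mom = compute_mom(profile, ref, warn_age_months=meta.age_months)
            if meta.sample_id in qc_sample_ids:
                qc_results[meta.sample_id] = qc_check(mom, registry, thresholds)
                lines.append(f"QC {meta.sample_id}: "
                             f"{'pass' if qc_results[meta.sample_id].passed else 'FAIL'}")
                continue
            reports.append(screen_sample(mom, registry, thresholds,
                                         quantifier_only=quantifier_only))
        except OligoscreenError as exc:
            errors[meta.sample_id] = str(exc)
            lines.append(f"sample {meta.sample_id}: ERROR {exc}")
    return RunResult(reports=tuple(reports), qc_results=qc_results,
                     sample_errors=errors, log_lines=tuple(lines))


def run_screening(config: WorkflowConfig) -> RunResult:
    """File-level entry point: load registry and references, read samples,
    screen, and (if an output directory is configured) write reports."""
    registry = load_panel_registry(config.panels_path)
    audit = validate_registry(registry)
    lines = [f"registry: {len(list(registry.all_transitions()))} transitions, "
             f"{len(registry.panels)} panels, audit "
             f"{'clean' if audit.clean else '; '.join(audit.flags)}"]

    references: dict[str, ControlReference] = {
        m: read_reference(p) for m, p in config.reference_paths.items()}
    if not references:
        if not (config.controls_areas_path and config.controls_meta_path):
            raise WorkflowError("no reference files and no control cohort to build one from")
        cmetas = read_sample_meta(config.controls_meta_path)
        profiles: dict[str, list] = {}
        for tab in read_peak_area_tables(config.controls_areas_path):
            meta = cmetas[tab.sample_id]
            prof = adjust_creatinine(compute_ratio_profile(tab, registry), meta)
            profiles.setdefault(meta.matrix, []).append(prof)
        references = {m: build_reference(profs, m) for m, profs in profiles.items()}
    for m, ref in references.items():
        lines.append(f"reference[{m}]: n_controls={ref.n_controls}, "
                     f"age_stratum={ref.age_stratum}")

    if config.chromatograms_path:
        traces = read_chromatogram_table(config.chromatograms_path)
        by_sample: dict[str, list] = {}
        for tr in traces:
            by_sample.setdefault(tr.sample_id, []).append(tr)
        tables = [integrate_sample(trs, registry) for trs in by_sample.values()]
    elif config.areas_path:
        tables = read_peak_area_tables(config.areas_path)
    else:
        raise WorkflowError("no input: provide areas_path or chromatograms_path")
    if not config.meta_path:
        raise WorkflowError("meta_path is required")
    metas = read_sample_meta(config.meta_path)
    samples = [(metas[t.sample_id], t) for t in tables]

    result = screen_batch(samples, registry, references, config.thresholds,
                          config.quantifier_only, config.qc_sample_ids)
    result = RunResult(reports=result.reports, qc_results=result.qc_results,
                       sample_errors=result.sample_errors,
                       log_lines=tuple(lines) + result.log_lines)
    if config.out_dir:
        write_report(result.reports, config.out_dir, config.output_format)
    return result


# ---------------------------------------------------------------------------
# report writing

PANEL_CALL_COLUMNS = ["sample_id", "matrix", "panel_id", "disorder", "status",
                      "n_transitions_over", "n_transitions_required",
                      "interpretation", "evidence"]


def _fmt_mom(v: float | None) -> str:
    return "NQ" if v is None else f"{v:.3g}"


def write_report(reports: Sequence[ScreenReport], out_dir: str | Path,
                 format: str = "tsv") -> dict[str, Path]:
    """Write one per-(sample, panel) TSV plus a per-sample summary.

    MoMs are rendered with 3 significant figures; ``NQ`` marks a transition
    that was not quantifiable.
    """
    if not reports:
        raise WorkflowError("no reports to write")
    if format not in ("tsv", "json_text"):
        raise WorkflowError(f"unknown report format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in reports:
        for call in rep.calls:
            evidence = ";".join(f"{k}={_fmt_mom(v)}" for k, v in call.evidence.items())
            rows.append({"sample_id": rep.sample_id, "matrix": rep.matrix,
                         "panel_id": call.panel_id, "disorder": call.disorder_name,
                         "status": call.status,
                         "n_transitions_over": call.n_transitions_over,
                         "n_transitions_required": call.n_transitions_required,
                         "interpretation": rep.interpretation, "evidence": evidence})
    calls_path = out / "panel_calls.tsv"
    pd.DataFrame(rows, columns=PANEL_CALL_COLUMNS).to_csv(calls_path, sep="\t", index=False)

    summary = [{"sample_id": r.sample_id, "matrix": r.matrix,
                "interpretation": r.interpretation, "disorder": r.disorder,
                "differential": list(r.differential), "notes": list(r.notes)}
               for r in reports]
    if format == "json_text":
        summary_path = out / "screen_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    else:
        summary_path = out / "screen_summary.tsv"
        pd.DataFrame([{**s, "differential": "; ".join(s["differential"]),
                       "notes": " | ".join(s["notes"])} for s in summary]
                     ).to_csv(summary_path, sep="\t", index=False)
    return {"panel_calls": calls_path, "summary": summary_path}


def read_panel_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
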
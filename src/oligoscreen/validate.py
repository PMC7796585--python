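"""Assay-validation statistics: linearity, precision, and batch QC.

Linearity is assessed per transition from three relative urine concentrations
(50/100/150 uL aliquots in a constant final volume, i.e. nominal levels
1/2/3) via the squared Pearson correlation of level vs response.  Precision is
the CV% of replicate injections: 10 in one run (intra-day) or 10 on each of
three days (inter-day, pooled).  Batch acceptance is gated on a mixed positive
internal QC containing eight disorders, which must screen positive on all
eight panels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PrecisionError
from .panels import PanelRegistry, TransitionKey
from .reference import MoMProfile
from .screen import ScreenThresholds, call_panel

#: The eight disorders in the mixed positive internal QC, by panel id.
IQC_PANELS = ("SIAL", "AMAN", "BMAN", "FUCO", "AGU", "GM1", "GM2", "GLC4")


@dataclass(frozen=True)
class LinearitySeries:
    """Response (area ratio) at increasing relative concentrations."""

    transition: TransitionKey
    nominal_levels: tuple[float, ...] = (1.0, 2.0, 3.0)
    responses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.nominal_levels) < 3:
            raise ValueError("need at least 3 levels")
        if len(self.responses) != len(self.nominal_levels):
            raise ValueError("responses must match nominal_levels in length")
        if np.any(np.diff(self.nominal_levels) <= 0):
            raise ValueError("nominal levels must be strictly increasing")


@dataclass(frozen=True)
class PrecisionSeries:
    """Replicate area ratios grouped by day."""

    transition: TransitionKey
    replicate_groups: tuple[tuple[float, ...], ...]
    design: str = "intra_day"

    def __post_init__(self) -> None:
        if self.design not in ("intra_day", "inter_day"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "intra_day" and len(self.replicate_groups) != 1:
            raise ValueError("intra_day series must have exactly one replicate group")
        if self.design == "inter_day" and len(self.replicate_groups) < 2:
            raise ValueError("inter_day series needs at least two days")

    def pooled(self) -> np.ndarray:
        return np.concatenate([np.asarray(g, dtype=float) for g in self.replicate_groups])


def linearity_r2(series: LinearitySeries) -> float | None:
    """Squared Pearson correlation between nominal level and response.

    Equals the coefficient of determination of the unconstrained least-squares
    line.  Returns ``None`` (undefined) when the responses have zero variance.
    """
    x = np.asarray(series.nominal_levels, dtype=float)
    y = np.asarray(series.responses, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.std(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def precision_cv(series: PrecisionSeries, per_day_mean: bool = False) -> float:
    """CV% over all replicates pooled (sample SD / mean x 100).

    ``per_day_mean`` computes the CV of day means instead (variant estimator
    for inter-day designs).
    """
    if per_day_mean:
        values = np.array([np.mean(g) for g in series.replicate_groups], dtype=float)
    else:
        values = series.pooled()
    if values.size < 2:
        raise PrecisionError("need at least 2 replicates")
    mean = float(np.mean(values))
    if mean <= 0:
        raise PrecisionError(f"replicate mean {mean} is not positive")
    return 100.0 * float(np.std(values, ddof=1)) / mean


@dataclass(frozen=True)
class QCResult:
    """Batch-gate outcome on the eight-disorder internal QC."""

    passed: bool
    panel_status: Mapping[str, str]
    missing_panels: tuple[str, ...]
    notes: tuple[str, ...] = ()


def qc_check(qc_mom: MoMProfile, registry: PanelRegistry,
             thresholds: ScreenThresholds | None = None) -> QCResult:
    """Pass iff all eight internal-QC constituent panels call positive."""
    if thresholds is None:
        thresholds = ScreenThresholds()
    status: dict[str, str] = {}
    notes: list[str] = []
    for pid in IQC_PANELS:
        call = call_panel(qc_mom, registry.panel(pid), thresholds)
        status[pid] = call.status
        if call.status == "not_assessable":
            notes.append(f"panel {pid} not assessable on this batch's reference")
    missing = tuple(pid for pid, st in status.items() if st != "positive")
    return QCResult(passed=not missing, panel_status=status,
                    missing_panels=missing, notes=tuple(notes))


@dataclass(frozen=True)
class ValidationBounds:
    """Acceptance gates for simulated validation runs (configurable)."""

    r2_min: float = 0.70
    cv_max_pct: float = 30.0


def build_validation_report(
        linearity: Sequence[LinearitySeries],
        intra: Sequence[PrecisionSeries],
        inter: Sequence[PrecisionSeries],
        bounds: ValidationBounds | None = None) -> pd.DataFrame:
    """Assemble a per-transition validation table with pass flags."""
    bounds = bounds or ValidationBounds()
    rows: dict[TransitionKey, dict] = {}

    def row(key: TransitionKey) -> dict:
        return rows.setdefault(key, {"q1_mz": key.q1_mz, "q3_mz": key.q3_mz,
                                     "polarity": key.polarity, "r2": np.nan,
                                     "cv_intra_pct": np.nan, "cv_inter_pct": np.nan})

    for s in linearity:
        r2 = linearity_r2(s)
        row(s.transition)["r2"] = np.nan if r2 is None else r2
    for s in intra:
        row(s.transition)["cv_intra_pct"] = precision_cv(s)
    for s in inter:
        row(s.transition)["cv_inter_pct"] = precision_cv(s)
    df = pd.DataFrame(list(rows.values()))
    df["r2_pass"] = df["r2"] >= bounds.r2_min
    df["cv_pass"] = (df[["cv_intra_pct", "cv_inter_pct"]].max(axis=1, skipna=True)
                     <= bounds.cv_max_pct)
    return df
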
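"""Per-transition chromatogram traces and peak integration.

Vendor software normally turns the extracted-ion chromatogram of each MRM
transition into a peak area.  This module makes that step an explicit,
testable operator: trapezoidal integration over a configured retention
window, with a linear baseline joining the signal values at the window edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrationError
from .panels import DETECTION_WINDOW_MIN, TransitionKey

log = logging.getLogger(__name__)

#: Total chromatographic run time (min): detection segment plus column
#: reconditioning.
TOTAL_RUN_TIME_MIN = 27.5


@dataclass(frozen=True)
class GradientStep:
    time_min: float
    pct_a: float
    pct_b: float
    flow_ml_min: float


#: Binary-gradient program of the HILIC separation.  A: 5 mM ammonium formate
#: + 0.05% formic acid in water; B: the same salts in acetonitrile/water 90/10.
GRADIENT_PROGRAM: tuple[GradientStep, ...] = (
    GradientStep(0.00, 5, 95, 0.5),
    GradientStep(5.00, 60, 40, 0.5),
    GradientStep(13.30, 60, 40, 0.5),
    GradientStep(13.50, 30, 70, 0.5),
    GradientStep(15.50, 30, 70, 0.5),
    GradientStep(17.50, 5, 95, 0.5),
    GradientStep(27.50, 5, 95, 0.5),
)


@dataclass(frozen=True)
class RetentionWindow:
    """Integration window [center - half_width, center + half_width] in minutes."""

    center_min: float
    half_width_min: float

    def __post_init__(self) -> None:
        if self.half_width_min <= 0:
            raise ValueError("half_width_min must be positive")
        if self.center_min - self.half_width_min < 0:
            raise ValueError("retention window starts before 0 min")
        if self.center_min + self.half_width_min > DETECTION_WINDOW_MIN:
            raise ValueError(
                f"retention window ends after the {DETECTION_WINDOW_MIN} min detection segment")

    @property
    def start(self) -> float:
        return self.center_min - self.half_width_min

    @property
    def stop(self) -> float:
        return self.center_min + self.half_width_min


@dataclass(frozen=True)
class ChromatogramTrace:
    """Time/intensity trace of one transition for one sample."""

    key: TransitionKey
    sample_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if times.shape != intens.shape or times.ndim != 1:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if times.size and (times[0] < 0 or times[-1] > TOTAL_RUN_TIME_MIN):
            raise ValueError(f"times must lie within [0, {TOTAL_RUN_TIME_MIN}] min")
        if np.any(np.diff(times) <= 0):
            raise IntegrationError("times must be strictly increasing")
        if np.any(intens < 0):
            raise ValueError("intensities must be non-negative")


def integrate_peak(trace: ChromatogramTrace, window: RetentionWindow) -> tuple[float, float]:
    """Integrate the trace over ``window`` after linear baseline subtraction.

    The baseline is the straight line joining the first and last signal values
    inside the window; the area is the trapezoidal integral of the corrected
    signal (clipped at zero if it comes out negative).  Returns
    ``(area, apex_time)`` where the apex is the time of the maximum corrected
    intensity (earliest on ties).
    """
    mask = (trace.times >= window.start) & (trace.times <= window.stop)
    t = trace.times[mask]
    y = trace.intensities[mask]
    if t.size < 3:
        raise IntegrationError(
            f"only {t.size} points inside window [{window.start:.2f}, {window.stop:.2f}] "
            f"min for {trace.key} (need >= 3)")
    baseline = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    corrected = y - baseline
    area = float(np.trapezoid(corrected, t))
    if area < 0:
        area = 0.0
    apex = float(t[int(np.argmax(corrected))])
    return area, apex


# ---------------------------------------------------------------------------
# exchange format

CHROM_COLUMNS = ["sample_id", "q1_mz", "q3_mz", "polarity", "time_min", "intensity"]


def read_chromatogram_table(path: str | Path) -> list[ChromatogramTrace]:
    """Read a TSV of chromatogram points into one trace per (sample, transition).

    Column order within each trace is preserved from the file.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except ValueError as exc:
        raise FormatError(f"cannot parse chromatogram table {path}: {exc}") from exc
    missing = [c for c in CHROM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"chromatogram table {path} missing column(s) {missing}")
    if df.empty:
        log.warning("chromatogram table %s has a header but no rows", path)
        return []
    for col in ("q1_mz", "q3_mz", "time_min", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"non-numeric value in column {col!r} at line {line} of {path}")
        df[col] = coerced
    traces = []
    for (sid, q1, q3, pol), grp in df.groupby(
            ["sample_id", "q1_mz", "q3_mz", "polarity"], sort=False):
        traces.append(ChromatogramTrace(
            key=TransitionKey(q1, q3, pol), sample_id=str(sid),
            times=grp["time_min"].to_numpy(), intensities=grp["intensity"].to_numpy()))
    return traces


def write_chromatogram_table(traces: Iterable[ChromatogramTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "sample_id": tr.sample_id,
            "q1_mz": tr.key.q1_mz,
            "q3_mz": tr.key.q3_mz,
            "polarity": tr.key.polarity,
            "time_min": tr.times,
            "intensity": tr.intensities,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
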
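"""Internal-standard ratios and creatinine normalization.

Every analyte peak area is ratioed to the Glc7 internal-standard area of the
*same* acquisition polarity.  Urinary concentration differences are removed by
normalizing to a creatinine concentration of 1 mM: samples at >= 1 mM are
physically diluted to 1 mM before the run (no arithmetic correction), samples
below 1 mM are run neat and corrected after the run by the factor
1 / creatinine.  Because the internal standard is spiked *after* the dilution
decision, its area is creatinine-independent and the post-hoc factor applies
directly to the analyte/IS ratios — the central assumption of this model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import FormatError, QuantificationError
from .panels import PanelRegistry, TransitionKey, POLARITIES

log = logging.getLogger(__name__)

MATRICES = ("urine", "dus")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one urine or dried-urine-spot (DUS) sample.

    ``creatinine_mM`` is the creatinine concentration of the analyzed fluid
    (urine, or DUS extract) before any dilution decision.  ``dilution_applied``
    records that the lab physically diluted the fluid to 1 mM.
    """

    sample_id: str
    matrix: str
    creatinine_mM: float
    age_months: float | None = None
    dilution_applied: bool = False

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValueError(f"matrix must be one of {MATRICES}, got {self.matrix!r}")
        if not self.creatinine_mM > 0:
            raise ValueError(f"creatinine_mM must be > 0, got {self.creatinine_mM}")
        if self.dilution_applied and self.creatinine_mM < 1.0:
            raise ValueError(
                f"sample {self.sample_id}: dilution to 1 mM recorded but creatinine "
                f"{self.creatinine_mM} mM < 1 (sub-1 mM samples are run neat)")


@dataclass(frozen=True)
class PeakAreaTable:
    """Per-transition peak areas of one sample; ``None`` marks a transition
    that was monitored in the method but not acquired (distinct from area 0)."""

    sample_id: str
    entries: Mapping[TransitionKey, float | None]

    def __post_init__(self) -> None:
        for key, area in self.entries.items():
            if area is not None and area < 0:
                raise ValueError(f"{self.sample_id}: negative area for {key}")


@dataclass(frozen=True)
class RatioProfile:
    """Dimensionless analyte/IS ratios for one sample.

    ``adjusted`` marks that creatinine normalization has been applied;
    ``adjustment_factor`` records the post-hoc factor (1.0 when the sample was
    physically diluted).
    """

    sample_id: str
    ratios: Mapping[TransitionKey, float | None]
    matrix: str | None = None
    adjusted: bool = False
    adjustment_factor: float = 1.0

    def __post_init__(self) -> None:
        for key, r in self.ratios.items():
            if r is not None and r < 0:
                raise ValueError(f"{self.sample_id}: negative ratio for {key}")
        if self.adjustment_factor < 1.0:
            raise ValueError("adjustment_factor must be >= 1")


def compute_ratio_profile(areas: PeakAreaTable, registry: PanelRegistry) -> RatioProfile:
    """Ratio every analyte area to the same-polarity internal-standard area.

    The IS area of a polarity is the summed area of the registry's
    internal-standard transitions of that polarity present in the table.
    Absent analytes propagate as absent; IS transitions are excluded from the
    output.  Raises :class:`QuantificationError` when a needed polarity has no
    positive IS area.
    """
    is_keys = {pol: set(registry.is_keys(pol)) for pol in POLARITIES}
    is_area: dict[str, float] = {}
    for pol in POLARITIES:
        present = [areas.entries[k] for k in is_keys[pol]
                   if areas.entries.get(k) is not None]
        is_area[pol] = float(sum(present)) if present else 0.0

    ratios: dict[TransitionKey, float | None] = {}
    for tdef in registry.analyte_transitions():
        key = tdef.key
        if key not in areas.entries:
            continue  # not acquired for this sample
        area = areas.entries[key]
        if area is None:
            ratios[key] = None
            continue
        denom = is_area[key.polarity]
        if denom <= 0:
            raise QuantificationError(
                f"sample {areas.sample_id}: internal-standard area missing or zero "
                f"in {key.polarity} mode")
        ratios[key] = area / denom

    unknown = set(areas.entries) - {t.key for t in registry.all_transitions()}
    if unknown:
        log.warning("sample %s: %d transition(s) not in registry ignored",
                    areas.sample_id, len(unknown))
    return RatioProfile(sample_id=areas.sample_id, ratios=ratios)


def adjust_creatinine(profile: RatioProfile, meta: SampleMeta) -> RatioProfile:
    """Apply the 1 mM creatinine normalization rule to an unadjusted profile.

    Physically diluted samples (creatinine >= 1 mM) need no correction; samples
    run neat below 1 mM are corrected by 1 / creatinine.  A sample recorded at
    >= 1 mM without dilution is treated as a data-entry inconsistency: warning,
    factor 1.0.  Adjusting an already-adjusted profile is rejected.
    """
    if profile.adjusted:
        raise QuantificationError(
            f"sample {profile.sample_id}: profile already creatinine-adjusted")
    if not meta.creatinine_mM > 0:
        raise ValueError("creatinine_mM must be > 0")
    if meta.dilution_applied:
        factor = 1.0
    elif meta.creatinine_mM < 1.0:
        factor = 1.0 / meta.creatinine_mM
    else:
        log.warning("sample %s: creatinine %.2f mM >= 1 without recorded dilution; "
                    "no adjustment applied", profile.sample_id, meta.creatinine_mM)
        factor = 1.0
    ratios = {k: (None if r is None else r * factor) for k, r in profile.ratios.items()}
    return RatioProfile(sample_id=profile.sample_id, ratios=ratios, matrix=meta.matrix,
                        adjusted=True, adjustment_factor=factor)


# ---------------------------------------------------------------------------
# exchange formats

AREA_COLUMNS = ["sample_id", "q1_mz", "q3_mz", "polarity", "area"]
META_COLUMNS = ["sample_id", "matrix", "creatinine_mM", "dilution_applied", "age_months"]


def read_peak_area_tables(path: str | Path) -> list[PeakAreaTable]:
    """Read a peak-area TSV (one row per sample and transition; empty area =
    absent) into one table per sample, order preserved."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peak-area table {path} missing column(s) {missing}")
    tables = []
    for sid, grp in df.groupby("sample_id", sort=False):
        entries: dict[TransitionKey, float | None] = {}
        for _, row in grp.iterrows():
            key = TransitionKey(row["q1_mz"], row["q3_mz"], row["polarity"])
            entries[key] = None if pd.isna(row["area"]) else float(row["area"])
        tables.append(PeakAreaTable(sample_id=str(sid), entries=entries))
    return tables


def write_peak_area_tables(tables: list[PeakAreaTable], path: str | Path) -> None:
    rows = []
    for tab in tables:
        for key, area in tab.entries.items():
            rows.append({"sample_id": tab.sample_id, "q1_mz": key.q1_mz,
                         "q3_mz": key.q3_mz, "polarity": key.polarity,
                         "area": area})
    pd.DataFrame(rows, columns=AREA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample metadata table {path} missing column(s) {missing}")
    metas = {}
    for _, row in df.iterrows():
        metas[str(row["sample_id"])] = SampleMeta(
            sample_id=str(row["sample_id"]), matrix=str(row["matrix"]),
            creatinine_mM=float(row["creatinine_mM"]),
            age_months=None if pd.isna(row["age_months"]) else float(row["age_months"]),
            dilution_applied=bool(row["dilution_applied"]))
    return metas


def write_sample_meta(metas: list[SampleMeta], path: str | Path) -> None:
    rows = [{"sample_id": m.sample_id, "matrix": m.matrix,
             "creatinine_mM": m.creatinine_mM, "dilution_applied": m.dilution_applied,
             "age_months": m.age_months} for m in metas]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)
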
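"""Control reference medians and multiple-of-the-median (MoM) scoring.

For each MRM transition, the reference value is the median (50th percentile)
of the creatinine-adjusted analyte/IS ratios of at least 10 control samples of
the same matrix.  A sample's score on a transition is its ratio divided by
that median — the multiple of the median (MoM).  Transitions whose control
median is zero, or that are absent from sample or reference, are reported as
not quantifiable rather than as an infinite or fabricated MoM.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ReferenceError, ScreeningError
from .quantify import MATRICES, RatioProfile
from .panels import TransitionKey

log = logging.getLogger(__name__)

MIN_CONTROLS = 10
AGE_STRATA = ("all", "under_6m", "over_6m")


@dataclass(frozen=True)
class ControlReference:
    """Per-transition control medians for one matrix (and age stratum)."""

    matrix: str
    medians: Mapping[TransitionKey, float]
    n_controls: int
    age_stratum: str = "all"
    n_quantifiable: Mapping[TransitionKey, int] | None = None
    build_date: str | None = None

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.age_stratum not in AGE_STRATA:
            raise ValueError(f"unknown age stratum {self.age_stratum!r}")
        if self.n_controls < MIN_CONTROLS:
            raise ReferenceError(
                f"control cohort of {self.n_controls} is below the required "
                f"minimum of {MIN_CONTROLS}")
        for key, med in self.medians.items():
            if med < 0:
                raise ValueError(f"negative median for {key}")

    def under_strength(self) -> tuple[TransitionKey, ...]:
        """Transitions quantifiable in fewer than MIN_CONTROLS controls."""
        if self.n_quantifiable is None:
            return ()
        return tuple(k for k, n in self.n_quantifiable.items() if n < MIN_CONTROLS)


@dataclass(frozen=True)
class MoMProfile:
    """Per-transition MoM scores for one sample; ``None`` = not quantifiable."""

    sample_id: str
    matrix: str
    moms: Mapping[TransitionKey, float | None]

    def __post_init__(self) -> None:
        for key, m in self.moms.items():
            if m is not None and m < 0:
                raise ValueError(f"negative MoM for {key}")


def build_reference(controls: Iterable[RatioProfile], matrix: str,
                    age_stratum: str = "all") -> ControlReference:
    """Compute per-transition medians over a control cohort.

    Requires >= 10 adjusted control profiles of the stated matrix.  Per
    transition, the median runs over controls with a quantifiable ratio
    (absent values excluded); transitions quantifiable in fewer than 10
    controls are flagged in ``n_quantifiable``.
    """
    controls = list(controls)
    if len(controls) < MIN_CONTROLS:
        raise ReferenceError(
            f"control cohort of {len(controls)} is below the required minimum "
            f"of {MIN_CONTROLS}")
    values: dict[TransitionKey, list[float]] = {}
    for prof in controls:
        if not prof.adjusted:
            raise ReferenceError(
                f"control {prof.sample_id} is not creatinine-adjusted")
        if prof.matrix != matrix:
            raise ReferenceError(
                f"control {prof.sample_id} has matrix {prof.matrix!r}, expected {matrix!r}")
        for key, r in prof.ratios.items():
            if r is not None:
                values.setdefault(key, []).append(r)
    medians = {key: float(np.median(v)) for key, v in values.items()}
    n_quant = {key: len(v) for key, v in values.items()}
    for key, n in n_quant.items():
        if n < MIN_CONTROLS:
            log.warning("transition %s quantifiable in only %d/%d controls",
                        key, n, len(controls))
    return ControlReference(matrix=matrix, medians=medians, n_controls=len(controls),
                            age_stratum=age_stratum, n_quantifiable=n_quant)


def compute_mom(profile: RatioProfile, reference: ControlReference,
                warn_age_months: float | None = None) -> MoMProfile:
    """Score an adjusted ratio profile against a matrix-matched reference.

    MoM = ratio / control median per transition.  Zero medians, transitions
    missing from the reference, and absent ratios all yield ``None``
    (not quantifiable).
    """
    if not profile.adjusted:
        raise ScreeningError(f"sample {profile.sample_id}: profile not creatinine-adjusted")
    if profile.matrix != reference.matrix:
        raise ScreeningError(
            f"sample {profile.sample_id}: matrix {profile.matrix!r} does not match "
            f"reference matrix {reference.matrix!r}")
    if (warn_age_months is not None and warn_age_months < 6
            and reference.age_stratum == "all"):
        log.warning("sample %s aged %.1f months scored against an unstratified "
                    "reference; control medians differ below 6 months",
                    profile.sample_id, warn_age_months)
    moms: dict[TransitionKey, float | None] = {}
    for key, r in profile.ratios.items():
        med = reference.medians.get(key)
        if r is None or med is None or med == 0:
            moms[key] = None
        else:
            moms[key] = r / med
    return MoMProfile(sample_id=profile.sample_id, matrix=profile.matrix, moms=moms)


# ---------------------------------------------------------------------------
# serialization

REF_COLUMNS = ["matrix", "q1_mz", "q3_mz", "polarity", "median_ratio", "n_quantifiable"]


def write_reference(reference: ControlReference, path: str | Path) -> None:
    """Write a reference TSV; the header comment records cohort size, stratum
    and (if provided) build date for audit."""
    lines = [f"# n_controls={reference.n_controls}",
             f"# age_stratum={reference.age_stratum}"]
    if reference.build_date:
        lines.append(f"# build_date={reference.build_date}")
    rows = []
    for key in sorted(reference.medians, key=lambda k: (k.polarity, k.q1_mz, k.q3_mz)):
        nq = (reference.n_quantifiable or {}).get(key, reference.n_controls)
        rows.append({"matrix": reference.matrix, "q1_mz": key.q1_mz, "q3_mz": key.q3_mz,
                     "polarity": key.polarity, "median_ratio": repr(reference.medians[key]),
                     "n_quantifiable": nq})
    body = pd.DataFrame(rows, columns=REF_COLUMNS).to_csv(sep="\t", index=False)
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_reference(path: str | Path) -> ControlReference:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            header[k.strip()] = v.strip()
    if "n_controls" not in header:
        raise FormatError(f"reference file {path} missing '# n_controls=' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"reference file {path} missing column(s) {missing}")
    matrices = df["matrix"].unique()
    if len(matrices) != 1:
        raise FormatError(f"reference file {path} must contain exactly one matrix")
    medians = {}
    n_quant = {}
    for _, row in df.iterrows():
        key = TransitionKey(row["q1_mz"], row["q3_mz"], row["polarity"])
        medians[key] = float(row["median_ratio"])
        n_quant[key] = int(row["n_quantifiable"])
    return ControlReference(matrix=str(matrices[0]), medians=medians,
                            n_controls=int(header["n_controls"]),
                            age_stratum=header.get("age_stratum", "all"),
                            n_quantifiable=n_quant,
                            build_date=header.get("build_date"))
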
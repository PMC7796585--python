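"""Synthetic cohorts, patients, QC mixes and chromatograms.

The generator emulates the statistical structure the screening analysis
assumes: control analyte/IS ratios are log-normal around a matrix-dependent
baseline (dried urine spots carry lower background than urine), with CV in
the 5-25% range observed for replicate injections; patients multiply their
disorder panel's transitions by the fold elevations reported per disorder and
matrix; the mixed positive QC combines eight disorders at an equal-part
dilution.  Creatinine follows a log-normal with a small sub-1-mM tail so both
normalization paths (physical dilution vs post-hoc factor) are exercised.
All randomness derives from a single configuration seed.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError
from .panels import PanelRegistry, TransitionKey, load_panel_registry
from .chromatograms import ChromatogramTrace, RetentionWindow
from .quantify import MATRICES, PeakAreaTable, SampleMeta
from .validate import LinearitySeries, PrecisionSeries


@dataclass(frozen=True)
class DisorderSignature:
    """Reported fold elevations over the control median, per matrix and panel.

    Matrices without a reported profile are simply absent; disorders reported
    as unremarkable carry an explicit empty mapping.
    """

    disorder: str
    folds: Mapping[str, Mapping[str, tuple[float, float]]]
    note: str = ""

    def __post_init__(self) -> None:
        for matrix, panels in self.folds.items():
            for pid, (lo, hi) in panels.items():
                if not (1.0 <= lo <= hi):
                    raise ValueError(
                        f"{self.disorder}/{matrix}/{pid}: need 1 <= min <= max, got ({lo}, {hi})")


def _sig(disorder: str, note: str = "", **matrices) -> DisorderSignature:
    return DisorderSignature(disorder=disorder, folds=matrices, note=note)


#: Per-disorder fold elevations of the characteristic panel transitions, as
#: reported for each matrix (single observed values become degenerate ranges).
SIGNATURES: dict[str, DisorderSignature] = {s.disorder: s for s in [
    _sig("sialidosis", urine={"SIAL": (102, 102)}, dus={"SIAL": (668, 668)}),
    _sig("alpha_mannosidosis", urine={"AMAN": (110, 118)}, dus={"AMAN": (29, 245)}),
    _sig("beta_mannosidosis", urine={"BMAN": (720, 720)}, dus={"BMAN": (155, 155)}),
    _sig("fucosidosis", urine={"FUCO": (220, 470)}, dus={"FUCO": (152, 373)}),
    _sig("aspartylglucosaminuria", urine={"AGU": (71, 71)}, dus={"AGU": (80, 80)}),
    _sig("gm1_gangliosidosis", urine={"GM1": (9, 1160)}, dus={"GM1": (69, 883)}),
    _sig("gm2_sandhoff", urine={"GM2": (99, 2102)}, dus={"GM2": (79, 79)}),
    _sig("gm2_tay_sachs", urine={}, dus={},
         note="no urinary oligosaccharide abnormalities"),
    _sig("pompe", urine={"GLC4": (10, 72)}, dus={"GLC4": (11, 13)}),
    _sig("vici_severe", urine={"GLC4": (21, 28)}, dus={"GLC4": (18, 18)},
         note="severe phenotype; mild sibs show no Glc4 elevation"),
    _sig("yunis_varon", dus={"GLC4": (51, 51)},
         note="only a DUS sample is on record"),
    _sig("danon", urine={"GLC4": (45, 45)}, dus={"GLC4": (75, 75)}),
    _sig("mucolipidosis_ii", urine={"AMAN": (10, 110), "GM1": (10, 110)},
         note="mixed non-specific profile; magnitudes unreported, encoded above-threshold"),
    _sig("mucolipidosis_iii", urine={"GM1": (5, 9)},
         note="GM1 transitions elevated to a lesser extent than in GM1 gangliosidosis"),
    _sig("mps_ivb", dus={"GLC4": (1.0, 2.0)},
         note="Glc4 elevated but below the positivity threshold"),
]}

#: Constituents of the mixed positive internal QC (equal-part urine mix).
IQC_DISORDERS = ("sialidosis", "alpha_mannosidosis", "beta_mannosidosis",
                 "fucosidosis", "aspartylglucosaminuria", "gm1_gangliosidosis",
                 "gm2_sandhoff", "pompe")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the assay's reported setting: 75 urine / 12 DUS controls,
    log-normal ratio dispersion at a mid-range 15% CV (replicate CVs ran
    5-25%), DUS baselines at a quarter of the urine background, creatinine
    log-normal around 6 mM with a few percent below 1 mM, and 16% of controls
    younger than 6 months.
    """

    seed: int = 0
    n_controls: Mapping[str, int] = field(
        default_factory=lambda: {"urine": 75, "dus": 12})
    baseline_ratio_urine: float = 0.08
    dus_background_scale: float = 0.25
    baseline_overrides: Mapping[TransitionKey, float] = field(default_factory=dict)
    cv: float = 0.15
    is_total_area: float = 1000.0
    creatinine_median_mM: float = 6.0
    creatinine_sigma_log: float = 0.9
    under_6m_fraction: float = 0.16
    age_effect_enabled: bool = False
    age_effect_factor: float = 2.0
    # chromatogram synthesis
    peak_sigma_min: float = 0.05
    chrom_dt_min: float = 0.01
    chrom_baseline: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cv <= 0.5):
            raise ConfigurationError(f"cv {self.cv} outside [0, 0.5]")
        if self.dus_background_scale > 1.0:
            raise ConfigurationError("DUS background must not exceed urine background")


def _rng(config: SimulationConfig, *tokens) -> np.random.Generator:
    """Deterministic per-purpose stream: seed plus a CRC of the token tuple."""
    crc = zlib.crc32(repr(tokens).encode())
    return np.random.default_rng([int(config.seed) % (2 ** 31), crc])


def control_baseline(config: SimulationConfig, key: TransitionKey, matrix: str) -> float:
    """Baseline control ratio of one transition (urine background, scaled down
    for DUS).  Per-transition variety comes from a deterministic key hash."""
    if key in config.baseline_overrides:
        base = config.baseline_overrides[key]
    else:
        # spread baselines over [0.5, 2] x the configured scalar, keyed to m/z
        h = zlib.crc32(f"{key.q1_mz}:{key.q3_mz}:{key.polarity}".encode())
        base = config.baseline_ratio_urine * (0.5 + 1.5 * (h % 1000) / 999.0)
    if matrix == "dus":
        base *= config.dus_background_scale
    return base


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal multiplier with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _draw_meta(config: SimulationConfig, rng: np.random.Generator,
               sample_id: str, matrix: str) -> SampleMeta:
    creat = float(rng.lognormal(np.log(config.creatinine_median_mM),
                                config.creatinine_sigma_log))
    if rng.uniform() < config.under_6m_fraction:
        age = float(rng.uniform(0.5, 6.0))
    else:
        age = float(rng.uniform(6.0, 204.0))
    return SampleMeta(sample_id=sample_id, matrix=matrix, creatinine_mM=creat,
                      age_months=age, dilution_applied=creat >= 1.0)


def _sample_areas(config: SimulationConfig, registry: PanelRegistry, matrix: str,
                  meta: SampleMeta, rng: np.random.Generator,
                  panel_folds: Mapping[str, float]) -> PeakAreaTable:
    entries: dict[TransitionKey, float | None] = {}
    for pol in ("positive", "negative"):
        keys = registry.is_keys(pol)
        for k in keys:
            entries[k] = config.is_total_area / len(keys)
    # sub-1 mM samples are run neat: the fluid is more dilute than the 1 mM
    # normalization point, so analyte (not IS) areas scale with creatinine
    conc_scale = meta.creatinine_mM if meta.creatinine_mM < 1.0 else 1.0
    age_scale = (config.age_effect_factor
                 if (config.age_effect_enabled and meta.age_months is not None
                     and meta.age_months < 6.0) else 1.0)
    tdefs = list(registry.analyte_transitions())
    noise = _lognormal_factor(rng, config.cv, len(tdefs))
    for tdef, nz in zip(tdefs, noise):
        base = control_baseline(config, tdef.key, matrix) * age_scale
        fold = panel_folds.get(tdef.panel_id, 1.0)
        entries[tdef.key] = config.is_total_area * base * fold * nz * conc_scale
    return PeakAreaTable(sample_id=meta.sample_id, entries=entries)


def gen_control_cohort(config: SimulationConfig, matrix: str, n: int | None = None,
                       registry: PanelRegistry | None = None,
                       ) -> list[tuple[SampleMeta, PeakAreaTable]]:
    """Generate ``n`` control samples (default: the configured cohort size)."""
    if matrix not in MATRICES:
        raise ConfigurationError(f"unknown matrix {matrix!r}")
    registry = registry or load_panel_registry()
    n = config.n_controls[matrix] if n is None else n
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    out = []
    for i in range(n):
        rng = _rng(config, "control", matrix, i)
        meta = _draw_meta(config, rng, f"{matrix}_ctrl_{i:03d}", matrix)
        out.append((meta, _sample_areas(config, registry, matrix, meta, rng, {})))
    return out


def gen_patient(config: SimulationConfig, disorder: str, matrix: str,
                fold_spec: float | str = "range",
                registry: PanelRegistry | None = None,
                sample_id: str | None = None,
                creatinine_mM: float | None = None, replicate: int = 0,
                ) -> tuple[SampleMeta, PeakAreaTable]:
    """Generate one patient sample with panel transitions elevated.

    ``fold_spec`` is either an explicit fold applied to every panel in the
    signature, the string ``"range"`` (uniform draw inside each panel's
    reported range), or ``"min"``/``"max"`` (the range endpoint).
    """
    if disorder not in SIGNATURES:
        raise GenerationError(
            f"unknown disorder {disorder!r}; known signatures: {sorted(SIGNATURES)}")
    sig = SIGNATURES[disorder]
    if matrix not in MATRICES:
        raise ConfigurationError(f"unknown matrix {matrix!r}")
    if matrix not in sig.folds:
        raise GenerationError(
            f"no reported {matrix} profile for {disorder!r} ({sig.note or 'not observed'})")
    registry = registry or load_panel_registry()
    rng = _rng(config, "patient", disorder, matrix, replicate)
    folds: dict[str, float] = {}
    for pid, (lo, hi) in sig.folds[matrix].items():
        if fold_spec == "range":
            folds[pid] = float(rng.uniform(lo, hi))
        elif fold_spec == "min":
            folds[pid] = lo
        elif fold_spec == "max":
            folds[pid] = hi
        else:
            folds[pid] = float(fold_spec)
    sid = sample_id or f"{matrix}_{disorder}_{replicate:02d}"
    meta = _draw_meta(config, rng, sid, matrix)
    if creatinine_mM is not None:
        meta = SampleMeta(sample_id=sid, matrix=matrix, creatinine_mM=creatinine_mM,
                          age_months=meta.age_months,
                          dilution_applied=creatinine_mM >= 1.0)
    return meta, _sample_areas(config, registry, matrix, meta, rng, folds)


def gen_qc_mix(config: SimulationConfig, matrix: str = "urine",
               constituents: Sequence[str] = IQC_DISORDERS,
               dilution_parts: float = 8.0,
               registry: PanelRegistry | None = None,
               ) -> tuple[SampleMeta, PeakAreaTable]:
    """Mixed positive QC: equal-part combination of the constituent disorders.

    Each constituent contributes its maximum reported urine fold divided by the
    number of parts, floored at 1 (the minimum folds of the weakest excretors
    would not survive an eight-fold dilution).
    """
    registry = registry or load_panel_registry()
    rng = _rng(config, "qc", matrix, tuple(constituents))
    folds: dict[str, float] = {}
    for disorder in constituents:
        sig = SIGNATURES[disorder]
        panels = sig.folds.get("urine") or next(iter(sig.folds.values()), {})
        for pid, (lo, hi) in panels.items():
            folds[pid] = max(folds.get(pid, 1.0), max(1.0, hi / dilution_parts))
    meta = SampleMeta(sample_id=f"{matrix}_iqc", matrix=matrix, creatinine_mM=1.0,
                      age_months=None, dilution_applied=True)
    return meta, _sample_areas(config, registry, matrix, meta, rng, folds)


def gen_chromatogram(sample: PeakAreaTable, config: SimulationConfig,
                     registry: PanelRegistry | None = None,
                     ) -> list[ChromatogramTrace]:
    """Render each acquired transition as a Gaussian peak in its retention
    window, on a flat baseline, with area matching the table entry."""
    registry = registry or load_panel_registry()
    defs = {t.key: t for t in registry.all_transitions()}
    traces = []
    for key, area in sample.entries.items():
        if area is None:
            continue  # non-acquired transitions have no trace at all
        tdef = defs.get(key)
        if tdef is None or tdef.expected_rt_min is None or tdef.rt_window_min is None:
            raise GenerationError(f"no retention window configured for {key}")
        window = RetentionWindow(tdef.expected_rt_min, tdef.rt_window_min)
        dt = config.chrom_dt_min
        times = np.arange(window.start, window.stop + dt / 2, dt)
        sigma = config.peak_sigma_min
        gauss = np.exp(-0.5 * ((times - tdef.expected_rt_min) / sigma) ** 2)
        intensities = area * gauss / (sigma * np.sqrt(2 * np.pi)) + config.chrom_baseline
        traces.append(ChromatogramTrace(key=key, sample_id=sample.sample_id,
                                        times=times, intensities=intensities))
    return traces


# ---------------------------------------------------------------------------
# validation-series simulation

def gen_linearity_series(config: SimulationConfig, key: TransitionKey,
                         levels: tuple[float, ...] = (1.0, 2.0, 3.0),
                         cv: float | None = None, token: int = 0) -> LinearitySeries:
    """Responses proportional to relative concentration, with log-normal noise."""
    rng = _rng(config, "linearity", key.q1_mz, key.q3_mz, key.polarity, token)
    cv = config.cv if cv is None else cv
    base = control_baseline(config, key, "urine")
    noise = _lognormal_factor(rng, cv, len(levels))
    responses = tuple(float(base * lv * nz) for lv, nz in zip(levels, noise))
    return LinearitySeries(transition=key, nominal_levels=levels, responses=responses)


def gen_precision_series(config: SimulationConfig, key: TransitionKey,
                         design: str = "intra_day", n_per_day: int = 10,
                         cv: float | None = None, token: int = 0) -> PrecisionSeries:
    """Replicate injections of one preparation: 10 x 1 day or 10 x 3 days."""
    rng = _rng(config, "precision", design, key.q1_mz, key.q3_mz, key.polarity, token)
    cv = config.cv if cv is None else cv
    base = control_baseline(config, key, "urine")
    n_days = 1 if design == "intra_day" else 3
    groups = tuple(tuple(float(v) for v in base * _lognormal_factor(rng, cv, n_per_day))
                   for _ in range(n_days))
    return PrecisionSeries(transition=key, replicate_groups=groups, design=design)
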
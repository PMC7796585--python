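"""MRM transition registry and disorder panels.

The screening assay monitors, for each lysosomal storage disorder, a small
panel of MRM transitions (precursor > product m/z in positive or negative
electrospray mode).  A subset of each panel is used quantitatively; the rest
confirm identity.  Maltoheptaose (Glc7) is the internal standard, monitored
with its own transitions in both polarities.  Only a handful of m/z pairs are
published for this assay; the remaining registry entries are shipped as
synthetic placeholders (``placeholder: true``) so that panel *counts* are
faithful while m/z values stay user-overridable.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError, TransitionNotFoundError

POLARITIES = ("positive", "negative")
ROLES = ("quantifier", "qualifier", "internal_standard")
CATEGORIES = ("specific", "glc4_group")

#: Maximum retention time (min) of the detection segment of the gradient.
DETECTION_WINDOW_MIN = 15.5

IS_PANEL_ID = "IS"


@dataclass(frozen=True)
class TransitionKey:
    """Identity of one MRM transition: (Q1 m/z, Q3 m/z, polarity).

    m/z values are rounded to one decimal on construction, the precision at
    which transitions are reported; equality and hashing use the rounded triple.
    """

    q1_mz: float
    q3_mz: float
    polarity: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "q1_mz", round(float(self.q1_mz), 1))
        object.__setattr__(self, "q3_mz", round(float(self.q3_mz), 1))
        if self.polarity not in POLARITIES:
            raise ConfigurationError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if self.q1_mz <= 0 or self.q3_mz <= 0:
            raise ConfigurationError(f"m/z must be positive: {self}")
        # product cannot exceed precursor beyond isotope tolerance
        if self.q3_mz >= self.q1_mz + 2.0:
            raise ConfigurationError(f"product m/z {self.q3_mz} heavier than precursor {self.q1_mz} + 2.0")

    def __str__(self) -> str:  # e.g. "665.0>179.0 (-)"
        sign = "+" if self.polarity == "positive" else "-"
        return f"{self.q1_mz}>{self.q3_mz} ({sign})"


@dataclass(frozen=True)
class TransitionDef:
    """One registry entry: a transition plus its role within a panel."""

    key: TransitionKey
    compound: str
    role: str
    panel_id: str
    expected_rt_min: float | None = None
    rt_window_min: float | None = None
    most_characteristic: bool = False
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r} for {self.key}")
        if (self.role == "internal_standard") != (self.panel_id == IS_PANEL_ID):
            raise ConfigurationError(
                f"{self.key}: role internal_standard iff panel_id == {IS_PANEL_ID!r}")
        if self.expected_rt_min is not None:
            if not (0.0 <= self.expected_rt_min <= DETECTION_WINDOW_MIN):
                raise ConfigurationError(
                    f"{self.key}: expected_rt {self.expected_rt_min} outside "
                    f"[0, {DETECTION_WINDOW_MIN}] min")

    @property
    def is_quantitative(self) -> bool:
        return self.role == "quantifier"


@dataclass(frozen=True)
class DisorderPanel:
    """Transitions monitored for one disorder, with its screening category."""

    panel_id: str
    disorder_name: str
    transitions: tuple[TransitionDef, ...]
    category_on_positive: str = "specific"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category_on_positive not in CATEGORIES:
            raise ConfigurationError(
                f"panel {self.panel_id}: unknown category {self.category_on_positive!r}")
        if self.n_quantitative < 1:
            raise ConfigurationError(f"panel {self.panel_id} has no quantifier transitions")
        mc = [t for t in self.transitions if t.most_characteristic]
        if len(mc) != 1:
            raise ConfigurationError(
                f"panel {self.panel_id} must have exactly one most-characteristic "
                f"transition, found {len(mc)}")
        if not mc[0].is_quantitative:
            raise ConfigurationError(
                f"panel {self.panel_id}: most-characteristic transition {mc[0].key} "
                f"must be a quantifier")

    @property
    def n_quantitative(self) -> int:
        return sum(t.is_quantitative for t in self.transitions)

    @property
    def most_characteristic(self) -> TransitionDef:
        return next(t for t in self.transitions if t.most_characteristic)

    def keys(self) -> tuple[TransitionKey, ...]:
        return tuple(t.key for t in self.transitions)


@dataclass(frozen=True)
class PanelRegistry:
    """All disorder panels plus the internal-standard transitions."""

    panels: tuple[DisorderPanel, ...]
    is_transitions: tuple[TransitionDef, ...]
    schema_version: int = 1

    def __post_init__(self) -> None:
        # per-polarity IS presence is enforced at load time and surfaced by
        # validate_registry, so that audits can still describe broken registries
        seen: dict[TransitionKey, str] = {}
        for tdef in self.all_transitions():
            if tdef.key in seen:
                raise ConfigurationError(
                    f"duplicate transition key {tdef.key} (panels "
                    f"{seen[tdef.key]!r} and {tdef.panel_id!r})")
            seen[tdef.key] = tdef.panel_id

    def all_transitions(self) -> Iterable[TransitionDef]:
        for panel in self.panels:
            yield from panel.transitions
        yield from self.is_transitions

    def analyte_transitions(self) -> Iterable[TransitionDef]:
        for panel in self.panels:
            yield from panel.transitions

    def panel(self, panel_id: str) -> DisorderPanel:
        for p in self.panels:
            if p.panel_id == panel_id:
                return p
        raise KeyError(panel_id)

    def is_keys(self, polarity: str) -> tuple[TransitionKey, ...]:
        return tuple(t.key for t in self.is_transitions if t.key.polarity == polarity)


def lookup_transition(registry: PanelRegistry, key: TransitionKey) -> TransitionDef:
    """Return the unique definition whose rounded key matches ``key``."""
    for tdef in registry.all_transitions():
        if tdef.key == key:
            return tdef
    raise TransitionNotFoundError(key)


# ---------------------------------------------------------------------------
# configuration I/O

def _parse_transition(raw: Mapping, panel_id: str, default_role: str) -> TransitionDef:
    for fld in ("q1", "q3", "polarity", "compound"):
        if fld not in raw:
            raise ConfigurationError(f"transition in panel {panel_id!r} missing field {fld!r}")
    role = raw.get("role", default_role)
    if raw.get("q1") is None or raw.get("q3") is None:
        raise ConfigurationError(
            f"transition {raw.get('compound')!r} in panel {panel_id!r} has no m/z; "
            f"m/z-less placeholders cannot be registered")
    return TransitionDef(
        key=TransitionKey(raw["q1"], raw["q3"], raw["polarity"]),
        compound=str(raw["compound"]),
        role=role,
        panel_id=panel_id,
        expected_rt_min=raw.get("expected_rt"),
        rt_window_min=raw.get("rt_window"),
        most_characteristic=bool(raw.get("most_characteristic", False)),
        placeholder=bool(raw.get("placeholder", False)),
    )


def load_panel_registry(config_source: str | Path | Mapping | None = None) -> PanelRegistry:
    """Load a :class:`PanelRegistry` from YAML text, a path, a parsed mapping,
    or — with no argument — the shipped default registry."""
    if config_source is None:
        config_source = default_config_path()
    if isinstance(config_source, Mapping):
        doc = config_source
    else:
        if isinstance(config_source, Path) or (
                isinstance(config_source, str) and "\n" not in config_source
                and Path(config_source).exists()):
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
        doc = yaml.safe_load(io.StringIO(text))
    if not isinstance(doc, Mapping):
        raise ConfigurationError("panel configuration is empty or not a mapping")
    raw_panels = doc.get("panels") or []
    raw_is = doc.get("internal_standard") or []
    if not raw_panels:
        raise ConfigurationError("panel configuration defines no panels")
    if not raw_is:
        raise ConfigurationError("panel configuration defines no internal-standard transitions")
    panels = []
    for rp in raw_panels:
        pid = rp.get("panel_id")
        if not pid:
            raise ConfigurationError("panel without panel_id")
        tdefs = tuple(_parse_transition(rt, pid, "qualifier") for rt in rp.get("transitions", []))
        panels.append(DisorderPanel(
            panel_id=pid,
            disorder_name=rp.get("disorder", pid),
            transitions=tdefs,
            category_on_positive=rp.get("category", "specific"),
            notes=rp.get("notes", ""),
        ))
    is_defs = tuple(_parse_transition(rt, IS_PANEL_ID, "internal_standard") for rt in raw_is)
    for pol in POLARITIES:
        if not any(t.key.polarity == pol for t in is_defs):
            raise ConfigurationError(f"no internal-standard transition in {pol} mode")
    return PanelRegistry(panels=tuple(panels), is_transitions=is_defs,
                         schema_version=int(doc.get("schema_version", 1)))


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "panels_default.yaml"


def dump_panel_registry(registry: PanelRegistry) -> str:
    """Serialize a registry back to YAML (round-trips through load)."""

    def dump_t(t: TransitionDef) -> dict:
        d: dict = {"q1": t.key.q1_mz, "q3": t.key.q3_mz, "polarity": t.key.polarity,
                   "compound": t.compound, "role": t.role}
        if t.most_characteristic:
            d["most_characteristic"] = True
        if t.placeholder:
            d["placeholder"] = True
        if t.expected_rt_min is not None:
            d["expected_rt"] = t.expected_rt_min
            d["rt_window"] = t.rt_window_min
        return d

    doc = {
        "schema_version": registry.schema_version,
        "internal_standard": [dump_t(t) for t in registry.is_transitions],
        "panels": [
            {"panel_id": p.panel_id, "disorder": p.disorder_name,
             "category": p.category_on_positive,
             **({"notes": p.notes} if p.notes else {}),
             "transitions": [dump_t(t) for t in p.transitions]}
            for p in registry.panels
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# audit

#: Published per-panel transition counts by polarity (panel chromatogram legend).
EXPECTED_PANEL_COUNTS: dict[str, dict[str, int]] = {
    "SIAL": {"negative": 3},
    "AMAN": {"positive": 8},
    "BMAN": {"positive": 9, "negative": 8},
    "FUCO": {"positive": 6},
    "AGU": {"positive": 5, "negative": 10},
    "GM1": {"positive": 5},
    "GM2": {"positive": 7},
    "GLC4": {"negative": 2},
}
EXPECTED_IS_COUNTS = {"positive": 7, "negative": 7}
#: Published number of quantitative transitions per panel (AGU: 3 positive + 3 negative).
EXPECTED_QUANTIFIER_COUNTS = {"SIAL": 1, "AMAN": 4, "BMAN": 5, "FUCO": 3,
                              "AGU": 6, "GM1": 3, "GM2": 4, "GLC4": 1}


@dataclass(frozen=True)
class RegistryAudit:
    """Per-panel transition/quantifier counts plus deviation flags."""

    panel_counts: Mapping[str, Mapping[str, int]]
    quantifier_counts: Mapping[str, int]
    is_counts: Mapping[str, int]
    flags: tuple[str, ...]

    @property
    def clean(self) -> bool:
        return not self.flags


def validate_registry(registry: PanelRegistry) -> RegistryAudit:
    """Audit a registry against the assay's default panel composition.

    Always returns; deviations from the default counts (or a missing
    internal standard in either polarity) are reported as flags.
    """
    panel_counts: dict[str, dict[str, int]] = {}
    quant_counts: dict[str, int] = {}
    for p in registry.panels:
        counts: dict[str, int] = {}
        for t in p.transitions:
            counts[t.key.polarity] = counts.get(t.key.polarity, 0) + 1
        panel_counts[p.panel_id] = counts
        quant_counts[p.panel_id] = p.n_quantitative
    is_counts = {pol: len(registry.is_keys(pol)) for pol in POLARITIES}

    flags: list[str] = []
    for pol in POLARITIES:
        if is_counts[pol] == 0:
            flags.append(f"missing internal standard in {pol} mode")
        elif is_counts[pol] != EXPECTED_IS_COUNTS[pol]:
            flags.append(f"IS {pol} count {is_counts[pol]} != default "
                         f"{EXPECTED_IS_COUNTS[pol]}")
    for pid, expected in EXPECTED_PANEL_COUNTS.items():
        got = panel_counts.get(pid)
        if got is None:
            flags.append(f"panel {pid} absent from registry")
        elif got != expected:
            flags.append(f"panel {pid} counts {got} != default {expected}")
    for pid, expected_q in EXPECTED_QUANTIFIER_COUNTS.items():
        got_q = quant_counts.get(pid)
        if got_q is not None and got_q != expected_q:
            flags.append(f"panel {pid} quantifier count {got_q} != default {expected_q}")
    return RegistryAudit(panel_counts=panel_counts, quantifier_counts=quant_counts,
                         is_counts=is_counts, flags=tuple(flags))
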
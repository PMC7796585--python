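"""Positivity rule and profile taxonomy for disorder calls.

A sample is positive for a disorder when the MoMs of *all* of that panel's
transitions (qualifiers and quantifiers) are elevated at least 5-fold in
fresh urine or at least 2-fold in dried urine spots.  On top of the per-panel
calls, a sample-level interpretation distinguishes specific profiles
(oligosaccharidoses, gangliosidoses), mixed non-specific profiles (seen in
mucolipidosis II/III), the Glc4 group (Pompe disease and the autophagy
disorders, indistinguishable by Glc4 alone), and borderline Glc4 elevations
(reported in mucopolysaccharidosis IVB).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ScreeningError
from .panels import DisorderPanel, PanelRegistry, TransitionKey
from .reference import MoMProfile

#: Differential diagnosis reported with any Glc4-group call; Glc4 alone cannot
#: rank these.
GLC4_DIFFERENTIAL = (
    "Pompe disease",
    "Vici syndrome",
    "Yunis-Varon syndrome",
    "Danon disease",
    "other glycogenoses (GSD III/VI)",
)

TAY_SACHS_CAVEAT = ("GM2 calls refer to the Sandhoff type; the Tay-Sachs variant does "
                    "not alter urinary oligosaccharides and is not detectable here.")
CONFIRMATORY_DISCLAIMER = ("Screening interpretation only; confirmation requires "
                           "enzymatic and/or genetic testing.")

STATUSES = ("positive", "negative", "borderline", "not_assessable")
INTERPRETATIONS = ("specific_profile", "mixed_nonspecific", "glc4_group",
                   "borderline_glc4", "negative")


@dataclass(frozen=True)
class ScreenThresholds:
    """Matrix-specific minimum MoM for positivity, plus the borderline floor."""

    urine_min_mom: float = 5.0
    dus_min_mom: float = 2.0
    borderline_floor: float = 1.5

    def __post_init__(self) -> None:
        if not (self.urine_min_mom > self.dus_min_mom > self.borderline_floor > 1.0):
            raise ValueError(
                "require urine_min_mom > dus_min_mom > borderline_floor > 1, got "
                f"{self.urine_min_mom}/{self.dus_min_mom}/{self.borderline_floor}")

    def for_matrix(self, matrix: str) -> float:
        if matrix == "urine":
            return self.urine_min_mom
        if matrix == "dus":
            return self.dus_min_mom
        raise ValueError(f"unknown matrix {matrix!r}")


@dataclass(frozen=True)
class PanelCall:
    """Outcome of the positivity rule for one panel on one sample."""

    panel_id: str
    disorder_name: str
    status: str
    n_transitions_over: int
    n_transitions_required: int
    evidence: Mapping[TransitionKey, float | None]

    @property
    def positive(self) -> bool:
        return self.status == "positive"


@dataclass(frozen=True)
class ScreenReport:
    """All panel calls plus the sample-level interpretation."""

    sample_id: str
    matrix: str
    calls: tuple[PanelCall, ...]
    interpretation: str
    disorder: str | None = None
    differential: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def call(self, panel_id: str) -> PanelCall:
        for c in self.calls:
            if c.panel_id == panel_id:
                return c
        raise KeyError(panel_id)


def call_panel(mom: MoMProfile, panel: DisorderPanel, thresholds: ScreenThresholds,
               quantifier_only: bool = False) -> PanelCall:
    """Apply the all-transition conjunction rule to one panel.

    Positive iff every quantifiable panel transition scores at or above the
    matrix threshold (inclusive: "at least"); borderline iff every
    quantifiable transition sits uniformly in the borderline band
    [borderline_floor, threshold); not assessable when more than half the
    considered transitions are not quantifiable; otherwise negative (including
    discordant panels where only some transitions clear the threshold).
    ``quantifier_only`` restricts the rule to the panel's quantitative
    transitions.
    """
    threshold = thresholds.for_matrix(mom.matrix)
    tdefs = [t for t in panel.transitions if t.is_quantitative] if quantifier_only \
        else list(panel.transitions)
    evidence = {t.key: mom.moms.get(t.key) for t in tdefs}
    quantifiable = {k: v for k, v in evidence.items() if v is not None}
    n_unquant = len(evidence) - len(quantifiable)
    n_over = sum(1 for v in quantifiable.values() if v >= threshold)

    if n_unquant * 2 > len(evidence):
        status = "not_assessable"
    elif quantifiable and all(v >= threshold for v in quantifiable.values()):
        status = "positive"
    elif quantifiable and all(thresholds.borderline_floor <= v < threshold
                              for v in quantifiable.values()):
        status = "borderline"
    else:
        status = "negative"
    return PanelCall(panel_id=panel.panel_id, disorder_name=panel.disorder_name,
                     status=status, n_transitions_over=n_over,
                     n_transitions_required=len(evidence), evidence=evidence)


def screen_sample(mom: MoMProfile, registry: PanelRegistry,
                  thresholds: ScreenThresholds | None = None,
                  quantifier_only: bool = False) -> ScreenReport:
    """Call every panel and derive the sample-level interpretation.

    Interpretation rules, applied in order: (1) exactly one specific panel
    positive with Glc4 not positive -> specific profile; (2) two or more
    specific panels positive -> mixed non-specific; (3) Glc4 positive ->
    Glc4 group with its fixed differential; (4) Glc4 borderline only ->
    borderline Glc4; (5) otherwise negative.
    """
    if thresholds is None:
        thresholds = ScreenThresholds()
    if not mom.moms:
        raise ScreeningError(f"sample {mom.sample_id}: empty MoM profile")

    calls = tuple(call_panel(mom, panel, thresholds, quantifier_only=quantifier_only)
                  for panel in registry.panels)
    by_id = {c.panel_id: c for c in calls}
    specific_pos = [p for p in registry.panels
                    if p.category_on_positive == "specific" and by_id[p.panel_id].positive]
    glc4_panels = [p for p in registry.panels if p.category_on_positive == "glc4_group"]
    glc4_positive = any(by_id[p.panel_id].positive for p in glc4_panels)
    glc4_borderline = any(by_id[p.panel_id].status == "borderline" for p in glc4_panels)

    notes = [CONFIRMATORY_DISCLAIMER, TAY_SACHS_CAVEAT]
    disorder = None
    differential: tuple[str, ...] = ()
    if len(specific_pos) == 1 and not glc4_positive:
        interpretation = "specific_profile"
        disorder = specific_pos[0].disorder_name
    elif len(specific_pos) >= 2:
        interpretation = "mixed_nonspecific"
        notes.append("Mixed profile across panels: consider mucolipidosis II/III.")
    elif glc4_positive:
        interpretation = "glc4_group"
        differential = GLC4_DIFFERENTIAL
    elif glc4_borderline and not specific_pos:
        interpretation = "borderline_glc4"
        notes.append("Sub-threshold Glc4 elevation: reported in mucopolysaccharidosis IVB.")
    else:
        interpretation = "negative"
    return ScreenReport(sample_id=mom.sample_id, matrix=mom.matrix, calls=calls,
                        interpretation=interpretation, disorder=disorder,
                        differential=differential, notes=tuple(notes))
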
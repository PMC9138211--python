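"""Eligibility screening, sensitization counting and dominant-allergen rules.

Screening mirrors routine SLIT work-up: patients under six, those with
asthma not controlled on pharmacotherapy (ACT below the controlled cutoff),
nasal polyposis, or profilin (Bet v2) sensitization are excluded, and a
documented positive SPT *and* positive specific IgE are required.

The dominant allergen(s) — those actually prescribed for immunotherapy — are
the smallest leading group of positive sensitizations that stands apart from
all remaining ones by BOTH a wheal margin (default 5 mm) and a specific-IgE
margin of half a decimal logarithm.  When no such group exists, every
positive sensitization is co-dominant.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

from .cohort import AllergenId, PatientRecord, PROFILIN_COMPONENT
from .errors import ValidationError
from .registry import DEFAULT_THRESHOLDS, Thresholds

EXCLUSION_CODES = (
    "age_under_6",
    "uncontrolled_asthma",
    "nasal_polyposis",
    "profilin_betv2",
    "no_positive_spt",
    "no_positive_sige",
)

CRD_CATEGORIES = ("negative", "positive", "high_positive")


@dataclasses.dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.eligible != (len(self.reasons) == 0):
            raise ValidationError("eligible flag inconsistent with reasons")


@dataclasses.dataclass(frozen=True)
class DominanceResult:
    """Ordered dominant allergens with the achieved boundary separations."""

    dominant: tuple[AllergenId, ...]
    n_dominant: int
    separation_log10_ige: float
    separation_wheal_mm: float

    def __post_init__(self) -> None:
        if self.n_dominant != len(self.dominant):
            raise ValidationError("n_dominant must equal |dominant|")


def spt_positive(wheal_mm: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """True when a wheal reaches the positivity diameter (default 3 mm)."""
    if wheal_mm < 0 or not math.isfinite(wheal_mm):
        raise ValidationError(f"wheal must be finite and >= 0, got {wheal_mm}")
    return wheal_mm >= thresholds.spt_positive_mm


def ige_positive(value_kua_l: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """True when a specific/component IgE reaches 0.35 kUA/L."""
    if value_kua_l < 0 or not math.isfinite(value_kua_l):
        raise ValidationError(f"IgE must be finite and >= 0, got {value_kua_l}")
    return value_kua_l >= thresholds.ige_positive_kua_l


def crd_category(
    component_ige_kua_l: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """Band a component IgE into negative / positive / high_positive."""
    if component_ige_kua_l < 0 or not math.isfinite(component_ige_kua_l):
        raise ValidationError(f"IgE must be finite and >= 0, got {component_ige_kua_l}")
    if component_ige_kua_l >= thresholds.crd_high_kua_l:
        return "high_positive"
    if component_ige_kua_l >= thresholds.ige_positive_kua_l:
        return "positive"
    return "negative"


def _source_panel(
    record: PatientRecord, thresholds: Thresholds
) -> dict[str, tuple[float, float]]:
    """Per allergen source: (max valid-battery wheal, specific IgE).

    Sources never tested on a given axis contribute 0 on that axis.  SPT rows
    whose control wheals invalidate the battery are ignored.
    """
    panel: dict[str, tuple[float, float]] = {}
    for s in record.spt:
        if not s.battery_valid:
            continue
        wheal, sige = panel.get(s.allergen.source, (0.0, 0.0))
        panel[s.allergen.source] = (max(wheal, s.wheal_mm), sige)
    if record.ige is not None:
        for key, value in record.ige.specific_ige.items():
            wheal, _ = panel.get(key.source, (0.0, 0.0))
            panel[key.source] = (wheal, value)
    return panel


def positive_sensitizations(
    record: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> dict[str, tuple[float, float]]:
    """Allergen sources positive by SPT or by specific IgE (union semantics)."""
    return {
        source: (wheal, sige)
        for source, (wheal, sige) in _source_panel(record, thresholds).items()
        if wheal >= thresholds.spt_positive_mm or sige >= thresholds.ige_positive_kua_l
    }


def count_sensitizations(
    record: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> int:
    """Number of distinct allergen sources positive by SPT and/or specific IgE."""
    return len(positive_sensitizations(record, thresholds))


def screen_eligibility(
    record: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> EligibilityResult:
    """Apply the inclusion/exclusion battery to one patient.

    Raises :class:`ValidationError` when asthma is present without an ACT
    score, since asthma control cannot then be assessed.
    """
    reasons: list[str] = []
    profile = record.profile
    if profile.age_years < 6:
        reasons.append("age_under_6")
    if profile.has_asthma:
        if profile.act_score is None:
            raise ValidationError(
                f"patient {record.id}: asthma without an ACT score; control "
                "cannot be assessed"
            )
        if profile.act_score < thresholds.act_controlled:
            reasons.append("uncontrolled_asthma")
    if profile.nasal_polyposis:
        reasons.append("nasal_polyposis")
    if record.ige is not None:
        for key, value in record.ige.component_ige.items():
            if key.component == PROFILIN_COMPONENT and ige_positive(value, thresholds):
                reasons.append("profilin_betv2")
                break
    panel = _source_panel(record, thresholds)
    if not any(w >= thresholds.spt_positive_mm for w, _ in panel.values()):
        reasons.append("no_positive_spt")
    if not any(s >= thresholds.ige_positive_kua_l for _, s in panel.values()):
        reasons.append("no_positive_sige")
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


def identify_dominant_allergens(
    record: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> DominanceResult:
    """Find the dominant allergen group of a sensitized patient.

    Positive sensitizations are ranked by specific IgE (descending), ties
    broken by wheal then label.  The dominant set is the shortest non-empty
    prefix whose every member exceeds every non-member by both the wheal
    margin and the log10-IgE margin; with no separating prefix, all positive
    allergens are co-dominant and both separations are reported as 0.

    Specific IgE values are floored at the assay floor (default 0.01 kUA/L)
    before taking logs so that untested or undetectable allergens yield
    finite margins.
    """
    positives = positive_sensitizations(record, thresholds)
    if not positives:
        raise ValidationError(
            f"patient {record.id}: no positive sensitization; dominance undefined"
        )
    floor = thresholds.ige_floor_kua_l
    ranked = sorted(
        (
            (source, wheal, max(sige, floor))
            for source, (wheal, sige) in positives.items()
        ),
        key=lambda t: (-t[2], -t[1], t[0]),
    )
    n = len(ranked)
    chosen = n
    sep_log = 0.0
    sep_wheal = 0.0
    for k in range(1, n):
        members, rest = ranked[:k], ranked[k:]
        d_log = min(math.log10(m[2]) for m in members) - max(
            math.log10(r[2]) for r in rest
        )
        d_wheal = min(m[1] for m in members) - max(r[1] for r in rest)
        if (
            d_log >= thresholds.dominance_log10_ige
            and d_wheal >= thresholds.dominance_wheal_mm
        ):
            chosen, sep_log, sep_wheal = k, d_log, d_wheal
            break
    dominant = tuple(AllergenId(source) for source, _, _ in ranked[:chosen])
    return DominanceResult(
        dominant=dominant,
        n_dominant=chosen,
        separation_log10_ige=sep_log if chosen < n else 0.0,
        separation_wheal_mm=sep_wheal if chosen < n else 0.0,
    )
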
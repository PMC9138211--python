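"""The Predictive Response to Immunotherapy Score (PRIS).

PRIS sums eight banded component scores — age, clinical features, disease
onset, number of sensitizations, symptom-triggering exposures, specific/total
IgE ratio, component-resolved diagnosis (CRD) and allergen dominance — into a
total ranging from 20 (every component at its floor) to 100 (every component
at its ceiling).  The total stratifies into bands Q1 (>= 80, best prognosis)
through Q4 (< 40).

The band edges and point values are fixed by design; this module implements
them verbatim and performs no re-weighting or calibration.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional

from .cohort import PatientRecord
from .errors import ValidationError
from .registry import DEFAULT_THRESHOLDS, Thresholds
from .screening import DominanceResult, crd_category

#: Valid point values per component, used by the exhaustive bound check.
COMPONENT_LEVELS: dict[str, tuple[int, ...]] = {
    "age_score": (3, 6, 9, 12, 15),
    "clinical_score": (3, 6, 9),
    "onset_score": (3, 6, 9),
    "sensitization_score": (4, 8, 12, 16),
    "exposure_score": (3, 6, 9, 12),
    "ratio_score": (4, 8, 12),
    "crd_score": (0, 6, 12),
    "dominance_score": (0, 5, 10, 15),
}

PRIS_MIN = sum(min(v) for v in COMPONENT_LEVELS.values())  # 20
PRIS_MAX = sum(max(v) for v in COMPONENT_LEVELS.values())  # 100


@dataclasses.dataclass(frozen=True)
class PRISBreakdown:
    """The eight component scores, their sum, and any extrapolation notes."""

    age_score: int
    clinical_score: int
    onset_score: int
    sensitization_score: int
    exposure_score: int
    ratio_score: int
    crd_score: int
    dominance_score: int
    total: int
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        components = [
            getattr(self, name) for name in COMPONENT_LEVELS
        ]
        if self.total != sum(components):
            raise ValidationError("PRIS total must equal the sum of components")
        for name, levels in COMPONENT_LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValidationError(f"{name} = {getattr(self, name)} not a valid level")


def score_age(age_years: float) -> int:
    """Age component: younger patients score higher (0-12 -> 15 ... >38 -> 3).

    Fractional ages are floored to whole years before lookup.
    """
    if age_years < 0:
        raise ValidationError(f"age must be >= 0, got {age_years}")
    age = math.floor(age_years)
    if age <= 12:
        return 15
    if age <= 18:
        return 12
    if age <= 28:
        return 9
    if age <= 38:
        return 6
    return 3


def score_clinical(diseases: Iterable[str]) -> int:
    """Clinical-features component: fewer allergic comorbidities score higher.

    Rhinitis alone -> 9; rhinitis + asthma -> 6; rhinitis + asthma + other
    allergies -> 3.  Rhinitis with other allergies but no asthma is not a
    tabulated combination; it is scored 6 (one-comorbidity tier) and flagged
    by :func:`compute_pris` as extrapolated.
    """
    ds = set(diseases)
    if "rhinitis" not in ds:
        raise ValidationError("every scored patient must have rhinitis")
    n_comorbid = len(ds - {"rhinitis"})
    return {0: 9, 1: 6, 2: 3}[min(n_comorbid, 2)]


def score_onset(onset_years: float) -> int:
    """Disease-onset component: recent onset scores higher (<=3 y -> 9)."""
    if onset_years < 0:
        raise ValidationError(f"onset must be >= 0, got {onset_years}")
    if onset_years <= 3:
        return 9
    if onset_years <= 10:
        return 6
    return 3


def score_sensitizations(n: int) -> int:
    """Sensitization-count component: monosensitized patients score highest."""
    if n < 1:
        raise ValidationError("a scored patient has at least one sensitization")
    if n == 1:
        return 16
    if n <= 3:
        return 12
    if n <= 5:
        return 8
    return 4


def score_exposure(n_symptom_triggering_allergens: int) -> int:
    """Exposure component: symptoms after exposure to fewer allergens score higher."""
    n = n_symptom_triggering_allergens
    if n < 1:
        raise ValidationError("at least one symptom-triggering allergen required")
    if n == 1:
        return 12
    if n == 2:
        return 9
    if n == 3:
        return 6
    return 3


def score_ratio(
    specific_ige: float,
    total_ige: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Specific/total IgE ratio component: s/t >= 0.2 -> 12, >= 0.05 -> 8, else 4."""
    if total_ige <= 0:
        raise ValidationError(f"total IgE must be > 0, got {total_ige}")
    if specific_ige < 0:
        raise ValidationError(f"specific IgE must be >= 0, got {specific_ige}")
    ratio = specific_ige / total_ige
    if ratio >= thresholds.ratio_high:
        return 12
    if ratio >= thresholds.ratio_mid:
        return 8
    return 4


def score_crd(category: str) -> int:
    """CRD component: high_positive -> 12, positive -> 6, negative -> 0."""
    try:
        return {"high_positive": 12, "positive": 6, "negative": 0}[category]
    except KeyError:
        raise ValidationError(f"unknown CRD category {category!r}") from None


def score_dominance(n_dominant: int) -> int:
    """Dominance component: one dominant allergen -> 15, two -> 10, three -> 5, more -> 0."""
    if n_dominant < 1:
        raise ValidationError("dominance requires at least one dominant allergen")
    if n_dominant <= 3:
        return {1: 15, 2: 10, 3: 5}[n_dominant]
    return 0


def compute_pris(
    record: PatientRecord,
    dominance: DominanceResult,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> PRISBreakdown:
    """Assemble the full PRIS breakdown for an eligible patient.

    Resolution of the two inputs the band table does not pin down:

    * the s/t ratio uses the specific IgE of the highest-sIgE dominant
      allergen (the allergen that drives the SLIT prescription);
    * the CRD category is the maximum category over panel components of the
      dominant allergen source(s); with no applicable component it is
      ``negative`` (the 0-point floor).
    """
    from .screening import count_sensitizations  # local to avoid cycle noise

    notes: list[str] = []
    profile = record.profile
    ds = set(profile.diseases)
    if ds == {"rhinitis", "other_allergies"}:
        notes.append("clinical_extrapolated:rhinitis+other_allergies->6")

    if record.ige is None:
        raise ValidationError(f"patient {record.id}: PRIS requires an IgE panel")

    # s/t ratio from the highest-sIgE dominant allergen (first in rank order).
    top = dominance.dominant[0]
    top_sige = record.ige.specific_ige.get(top, 0.0)

    dominant_sources = {a.source for a in dominance.dominant}
    crd_values = [
        value
        for key, value in record.ige.component_ige.items()
        if key.source in dominant_sources
    ]
    if crd_values:
        category = max(
            (crd_category(v, thresholds) for v in crd_values),
            key=("negative", "positive", "high_positive").index,
        )
    else:
        category = "negative"
        notes.append("crd_no_applicable_component")

    parts = {
        "age_score": score_age(profile.age_years),
        "clinical_score": score_clinical(profile.diseases),
        "onset_score": score_onset(profile.onset_years),
        "sensitization_score": score_sensitizations(
            count_sensitizations(record, thresholds)
        ),
        "exposure_score": score_exposure(profile.n_symptom_triggering_allergens),
        "ratio_score": score_ratio(top_sige, record.ige.total_ige, thresholds),
        "crd_score": score_crd(category),
        "dominance_score": score_dominance(dominance.n_dominant),
    }
    return PRISBreakdown(total=sum(parts.values()), notes=tuple(notes), **parts)


def pris_quartile(total: float) -> str:
    """Map a PRIS total onto its prognostic band.

    Q1: >= 80, Q2: [60, 80), Q3: [40, 60), Q4: < 40; totals outside the
    achievable range [20, 100] are rejected.
    """
    if not PRIS_MIN <= total <= PRIS_MAX:
        raise ValidationError(
            f"PRIS total {total} outside achievable range [{PRIS_MIN}, {PRIS_MAX}]"
        )
    if total >= 80:
        return "Q1"
    if total >= 60:
        return "Q2"
    if total >= 40:
        return "Q3"
    return "Q4"
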
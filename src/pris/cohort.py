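"""Domain model for a sublingual-immunotherapy (SLIT) cohort and its CSV form.

A cohort is a list of :class:`PatientRecord` objects.  Each record carries the
clinical profile, the skin-prick-test (SPT) panel, the IgE panel (total,
allergen-specific and molecular-component IgE) and the longitudinal visual
analogue scale (VAS) assessments at baseline (T0) and after 12/24 months of
treatment (T12, T24).

On disk a cohort is four comma-separated UTF-8 tables keyed by patient id:

``patients.csv``
    id, age_years, sex, diseases (semicolon-joined), onset_years,
    n_symptom_triggering_allergens, act_score (may be empty),
    nasal_polyposis (0/1), dropped_out (0/1)
``spt.csv``
    id, allergen, wheal_mm, histamine_mm, saline_mm
``ige.csv``
    id, total_ige, allergen_or_component, value  (one ``total`` row per
    patient is encoded with allergen_or_component left empty and the
    concentration in total_ige; specific/component rows leave total_ige empty)
``vas.csv``
    id, timepoint (T0/T12/T24), item, score  (scores already normalized to
    the 0-100 scale)

Readers are strict: an unknown allergen label, a VAS score outside [0, 100]
or a negative wheal is a validation error naming the offending patient, never
a silent coercion.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Inhalant allergen extract sources used for SPT and specific IgE.
ALLERGEN_SOURCES: tuple[str, ...] = (
    "gramineae_grass",
    "ambrosia",
    "mugwort",
    "wall_pellitory",
    "olive",
    "cypress",
    "birch",
    "cat",
    "dog",
    "house_dust_mite",
    "molds",
)

#: Molecular components of the CRD panel, mapped to their source extract.
COMPONENT_SOURCES: dict[str, str] = {
    "Phl p1": "gramineae_grass",
    "Phl p5": "gramineae_grass",
    "Bet v1": "birch",
    "Bet v2": "birch",  # profilin; positivity excludes the patient
    "Amb a1": "ambrosia",
    "Art v1": "mugwort",
    "Par j2": "wall_pellitory",
    "Ole e1": "olive",
    "Cup a1": "cypress",
    "Fel d1": "cat",
    "Can f1": "dog",
    "Der p1": "house_dust_mite",
    "Der p2": "house_dust_mite",
    "Alt a1": "molds",
}

PROFILIN_COMPONENT = "Bet v2"

DISEASES: tuple[str, ...] = ("rhinitis", "asthma", "other_allergies")

TIMEPOINTS: tuple[str, ...] = ("T0", "T12", "T24")

#: VAS item vocabulary.  Rhinitis severity items are recorded for everyone;
#: asthma severity and exacerbation items only for patients with asthma;
#: frequency and on-demand medication are global items.
RHINITIS_ITEMS: tuple[str, ...] = (
    "sneezing",
    "nasal_congestion",
    "rhinorrhea",
    "nasal_itching",
    "throat_itching",
    "eye_itching",
    "ear_itching",
)
ASTHMA_ITEMS: tuple[str, ...] = (
    "chest_tightness",
    "breathlessness",
    "wheezing",
    "coughing",
    "asthma_exacerbations",
)
GENERAL_ITEMS: tuple[str, ...] = (
    "symptom_frequency",
    "on_demand_medication",
)
VAS_ITEMS: tuple[str, ...] = RHINITIS_ITEMS + ASTHMA_ITEMS + GENERAL_ITEMS


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, order=True)
class AllergenId:
    """An allergen extract source, optionally narrowed to a molecular component."""

    source: str
    component: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in ALLERGEN_SOURCES:
            raise ValidationError(f"unknown allergen source {self.source!r}")
        if self.component is not None:
            if self.component not in COMPONENT_SOURCES:
                raise ValidationError(f"unknown molecular component {self.component!r}")
            if COMPONENT_SOURCES[self.component] != self.source:
                raise ValidationError(
                    f"component {self.component!r} does not belong to source {self.source!r}"
                )

    @classmethod
    def from_component(cls, component: str) -> "AllergenId":
        if component not in COMPONENT_SOURCES:
            raise ValidationError(f"unknown molecular component {component!r}")
        return cls(COMPONENT_SOURCES[component], component)


@dataclasses.dataclass(frozen=True)
class SPTResult:
    """One skin-prick-test wheal with its control wheals."""

    allergen: AllergenId
    wheal_mm: float
    histamine_control_mm: float = 6.0
    saline_control_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("wheal_mm", "histamine_control_mm", "saline_control_mm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"SPT {name} must be finite and >= 0, got {v}")

    @property
    def battery_valid(self) -> bool:
        """A battery is interpretable when histamine reacts and saline does not."""
        return self.histamine_control_mm >= 3.0 and self.saline_control_mm < 3.0


@dataclasses.dataclass(frozen=True)
class IgEPanel:
    """Total, allergen-specific and component-resolved IgE concentrations."""

    total_ige: float  # kU/L
    specific_ige: Mapping[AllergenId, float] = dataclasses.field(default_factory=dict)
    component_ige: Mapping[AllergenId, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.total_ige) or self.total_ige <= 0:
            raise ValidationError(f"total IgE must be finite and > 0, got {self.total_ige}")
        for key, value in self.specific_ige.items():
            if key.component is not None:
                raise ValidationError(f"specific IgE key {key} must be a bare source")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"specific IgE for {key.source} must be >= 0")
        for key, value in self.component_ige.items():
            if key.component is None:
                raise ValidationError(f"component IgE key {key} must name a component")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"component IgE for {key.component} must be >= 0")


@dataclasses.dataclass(frozen=True)
class ClinicalProfile:
    """Demographics and clinical features feeding eligibility and scoring."""

    age_years: int
    diseases: frozenset[str]
    onset_years: float
    n_symptom_triggering_allergens: int
    act_score: Optional[int] = None
    nasal_polyposis: bool = False
    sex: Optional[str] = None  # "M"/"F"; descriptive only

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValidationError(f"age must be >= 0, got {self.age_years}")
        unknown = set(self.diseases) - set(DISEASES)
        if unknown:
            raise ValidationError(f"unknown diseases {sorted(unknown)}")
        if self.onset_years < 0:
            raise ValidationError("onset_years must be >= 0")
        if self.n_symptom_triggering_allergens < 0:
            raise ValidationError("n_symptom_triggering_allergens must be >= 0")
        if self.act_score is not None and not 5 <= self.act_score <= 25:
            raise ValidationError(f"ACT score must lie in 5-25, got {self.act_score}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")

    @property
    def has_asthma(self) -> bool:
        return "asthma" in self.diseases


@dataclasses.dataclass(frozen=True)
class VASAssessment:
    """Normalized 0-100 VAS item scores recorded at one timepoint."""

    timepoint: str
    items: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"timepoint must be one of {TIMEPOINTS}")
        for item, score in self.items.items():
            if item not in VAS_ITEMS:
                raise ValidationError(f"unknown VAS item {item!r}")
            if not math.isfinite(score) or not 0 <= score <= 100:
                raise ValidationError(
                    f"VAS item {item!r} score {score} outside [0, 100]"
                )


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One enrolled subject: profile, SPT/IgE panels and VAS trajectory."""

    id: str
    profile: ClinicalProfile
    spt: tuple[SPTResult, ...] = ()
    ige: Optional[IgEPanel] = None
    vas: tuple[VASAssessment, ...] = ()
    dropped_out: bool = False

    def __post_init__(self) -> None:
        seen = [a.timepoint for a in self.vas]
        if len(seen) != len(set(seen)):
            raise ValidationError(f"patient {self.id}: duplicate VAS timepoint")
        if not self.profile.has_asthma:
            for a in self.vas:
                bad = set(a.items) & set(ASTHMA_ITEMS)
                if bad:
                    raise ValidationError(
                        f"patient {self.id}: asthma VAS items {sorted(bad)} "
                        "recorded without an asthma diagnosis"
                    )

    def vas_at(self, timepoint: str) -> Optional[VASAssessment]:
        for a in self.vas:
            if a.timepoint == timepoint:
                return a
        return None


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = [
    "id",
    "age_years",
    "sex",
    "diseases",
    "onset_years",
    "n_symptom_triggering_allergens",
    "act_score",
    "nasal_polyposis",
    "dropped_out",
]
_SPT_COLUMNS = ["id", "allergen", "wheal_mm", "histamine_mm", "saline_mm"]
_IGE_COLUMNS = ["id", "total_ige", "allergen_or_component", "value"]
_VAS_COLUMNS = ["id", "timepoint", "item", "score"]


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing cohort table {path.name}")
    frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return frame


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read the four cohort tables under ``path`` into cross-linked records.

    ``path`` is the directory holding ``patients.csv``, ``spt.csv``,
    ``ige.csv`` and ``vas.csv``.  Any single-cell invariant violation raises
    :class:`ValidationError` naming the patient; a malformed table raises
    :class:`SchemaError` naming the column.
    """
    root = Path(path)
    patients = _read_table(root / "patients.csv", _PATIENT_COLUMNS)
    spt = _read_table(root / "spt.csv", _SPT_COLUMNS)
    ige = _read_table(root / "ige.csv", _IGE_COLUMNS)
    vas = _read_table(root / "vas.csv", _VAS_COLUMNS)

    spt_by_id: dict[str, list] = {}
    for row in spt.itertuples(index=False):
        if row.allergen not in ALLERGEN_SOURCES:
            raise ValidationError(
                f"patient {row.id}: unknown SPT allergen {row.allergen!r}"
            )
        if row.wheal_mm < 0:
            raise ValidationError(f"patient {row.id}: negative wheal {row.wheal_mm}")
        spt_by_id.setdefault(row.id, []).append(
            SPTResult(
                allergen=AllergenId(row.allergen),
                wheal_mm=float(row.wheal_mm),
                histamine_control_mm=float(row.histamine_mm),
                saline_control_mm=float(row.saline_mm),
            )
        )

    total_by_id: dict[str, float] = {}
    specific_by_id: dict[str, dict[AllergenId, float]] = {}
    component_by_id: dict[str, dict[AllergenId, float]] = {}
    for row in ige.itertuples(index=False):
        label = row.allergen_or_component
        if pd.isna(label) or label == "":
            total_by_id[row.id] = float(row.total_ige)
        elif label in ALLERGEN_SOURCES:
            specific_by_id.setdefault(row.id, {})[AllergenId(label)] = float(row.value)
        elif label in COMPONENT_SOURCES:
            component_by_id.setdefault(row.id, {})[
                AllergenId.from_component(label)
            ] = float(row.value)
        else:
            raise ValidationError(
                f"patient {row.id}: unknown allergen/component label {label!r}"
            )

    vas_by_id: dict[str, dict[str, dict[str, float]]] = {}
    for row in vas.itertuples(index=False):
        score = float(row.score)
        if not 0 <= score <= 100:
            raise ValidationError(
                f"patient {row.id}: VAS item {row.item!r} score {score} outside [0, 100]"
            )
        vas_by_id.setdefault(row.id, {}).setdefault(row.timepoint, {})[row.item] = score

    records: list[PatientRecord] = []
    for row in patients.itertuples(index=False):
        pid = row.id
        diseases = frozenset(
            d for d in str(row.diseases).split(";") if d and d != "nan"
        )
        act = None if pd.isna(row.act_score) else int(row.act_score)
        sex = None if pd.isna(row.sex) else str(row.sex)
        profile = ClinicalProfile(
            age_years=int(row.age_years),
            diseases=diseases,
            onset_years=float(row.onset_years),
            n_symptom_triggering_allergens=int(row.n_symptom_triggering_allergens),
            act_score=act,
            nasal_polyposis=bool(int(row.nasal_polyposis)),
            sex=sex,
        )
        panel = None
        if pid in total_by_id or pid in specific_by_id or pid in component_by_id:
            if pid not in total_by_id:
                raise ValidationError(f"patient {pid}: IgE rows without a total IgE row")
            panel = IgEPanel(
                total_ige=total_by_id[pid],
                specific_ige=specific_by_id.get(pid, {}),
                component_ige=component_by_id.get(pid, {}),
            )
        assessments = tuple(
            VASAssessment(timepoint=tp, items=items)
            for tp, items in sorted(vas_by_id.get(pid, {}).items())
        )
        records.append(
            PatientRecord(
                id=pid,
                profile=profile,
                spt=tuple(spt_by_id.get(pid, [])),
                ige=panel,
                vas=assessments,
                dropped_out=bool(int(row.dropped_out)),
            )
        )
    return records


def write_cohort(cohort: Iterable[PatientRecord], path: str | Path) -> None:
    """Write a cohort to the four CSV tables under directory ``path``.

    Numeric fields are serialized at full precision (``repr``), so a
    write/read round trip reproduces every field bit-exactly.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    patient_rows, spt_rows, ige_rows, vas_rows = [], [], [], []
    for rec in cohort:
        p = rec.profile
        patient_rows.append(
            {
                "id": rec.id,
                "age_years": p.age_years,
                "sex": "" if p.sex is None else p.sex,
                "diseases": ";".join(sorted(p.diseases)),
                "onset_years": repr(float(p.onset_years)),
                "n_symptom_triggering_allergens": p.n_symptom_triggering_allergens,
                "act_score": "" if p.act_score is None else p.act_score,
                "nasal_polyposis": int(p.nasal_polyposis),
                "dropped_out": int(rec.dropped_out),
            }
        )
        for s in rec.spt:
            spt_rows.append(
                {
                    "id": rec.id,
                    "allergen": s.allergen.source,
                    "wheal_mm": repr(float(s.wheal_mm)),
                    "histamine_mm": repr(float(s.histamine_control_mm)),
                    "saline_mm": repr(float(s.saline_control_mm)),
                }
            )
        if rec.ige is not None:
            ige_rows.append(
                {
                    "id": rec.id,
                    "total_ige": repr(float(rec.ige.total_ige)),
                    "allergen_or_component": "",
                    "value": "",
                }
            )
            for key in sorted(rec.ige.specific_ige):
                ige_rows.append(
                    {
                        "id": rec.id,
                        "total_ige": "",
                        "allergen_or_component": key.source,
                        "value": repr(float(rec.ige.specific_ige[key])),
                    }
                )
            for key in sorted(rec.ige.component_ige):
                ige_rows.append(
                    {
                        "id": rec.id,
                        "total_ige": "",
                        "allergen_or_component": key.component,
                        "value": repr(float(rec.ige.component_ige[key])),
                    }
                )
        for a in rec.vas:
            for item in sorted(a.items):
                vas_rows.append(
                    {
                        "id": rec.id,
                        "timepoint": a.timepoint,
                        "item": item,
                        "score": repr(float(a.items[item])),
                    }
                )

    pd.DataFrame(patient_rows, columns=_PATIENT_COLUMNS).to_csv(
        root / "patients.csv", index=False
    )
    pd.DataFrame(spt_rows, columns=_SPT_COLUMNS).to_csv(root / "spt.csv", index=False)
    pd.DataFrame(ige_rows, columns=_IGE_COLUMNS).to_csv(root / "ige.csv", index=False)
    pd.DataFrame(vas_rows, columns=_VAS_COLUMNS).to_csv(root / "vas.csv", index=False)
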
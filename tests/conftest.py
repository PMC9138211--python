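import pytest

from pris.cohort import (
    AllergenId,
    ClinicalProfile,
    IgEPanel,
    PatientRecord,
    SPTResult,
    VASAssessment,
)


def make_record(
    pid="P1",
    age=30,
    diseases=("rhinitis",),
    onset=2.0,
    n_expo=1,
    act=None,
    nasal_polyposis=False,
    allergens=(("gramineae_grass", 9.0, 10.0),),
    total_ige=100.0,
    components=None,
    vas=None,
    dropped_out=False,
):
    """Compact patient-record builder for tests.

    ``allergens`` is a sequence of (source, wheal_mm, specific_ige);
    ``components`` maps component label -> kUA/L; ``vas`` maps timepoint ->
    {item: score}.
    """
    spt = tuple(
        SPTResult(AllergenId(src), wheal_mm=wheal) for src, wheal, _ in allergens
    )
    specific = {AllergenId(src): sige for src, _, sige in allergens}
    component_ige = {
        AllergenId.from_component(c): v for c, v in (components or {}).items()
    }
    assessments = tuple(
        VASAssessment(tp, items) for tp, items in (vas or {}).items()
    )
    return PatientRecord(
        id=pid,
        profile=ClinicalProfile(
            age_years=age,
            diseases=frozenset(diseases),
            onset_years=onset,
            n_symptom_triggering_allergens=n_expo,
            act_score=act,
            nasal_polyposis=nasal_polyposis,
        ),
        spt=spt,
        ige=IgEPanel(
            total_ige=total_ige, specific_ige=specific, component_ige=component_ige
        ),
        vas=assessments,
        dropped_out=dropped_out,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A seeded default-parameter synthetic cohort shared across tests."""
    from pris.simulate import SyntheticCohortConfig, generate_with_truth

    cohort, truth, link = generate_with_truth(SyntheticCohortConfig(seed=7))
    return cohort, truth, link


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    from pris.pipeline import cohort_frame

    cohort, _, _ = default_cohort
    return cohort_frame(cohort)
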
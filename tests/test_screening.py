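import itertools
import random

import pytest

from conftest import make_record
from oracles import brute_force_dominant
from pris.errors import ValidationError
from pris.screening import (
    count_sensitizations,
    crd_category,
    identify_dominant_allergens,
    ige_positive,
    screen_eligibility,
    spt_positive,
)


@pytest.mark.parametrize(
    "wheal, expected",
    [(3.0, True), (2.9, False), (0.0, False), (10.0, True)],
)
def test_spt_positivity_cutoff(wheal, expected):
    assert spt_positive(wheal) is expected


@pytest.mark.parametrize(
    "value, expected",
    [(0.35, True), (0.34, False), (0.0, False), (100.0, True)],
)
def test_ige_positivity_cutoff(value, expected):
    assert ige_positive(value) is expected


@pytest.mark.parametrize(
    "value, expected",
    [
        (3.50, "high_positive"),
        (3.49, "positive"),
        (0.35, "positive"),
        (0.34, "negative"),
        (0.10, "negative"),
    ],
)
def test_crd_categories(value, expected):
    assert crd_category(value) == expected


def test_negative_inputs_rejected():
    for fn in (spt_positive, ige_positive, crd_category):
        with pytest.raises(ValidationError):
            fn(-0.1)


class TestCountSensitizations:
    def test_union_of_spt_and_sige(self):
        # SPT+ for grass only; sIgE+ for grass and mite
        rec = make_record(
            allergens=(("gramineae_grass", 9.0, 10.0), ("house_dust_mite", 0.0, 1.0))
        )
        assert count_sensitizations(rec) == 2

    def test_same_source_counted_once(self):
        rec = make_record(allergens=(("gramineae_grass", 9.0, 10.0),))
        assert count_sensitizations(rec) == 1

    def test_no_positives(self):
        rec = make_record(allergens=(("cat", 1.0, 0.1),))
        assert count_sensitizations(rec) == 0


class TestEligibility:
    def test_age_under_6_excluded(self):
        res = screen_eligibility(make_record(age=5))
        assert not res.eligible and "age_under_6" in res.reasons

    def test_profilin_positive_excluded(self):
        res = screen_eligibility(make_record(components={"Bet v2": 1.2}))
        assert res.reasons == ("profilin_betv2",)

    def test_plain_rhinitis_patient_eligible(self):
        res = screen_eligibility(make_record(age=30))
        assert res.eligible and res.reasons == ()

    def test_uncontrolled_asthma_excluded(self):
        rec = make_record(diseases=("rhinitis", "asthma"), act=15)
        assert "uncontrolled_asthma" in screen_eligibility(rec).reasons

    def test_controlled_asthma_eligible(self):
        rec = make_record(diseases=("rhinitis", "asthma"), act=20)
        assert screen_eligibility(rec).eligible

    def test_asthma_without_act_is_an_error(self):
        rec = make_record(diseases=("rhinitis", "asthma"))
        with pytest.raises(ValidationError, match="ACT"):
            screen_eligibility(rec)

    def test_nasal_polyposis_excluded(self):
        rec = make_record(nasal_polyposis=True)
        assert "nasal_polyposis" in screen_eligibility(rec).reasons

    def test_missing_positive_tests_excluded(self):
        rec = make_record(allergens=(("cat", 1.0, 0.1),))
        reasons = screen_eligibility(rec).reasons
        assert "no_positive_spt" in reasons and "no_positive_sige" in reasons


def panel_record(panel):
    """Build a record whose positive sensitizations equal ``panel``."""
    return make_record(allergens=tuple((s, w, g) for s, (w, g) in panel.items()))


class TestDominance:
    def test_single_clear_dominant(self):
        rec = panel_record(
            {"gramineae_grass": (9.0, 10.0), "house_dust_mite": (3.0, 1.0)}
        )
        res = identify_dominant_allergens(rec)
        assert [a.source for a in res.dominant] == ["gramineae_grass"]
        assert res.separation_wheal_mm == pytest.approx(6.0)
        assert res.separation_log10_ige == pytest.approx(1.0)

    def test_identical_pair_is_codominant(self):
        rec = panel_record({"cat": (6.0, 2.0), "dog": (6.0, 2.0)})
        res = identify_dominant_allergens(rec)
        assert res.n_dominant == 2
        assert res.separation_wheal_mm == 0.0 == res.separation_log10_ige

    def test_single_positive_allergen_dominant(self):
        rec = panel_record({"birch": (5.0, 1.0)})
        res = identify_dominant_allergens(rec)
        assert [a.source for a in res.dominant] == ["birch"]

    def test_both_margins_required(self):
        # IgE margin met, wheal margin not: no separation
        rec = panel_record({"cat": (6.0, 10.0), "dog": (5.0, 0.5)})
        assert identify_dominant_allergens(rec).n_dominant == 2

    def test_no_sensitization_is_an_error(self):
        with pytest.raises(ValidationError):
            identify_dominant_allergens(make_record(allergens=(("cat", 0.0, 0.1),)))

    def test_permutation_invariance(self):
        panel = {
            "gramineae_grass": (9.0, 12.0),
            "wall_pellitory": (8.5, 11.0),
            "house_dust_mite": (3.0, 0.9),
            "cat": (3.5, 0.4),
        }
        baseline = identify_dominant_allergens(panel_record(panel)).dominant
        rnd = random.Random(0)
        items = list(panel.items())
        for _ in range(10):
            rnd.shuffle(items)
            res = identify_dominant_allergens(panel_record(dict(items)))
            assert res.dominant == baseline

    @pytest.mark.parametrize("factor", [0.37, 2.0, 118.0])
    def test_ige_scale_invariance(self, factor):
        """Scaling all sIgE by one factor leaves the dominant set unchanged
        (log-difference criterion); values kept above the assay floor."""
        panel = {
            "gramineae_grass": (9.0, 12.0),
            "olive": (3.0, 1.1),
            "mugwort": (4.0, 0.6),
        }
        scaled = {s: (w, g * factor) for s, (w, g) in panel.items()}
        a = identify_dominant_allergens(panel_record(panel)).dominant
        b = identify_dominant_allergens(panel_record(scaled)).dominant
        assert a == b


WHEAL_GRID = (3.0, 8.0, 13.0)
IGE_GRID = (0.5, 1.0, 1.9, 10.0)
STATES = list(itertools.product(WHEAL_GRID, IGE_GRID))
SOURCES = ("gramineae_grass", "wall_pellitory", "house_dust_mite", "cat", "olive")


def assert_matches_oracle(panel):
    res = identify_dominant_allergens(panel_record(panel))
    assert {a.source for a in res.dominant} == set(brute_force_dominant(panel))


@pytest.mark.parametrize("size", [2, 3])
def test_dominance_matches_bruteforce_exhaustive(size):
    """Exhaustive check against subset enumeration on gridded small panels."""
    for states in itertools.product(STATES, repeat=size):
        panel = dict(zip(SOURCES, states))
        assert_matches_oracle(panel)


@pytest.mark.parametrize("size", [4, 5])
def test_dominance_matches_bruteforce_sampled(size):
    rnd = random.Random(size)
    for _ in range(300):
        panel = {s: rnd.choice(STATES) for s in SOURCES[:size]}
        assert_matches_oracle(panel)
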
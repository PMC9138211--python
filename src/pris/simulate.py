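"""Seeded synthetic SLIT cohort generator.

No public dataset accompanies the score, so every analysis in this package is
exercised on synthetic cohorts that emulate the study population: allergic
rhinitis patients (half with concomitant controlled asthma) aged 6-63
(24.87 +/- 10.80 years), ~11% dropout over 24 months, baseline mean symptom
score 80.97 +/- 8.24, and an allergen mix dominated by wall pellitory,
grasses and house dust mite.

Each patient is drawn in two passes.  Pass one samples the clinical profile
and one category per score parameter, then *realizes* raw measurements
consistent with the sampled categories: SPT wheals and specific IgE levels
are constructed so that the dominance rule recovers the sampled number of
dominant allergens, the s/t ratio falls in the sampled band for the top
dominant allergen, and a molecular component of the dominant source carries
the sampled CRD band.  Pass two computes the patient's PRIS total from those
raw fields and draws the latent response

    dMSS-24(%) = a + b * PRIS + eps,   eps ~ N(0, noise_sd),

clipped to [-25, 100]; dMSS-12 lags it by a configurable gap.  VAS items are
back-solved from the latent response (all items equal at a timepoint), so
recomputing MSS and dMSS from the records reproduces the latent draws up to
clipping.  The link intercept/slope default to a calibration targeting a
population PRIS-response correlation of 0.62 and a mean dMSS-24 of 67.71%.

Generated patients always pass eligibility screening (profilin-positive or
uncontrolled-asthma patients are never emitted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    ALLERGEN_SOURCES,
    ASTHMA_ITEMS,
    COMPONENT_SOURCES,
    GENERAL_ITEMS,
    RHINITIS_ITEMS,
    AllergenId,
    ClinicalProfile,
    IgEPanel,
    PatientRecord,
    SPTResult,
    VASAssessment,
)
from .errors import ValidationError
from .registry import DEFAULT_THRESHOLDS, Thresholds
from .scoring import compute_pris
from .screening import identify_dominant_allergens

logger = logging.getLogger("pris.simulate")

#: Allergen-mix marginal weights, from the distribution of allergens actually
#: prescribed in the study cohort (wall pellitory 69/130 mentions, grasses 47,
#: house dust mite 19, mugwort 4, olive 4, molds 1), with a small floor weight
#: for sources that are tested but were never prescribed.
DEFAULT_ALLERGEN_MIX: dict[str, float] = {
    "wall_pellitory": 69.0,
    "gramineae_grass": 47.0,
    "house_dust_mite": 19.0,
    "mugwort": 4.0,
    "olive": 4.0,
    "molds": 1.0,
    "ambrosia": 0.5,
    "cypress": 0.5,
    "birch": 0.5,
    "cat": 0.5,
    "dog": 0.5,
}

#: Category probabilities per score parameter (chosen to emulate a mixed
#: mono-/poly-sensitized SLIT referral population; see the methods note).
DEFAULT_CATEGORY_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "onset": {"le3": 0.35, "4_10": 0.40, "gt10": 0.25},
    "sensitizations": {"1": 0.30, "2_3": 0.40, "4_5": 0.20, "gt5": 0.10},
    "exposure": {"1": 0.35, "2": 0.35, "3": 0.20, "ge4": 0.10},
    "ratio": {"high": 0.30, "mid": 0.45, "low": 0.25},
    "crd": {"high_positive": 0.40, "positive": 0.40, "negative": 0.20},
    "dominance": {"1": 0.64, "2": 0.31, "3": 0.03, "gt3": 0.02},
}

#: Preferred molecular component used to realize the CRD band of a dominant
#: source (Bet v2 is never emitted: profilin positivity excludes patients).
_MAJOR_COMPONENT: dict[str, str] = {}
for comp, src in COMPONENT_SOURCES.items():
    if comp != "Bet v2" and src not in _MAJOR_COMPONENT:
        _MAJOR_COMPONENT[src] = comp


@dataclasses.dataclass
class SyntheticCohortConfig:
    """Distributional and response-link parameters of the generator."""

    n_patients: int = 110
    seed: int = 0
    # demographics
    age_mean: float = 24.87
    age_sd: float = 10.80
    age_range: tuple[int, int] = (6, 63)
    male_fraction: float = 0.618
    asthma_fraction: float = 0.5
    other_allergies_given_asthma: float = 0.2
    dropout_prob: float = 0.109
    # baseline symptom burden
    mss0_mean: float = 80.97
    mss0_sd: float = 8.24
    # response link dMSS-24 = a + b * PRIS + N(0, noise_sd)
    target_r: float = 0.62
    mean_delta24: float = 67.71
    noise_sd: float = 14.0
    link_intercept: Optional[float] = None
    link_slope: Optional[float] = None
    # dMSS-12 = dMSS-24 - N(gap_mean, gap_sd)
    gap_mean: float = 6.36
    gap_sd: float = 20.0
    delta_clip: tuple[float, float] = (-25.0, 100.0)
    allergen_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ALLERGEN_MIX)
    )
    category_distributions: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_CATEGORY_DISTRIBUTIONS.items()
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.gap_sd < 0:
            raise ValidationError("gap_sd must be >= 0")
        for p in (
            self.male_fraction,
            self.asthma_fraction,
            self.other_allergies_given_asthma,
            self.dropout_prob,
        ):
            if not 0 <= p <= 1:
                raise ValidationError(f"fraction {p} outside [0, 1]")
        if self.delta_clip[0] >= self.delta_clip[1]:
            raise ValidationError("delta_clip must be an increasing interval")
        for name, dist in self.category_distributions.items():
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or not math.isclose(
                total, 1.0, abs_tol=1e-6
            ):
                raise ValidationError(
                    f"category distribution {name!r} must be a probability vector"
                )
        mix_total = sum(self.allergen_mix.values())
        if mix_total <= 0 or any(w < 0 for w in self.allergen_mix.values()):
            raise ValidationError("allergen_mix weights must be non-negative, not all 0")
        unknown = set(self.allergen_mix) - set(ALLERGEN_SOURCES)
        if unknown:
            raise ValidationError(f"allergen_mix names unknown sources {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Pass one: clinical profile, panels, categories
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


_AGE_LOC_CACHE: dict[tuple, float] = {}


def _age_loc(cfg: SyntheticCohortConfig) -> float:
    """Latent normal location whose truncated-and-floored draws average to
    the configured mean age (truncation pulls the mean up, flooring down)."""
    key = (cfg.age_mean, cfg.age_sd, cfg.age_range)
    if key not in _AGE_LOC_CACHE:
        from scipy import optimize
        from scipy import stats as sps

        lo, hi = cfg.age_range
        target = cfg.age_mean + 0.5  # flooring removes ~half a year

        def gap(mu: float) -> float:
            a = (lo - mu) / cfg.age_sd
            b = (hi + 1 - mu) / cfg.age_sd
            return sps.truncnorm.mean(a, b, loc=mu, scale=cfg.age_sd) - target

        _AGE_LOC_CACHE[key] = float(optimize.brentq(gap, lo, hi))
    return _AGE_LOC_CACHE[key]


def _truncated_age(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> int:
    lo, hi = cfg.age_range
    loc = _age_loc(cfg)
    while True:
        age = rng.normal(loc, cfg.age_sd)
        if lo <= age < hi + 1:
            return int(math.floor(age))


def _sample_core(
    rng: np.random.Generator, cfg: SyntheticCohortConfig, pid: str
) -> tuple[PatientRecord, dict]:
    """Sample one patient without VAS; return the record and sampled categories."""
    cats: dict[str, str] = {}
    age = _truncated_age(rng, cfg)
    sex = "M" if rng.random() < cfg.male_fraction else "F"
    asthma = rng.random() < cfg.asthma_fraction
    other = asthma and rng.random() < cfg.other_allergies_given_asthma
    diseases = frozenset(
        ["rhinitis"] + (["asthma"] if asthma else []) + (["other_allergies"] if other else [])
    )
    act = int(rng.integers(20, 26)) if asthma else None

    # disease onset, restricted to bands feasible at the sampled age
    onset_dist = dict(cfg.category_distributions["onset"])
    if age < 11:
        onset_dist.pop("gt10", None)
    onset_cat = _pick(rng, onset_dist)
    cats["onset"] = onset_cat
    if onset_cat == "le3":
        onset = int(rng.integers(0, 4))
    elif onset_cat == "4_10":
        onset = int(rng.integers(4, min(10, age) + 1))
    else:
        onset = int(rng.integers(11, min(age, 30) + 1))

    # number of sensitizations
    sens_cat = _pick(rng, cfg.category_distributions["sensitizations"])
    cats["sensitizations"] = sens_cat
    n_sens = {
        "1": 1,
        "2_3": int(rng.integers(2, 4)),
        "4_5": int(rng.integers(4, 6)),
        "gt5": int(rng.integers(6, 9)),
    }[sens_cat]

    # dominance, feasible given n_sens
    dom_dist = {
        k: v
        for k, v in cfg.category_distributions["dominance"].items()
        if {"1": 1, "2": 2, "3": 3, "gt3": 4}[k] <= n_sens
    }
    dom_cat = _pick(rng, dom_dist)
    cats["dominance"] = dom_cat
    n_dom = {"1": 1, "2": 2, "3": 3, "gt3": 4}[dom_cat]

    # symptom-triggering exposures, capped at the sensitization count
    expo_dist = {
        k: v
        for k, v in cfg.category_distributions["exposure"].items()
        if {"1": 1, "2": 2, "3": 3, "ge4": 4}[k] <= n_sens
    }
    expo_cat = _pick(rng, expo_dist)
    cats["exposure"] = expo_cat
    n_expo = (
        int(rng.integers(4, n_sens + 1)) if expo_cat == "ge4" else int(expo_cat)
    )

    # allergen sources, dominants first
    mix_sources = list(cfg.allergen_mix)
    weights = np.array([cfg.allergen_mix[s] for s in mix_sources], dtype=float)
    idx = rng.choice(len(mix_sources), size=n_sens, replace=False, p=weights / weights.sum())
    sources = [mix_sources[i] for i in idx]
    dominants, others_src = sources[:n_dom], sources[n_dom:]

    # realize wheals and specific IgE so the dominance rule recovers n_dom:
    # dominants sit within 0.2 log / 3 mm of each other (no internal split
    # can separate), non-dominants trail by >= 0.7 log and >= 5 mm.
    base_log = float(rng.uniform(0.6, 1.3))
    dom_logs = base_log + rng.uniform(-0.1, 0.1, size=n_dom)
    dom_wheals = rng.uniform(8.0, 11.0, size=n_dom)
    specific: dict[AllergenId, float] = {}
    spt: list[SPTResult] = []
    for src, lg, wh in zip(dominants, dom_logs, dom_wheals):
        specific[AllergenId(src)] = float(10.0**lg)
        spt.append(SPTResult(AllergenId(src), wheal_mm=float(wh)))
    if others_src:
        min_dom_log = float(dom_logs.min())
        for src in others_src:
            lg = min_dom_log - 0.7 - rng.uniform(0.0, 0.8)
            specific[AllergenId(src)] = float(10.0**lg)
            spt.append(SPTResult(AllergenId(src), wheal_mm=3.0))

    # s/t ratio band realized through the top dominant allergen
    ratio_cat = _pick(rng, cfg.category_distributions["ratio"])
    cats["ratio"] = ratio_cat
    ratio = {
        "high": rng.uniform(0.2, 0.4),
        "mid": rng.uniform(0.05, 0.2),
        "low": rng.uniform(0.01, 0.05),
    }[ratio_cat]
    top_sige = max(specific[AllergenId(s)] for s in dominants)
    total_ige = top_sige / ratio

    # CRD band on a major component of the first dominant source
    crd_cat = _pick(rng, cfg.category_distributions["crd"])
    cats["crd"] = crd_cat
    component = _MAJOR_COMPONENT[dominants[0]]
    crd_value = {
        "high_positive": rng.uniform(3.5, 15.0),
        "positive": rng.uniform(0.35, 3.5),
        "negative": rng.uniform(0.01, 0.34),
    }[crd_cat]

    profile = ClinicalProfile(
        age_years=age,
        diseases=diseases,
        onset_years=float(onset),
        n_symptom_triggering_allergens=n_expo,
        act_score=act,
        nasal_polyposis=False,
        sex=sex,
    )
    record = PatientRecord(
        id=pid,
        profile=profile,
        spt=tuple(spt),
        ige=IgEPanel(
            total_ige=float(total_ige),
            specific_ige=specific,
            component_ige={AllergenId.from_component(component): float(crd_value)},
        ),
        vas=(),
        dropped_out=bool(rng.random() < cfg.dropout_prob),
    )
    return record, cats


# ---------------------------------------------------------------------------
# Link calibration
# ---------------------------------------------------------------------------

_CALIBRATION_CACHE: dict[str, tuple[float, float]] = {}
_CALIBRATION_SEED = 20_220_422  # fixed internal seed: link params are constants


def _pris_moments(cfg: SyntheticCohortConfig, n_mc: int) -> tuple[float, float]:
    """Monte-Carlo mean and SD of the PRIS total under the configured
    category distributions (uses the full pass-one machinery)."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    totals = np.empty(n_mc)
    for i in range(n_mc):
        record, _ = _sample_core(rng, cfg, pid=f"mc{i}")
        dom = identify_dominant_allergens(record)
        totals[i] = compute_pris(record, dom).total
    return float(totals.mean()), float(totals.std(ddof=1))


def calibrate_link(
    target_r: float,
    noise_sd: float,
    target_mean_delta: float = 67.71,
    config: Optional[SyntheticCohortConfig] = None,
    n_mc: int = 20_000,
) -> tuple[float, float]:
    """Solve for link intercept/slope (a, b) hitting a population correlation.

    Given the PRIS SD sigma_P implied by the configured category
    distributions, the slope ``b = (noise_sd / sigma_P) * r / sqrt(1 - r^2)``
    makes the latent (pre-clipping) correlation between PRIS and dMSS-24
    equal ``target_r``; the intercept centres the mean response at
    ``target_mean_delta``.  With ``noise_sd = 0`` the link is deterministic
    (correlation 1 for any positive slope) and only ``target_r = 1`` is
    reachable.
    """
    if not 0 <= target_r <= 1:
        raise ValidationError(f"target_r must lie in [0, 1], got {target_r}")
    cfg = config if config is not None else SyntheticCohortConfig()
    if not cfg.delta_clip[0] <= target_mean_delta <= cfg.delta_clip[1]:
        raise ValidationError(
            f"target mean {target_mean_delta} outside the dMSS support {cfg.delta_clip}"
        )
    if target_r == 0:
        return (target_mean_delta, 0.0)
    if noise_sd == 0:
        if target_r < 1:
            raise ValidationError(
                "with zero noise the link correlation is 1; target_r < 1 unreachable"
            )
        mu_p, _ = _cached_moments(cfg, n_mc)
        return (target_mean_delta - mu_p, 1.0)
    if target_r == 1:
        raise ValidationError("target_r = 1 requires noise_sd = 0")
    mu_p, sigma_p = _cached_moments(cfg, n_mc)
    b = (noise_sd / sigma_p) * target_r / math.sqrt(1 - target_r**2)
    a = target_mean_delta - b * mu_p
    total_sd = b * sigma_p / target_r
    if total_sd > (cfg.delta_clip[1] - cfg.delta_clip[0]) / 2:
        raise ValidationError(
            "requested link would spread dMSS far beyond its bounded support"
        )
    return (a, b)


def _cached_moments(cfg: SyntheticCohortConfig, n_mc: int) -> tuple[float, float]:
    key = json.dumps(
        [
            n_mc,
            cfg.age_mean,
            cfg.age_sd,
            cfg.age_range,
            cfg.asthma_fraction,
            cfg.other_allergies_given_asthma,
            sorted(cfg.allergen_mix.items()),
            {k: sorted(v.items()) for k, v in sorted(cfg.category_distributions.items())},
        ],
        default=str,
    )
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = _pris_moments(cfg, n_mc)
    return _CALIBRATION_CACHE[key]


# ---------------------------------------------------------------------------
# Pass two: response link and VAS back-solving
# ---------------------------------------------------------------------------


def _vas_items(profile: ClinicalProfile, value: float) -> dict[str, float]:
    items = {item: value for item in RHINITIS_ITEMS + GENERAL_ITEMS}
    if profile.has_asthma:
        items.update({item: value for item in ASTHMA_ITEMS})
    return items


def generate_with_truth(
    config: SyntheticCohortConfig,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[PatientRecord], pd.DataFrame, tuple[float, float]]:
    """Generate a cohort plus its latent ground truth.

    Returns ``(cohort, truth, (a, b))`` where ``truth`` has one row per
    patient: the PRIS total, the sampled score categories, the latent and
    realized response draws, and clip flags.
    """
    cfg = config
    if cfg.link_intercept is not None and cfg.link_slope is not None:
        a, b = cfg.link_intercept, cfg.link_slope
    elif cfg.link_intercept is None and cfg.link_slope is None:
        a, b = calibrate_link(cfg.target_r, cfg.noise_sd, cfg.mean_delta24, cfg)
    else:
        raise ValidationError("link_intercept and link_slope must be set together")

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.delta_clip
    cohort: list[PatientRecord] = []
    truth_rows: list[dict] = []
    n_clipped = 0
    for i in range(cfg.n_patients):
        record, cats = _sample_core(rng, cfg, pid=f"P{i:04d}")
        dom = identify_dominant_allergens(record, thresholds)
        total = compute_pris(record, dom, thresholds).total

        latent24 = a + b * total + rng.normal(0.0, cfg.noise_sd)
        delta24 = min(max(latent24, lo), hi)
        latent12 = delta24 - rng.normal(cfg.gap_mean, cfg.gap_sd)
        delta12 = min(max(latent12, lo), hi)
        clipped = latent24 != delta24 or latent12 != delta12

        mss0 = float(np.clip(rng.normal(cfg.mss0_mean, cfg.mss0_sd), 0.5, 100.0))
        mss12 = float(np.clip(mss0 * (1 - delta12 / 100.0), 0.0, 100.0))
        mss24 = float(np.clip(mss0 * (1 - delta24 / 100.0), 0.0, 100.0))
        if clipped:
            n_clipped += 1

        profile = record.profile
        vas = [VASAssessment("T0", _vas_items(profile, mss0))]
        if not record.dropped_out:
            vas.append(VASAssessment("T12", _vas_items(profile, mss12)))
            vas.append(VASAssessment("T24", _vas_items(profile, mss24)))
        record = dataclasses.replace(record, vas=tuple(vas))
        cohort.append(record)
        truth_rows.append(
            {
                "id": record.id,
                "pris_total": total,
                "latent_delta24": latent24,
                "delta24": delta24,
                "latent_delta12": latent12,
                "delta12": delta12,
                "mss0": mss0,
                "clipped": clipped,
                "dropped_out": record.dropped_out,
                **{f"cat_{k}": v for k, v in cats.items()},
            }
        )
    if n_clipped:
        logger.info(
            "clipped latent dMSS draws for %d/%d patients", n_clipped, cfg.n_patients
        )
    return cohort, pd.DataFrame(truth_rows), (a, b)


def generate_cohort(
    config: SyntheticCohortConfig,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[PatientRecord]:
    """Generate a synthetic cohort (see module docstring for the model)."""
    cohort, _, _ = generate_with_truth(config, thresholds)
    return cohort
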
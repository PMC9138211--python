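"""VAS-based treatment outcome indices and responder stratification.

The mean symptom score (MSS) at a timepoint is the unweighted arithmetic mean
of every VAS item recorded there — severity, frequency, exacerbation and
on-demand medication items alike — so it is a combined symptom-and-medication
score on the 0-100 scale.  Treatment efficacy after t months is the relative
improvement

    dMSS-t(%) = (MSS-0 - MSS-t) / MSS-0 * 100,

negative when symptoms worsen.  Responders stratify into very_high (>= 75%),
high ([50, 75)), mild ([25, 50)) and low (< 25%, including any worsening).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, VASAssessment
from .errors import DegenerateDesignError, ValidationError

RESPONSE_BANDS = ("very_high", "high", "mild", "low")


@dataclasses.dataclass(frozen=True)
class OutcomeRecord:
    """Per-patient MSS trajectory and efficacy indices (completers only
    carry T12/T24 entries)."""

    mss0: float
    mss12: Optional[float] = None
    mss24: Optional[float] = None
    delta12_pct: Optional[float] = None
    delta24_pct: Optional[float] = None
    response12: Optional[str] = None
    response24: Optional[str] = None


def mss(assessment: VASAssessment) -> float:
    """Unweighted mean of all recorded VAS item scores, on [0, 100]."""
    if not assessment.items:
        raise ValidationError(
            f"MSS undefined at {assessment.timepoint}: no VAS items recorded"
        )
    return float(np.mean(list(assessment.items.values())))


def delta_mss(mss0: float, mss_t: float) -> float:
    """Percentage improvement from baseline: (MSS-0 - MSS-t)/MSS-0 * 100."""
    if mss0 <= 0:
        raise DegenerateDesignError(
            f"baseline MSS must be > 0 to express relative change, got {mss0}"
        )
    return (mss0 - mss_t) / mss0 * 100.0


def response_quartile(delta_pct: float) -> str:
    """Band a dMSS(%) value: >=75 very_high, [50,75) high, [25,50) mild, <25 low."""
    if not math.isfinite(delta_pct):
        raise ValidationError(f"dMSS must be finite, got {delta_pct}")
    if delta_pct >= 75:
        return "very_high"
    if delta_pct >= 50:
        return "high"
    if delta_pct >= 25:
        return "mild"
    return "low"


def patient_outcome(record: PatientRecord) -> OutcomeRecord:
    """Compute the outcome record of one patient from its VAS trajectory.

    T0 must be present; T12/T24 indices are filled only where those
    assessments exist (dropouts keep ``None``).
    """
    t0 = record.vas_at("T0")
    if t0 is None:
        raise ValidationError(f"patient {record.id}: baseline VAS (T0) missing")
    mss0 = mss(t0)

    def at(tp: str) -> tuple[Optional[float], Optional[float], Optional[str]]:
        a = record.vas_at(tp)
        if a is None:
            return None, None, None
        m = mss(a)
        d = delta_mss(mss0, m)
        return m, d, response_quartile(d)

    mss12, d12, r12 = at("T12")
    mss24, d24, r24 = at("T24")
    return OutcomeRecord(
        mss0=mss0,
        mss12=mss12,
        mss24=mss24,
        delta12_pct=d12,
        delta24_pct=d24,
        response12=r12,
        response24=r24,
    )


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """A printed-table percentage: ``count/total*100`` rounded half-up."""
    if total <= 0:
        raise ValidationError("percentage needs a positive denominator")
    value = count / total * 100.0
    shift = 10**decimals
    return math.floor(value * shift + 0.5) / shift


_OUTCOME_COLUMNS = ("mss0", "mss12", "mss24", "delta12_pct", "delta24_pct")


def summarize_cohort(frame: pd.DataFrame, by: Optional[str] = None) -> pd.DataFrame:
    """Group-level summary: n, mean and SD of MSS-0/12/24 and dMSS-12/24.

    ``frame`` is a per-patient analysis frame (see
    :func:`pris.pipeline.cohort_frame`) restricted to the rows of interest —
    typically completers.  ``by`` selects a grouping column (for instance
    ``slit_type``, ``disease_group`` or ``pris_band``); ``None`` summarizes
    the whole frame as one group.  A single-patient group reports SD = 0;
    an empty frame yields an n = 0 row with statistics omitted.
    """
    def one_group(label: str, sub: pd.DataFrame) -> dict:
        row: dict = {"group": label, "n": len(sub)}
        if len(sub) == 0:
            return row
        for col in _OUTCOME_COLUMNS:
            if col not in sub.columns:
                continue
            values = sub[col].dropna().to_numpy(dtype=float)
            if values.size == 0:
                continue
            row[f"{col}_mean"] = float(np.mean(values))
            row[f"{col}_sd"] = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        return row

    if by is None:
        rows = [one_group("all", frame)]
    else:
        rows = [
            one_group(str(label), sub)
            for label, sub in frame.groupby(by, observed=True, sort=True)
        ]
        if not rows:
            rows = [one_group("(empty)", frame)]
    return pd.DataFrame(rows)


def response_band_counts(frame: pd.DataFrame) -> pd.DataFrame:
    """Responder-band counts and percentages at T12 and T24.

    Reproduces the shape of a responder table: one row per band plus a
    total row; counts in each column sum to the number of completers.
    """
    rows = []
    for band in RESPONSE_BANDS:
        row = {"band": band}
        for tp in ("12", "24"):
            col = frame[f"response{tp}"].dropna()
            n = int((col == band).sum())
            row[f"n_{tp}"] = n
            row[f"pct_{tp}"] = percentage(n, len(col)) if len(col) else float("nan")
        rows.append(row)
    total = {
        "band": "total",
        "n_12": int(frame["response12"].notna().sum()),
        "pct_12": 100.0,
        "n_24": int(frame["response24"].notna().sum()),
        "pct_24": 100.0,
    }
    rows.append(total)
    return pd.DataFrame(rows)


def cross_tab(
    pris_bands: Sequence[str], response_bands: Sequence[str]
) -> pd.DataFrame:
    """PRIS-band x response-band count matrix (rows: Q1..Q4, cols: bands).

    Row/column sums equal the stratum sizes and the grand total equals the
    number of patients supplied.
    """
    if len(pris_bands) != len(response_bands):
        raise ValidationError("pris_bands and response_bands must align")
    table = pd.crosstab(
        pd.Categorical(pris_bands, categories=["Q1", "Q2", "Q3", "Q4"]),
        pd.Categorical(response_bands, categories=list(RESPONSE_BANDS)),
        dropna=False,
    )
    table.index.name = "pris_band"
    table.columns.name = "response"
    return table
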
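"""End-to-end analysis pipeline: screen -> dominance -> score -> outcomes -> stats.

The central object is the *analysis frame* built by :func:`cohort_frame`: one
row per patient carrying eligibility, dominance, the PRIS breakdown and band,
the MSS trajectory, the efficacy indices and responder bands, plus the
grouping columns used by the published comparisons (mono- vs two-allergen
SLIT, rhinitis vs rhinitis+asthma).  Everything downstream — summary tables,
the statistical battery, figures — consumes this frame.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import outcomes as out
from . import stats as st
from .cohort import PatientRecord, read_cohort
from .errors import PrisError, ValidationError
from .registry import Thresholds
from .scoring import compute_pris, pris_quartile
from .screening import (
    count_sensitizations,
    identify_dominant_allergens,
    screen_eligibility,
)

logger = logging.getLogger("pris.pipeline")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    input_dir: Optional[str] = None  # cohort CSV directory; None -> simulate
    output_dir: str = "pris_run"
    n_patients: int = 110
    seed: int = 0
    act_threshold: int = 20
    posthoc: str = "tukey"
    dominance_wheal_mm: float = 5.0
    dominance_log10_ige: float = 0.5
    figures: bool = True
    verbosity: str = "INFO"

    def thresholds(self) -> Thresholds:
        return Thresholds(
            act_controlled=self.act_threshold,
            dominance_wheal_mm=self.dominance_wheal_mm,
            dominance_log10_ige=self.dominance_log10_ige,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)


def cohort_frame(
    cohort: list[PatientRecord], thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Build the per-patient analysis frame for an enrolled cohort."""
    if not cohort:
        raise PrisError("empty cohort: nothing to analyse")
    rows = []
    for rec in cohort:
        eligibility = screen_eligibility(rec, thresholds)
        row: dict = {
            "id": rec.id,
            "age_years": rec.profile.age_years,
            "sex": rec.profile.sex,
            "asthma": rec.profile.has_asthma,
            "dropped_out": rec.dropped_out,
            "eligible": eligibility.eligible,
            "exclusion_reasons": ";".join(eligibility.reasons),
        }
        if eligibility.eligible:
            dom = identify_dominant_allergens(rec, thresholds)
            breakdown = compute_pris(rec, dom, thresholds)
            row.update(
                {
                    "n_sensitizations": count_sensitizations(rec, thresholds),
                    "n_dominant": dom.n_dominant,
                    "dominant_allergens": ";".join(a.source for a in dom.dominant),
                    "separation_wheal_mm": dom.separation_wheal_mm,
                    "separation_log10_ige": dom.separation_log10_ige,
                    "age_score": breakdown.age_score,
                    "clinical_score": breakdown.clinical_score,
                    "onset_score": breakdown.onset_score,
                    "sensitization_score": breakdown.sensitization_score,
                    "exposure_score": breakdown.exposure_score,
                    "ratio_score": breakdown.ratio_score,
                    "crd_score": breakdown.crd_score,
                    "dominance_score": breakdown.dominance_score,
                    "pris_total": breakdown.total,
                    "pris_band": pris_quartile(breakdown.total),
                    "slit_type": "mono" if dom.n_dominant == 1 else "mix",
                    "disease_group": "rhinitis+asthma"
                    if rec.profile.has_asthma
                    else "rhinitis",
                }
            )
            oc = out.patient_outcome(rec)
            row.update(dataclasses.asdict(oc))
        rows.append(row)
    return pd.DataFrame(rows)


def completers(frame: pd.DataFrame) -> pd.DataFrame:
    """Eligible patients with both follow-up assessments."""
    mask = (
        frame["eligible"]
        & ~frame["dropped_out"]
        & frame["mss12"].notna()
        & frame["mss24"].notna()
    )
    return frame[mask].reset_index(drop=True)


def run_validation(frame: pd.DataFrame, posthoc: str = "tukey") -> dict:
    """The full statistical battery on an analysis frame.

    Returns a JSON-serializable report: power/sample-size planning numbers,
    the within-subject ANOVA over MSS-0/12/24, the PRIS -> dMSS-24
    regressions (overall and per subgroup), per-parameter category
    regressions, the between-band ANOVA with post-hoc contrasts, and the
    group summary tables.
    """
    comp = completers(frame)
    if len(comp) < 4:
        raise PrisError(f"only {len(comp)} completers: battery needs at least 4")

    spec = st.PowerSpec()
    report: dict = {
        "n_enrolled": int(len(frame)),
        "n_completers": int(len(comp)),
        "dropout_pct": out.percentage(int(len(frame) - len(comp)), int(len(frame)), 1),
        "power": {
            "target_r": spec.r,
            "alpha": spec.alpha,
            "target_power": spec.power,
            "required_n": st.sample_size_pearson(spec),
            "achieved_power_at_required_n": st.power_pearson(
                st.sample_size_pearson(spec), spec.r, spec.alpha
            ),
        },
    }

    mss_matrix = comp[["mss0", "mss12", "mss24"]].rename(
        columns={"mss0": "T0", "mss12": "T12", "mss24": "T24"}
    )
    rm = st.rm_anova(mss_matrix)
    report["rm_anova_mss"] = {
        "f": rm.f_stat,
        "df": list(rm.df),
        "p": rm.p_value,
        "pairwise": {pair: p for pair, p in rm.pairwise},
    }

    def regression_block(sub: pd.DataFrame) -> dict:
        fit = st.simple_regression(sub["pris_total"], sub["delta24_pct"])
        return {
            "n": int(len(sub)),
            "slope": fit.slope,
            "intercept": fit.intercept,
            "R": fit.r,
            "F": fit.f_stat,
            "df": list(fit.df),
            "p": fit.p_value,
            "note": fit.note,
        }

    report["regression_pris_delta24"] = {"overall": regression_block(comp)}
    for column, label in (("slit_type", "slit"), ("disease_group", "disease")):
        for value, sub in comp.groupby(column):
            if len(sub) >= 3 and sub["pris_total"].nunique() > 1:
                report["regression_pris_delta24"][f"{label}:{value}"] = (
                    regression_block(sub)
                )

    comp_reg = st.component_regression(comp)
    report["component_regression"] = {
        param: {
            "F": res.f_stat,
            "df": list(res.df),
            "p": res.p_value,
            "betas": res.component_betas.to_dict(orient="records"),
        }
        for param, res in comp_reg.items()
    }

    bands_present = comp["pris_band"].nunique()
    if bands_present >= 2:
        anova = st.oneway_anova_posthoc(
            comp["delta24_pct"], comp["pris_band"], posthoc=posthoc
        )
        report["oneway_anova_delta24_by_band"] = {
            "f": anova.f_stat,
            "df": list(anova.df),
            "p": anova.p_value,
            "posthoc_method": posthoc,
            "pairwise": {pair: p for pair, p in anova.pairwise},
        }
    strata = (
        comp.groupby("pris_band")["delta24_pct"]
        .agg(["count", "mean", "std"])
        .fillna(0.0)
    )
    report["delta24_by_band"] = {
        str(band): {
            "n": int(row["count"]),
            "mean": float(row["mean"]),
            "sd": float(row["std"]),
        }
        for band, row in strata.iterrows()
    }
    report["notes"] = [
        "regression denominator df = n - 2 (simple OLS)",
    ]
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _figures(frame: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = completers(frame)

    fig, ax = plt.subplots(figsize=(5, 4))
    means = [comp["mss0"].mean(), comp["mss12"].mean(), comp["mss24"].mean()]
    sds = [comp["mss0"].std(), comp["mss12"].std(), comp["mss24"].std()]
    ax.bar(["MSS-0", "MSS-12", "MSS-24"], means, yerr=sds, capsize=4, color="#4878a8")
    ax.set_ylabel("mean symptom score")
    ax.set_title("Symptom improvement under SLIT")
    fig.tight_layout()
    fig.savefig(outdir / "mss_by_timepoint.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(comp["pris_total"], comp["delta24_pct"], s=14, alpha=0.7)
    fit = st.simple_regression(comp["pris_total"], comp["delta24_pct"])
    xs = np.linspace(comp["pris_total"].min(), comp["pris_total"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson")
    ax.set_xlabel("PRIS")
    ax.set_ylabel("dMSS-24 (%)")
    ax.set_title(f"R = {fit.r:.3f}")
    fig.tight_layout()
    fig.savefig(outdir / "pris_vs_delta24.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    strata = comp.groupby("pris_band")["delta24_pct"].agg(["mean", "std"])
    ax.bar(
        strata.index.astype(str),
        strata["mean"],
        yerr=strata["std"].fillna(0),
        capsize=4,
        color="#6aa66a",
    )
    ax.set_xlabel("PRIS band")
    ax.set_ylabel("dMSS-24 (%)")
    ax.set_title("Response by PRIS stratum")
    fig.tight_layout()
    fig.savefig(outdir / "delta24_by_band.png", dpi=120)
    plt.close(fig)

    table = out.cross_tab(comp["pris_band"].tolist(), comp["response24"].tolist())
    fig, ax = plt.subplots(figsize=(5.5, 4))
    bottom = np.zeros(len(table.index))
    for band in table.columns:
        ax.bar(table.index.astype(str), table[band], bottom=bottom, label=str(band))
        bottom += table[band].to_numpy()
    ax.set_xlabel("PRIS band")
    ax.set_ylabel("patients")
    ax.legend(title="dMSS-24 response", fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "crosstab_stacked.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Reads the cohort from ``config.input_dir`` (or simulates one when no
    input is given), computes the analysis frame, the summary tables, the
    cross-tabulation, the validation battery JSON and (optionally) the
    figures, all under ``config.output_dir``.  Returns the metrics dict.
    """
    logging.basicConfig(level=config.verbosity)
    thresholds = config.thresholds()
    thresholds.log()

    if config.input_dir is not None:
        stage = "read"
        cohort = read_cohort(config.input_dir)
    else:
        stage = "simulate"
        from .simulate import SyntheticCohortConfig, generate_cohort

        cohort = generate_cohort(
            SyntheticCohortConfig(n_patients=config.n_patients, seed=config.seed),
            thresholds,
        )
    logger.info("stage %s: %d patients", stage, len(cohort))

    frame = cohort_frame(cohort, thresholds)
    report = run_validation(frame, posthoc=config.posthoc)
    comp = completers(frame)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "analysis_frame.csv", index=False)
    out.summarize_cohort(comp).to_csv(outdir / "summary_all.csv", index=False)
    out.summarize_cohort(comp, by="slit_type").to_csv(
        outdir / "summary_by_slit.csv", index=False
    )
    out.summarize_cohort(comp, by="disease_group").to_csv(
        outdir / "summary_by_disease.csv", index=False
    )
    out.summarize_cohort(comp, by="pris_band").to_csv(
        outdir / "summary_by_band.csv", index=False
    )
    out.response_band_counts(comp).to_csv(outdir / "response_bands.csv", index=False)
    out.cross_tab(comp["pris_band"].tolist(), comp["response24"].tolist()).to_csv(
        outdir / "crosstab_pris_response.csv"
    )
    with open(outdir / "metrics.json", "w") as handle:
        json.dump(_jsonable(report), handle, indent=2, sort_keys=True)
    if config.figures:
        _figures(frame, outdir)
    logger.info("report bundle written to %s", outdir)
    return report
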
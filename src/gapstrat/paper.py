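"""Packaged series-1 study fixtures and the published-results reproduction.

The fixtures transcribe the study's printed per-tumor amplified-band lists
(45 amplified tumors) and the 80-patient clinical roster; the reproduction
pipeline re-derives the class counts, inclusion filtering, per-class and
regrouped Kaplan-Meier medians, log-rank tests and the stepwise Cox model
from those tables alone.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import (
    AmplificationProfile,
    GAP_CLASS_ORDER,
    GapClass,
    RiskGroup,
    classify_gap,
    cohort_frequency_table,
    profile_from_bands,
    risk_group,
)
from .genome import CytobandMap, GeneCatalog, read_cytobands, read_gene_bed
from .io import read_clinical_tsv
from .survival import (
    Covariate,
    apply_inclusion_filter,
    km_by_group,
    km_fit,
    km_median,
    logrank_test,
    stepwise_cox,
)

_FIXTURES = resources.files("gapstrat") / "fixtures"


def _fixture_path(name: str):
    return resources.as_file(_FIXTURES / name)


def load_cytobands() -> CytobandMap:
    with _fixture_path("cytobands_hg19.txt") as p:
        return read_cytobands(p)


def load_gene_catalog(cytobands: CytobandMap | None = None) -> GeneCatalog:
    cytobands = cytobands if cytobands is not None else load_cytobands()
    with _fixture_path("genes_hg19.bed") as p:
        return read_gene_bed(p, cytobands)


def load_series1_clinical() -> pd.DataFrame:
    with _fixture_path("series1_clinical.tsv") as p:
        df = read_clinical_tsv(p)
    df["event"] = df["event"].astype(int)
    df["os_months"] = df["os_months"].astype(int)
    return df


def load_series1_profiles() -> list[AmplificationProfile]:
    """One profile per series-1 tumor: 45 amplified + 35 with no amplification."""
    with _fixture_path("series1_profiles.tsv") as p:
        amp = pd.read_csv(p, sep="\t")
    clinical = load_series1_clinical()
    amp_ids = set(amp["tumor_id"])
    roster = set(clinical["id"])
    stray = amp_ids - roster
    if stray:
        raise ValueError(f"profile fixture ids not in the clinical roster: {stray}")
    profiles = [
        profile_from_bands(row.tumor_id, row.bands.split(","))
        for row in amp.itertuples(index=False)
    ]
    profiles += [
        AmplificationProfile(tid) for tid in clinical["id"] if tid not in amp_ids
    ]
    return profiles


def _chemo_category(raw) -> str | None:
    """Collapse the roster's treatment strings to the 3-level analysis variable.

    ``None`` (documented no chemotherapy) stays its own level; every
    non-Stupp regimen (Sequential, PCV, BCNU+TMZ) is pooled; unknown or
    mixed entries become missing.
    """
    if pd.isna(raw):
        return None
    raw = str(raw)
    if raw == "Stupp":
        return "Stupp"
    if raw == "None":
        return "none"
    if raw in ("Sequential", "PCV", "BCNU+TMZ", "BCNU"):
        return "other"
    return None


def _age_bin(age: float) -> str:
    if age <= 30:
        return "<=30"
    if age <= 45:
        return "31-45"
    if age <= 60:
        return "46-60"
    if age <= 75:
        return "61-75"
    return ">75"


def prepare_survival_table(
    clinical: pd.DataFrame, profiles: list[AmplificationProfile]
) -> pd.DataFrame:
    """Join clinical records with GAP classes and derive analysis covariates."""
    cls = {p.tumor_id: classify_gap(p) for p in profiles}
    df = clinical.copy()
    df["gap_class"] = df["id"].map(lambda i: cls[i].value)
    df["risk_group"] = df["id"].map(lambda i: risk_group(cls[i]).value)
    df["age_group"] = df["age"].map(_age_bin)
    df["karnofsky_bin"] = df["karnofsky"].map(
        lambda k: None if pd.isna(k) else (">70" if k > 70 else "<=70"))
    df["chemo_cat"] = df["chemotherapy"].map(_chemo_category)
    return df


def series1_candidates() -> list[Covariate]:
    """The published univariate screen variables with their category bins."""
    return [
        Covariate("age_group", "age_group",
                  ("<=30", "31-45", "46-60", "61-75", ">75")),
        Covariate("karnofsky", "karnofsky_bin", (">70", "<=70")),
        Covariate("surgery", "surgery", ("total", "partial", "biopsy")),
        Covariate("chemotherapy", "chemo_cat", ("none", "other", "Stupp")),
        Covariate("risk_group", "risk_group",
                  (RiskGroup.FAVORABLE.value, RiskGroup.UNFAVORABLE.value)),
    ]


def reproduce_paper() -> dict:
    """Recompute the fixture-derivable published results as a report dict."""
    profiles = load_series1_profiles()
    clinical = load_series1_clinical()
    freq = cohort_frequency_table(profiles)
    n_amplified = sum(1 for p in profiles if p.n_regions >= 1)
    n_egfr = sum(1 for p in profiles if p.egfr_involved)
    n_multi = sum(1 for p in profiles if p.n_regions >= 2)

    table = prepare_survival_table(clinical, profiles)
    included, excluded = apply_inclusion_filter(table)

    class_order = [c.value for c in GAP_CLASS_ORDER]
    km_class = km_by_group(included, "gap_class", group_order=class_order)
    km_risk = km_by_group(
        included, "risk_group",
        group_order=[RiskGroup.FAVORABLE.value, RiskGroup.UNFAVORABLE.value])

    class_groups = [
        (sub["os_months"], sub["event"])
        for c in class_order
        for sub in [included[included["gap_class"] == c]]
    ]
    lr_class = logrank_test(class_groups)
    risk_groups = [
        (sub["os_months"], sub["event"])
        for r in (RiskGroup.FAVORABLE.value, RiskGroup.UNFAVORABLE.value)
        for sub in [included[included["risk_group"] == r]]
    ]
    lr_risk = logrank_test(risk_groups)

    cox = stepwise_cox(included, series1_candidates())

    overall = km_fit(included["os_months"], included["event"])
    return {
        "cohort": {
            "n_total": len(profiles),
            "n_amplified": n_amplified,
            "n_egfr_involved": n_egfr,
            "n_multi_region": n_multi,
            "class_counts": dict(zip(freq["gap_class"], freq["count"])),
        },
        "inclusion": {
            "n_included": len(included),
            "n_excluded": len(excluded),
            "exclusion_reasons": dict(
                excluded["exclusion_reason"].value_counts()),
        },
        "km": {
            "overall_median": km_median(overall),
            "per_class": km_class.to_dict(orient="records"),
            "per_risk_group": km_risk.to_dict(orient="records"),
        },
        "logrank": {
            "five_class": {"statistic": lr_class.statistic, "df": lr_class.df,
                           "p_value": lr_class.p_value},
            "risk_group": {"statistic": lr_risk.statistic, "df": lr_risk.df,
                           "p_value": lr_risk.p_value},
        },
        "stepwise_cox": {
            "selected": cox.selected,
            "params": cox.params.round(6).to_dict(orient="index"),
            "selection_log": cox.selection_log,
            "n": cox.n,
            "n_events": cox.n_events,
        },
    }


def summarize_report(report: dict) -> str:
    """Human-readable one-page summary of :func:`reproduce_paper` output."""
    lines = ["series-1 reproduction", "=" * 21, ""]
    c = report["cohort"]
    lines.append(f"tumors: {c['n_total']}  amplified: {c['n_amplified']}  "
                 f"EGFR-involved: {c['n_egfr_involved']}")
    lines.append("class counts: " + ", ".join(
        f"{k}={v}" for k, v in c["class_counts"].items()))
    lines.append(f"included in OS analysis: {report['inclusion']['n_included']}")
    lines.append("")
    lines.append("KM medians (months):")
    for row in report["km"]["per_class"]:
        lines.append(f"  {row['group']:<20} n={row['n']:<3} median={row['median']}")
    for row in report["km"]["per_risk_group"]:
        lines.append(f"  {row['group']:<20} n={row['n']:<3} median={row['median']}")
    lr = report["logrank"]
    lines.append(f"log-rank 5-class: chi2={lr['five_class']['statistic']:.2f} "
                 f"p={lr['five_class']['p_value']:.2g}")
    lines.append(f"log-rank risk-group: chi2={lr['risk_group']['statistic']:.2f} "
                 f"p={lr['risk_group']['p_value']:.2g}")
    lines.append("stepwise Cox retained: "
                 + (", ".join(report["stepwise_cox"]["selected"]) or "(null model)"))
    return "\n".join(lines) + "\n"
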
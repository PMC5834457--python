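"""Survival-analysis battery: cohort filtering, Kaplan-Meier with median
dichotomisation, univariate/multivariate Cox proportional-hazards models,
the PD-L1 x SI interaction model, and the delta-value subgroup analysis.

All fits go through lifelines; ties use the Breslow approximation by
default (Efron available).  Hazard ratios are per unit of the covariate:
SI per unit of proportion (HR < 1 means protective), stage and grade coded
as ordinal integers entering linearly, age per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "MULTIVARIATE_VARIABLES",
    "ModelReport",
    "KMResult",
    "InteractionResult",
    "filter_cohort",
    "km_by_median_si",
    "cph_univariate",
    "cph_multivariate",
    "interaction_model",
    "subgroup_analysis",
]

MULTIVARIATE_VARIABLES = (
    "stage", "age", "vascular_invasion", "si", "pleural_invasion", "grade"
)


@dataclass
class ModelReport:
    """One fitted proportional-hazards model, Table-style.

    ``table`` has one row per variable (hazard_ratio, ci_low, ci_high,
    p), ordered by p-value (most significant first) for multivariate
    models.
    """

    table: pd.DataFrame
    model_type: str
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)


def _fit_cph(
    df: pd.DataFrame, covariates: list[str], time_col: str, event_col: str,
    ties: str = "breslow",
) -> tuple[pd.DataFrame, int, int, list[str]]:
    data = df[covariates + [time_col, event_col]].dropna()
    n, n_events = len(data), int(data[event_col].sum())
    notes: list[str] = []
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant on the complete cases")
    corr = data[covariates].corr().abs()
    high = [
        (a, b)
        for i, a in enumerate(covariates)
        for b in covariates[i + 1:]
        if corr.loc[a, b] > 0.999
    ]
    if high:
        notes.append(f"collinear covariates: {high}")
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(
                data.astype(float), duration_col=time_col, event_col=event_col,
                fit_options={"step_size": 0.5},
            )
        except Exception as exc:  # non-convergence is reported, not raised
            notes.append(f"fit failed: {exc}")
            tab = pd.DataFrame(
                np.nan, index=covariates,
                columns=["hazard_ratio", "ci_low", "ci_high", "p"],
            )
            return tab, n, n_events, notes
        for wmsg in caught:
            if "converge" in str(wmsg.message).lower():
                notes.append(str(wmsg.message))
    summ = cph.summary
    tab = pd.DataFrame(
        {
            "hazard_ratio": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    tab.index.name = "variable"
    return tab, n, n_events, notes


def filter_cohort(
    raw: pd.DataFrame, time_col: str = "time_months", min_months: float = 1.0
) -> tuple[pd.DataFrame, int]:
    """Apply the cohort inclusion rule: survival of at least one month.

    Returns the filtered table and the number of excluded cases.
    """
    keep = raw[time_col] >= min_months
    n_removed = int((~keep).sum())
    out = raw.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("no cases remain after the one-month survival filter")
    return out, n_removed


@dataclass
class KMResult:
    """Median-dichotomised Kaplan-Meier comparison of two groups."""

    curves: pd.DataFrame  # columns: time, survival, n_at_risk, group
    logrank_p: float
    group_sizes: dict[str, int]
    median_survival: dict[str, float]
    split_value: float


def _km_two_groups(
    df: pd.DataFrame, group: pd.Series, time_col: str, event_col: str,
    split_value: float,
) -> KMResult:
    frames, medians, sizes = [], {}, {}
    fitters = {}
    for g in ("high", "low"):
        sub = df[group == g]
        sizes[g] = len(sub)
        kmf = KaplanMeierFitter(label=g)
        kmf.fit(sub[time_col], sub[event_col])
        fitters[g] = kmf
        medians[g] = float(kmf.median_survival_time_)
        ev = kmf.event_table
        frames.append(
            pd.DataFrame(
                {
                    "time": kmf.survival_function_.index,
                    "survival": kmf.survival_function_[g].to_numpy(),
                    "n_at_risk": ev["at_risk"].to_numpy(),
                    "group": g,
                }
            )
        )
    hi, lo = df[group == "high"], df[group == "low"]
    lr = logrank_test(
        hi[time_col], lo[time_col], hi[event_col], lo[event_col]
    )
    return KMResult(
        pd.concat(frames, ignore_index=True), float(lr.p_value), sizes, medians,
        split_value,
    )


def km_by_median_si(
    df: pd.DataFrame,
    si_col: str = "si",
    time_col: str = "time_months",
    event_col: str = "event",
) -> KMResult:
    """Kaplan-Meier curves for high-SI (> median) versus low-SI (<= median).

    Ties at the median go to the low group.  Raises when all SI values are
    equal (no split possible).
    """
    data = df[[si_col, time_col, event_col]].dropna()
    if data[si_col].nunique() < 2:
        raise ValueError("all SI values are equal; median split impossible")
    med = float(data[si_col].median())
    group = pd.Series(
        np.where(data[si_col] > med, "high", "low"), index=data.index
    )
    if (group == "high").sum() < 2 or (group == "low").sum() < 2:
        raise ValueError("median split leaves fewer than 2 cases in a group")
    return _km_two_groups(data, group, time_col, event_col, med)


def cph_univariate(
    df: pd.DataFrame,
    variable: str,
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "breslow",
) -> ModelReport:
    """Univariate Cox proportional-hazards model for one variable."""
    data = df[[variable, time_col, event_col]].dropna()
    if data[event_col].sum() < 3:
        raise ValueError("need at least 3 events")
    tab, n, n_events, notes = _fit_cph(data, [variable], time_col, event_col, ties)
    return ModelReport(tab, "univariate", n, n_events, notes)


def cph_multivariate(
    df: pd.DataFrame,
    variables: tuple[str, ...] = MULTIVARIATE_VARIABLES,
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "breslow",
) -> ModelReport:
    """Joint Cox model on the complete cases, report ordered by p-value."""
    variables = [v for v in variables]
    data = df[variables + [time_col, event_col]].dropna()
    if len(data) < 10 * len(variables):
        warnings.warn(
            f"only {len(data)} complete cases for {len(variables)} covariates "
            "(guideline: >= 10 per covariate)",
            stacklevel=2,
        )
    tab, n, n_events, notes = _fit_cph(data, variables, time_col, event_col, ties)
    tab = tab.sort_values("p")
    return ModelReport(tab, "multivariate", n, n_events, notes)


@dataclass
class InteractionResult:
    """PD-L1 x SI interaction model plus per-stratum KM comparisons."""

    report: ModelReport
    interaction_p: float
    strata_km: dict[str, KMResult | None]


def interaction_model(
    df: pd.DataFrame,
    si_col: str = "si",
    stratum_col: str = "pdl1_stratum",
    time_col: str = "time_months",
    event_col: str = "event",
    split_within_stratum: bool = True,
) -> InteractionResult:
    """Test whether PD-L1 expression modifies the prognostic value of SI.

    Fits a Cox model with SI, the PD-L1-high indicator and their product
    term, and reports the interaction p-value; additionally computes a
    median-SI-split KM comparison inside each PD-L1 stratum (split at the
    within-stratum median by default).
    """
    data = df[[si_col, stratum_col, time_col, event_col]].dropna().copy()
    data["pdl1_high"] = (data[stratum_col] == "high").astype(float)
    for g in ("high", "low"):
        sub = data[data[stratum_col] == g]
        if sub.empty or sub[event_col].sum() == 0:
            raise ValueError(f"PD-L1 {g} stratum has no cases or no events")
    data["si_x_pdl1"] = data[si_col] * data["pdl1_high"]
    tab, n, n_events, notes = _fit_cph(
        data.rename(columns={si_col: "si"}),
        ["si", "pdl1_high", "si_x_pdl1"],
        time_col, event_col,
    )
    report = ModelReport(tab, "interaction", n, n_events, notes)
    inter_p = float(tab.loc["si_x_pdl1", "p"])

    global_med = float(data[si_col].median())
    strata_km: dict[str, KMResult | None] = {}
    for g in ("high", "low"):
        sub = data[data[stratum_col] == g]
        try:
            if split_within_stratum:
                strata_km[g] = km_by_median_si(sub, si_col, time_col, event_col)
            else:
                grp = pd.Series(
                    np.where(sub[si_col] > global_med, "high", "low"),
                    index=sub.index,
                )
                strata_km[g] = _km_two_groups(sub, grp, time_col, event_col, global_med)
        except ValueError as exc:
            warnings.warn(f"stratified KM skipped for PD-L1 {g}: {exc}", stacklevel=2)
            strata_km[g] = None
    return InteractionResult(report, inter_p, strata_km)


def subgroup_analysis(
    df: pd.DataFrame,
    si_col: str = "si",
    core1_col: str = "si_core1",
    core2_col: str = "si_core2",
    delta_stratum_col: str = "delta_stratum",
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per delta-subgroup prognostic value and paired-core concordance.

    For each heterogeneity subgroup (delta-high / delta-low) reports the
    univariate SI hazard ratio with CI and the Spearman rho between the two
    core scores.  Degenerate subgroups (under 3 events or constant SI)
    yield an NA row.
    """
    rows = []
    for g in ("high", "low"):
        sub = df[df[delta_stratum_col] == g]
        row: dict = {"subgroup": g, "n": len(sub)}
        try:
            rep = cph_univariate(sub, si_col, time_col, event_col)
            row.update(
                hazard_ratio=rep.table.loc[si_col, "hazard_ratio"],
                ci_low=rep.table.loc[si_col, "ci_low"],
                ci_high=rep.table.loc[si_col, "ci_high"],
                p=rep.table.loc[si_col, "p"],
            )
        except ValueError:
            row.update(hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        pair = sub[[core1_col, core2_col]].dropna()
        if len(pair) >= 3 and pair[core1_col].nunique() > 1 and pair[core2_col].nunique() > 1:
            from scipy.stats import spearmanr

            row["paired_core_rho"] = float(
                spearmanr(pair[core1_col], pair[core2_col]).statistic
            )
        else:
            row["paired_core_rho"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("subgroup")
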
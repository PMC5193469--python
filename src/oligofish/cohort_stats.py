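"""Cohort-level statistics: group tests, deletion counts, survival.

Implements the analysis surface applied to the 33-case series:
chi-square group comparisons (Yates-corrected for 2x2 tables),
per-case deleted/altered chromosome-arm counts, Kaplan-Meier curves,
log-rank tests, and a univariate-screen -> multivariate Cox workflow
with the stated covariate dichotomizations (age 50 years, mitoses 5,
Ki67 12%, INA 10%, ATRX 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .caller import ArmStatus
from .concordance import round_half_up

#: Dichotomization cutoffs used in the survival analyses.
COVARIATE_CUTOFFS = {
    "age": 50.0,            # years
    "mitoses_per_10hpf": 5.0,
    "ki67_pct": 12.0,       # percent
    "ina_pct": 10.0,        # percent positive cells
    "atrx_pct": 10.0,       # percent retained nuclei
}

STATUS_COLUMNS = ["status_1p", "status_19q", "status_9p", "status_10q"]
GROUP_ORDER = ["OII", "OIII", "AII", "AIII", "GBM"]


def chi_square_test(table: Sequence[Sequence[int]] | pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square on a contingency table.

    Yates continuity correction is applied for 2x2 tables (the
    convention under which the published 9p OII-vs-OIII comparison
    yields p = 0.002); larger tables use the uncorrected statistic.
    """
    arr = np.asarray(table, dtype=float)
    if arr.min() < 0:
        raise ValueError("cell counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    correction = arr.shape == (2, 2)
    res = sps.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DeletionSummary:
    """Per-case deleted/altered arm counts and their group means."""

    per_case: pd.DataFrame       # case_id, group, n_deleted, n_altered
    group_means: pd.Series       # mean n_deleted per group
    group_means_altered: pd.Series
    total_mean: float
    total_mean_altered: float


def deletion_count_summary(calls: pd.DataFrame) -> DeletionSummary:
    """Count deleted and altered arms per case among {1p, 19q, 9p, 10q}.

    Whole-chromosome-9 (or -10) loss contributes exactly one deleted
    arm — the target arm — to the count; the concomitant control-arm
    deletion (9q, 10p) is reported separately and never added.
    Altered counts add IMBALANCED statuses on the four target arms.
    """
    missing = [c for c in STATUS_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"calls table missing columns: {missing}")
    sts = calls[STATUS_COLUMNS].map(
        lambda s: s.value if isinstance(s, ArmStatus) else str(s))
    n_del = (sts == "DELETED").sum(axis=1)
    n_alt = n_del + (sts == "IMBALANCED").sum(axis=1)
    per_case = pd.DataFrame({
        "case_id": calls["case_id"].values,
        "group": calls["group"].values,
        "n_deleted": n_del.values,
        "n_altered": n_alt.values,
    })
    g = per_case.groupby("group", sort=False)
    order = [x for x in GROUP_ORDER if x in set(per_case["group"])]
    return DeletionSummary(
        per_case=per_case,
        group_means=g["n_deleted"].mean().reindex(order),
        group_means_altered=g["n_altered"].mean().reindex(order),
        total_mean=float(per_case["n_deleted"].mean()),
        total_mean_altered=float(per_case["n_altered"].mean()),
    )


@dataclass
class KMEstimate:
    """Kaplan-Meier curve with median survival (None if not reached)."""

    fitter: KaplanMeierFitter
    n: int
    n_events: int
    median_months: float | None

    @property
    def survival_function(self) -> pd.DataFrame:
        return self.fitter.survival_function_


def km_estimate(time: Sequence[float], event: Sequence[bool],
                label: str = "KM") -> KMEstimate:
    """Product-limit estimate with right censoring."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event, label=label)
    med = float(kmf.median_survival_time_)
    return KMEstimate(
        fitter=kmf, n=len(time), n_events=int(event.sum()),
        median_months=None if np.isinf(med) else med,
    )


def logrank_test(time: Sequence[float], event: Sequence[bool],
                 group: Sequence) -> tuple[float, float]:
    """Log-rank chi-square comparing >= 2 groups (1 df for two)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if len(set(group.tolist())) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Multivariate Cox fit: HRs with 95% CIs, or a degeneracy flag."""

    converged: bool
    flag: str = ""
    hazard_ratios: pd.Series | None = None
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None
    p_values: pd.Series | None = None
    fitter: CoxPHFitter | None = None


def cox_fit(df: pd.DataFrame, covariates: Sequence[str],
            time_col: str = "time_months", event_col: str = "event",
            warn_events_per_covariate: float = 10.0) -> CoxResult:
    """Cox proportional-hazards fit (Breslow tie handling).

    Non-convergence or complete separation is reported as a flagged
    result rather than a silent estimate.  A warning is emitted when
    there are fewer than ~10 events per covariate.
    """
    covariates = list(covariates)
    data = df[[time_col, event_col, *covariates]].astype(float)
    n_events = int(data[event_col].sum())
    if n_events < warn_events_per_covariate * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates; "
            "estimates may be unstable", stacklevel=2)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # lifelines reports separation / ill-conditioning as warnings;
            # surface them as flagged results instead of silent estimates.
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(data, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, ConvergenceWarning,
            np.linalg.LinAlgError) as exc:
        return CoxResult(converged=False, flag=f"fit failed: {exc}")
    ci = np.exp(cph.confidence_intervals_)
    return CoxResult(
        converged=True,
        hazard_ratios=cph.hazard_ratios_,
        ci_lower=ci.iloc[:, 0],
        ci_upper=ci.iloc[:, 1],
        p_values=cph.summary["p"],
        fitter=cph,
    )


def univariate_screen(df: pd.DataFrame, covariates: Sequence[str],
                      alpha: float = 0.05,
                      time_col: str = "time_months",
                      event_col: str = "event") -> pd.DataFrame:
    """Screen dichotomous covariates by univariate log-rank at ``alpha``."""
    rows = []
    for cov in covariates:
        groups = df[cov]
        if groups.nunique() < 2:
            rows.append({"covariate": cov, "p": np.nan, "selected": False})
            continue
        _, p = logrank_test(df[time_col], df[event_col], groups)
        rows.append({"covariate": cov, "p": p, "selected": p < alpha})
    return pd.DataFrame(rows)


def cox_workflow(df: pd.DataFrame, covariates: Sequence[str],
                 alpha: float = 0.05) -> tuple[pd.DataFrame, CoxResult | None]:
    """Univariate log-rank screen, then multivariate Cox on survivors."""
    screen = univariate_screen(df, covariates, alpha=alpha)
    selected = screen.loc[screen["selected"], "covariate"].tolist()
    if not selected:
        return screen, None
    return screen, cox_fit(df, selected)


def save_km_plot(estimates: Sequence[KMEstimate], path, title: str = "") -> None:
    """Write overlaid Kaplan-Meier curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for est in estimates:
        est.fitter.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Table-1-style group frequency report
# ---------------------------------------------------------------------------

def _fmt_count_pct(k: int, n: int) -> str:
    pct = 0 if n == 0 else int(round_half_up(100.0 * k / n))
    return f"{k} ({pct})"


def group_frequency_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Counts with integer percentages (and means/medians) per group.

    Reproduces the layout of the published clinicopathological table:
    one row per variable level, columns for the total cohort and each
    diagnostic group, cells formatted ``count (percent)`` with
    percentages rounded half-up; numeric variables report the group
    mean and median instead.  Division by an empty group yields a
    zero row, not an error.
    """
    groups = [g for g in GROUP_ORDER if g in set(cases["group"])]
    cols = ["Total", *groups]

    def subsets():
        yield "Total", cases
        for g in groups:
            yield g, cases[cases["group"] == g]

    rows: dict[str, dict[str, str]] = {}

    def add_bool_row(name: str, mask_fn) -> None:
        rows[name] = {label: _fmt_count_pct(int(mask_fn(sub).sum()), len(sub))
                      for label, sub in subsets()}

    def add_numeric_rows(name: str, col: str) -> None:
        rows[f"{name} mean"] = {
            label: ("-" if len(sub) == 0
                    else f"{round_half_up(float(sub[col].mean()), 1):g}")
            for label, sub in subsets()}
        rows[f"{name} median"] = {
            label: ("-" if len(sub) == 0
                    else f"{round_half_up(float(sub[col].median()), 1):g}")
            for label, sub in subsets()}

    add_bool_row("Recurrence yes", lambda s: s["recurrence"])
    add_bool_row("Sex male", lambda s: s["sex"] == "M")
    add_bool_row("Sex female", lambda s: s["sex"] == "F")
    add_bool_row("MVP endocrinoid", lambda s: s["mvp"] == "endocrinoid")
    add_bool_row("MVP glomeruloid", lambda s: s["mvp"] == "glomeruloid")
    add_bool_row("Calcifications", lambda s: s["calcifications"])
    add_numeric_rows("Age", "age")
    add_numeric_rows("Mitoses/10HPF", "mitoses_per_10hpf")
    add_numeric_rows("Ki67 %", "ki67_pct")
    add_bool_row("INA positive", lambda s: s["ina_positive"])
    add_bool_row("IDH1R132H positive", lambda s: s["idh1r132h_positive"])
    add_bool_row("ATRX positive", lambda s: s["atrx"] == "retained")
    for col, arm in (("status_1p", "1p"), ("status_19q", "19q"),
                     ("status_9p", "9p"), ("status_10q", "10q")):
        add_bool_row(f"Chr {arm} loss", lambda s, c=col: s[c] == "DELETED")
        add_bool_row(f"Chr {arm} no deletion", lambda s, c=col: s[c] == "NORMAL")
        add_bool_row(f"Chr {arm} imbalance", lambda s, c=col: s[c] == "IMBALANCED")
    add_bool_row("Chr 9q loss", lambda s: s["control_9q_deleted"])

    dels = deletion_count_summary(cases)
    rows["Chr arm deletion mean"] = {
        "Total": f"{round_half_up(dels.total_mean, 2):g}",
        **{g: f"{round_half_up(float(dels.group_means[g]), 2):g}"
           for g in groups},
    }
    rows["Chr arm alteration mean"] = {
        "Total": f"{round_half_up(dels.total_mean_altered, 2):g}",
        **{g: f"{round_half_up(float(dels.group_means_altered[g]), 2):g}"
           for g in groups},
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.reindex(columns=cols)
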
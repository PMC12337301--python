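"""Lifespan analysis: Kaplan-Meier curves, Cox regression, hazard translation.

Kaplan-Meier product-limit estimates (with Greenwood variance and log-log 95%
bands) summarise each treatment group's survival; a Cox proportional-hazards
model with Efron tie handling estimates the treatment hazard ratio.  The
hazard-translation step back-calculates, from the treatment hazard ratio and
an epigenetic-age difference, the per-day hazard coefficient implied by a
simplified model in which mortality hazard rises exponentially with
epigenetic age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times

logger = logging.getLogger("epiclock")


@dataclass
class GroupKm:
    """One group's product-limit estimate."""

    group: str
    n: int
    n_events: int
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray           # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]


@dataclass
class KmEstimate:
    groups: dict[str, GroupKm]


@dataclass
class CoxFit:
    """Treatment hazard ratio from a Cox proportional-hazards fit (Efron ties)."""

    reference: str
    comparison: str
    log_hr: float
    se: float
    hr: float
    hr_ci: tuple[float, float]
    z: float
    p: float
    n: int
    n_events: int
    flagged: bool = False          # monotone-likelihood / convergence warning


@dataclass
class HazardTranslation:
    """Per-day hazard increment implied by a group HR acting through an
    epigenetic-age difference."""

    hazard_ratio: float
    delta_days: float
    coefficient: float             # per-day log-hazard slope
    percent_increase: float        # (exp(coefficient) - 1) x 100


def _validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_days", "event", "group"):
        if col not in cohort.columns:
            raise ValueError(f"cohort missing column {col!r}")
    if (cohort["time_days"] <= 0).any():
        raise ValueError("survival times must be positive")
    return cohort


def _greenwood(times: np.ndarray, events: np.ndarray, at_risk: np.ndarray,
               survival: np.ndarray) -> np.ndarray:
    """Greenwood variance S(t)^2 * cumsum d / (n (n - d)) over event times."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > events, events / (at_risk * (at_risk - events)), np.inf)
    return survival ** 2 * np.cumsum(terms)


def km_fit(cohort: pd.DataFrame, alpha: float = 0.05) -> KmEstimate:
    """Per-group Kaplan-Meier estimate with medians and 95% CIs."""
    cohort = _validate_cohort(cohort)
    groups: dict[str, GroupKm] = {}
    for g, sub in cohort.groupby("group", sort=True):
        if sub["event"].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(sub["time_days"], event_observed=sub["event"], label=str(g))
        table = kmf.event_table
        table = table[table["observed"] > 0]  # survival steps occur at death times
        times = table.index.to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(times).to_numpy()
        var = _greenwood(times, table["observed"].to_numpy(dtype=float),
                         table["at_risk"].to_numpy(dtype=float), surv)
        ci = kmf.confidence_interval_
        ci_at = ci.reindex(times, method="ffill")
        median = kmf.median_survival_time_
        if np.isinf(median):
            logger.warning("km_fit: group %s never reaches S <= 0.5; median undefined", g)
            median_out = None
        else:
            median_out = float(median)
        med_ci = median_survival_times(kmf.confidence_interval_)
        lo = float(med_ci.iloc[0, 0])
        hi = float(med_ci.iloc[0, 1])
        groups[str(g)] = GroupKm(
            group=str(g), n=len(sub), n_events=int(sub["event"].sum()),
            times=times, survival=surv, variance=var,
            ci_lower=ci_at.iloc[:, 0].to_numpy(), ci_upper=ci_at.iloc[:, 1].to_numpy(),
            median=median_out,
            median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
        )
    return KmEstimate(groups=groups)


def cox_fit(cohort: pd.DataFrame, reference: str | None = None) -> CoxFit:
    """Cox PH fit of the treatment effect (Efron tie handling, Wald test)."""
    cohort = _validate_cohort(cohort)
    labels = sorted(cohort["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"expected two groups, found {labels}")
    if reference is None:
        reference = labels[0]
    comparison = [l for l in labels if l != reference][0]
    for g in labels:
        if cohort.loc[cohort["group"] == g, "event"].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
    frame = pd.DataFrame({
        "time_days": cohort["time_days"].to_numpy(dtype=float),
        "event": cohort["event"].to_numpy(dtype=int),
        "treat": (cohort["group"] == comparison).astype(float).to_numpy(),
    })
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(frame, duration_col="time_days", event_col="event")
        flagged = any("convergence" in str(w.message).lower()
                      or "monotone" in str(w.message).lower() for w in caught)
    if flagged:
        logger.warning("cox_fit: convergence warning (possible monotone likelihood)")
    s = cph.summary.loc["treat"]
    return CoxFit(
        reference=reference, comparison=comparison,
        log_hr=float(s["coef"]), se=float(s["se(coef)"]),
        hr=float(np.exp(s["coef"])),
        hr_ci=(float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        z=float(s["z"]), p=float(s["p"]),
        n=len(frame), n_events=int(frame["event"].sum()), flagged=flagged,
    )


def median_extension_percent(median_treatment: float, median_control: float) -> float:
    """Percent extension of median lifespan: (m_t/m_c - 1) x 100."""
    if median_control <= 0:
        raise ValueError("control median must be positive")
    if median_treatment <= 0:
        raise ValueError("treatment median must be positive")
    return (median_treatment / median_control - 1.0) * 100.0


def hazard_per_epigenetic_day(hr: float, delta_days: float) -> HazardTranslation:
    """Per-day hazard increment implied by a treatment HR and an
    epigenetic-age difference.

    Interprets the treatment hazard ratio as acting entirely through a
    ``delta_days`` reduction in epigenetic age under hazard proportional to
    exp(beta * epigenetic age): beta = -ln(HR)/delta, and each additional day
    of epigenetic age multiplies the hazard by exp(beta).
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if delta_days == 0:
        raise ValueError("delta_days must be nonzero")
    beta = -np.log(hr) / delta_days
    return HazardTranslation(hazard_ratio=hr, delta_days=delta_days,
                             coefficient=float(beta),
                             percent_increase=float((np.exp(beta) - 1.0) * 100.0))


def hazard_reduction_percent(hr: float) -> float:
    """Percent reduction in the hazard of death: (1 - HR) x 100."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return (1.0 - hr) * 100.0


def survival_table(km: KmEstimate, cox: CoxFit) -> pd.DataFrame:
    """Tidy per-group medians plus the Cox summary."""
    rows = []
    for g, est in km.groups.items():
        rows.append(("median_survival", g, est.median,
                     est.median_ci[0], est.median_ci[1], np.nan))
    rows.append(("hazard_ratio", f"{cox.comparison} vs {cox.reference}", cox.hr,
                 cox.hr_ci[0], cox.hr_ci[1], cox.p))
    return pd.DataFrame(rows, columns=["quantity", "group", "estimate",
                                       "ci_lower", "ci_upper", "p"])


def plot_survival(km: KmEstimate, path=None):
    """Step plot of the group survival curves with CI bands (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, est in km.groups.items():
        t = np.concatenate([[0.0], est.times])
        s = np.concatenate([[1.0], est.survival])
        ax.step(t, s, where="post", label=g)
        ax.fill_between(est.times, est.ci_lower, est.ci_upper, step="post", alpha=0.2)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
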
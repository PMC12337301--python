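"""Epigenetic-aging-rate analysis: two-group linear trajectories of predicted age.

Predicted epigenetic age is regressed on chronological day, treatment, and
their interaction by ordinary least squares.  The interaction term is the
difference in aging rate between the groups; estimated marginal means at
chosen days give post-hoc group contrasts with the pooled residual variance.
Chronological day is centred at the first sampling day for conditioning, and
every reported quantity is back-transformed to the raw day scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("epiclock")


@dataclass
class TrajectoryFit:
    """OLS fit of epigenetic age ~ day * treatment.

    ``reference`` is the first (baseline) treatment; the interaction estimate
    is (other slope - reference slope).  ``mean_at_center`` holds each group's
    fitted epigenetic age at ``center_day``; ``intercepts`` are extrapolations
    to day 0.
    """

    reference: str
    other: str
    slopes: dict[str, float]
    intercepts: dict[str, float]
    mean_at_center: dict[str, float]
    interaction: float
    interaction_se: float
    interaction_t: float
    interaction_p: float
    df_resid: int
    sigma2: float
    cov: np.ndarray          # 4x4 covariance of (const, day_c, treat, day_c:treat)
    params: np.ndarray
    center_day: float
    day_range: tuple[float, float]
    n: int


@dataclass
class DayContrast:
    """Group contrast of estimated marginal means at a fixed chronological day."""

    day: float
    means: dict[str, float]
    difference: float        # other - reference
    se: float
    t: float
    df: int
    p: float


def fit_trajectory(predicted_ages: pd.Series, days: pd.Series, treatments: pd.Series,
                   reference: str | None = None, center_day: float | None = None
                   ) -> TrajectoryFit:
    """OLS of predicted epigenetic age on day, treatment and day x treatment."""
    frame = pd.DataFrame({"y": predicted_ages, "day": days, "treat": treatments}).dropna()
    labels = list(pd.unique(frame["treat"]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two treatment groups, found {labels}")
    if reference is None:
        reference = labels[0]
    other = [l for l in labels if l != reference][0]
    for lab in (reference, other):
        if frame.loc[frame["treat"] == lab, "day"].nunique() < 2:
            raise ValueError(f"group {lab!r} must span >= 2 distinct days "
                             "(day x treatment term is collinear otherwise)")
    if center_day is None:
        center_day = float(frame["day"].min())

    dc = frame["day"].to_numpy(dtype=float) - center_day
    z = (frame["treat"] == other).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(frame)), dc, z, dc * z])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (day x treatment)")
    y = frame["y"].to_numpy(dtype=float)

    fit = sm.OLS(y, X).fit()
    b = fit.params
    cov = np.asarray(fit.cov_params())
    df = int(fit.df_resid)

    slopes = {reference: float(b[1]), other: float(b[1] + b[3])}
    mean_at_center = {reference: float(b[0]), other: float(b[0] + b[2])}
    intercepts = {g: mean_at_center[g] - slopes[g] * center_day for g in slopes}
    return TrajectoryFit(
        reference=reference, other=other, slopes=slopes, intercepts=intercepts,
        mean_at_center=mean_at_center,
        interaction=float(b[3]), interaction_se=float(fit.bse[3]),
        interaction_t=float(fit.tvalues[3]), interaction_p=float(fit.pvalues[3]),
        df_resid=df, sigma2=float(fit.mse_resid), cov=cov, params=np.asarray(b),
        center_day=center_day,
        day_range=(float(frame["day"].min()), float(frame["day"].max())),
        n=len(frame),
    )


def contrast_at_day(fit: TrajectoryFit, day: float) -> DayContrast:
    """Estimated marginal means and the group difference at a chronological day."""
    lo, hi = fit.day_range
    if day < lo or day > hi:
        warnings.warn(f"day {day} is outside the observed range [{lo}, {hi}]; "
                      "contrast is an extrapolation", stacklevel=2)
    d = day - fit.center_day
    b = fit.params
    means = {fit.reference: float(b[0] + b[1] * d),
             fit.other: float(b[0] + b[2] + (b[1] + b[3]) * d)}
    L = np.array([0.0, 0.0, 1.0, d])
    diff = float(L @ b)
    se = float(np.sqrt(L @ fit.cov @ L))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
    return DayContrast(day=day, means=means, difference=diff, se=se, t=t,
                       df=fit.df_resid, p=float(p))


def percent_slowdown(control_slope: float, treatment_slope: float) -> float:
    """Percent reduction in epigenetic aging rate: (1 - s_treat/s_control) x 100."""
    if control_slope == 0:
        raise ValueError("control slope is zero; slowdown undefined")
    return (1.0 - treatment_slope / control_slope) * 100.0


def percent_slowdown_ci(fit: TrajectoryFit, level: float = 0.95) -> tuple[float, float, float]:
    """Delta-method CI for the percent slowdown (point, lower, upper).

    slowdown = -b3/b1 in the centred parameterisation; the gradient wrt
    (b1, b3) is (b3/b1^2, -1/b1).
    """
    b1 = fit.params[1]
    b3 = fit.params[3]
    if b1 == 0:
        raise ValueError("control slope is zero; slowdown undefined")
    theta = -b3 / b1
    grad = np.array([b3 / b1 ** 2, -1.0 / b1])
    sub = fit.cov[np.ix_([1, 3], [1, 3])]
    se = float(np.sqrt(grad @ sub @ grad))
    crit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
    return (theta * 100.0, (theta - crit * se) * 100.0, (theta + crit * se) * 100.0)


def convergence_day(fit: TrajectoryFit, tol: float = 1e-12) -> float | None:
    """Day at which the two fitted lines intersect; None for parallel lines."""
    s1 = fit.slopes[fit.reference]
    s2 = fit.slopes[fit.other]
    if abs(s1 - s2) <= tol:
        if abs(fit.intercepts[fit.reference] - fit.intercepts[fit.other]) <= tol:
            logger.info("convergence_day: lines are identical")
        return None
    i1 = fit.intercepts[fit.reference]
    i2 = fit.intercepts[fit.other]
    return (i2 - i1) / (s1 - s2)


def extrapolate_group_age(anchor_day: float, anchor_mean: float, slope: float,
                          target_day: float) -> float:
    """Linear extrapolation of a group's epigenetic age from an anchored mean."""
    vals = [anchor_day, anchor_mean, slope, target_day]
    if not all(np.isfinite(vals)):
        raise ValueError("inputs must be finite")
    return anchor_mean + slope * (target_day - anchor_day)


def trajectory_table(fit: TrajectoryFit, contrasts: list[DayContrast]) -> pd.DataFrame:
    """Tidy one-row-per-quantity summary of a trajectory analysis."""
    rows = []
    for g in (fit.reference, fit.other):
        rows.append(("slope", g, fit.slopes[g], np.nan, np.nan, np.nan))
        rows.append(("mean_at_center", g, fit.mean_at_center[g], np.nan, np.nan, np.nan))
    rows.append(("interaction", f"{fit.other}-{fit.reference}", fit.interaction,
                 fit.interaction_se, fit.interaction_t, fit.interaction_p))
    for c in contrasts:
        rows.append((f"contrast_day_{c.day:g}", f"{fit.other}-{fit.reference}",
                     c.difference, c.se, c.t, c.p))
    slow = percent_slowdown(fit.slopes[fit.reference], fit.slopes[fit.other])
    rows.append(("percent_slowdown", fit.other, slow, np.nan, np.nan, np.nan))
    conv = convergence_day(fit)
    rows.append(("convergence_day", "both", np.nan if conv is None else conv,
                 np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["quantity", "group", "estimate", "se", "t", "p"])


def plot_trajectory(fit: TrajectoryFit, predicted_ages: pd.Series, days: pd.Series,
                    treatments: pd.Series, path=None):
    """Scatter of predicted age vs day with the two fitted lines (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, color in zip((fit.reference, fit.other), ("tab:blue", "tab:orange")):
        mask = treatments == g
        ax.scatter(days[mask], predicted_ages[mask], s=18, color=color, label=g, alpha=0.7)
        grid = np.linspace(fit.day_range[0], fit.day_range[1], 50)
        ax.plot(grid, fit.intercepts[g] + fit.slopes[g] * grid, color=color)
    ax.set_xlabel("chronological day")
    ax.set_ylabel("predicted epigenetic age (d)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
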
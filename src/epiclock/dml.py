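"""Age-related differential methylation via per-site binomial GLMs.

Each CpG's (methylated, unmethylated) counts are modelled as binomial with a
logit link on chronological age in days; significance is a 1-df likelihood
ratio test against the intercept-only model, with Benjamini-Hochberg control
across sites.  When a site's Pearson dispersion exceeds a threshold the test
falls back to a quasi-binomial F test and the result is flagged.

The fits are a hand-vectorised Newton iteration over all sites at once: the
design matrix is shared across sites, so the per-site score and information
reduce to small (k x k) solves that numpy batches efficiently.  This is what
makes replicated whole-matrix scans cheap enough for simulation studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, f as f_dist
from statsmodels.stats.multitest import multipletests

from .io import CpGCountMatrix

logger = logging.getLogger("epiclock")

_ETA_CLIP = 30.0


@dataclass
class AgeDmlResult:
    """Per-site GLM result; ``q`` is NaN until set by a scan's BH pass."""

    site_id: str
    slope: float       # logit-methylation change per day
    se: float
    stat: float        # LRT chi-square (or F when quasibinomial)
    p: float
    q: float
    n_used: int
    converged: bool
    quasibinomial: bool
    dispersion: float


def _deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Binomial deviance summed over libraries; zero-total cells contribute 0."""
    nmu = n * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / np.where(nmu > 0, nmu, 1.0)), 0.0)
        r = n - y
        nr = n - nmu
        t2 = np.where(r > 0, r * np.log(r / np.where(nr > 0, nr, 1.0)), 0.0)
    return 2.0 * (t1 + t2).sum(axis=1)


def _fit_binomial_glm(y: np.ndarray, n: np.ndarray, X: np.ndarray,
                      max_iter: int = 50, ridge: float = 1e-10
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Newton fit of S independent binomial-logit GLMs sharing design X.

    y, n : (S, L) methylated / total counts; X : (L, k).
    Returns (beta (S,k), deviance (S,), cov (S,k,k), converged (S,)).
    """
    S, L = y.shape
    k = X.shape[1]
    beta = np.zeros((S, k))
    tot_y = y.sum(axis=1)
    tot_n = n.sum(axis=1)
    p0 = (tot_y + 0.5) / (tot_n + 1.0)
    beta[:, 0] = np.log(p0 / (1.0 - p0))  # assumes column 0 is the intercept

    eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    dev = _deviance(y, n, mu)
    eye = ridge * np.eye(k)

    for _ in range(max_iter):
        W = n * mu * (1.0 - mu)
        g = (y - n * mu) @ X                      # (S, k) score
        H = np.einsum("sl,lk,lj->skj", W, X, X) + eye
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        step = np.ones((S, 1))
        for _half in range(20):
            beta_new = beta + step * delta
            eta = np.clip(beta_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
            mu_new = expit(eta)
            dev_new = _deviance(y, n, mu_new)
            worse = dev_new > dev + 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        beta = beta + step * delta
        eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        new_dev = _deviance(y, n, mu)
        moved = np.abs(dev - new_dev)
        dev = new_dev
        g = (y - n * mu) @ X
        gscale = 1e-8 * (1.0 + tot_n)
        if (np.abs(g).max(axis=1) < gscale).all() or (moved < 1e-12).all():
            break

    g = (y - n * mu) @ X
    converged = np.abs(g).max(axis=1) < 1e-6 * (1.0 + tot_n)
    W = n * mu * (1.0 - mu)
    H = np.einsum("sl,lk,lj->skj", W, X, X) + 1e-12 * np.eye(k)
    cov = np.linalg.inv(H)
    return beta, dev, cov, converged


def _pearson_dispersion(y, n, mu, k):
    used = n > 0
    m = used.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(used, (y - n * mu) ** 2 / np.where(n * mu * (1 - mu) > 0,
                                                              n * mu * (1 - mu), 1.0), 0.0)
    x2 = contrib.sum(axis=1)
    df = np.maximum(m - k, 1)
    return x2 / df, m


def _scan_arrays(meth: np.ndarray, total: np.ndarray, ages: np.ndarray,
                 treatment: np.ndarray | None = None,
                 dispersion_threshold: float = 1.0,
                 dispersion_mode: str = "pooled") -> pd.DataFrame:
    """Core scan on raw arrays; returns a per-site frame without q-values.

    ``dispersion_mode`` controls the quasi-binomial adjustment: "pooled"
    (default) squeezes the per-site Pearson dispersions to their trimmed mean
    across sites — all libraries are pools of the same size, so a shared
    dispersion is the natural model and avoids the power loss of noisy
    per-site estimates; "per_site" uses each site's own dispersion with an
    F(1, m-k) reference; "none" disables the adjustment.
    """
    if dispersion_mode not in ("pooled", "per_site", "none"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    S, L = meth.shape
    cols = [np.ones(L), ages - ages.mean()]
    if treatment is not None:
        cols.append(treatment.astype(float))
    X_full = np.column_stack(cols)
    age_col = 1

    y = meth.astype(float)
    n = total.astype(float)
    n_used = (total > 0).sum(axis=1)
    age_ok = np.array([np.unique(ages[total[i] > 0]).size >= 2 for i in range(S)])
    fit_ok = (n_used >= 3) & age_ok

    beta, dev1, cov, conv = _fit_binomial_glm(y, n, X_full)
    # reduced model: drop the age column
    X_red = np.delete(X_full, age_col, axis=1)
    _, dev0, _, conv0 = _fit_binomial_glm(y, n, X_red)

    lrt = np.maximum(dev0 - dev1, 0.0)
    eta = np.clip(beta @ X_full.T, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    phi, m = _pearson_dispersion(y, n, mu, X_full.shape[1])
    se = np.sqrt(np.maximum(cov[:, age_col, age_col], 0.0))
    df_resid = np.maximum(m - X_full.shape[1], 1)

    if dispersion_mode == "none":
        quasi = np.zeros(S, dtype=bool)
        stat = lrt
        p = chi2.sf(stat, 1)
    elif dispersion_mode == "per_site":
        quasi = phi > dispersion_threshold
        stat = np.where(quasi, lrt / np.maximum(phi, 1e-12), lrt)
        p = np.where(quasi, f_dist.sf(stat, 1, df_resid), chi2.sf(stat, 1))
        se = np.where(quasi, se * np.sqrt(np.maximum(phi, 0.0)), se)
    else:  # pooled: common dispersion shared by all sites
        finite = np.isfinite(phi) & conv & fit_ok
        if finite.sum() >= 3:
            vals = np.sort(phi[finite])
            cut = max(1, int(0.1 * len(vals)))
            phi_pool = float(vals[cut:-cut].mean()) if len(vals) > 2 * cut else float(vals.mean())
        else:
            phi_pool = float(np.nanmean(phi)) if np.isfinite(phi).any() else 1.0
        phi_pool = max(phi_pool, 1.0)
        if phi_pool > dispersion_threshold:
            quasi = np.ones(S, dtype=bool)
            stat = lrt / phi_pool
            se = se * np.sqrt(phi_pool)
        else:
            quasi = np.zeros(S, dtype=bool)
            stat = lrt
        p = chi2.sf(stat, 1)
        phi = np.full(S, phi_pool)

    converged = conv & conv0 & fit_ok
    p = np.where(converged, p, np.nan)
    return pd.DataFrame({
        "slope": beta[:, age_col],
        "se": se,
        "stat": stat,
        "p": p,
        "n_used": n_used,
        "converged": converged,
        "quasibinomial": quasi,
        "dispersion": phi,
    })


def fit_age_glm(meth: np.ndarray, total: np.ndarray, ages: np.ndarray,
                dispersion_threshold: float = 1.0,
                dispersion_mode: str = "per_site") -> AgeDmlResult:
    """Fit a single site's binomial GLM of methylation on age.

    Requires >= 3 libraries with coverage and at least two distinct ages
    among them.  A lone site has no cross-site information, so the default
    dispersion adjustment is its own Pearson estimate (F reference).
    """
    meth = np.asarray(meth)
    total = np.asarray(total)
    ages = np.asarray(ages, dtype=float)
    if (total > 0).sum() < 3:
        raise ValueError("need >= 3 libraries with nonzero total")
    if np.unique(ages[total > 0]).size < 2:
        raise ValueError("ages must not all be equal among covered libraries")
    frame = _scan_arrays(meth[None, :], total[None, :], ages,
                         dispersion_threshold=dispersion_threshold,
                         dispersion_mode=dispersion_mode)
    row = frame.iloc[0]
    return AgeDmlResult(site_id="", slope=row["slope"], se=row["se"],
                        stat=row["stat"], p=row["p"], q=np.nan,
                        n_used=int(row["n_used"]), converged=bool(row["converged"]),
                        quasibinomial=bool(row["quasibinomial"]),
                        dispersion=row["dispersion"])


def run_dml_scan(matrix: CpGCountMatrix, sample_sheet: pd.DataFrame,
                 fdr_q: float = 0.05, adjust_treatment: bool = False,
                 treatment_subset: str | None = None,
                 dispersion_threshold: float = 1.0,
                 dispersion_mode: str = "pooled") -> pd.DataFrame:
    """Scan every site for age-related differential methylation.

    Returns a site-indexed frame with slope, se, stat, p, q, n_used, flags and
    a ``significant`` column (q <= fdr_q).  Non-converged or unfittable sites
    get p = q = NaN and are excluded from the BH family (their count is
    logged), never significant.
    """
    if matrix.n_sites == 0:
        return pd.DataFrame(columns=["slope", "se", "stat", "p", "q", "n_used",
                                     "converged", "quasibinomial", "dispersion",
                                     "significant"])
    sheet = sample_sheet.set_index("library_id").loc[matrix.libraries]
    keep = np.ones(len(sheet), dtype=bool)
    if treatment_subset is not None:
        keep = (sheet["treatment"] == treatment_subset).to_numpy()
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 libraries in treatment {treatment_subset!r}")
    ages = sheet["age_days"].to_numpy(dtype=float)[keep]
    treatment = None
    if adjust_treatment and treatment_subset is None:
        labels = pd.unique(sheet["treatment"])
        treatment = (sheet["treatment"].to_numpy() == labels[1]).astype(float)[keep]

    meth = matrix.meth.to_numpy()[:, keep]
    total = matrix.total.to_numpy()[:, keep]
    frame = _scan_arrays(meth, total, ages, treatment=treatment,
                         dispersion_threshold=dispersion_threshold,
                         dispersion_mode=dispersion_mode)
    frame.index = matrix.site_ids

    testable = frame["p"].notna().to_numpy()
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("run_dml_scan: %d sites excluded from the BH family "
                    "(non-converged or unfittable)", n_excluded)
    q = np.full(len(frame), np.nan)
    if testable.any():
        q[testable] = multipletests(frame["p"].to_numpy()[testable], method="fdr_bh")[1]
    frame["q"] = q
    frame["significant"] = testable & (frame["q"].to_numpy() <= fdr_q)
    logger.info("run_dml_scan: %d / %d sites significant at q <= %g",
                int(frame["significant"].sum()), len(frame), fdr_q)
    return frame
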
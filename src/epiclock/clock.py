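"""Elastic-net epigenetic clock: feature filtering, fitting, prediction.

The clock is a sparse linear map from per-CpG methylation proportions to age
in days.  Candidate CpGs (the age-DML set) are first filtered by Pearson
correlation with chronological age in the reference ("control") libraries
(|r| >= r_min, uncorrected two-sided p <= p_max); the surviving features feed
an elastic net (mixing parameter alpha, default 0.5) whose regularisation
strength lambda is chosen by repeated k-fold cross-validation minimising RMSE
over held-out libraries.  Features are standardised internally and the fitted
coefficients are reported back on the original proportion scale, so a stored
model is self-contained.

The penalised objective follows the glmnet convention
    (1/2n) ||y - Xb||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||^2),
which is what sklearn's ElasticNet(alpha=lambda, l1_ratio=alpha) solves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path

logger = logging.getLogger("epiclock")


# ---------------------------------------------------------------------------
# correlation filter

def correlation_filter(proportions: pd.DataFrame, ages: pd.Series,
                       r_min: float = 0.3, p_max: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each site's proportion with age; retain strong sites.

    ``proportions`` is site x library restricted to the reference-group
    libraries; ``ages`` gives each of those libraries' chronological age.
    Returns a site-indexed frame (r, p, n, retained).  Zero-variance sites are
    excluded (r undefined) with a log entry.
    """
    if not (0.0 < r_min < 1.0) or not (0.0 < p_max < 1.0):
        raise ValueError("r_min and p_max must lie in (0, 1)")
    libs = [l for l in proportions.columns if l in ages.index]
    if len(libs) < 3:
        raise ValueError("need >= 3 reference libraries for the correlation filter")
    X = proportions[libs].to_numpy(dtype=float)
    a = ages.loc[libs].to_numpy(dtype=float)

    valid = ~np.isnan(X)
    n = valid.sum(axis=1)
    Xf = np.where(valid, X, 0.0)
    af = np.where(valid, a[None, :], 0.0)
    sx = Xf.sum(axis=1)
    sa = af.sum(axis=1)
    sxx = (Xf ** 2).sum(axis=1)
    saa = (af ** 2).sum(axis=1)
    sxa = (Xf * af).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxa - sx * sa / np.where(n > 0, n, 1)
        vx = sxx - sx ** 2 / np.where(n > 0, n, 1)
        va = saa - sa ** 2 / np.where(n > 0, n, 1)
        r = cov / np.sqrt(vx * va)
    defined = (n >= 3) & (vx > 1e-300) & (va > 0)
    r = np.where(defined, np.clip(r, -1.0, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = np.where(defined, 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)), np.nan)

    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("correlation_filter: %d sites with undefined r excluded", n_undef)
    retained = defined & (np.abs(r) >= r_min) & (p <= p_max)
    return pd.DataFrame({"r": r, "p": p, "n": n, "retained": retained},
                        index=proportions.index)


# ---------------------------------------------------------------------------
# model container

@dataclass
class ClockModel:
    """Sparse linear age predictor on the methylation-proportion scale."""

    intercept: float
    coefficients: dict[str, float]      # site id -> days per unit proportion
    alpha: float                        # elastic-net mixing parameter
    lam: float                          # regularisation strength
    training_libraries: list[str]
    feature_means: dict[str, float]     # training means on the proportion scale
    feature_sds: dict[str, float]
    seed: int = 0
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def panel(self) -> list[str]:
        """Sites with nonzero coefficient, in stored feature order."""
        return [s for s, c in self.coefficients.items() if c != 0.0]

    def to_json(self) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "alpha": self.alpha,
            "lambda": self.lam,
            "training_libraries": self.training_libraries,
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        return cls(intercept=d["intercept"], coefficients=d["coefficients"],
                   alpha=d["alpha"], lam=d["lambda"],
                   training_libraries=d["training_libraries"],
                   feature_means=d["feature_means"], feature_sds=d["feature_sds"],
                   seed=d.get("seed", 0))

    @classmethod
    def load(cls, path: str | Path) -> "ClockModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class ClockValidation:
    """Agreement of predicted with chronological age for one group."""

    group: str
    n: int
    r2: float
    rmse: float
    predictions: pd.DataFrame  # library-indexed: age_days, predicted_age


# ---------------------------------------------------------------------------
# cross-validated fit

def _age_stratified_folds(ages: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign libraries to k folds, spreading each age class across folds."""
    order = []
    for age in np.unique(ages):
        ix = np.flatnonzero(ages == age)
        rng.shuffle(ix)
        order.extend(ix)
    folds = np.empty(len(ages), dtype=int)
    offset = rng.integers(k)
    for rank, ix in enumerate(order):
        folds[ix] = (rank + offset) % k
    return folds


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int,
                 lambda_min_ratio: float) -> np.ndarray:
    if alpha <= 0:
        raise ValueError("automatic lambda grid requires alpha > 0; pass lambda_grid explicitly")
    n = len(y)
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / (n * alpha)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def fit_elastic_net_clock(proportions: pd.DataFrame, ages: pd.Series,
                          alpha: float = 0.5, lambda_grid: np.ndarray | None = None,
                          n_lambda: int = 100, lambda_min_ratio: float = 1e-3,
                          k_folds: int = 10, repeats: int = 3,
                          seed: int = 0) -> tuple[ClockModel, ClockValidation]:
    """Fit the clock on the training (reference-group) libraries.

    ``proportions`` is library x site.  lambda is selected by repeated k-fold
    CV minimising held-out RMSE (ties broken toward the larger, sparser
    lambda); the final model is refit on all training libraries at lambda*.
    The returned validation holds cross-validated predictions (out-of-fold,
    averaged over repeats per library) with their R^2 and RMSE.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    libs = list(proportions.index)
    if proportions.shape[1] < 1:
        raise ValueError("no features available for the clock fit")
    incomplete = proportions.columns[proportions.isna().any(axis=0)]
    if len(incomplete):
        logger.info("fit_elastic_net_clock: dropping %d sites with missing "
                    "proportions", len(incomplete))
        proportions = proportions.drop(columns=incomplete)
        if proportions.shape[1] < 1:
            raise ValueError("no complete features available for the clock fit")
    n = len(libs)
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds the {n} training libraries")
    X = proportions.to_numpy(dtype=float)
    y = ages.loc[libs].to_numpy(dtype=float)
    sites = list(proportions.columns)

    Xs_full, mu_full, sd_full = _standardize(X)
    if lambda_grid is None:
        lambda_grid = _lambda_grid(Xs_full, y, alpha, n_lambda, lambda_min_ratio)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)
    n_lam = len(lambda_grid)

    rng = np.random.default_rng(seed)
    age_arr = ages.loc[libs].to_numpy(dtype=float)
    cv_preds = np.full((repeats, n, n_lam), np.nan)
    for rep in range(repeats):
        for attempt in range(10):
            folds = _age_stratified_folds(age_arr, k_folds, rng)
            ok = all(np.unique(age_arr[folds != f]).size >= 2 for f in range(k_folds))
            if ok:
                break
            logger.info("fit_elastic_net_clock: degenerate fold, refolding (repeat %d)", rep)
        for f in range(k_folds):
            tr = folds != f
            te = ~tr
            Xtr, mu, sd = _standardize(X[tr])
            ytr = y[tr]
            _, coefs, _ = enet_path(Xtr, ytr - ytr.mean(), l1_ratio=alpha,
                                    alphas=lambda_grid, tol=1e-4, max_iter=10000)
            Xte = (X[te] - mu) / sd
            cv_preds[rep, te, :] = Xte @ coefs + ytr.mean()

    sq = (cv_preds - y[None, :, None]) ** 2
    cv_rmse = np.sqrt(np.nanmean(sq, axis=(0, 1)))          # per lambda
    best = cv_rmse.min()
    # ties toward the larger lambda: the grid is descending, take first match
    lam_star = float(lambda_grid[np.flatnonzero(cv_rmse <= best + 1e-12)[0]])

    lam_ix = int(np.flatnonzero(lambda_grid == lam_star)[0])
    per_lib_pred = cv_preds[:, :, lam_ix].mean(axis=0)      # average over repeats

    final = ElasticNet(alpha=lam_star, l1_ratio=alpha, fit_intercept=True,
                       max_iter=100000, tol=1e-10)
    final.fit(Xs_full, y)
    coef_orig = final.coef_ / sd_full
    intercept_orig = float(final.intercept_ - np.sum(final.coef_ * mu_full / sd_full))

    model = ClockModel(
        intercept=intercept_orig,
        coefficients={s: float(c) for s, c in zip(sites, coef_orig)},
        alpha=alpha, lam=lam_star, training_libraries=libs,
        feature_means={s: float(m) for s, m in zip(sites, mu_full)},
        feature_sds={s: float(v) for s, v in zip(sites, sd_full)},
        seed=seed,
        cv_table=pd.DataFrame({"lambda": lambda_grid, "cv_rmse": cv_rmse}),
    )
    pred_frame = pd.DataFrame({"age_days": y, "predicted_age": per_lib_pred},
                              index=pd.Index(libs, name="library_id"))
    validation = validate_clock(pred_frame["predicted_age"],
                                pred_frame["age_days"], group="training")
    logger.info("fit_elastic_net_clock: lambda*=%.5g, panel size %d, CV RMSE %.3f d",
                lam_star, len(model.panel()), validation.rmse)
    return model, validation


def predict_epigenetic_age(model: ClockModel, proportions: pd.DataFrame,
                           impute: str | None = None) -> pd.Series:
    """Predict age (days) for libraries (rows) from panel-site proportions.

    All panel sites must be present with observed (non-missing) proportions;
    with ``impute="mean"`` missing values fall back to the training means
    (logged).
    """
    panel = model.panel()
    if not panel:
        return pd.Series(model.intercept, index=proportions.index, name="predicted_age")
    missing_cols = [s for s in panel if s not in proportions.columns]
    if missing_cols and impute != "mean":
        raise KeyError(f"panel sites missing from input: {missing_cols[:10]}")
    vals = pd.DataFrame(index=proportions.index, columns=panel, dtype=float)
    for s in panel:
        if s in proportions.columns:
            vals[s] = proportions[s]
        else:
            vals[s] = np.nan
    if vals.isna().any().any():
        if impute != "mean":
            bad = vals.columns[vals.isna().any(axis=0)].tolist()
            raise ValueError(f"missing proportions for panel sites: {bad[:10]}; "
                             "pass impute='mean' to use training means")
        n_imp = int(vals.isna().to_numpy().sum())
        logger.info("predict_epigenetic_age: imputing %d missing values with training means", n_imp)
        for s in panel:
            vals[s] = vals[s].fillna(model.feature_means[s])
    coef = np.array([model.coefficients[s] for s in panel])
    pred = model.intercept + vals.to_numpy(dtype=float) @ coef
    return pd.Series(pred, index=proportions.index, name="predicted_age")


def validate_clock(predictions: pd.Series, ages: pd.Series, group: str) -> ClockValidation:
    """R^2 (variance of chronological age explained) and RMSE of predictions."""
    joined = pd.DataFrame({"predicted_age": predictions, "age_days": ages}).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 libraries to validate")
    y = joined["age_days"].to_numpy(dtype=float)
    yhat = joined["predicted_age"].to_numpy(dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in chronological ages")
    ss_res = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return ClockValidation(group=group, n=n, r2=r2, rmse=rmse,
                           predictions=joined[["age_days", "predicted_age"]])
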
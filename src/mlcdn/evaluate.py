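"""Evaluation protocols for ML-CDN models.

Three-fold cross-validation at the cell line-drug *pair* level (two folds
fit the decay parameters, the third is scored), the 16-model CSN x DSN
comparison harness, and the pathway-gene association regression with
Bonferroni correction used to sanity-check predicted responses against
target-pathway expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import FeatureMatrix, ResponseMatrix
from .model import DecayParams, grid_search, predict_loo
from .similarity import SimilarityNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_and_rmse",
    "CVReport",
    "threefold_cv",
    "model_grid",
    "AssociationReport",
    "association_regression",
    "group_ttest",
    "group_anova",
]


def pearson_and_rmse(observed, predicted) -> tuple[float, float]:
    """Pearson correlation and root-mean-squared error between two vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if obs.size < 3:
        raise ValueError(f"need at least 3 values, got {obs.size}")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("inputs must be finite")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("Pearson correlation undefined: zero variance input")
    r = float(scipy.stats.pearsonr(obs, pred).statistic)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return r, rmse


@dataclass
class FoldResult:
    fold: int
    params: DecayParams
    pearson_r: float
    rmse: float
    n_test: int


@dataclass
class CVReport:
    """Pair-level cross-validation report: fold assignment for every
    observed pair, per-fold metrics and fitted decay parameters, and pooled
    metrics over the union of held-out predictions."""

    fold_assignments: dict
    per_fold: list[FoldResult]
    pooled_pearson_r: float
    pooled_rmse: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": f.fold,
                "sigma": f.params.sigma,
                "tau": f.params.tau,
                "pearson_r": f.pearson_r,
                "rmse": f.rmse,
                "n_test": f.n_test,
            }
            for f in self.per_fold
        ]
        rows.append(
            {
                "fold": "pooled",
                "sigma": np.nan,
                "tau": np.nan,
                "pearson_r": self.pooled_pearson_r,
                "rmse": self.pooled_rmse,
                "n_test": sum(f.n_test for f in self.per_fold),
            }
        )
        return pd.DataFrame(rows)


def threefold_cv(
    response: ResponseMatrix,
    csn: SimilarityNetwork,
    dsn: SimilarityNetwork,
    seed: int,
    n_folds: int = 3,
    grid_step: float = 0.01,
) -> CVReport:
    """Cross-validate an ML-CDN by splitting the observed pairs into folds.

    Observed pairs are shuffled with ``seed`` and partitioned into
    ``n_folds`` near-equal folds (remainders go to the earliest folds).
    For each fold, the decay parameters are fitted by grid search on the
    remaining pairs and the held-out pairs are predicted with the training
    observations only, then scored; pooled metrics use all held-out
    predictions together.
    """
    mask = response.observed_mask.to_numpy()
    pairs = np.argwhere(mask)
    if len(pairs) < 3 * n_folds:
        raise ValueError(f"need at least {3 * n_folds} observed pairs, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    folds = np.array_split(perm, n_folds)

    cells, drugs = response.cell_ids, response.drug_ids
    fold_assignments = {}
    for f, idx in enumerate(folds):
        if idx.size == 0:
            raise ValueError("empty test fold")
        for k in idx:
            i, j = pairs[k]
            fold_assignments[(cells[i], drugs[j])] = f

    values = response.values.to_numpy()
    per_fold: list[FoldResult] = []
    pooled_obs, pooled_pred = [], []
    for f, idx in enumerate(folds):
        test = pairs[idx]
        train_values = values.copy()
        train_values[test[:, 0], test[:, 1]] = np.nan
        train_resp = ResponseMatrix(
            pd.DataFrame(train_values, index=cells, columns=drugs),
            normalization_meta=response.normalization_meta,
        )
        gs = grid_search(train_resp, csn, dsn, grid_step=grid_step)
        pred = predict_loo(train_resp, csn, dsn, gs.best)
        pred_arr = pred.values.to_numpy()
        obs_v = values[test[:, 0], test[:, 1]]
        pred_v = pred_arr[test[:, 0], test[:, 1]]
        try:
            r, rmse = pearson_and_rmse(obs_v, pred_v)
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from exc
        per_fold.append(FoldResult(f, gs.best, r, rmse, len(test)))
        pooled_obs.append(obs_v)
        pooled_pred.append(pred_v)

    r_pool, rmse_pool = pearson_and_rmse(np.concatenate(pooled_obs), np.concatenate(pooled_pred))
    return CVReport(fold_assignments, per_fold, r_pool, rmse_pool, seed)


def model_grid(
    response: ResponseMatrix,
    csns: list[SimilarityNetwork],
    dsns: list[SimilarityNetwork],
    protocol: str = "threefold",
    seed: int = 0,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Score every CSN x DSN combination (16 rows for 4 + 4 networks).

    ``protocol='threefold'`` reports pooled cross-validated metrics;
    ``protocol='full_fit'`` fits on all observed pairs and scores the
    in-sample leave-target-out predictions.  Rows are stably sorted by
    (csn_label, dsn_label).
    """
    if protocol not in ("threefold", "full_fit"):
        raise ValueError("protocol must be 'threefold' or 'full_fit'")
    rows = []
    for csn in csns:
        for dsn in dsns:
            if protocol == "threefold":
                report = threefold_cv(response, csn, dsn, seed=seed, grid_step=grid_step)
                r, rmse = report.pooled_pearson_r, report.pooled_rmse
            else:
                gs = grid_search(response, csn, dsn, grid_step=grid_step)
                pred = predict_loo(response, csn, dsn, gs.best)
                mask = response.observed_mask.to_numpy()
                r, rmse = pearson_and_rmse(
                    response.values.to_numpy()[mask], pred.values.to_numpy()[mask]
                )
            rows.append(
                {"csn_label": csn.layer_label, "dsn_label": dsn.layer_label, "rmse": rmse, "pearson_r": r}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["csn_label", "dsn_label"], kind="stable", ignore_index=True)


@dataclass
class AssociationReport:
    """Per-gene association between a predicted drug response and the
    expression of one pathway's genes, from one multiple OLS regression."""

    table: pd.DataFrame  # gene, coef, p_raw, p_adj, significant
    n_samples: int
    n_predictors: int
    alpha: float
    bonferroni_factor: int


def association_regression(
    predicted_ic50,
    expression: FeatureMatrix,
    alpha: float = 0.05,
) -> AssociationReport:
    """Regress a predicted per-sample drug response on pathway-gene
    expression (one multiple OLS fit with intercept).

    Per-gene p-values come from coefficient t-tests; the Bonferroni factor
    is the number of gene predictors in this regression, and genes are
    flagged significant when the adjusted p-value is below ``alpha``.
    """
    y = np.asarray(predicted_ic50, dtype=float)
    X = expression.values
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"response length {y.shape} does not match {n} samples")
    if not (np.isfinite(y).all() and np.isfinite(X.to_numpy()).all()):
        raise ValueError("missing values in regression inputs")
    if n <= p + 1:
        raise ValueError(
            f"need more samples than predictors plus intercept ({n} samples, {p} genes); "
            "filter the gene set first"
        )
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < p + 1:
        _, R = np.linalg.qr(design.to_numpy())
        diag = np.abs(np.diag(R))
        dep = diag < diag.max() * 1e-10
        bad = [c for c, flag in zip(design.columns, dep) if flag and c != "const"]
        raise ValueError(f"rank-deficient design; collinear genes: {bad}")
    fit = sm.OLS(y, design).fit()
    genes = list(X.columns)
    raw = fit.pvalues[genes].to_numpy()
    adj = np.minimum(1.0, raw * p)
    table = pd.DataFrame(
        {
            "gene": genes,
            "coef": fit.params[genes].to_numpy(),
            "p_raw": raw,
            "p_adj": adj,
            "significant": adj < alpha,
        }
    )
    return AssociationReport(table, n, p, alpha, p)


# thin wrappers for responder / receptor-status group comparisons


def group_ttest(a, b) -> tuple[float, float]:
    """Two-tailed Welch-free two-sample t-test (equal variance, as in the
    classic responder vs non-responder comparison)."""
    res = scipy.stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def group_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA across groups (e.g. receptor-status strata)."""
    res = scipy.stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)
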
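"""Cross-validated random-forest prediction power with permutation nulls.

Each host factor (or ome variable) is regressed on the transformed taxon
matrix with a k-fold random forest; performance is the Spearman correlation
between measurement and out-of-fold prediction. Significance comes from a
one-sided add-one permutation test (targets permuted, the full
cross-validation recomputed each time), with BH adjustment across the factor
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from crowdome.stats import bh_adjust

logger = logging.getLogger(__name__)

#: trees per forest; mirrors the reference implementation's regression default
DEFAULT_N_TREES = 500


@dataclass
class ImportanceResult:
    """Prediction power of the feature block for one factor."""

    factor: str
    rho: float
    p_perm: float = np.nan
    q: float = np.nan
    n_perm: int = 0
    k_folds: int = 5
    seed: int = 0


def _mtry(n_features: int) -> int:
    # regression default of the classic randomForest: floor(p / 3), min 1
    return max(1, n_features // 3)


def _as_xy(features, target):
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = target.to_numpy(dtype=float) if isinstance(target, pd.Series) else np.asarray(target, dtype=float)
    keep = ~np.isnan(y)
    if not keep.all():
        logger.info("dropping %d samples with missing target", int((~keep).sum()))
        X, y = X[keep], y[keep]
    return X, y


def _oof_predictions(X, y, k_folds, seed, n_trees):
    folds = list(KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(X))
    mtry = _mtry(X.shape[1])
    pred = np.empty_like(y)
    for i, (train, test) in enumerate(folds):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, random_state=seed + i, n_jobs=1
        )
        rf.fit(X[train], y[train])
        pred[test] = rf.predict(X[test])
    return pred, folds


def _cv_rho(X, y, folds, seed, n_trees):
    mtry = _mtry(X.shape[1])
    pred = np.empty_like(y)
    for i, (train, test) in enumerate(folds):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, random_state=seed + i, n_jobs=1
        )
        rf.fit(X[train], y[train])
        pred[test] = rf.predict(X[test])
    return float(spearmanr(y, pred).statistic)


def rfcv_performance(
    features,
    target,
    k_folds: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> float:
    """Spearman rho between a target and its out-of-fold RF predictions."""
    X, y = _as_xy(features, target)
    if len(y) < 2 * k_folds and k_folds != len(y):
        raise ValueError("need at least 2*k_folds complete samples")
    if np.ptp(y) == 0:
        raise ValueError("constant target: Spearman rho undefined")
    pred, _ = _oof_predictions(X, y, k_folds, seed, n_trees)
    return float(spearmanr(y, pred).statistic)


def permutation_test(
    features,
    target,
    n_perm: int = 999,
    k_folds: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    factor: str = "",
) -> ImportanceResult:
    """One-sided permutation P for the RF-CV prediction power.

    The observed fold partition is reused for every permutation, so label
    permutation is the only source of variation. The add-one estimator gives
    ``p = (1 + #{rho_perm >= rho_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = _as_xy(features, target)
    if np.ptp(y) == 0:
        raise ValueError("constant target: Spearman rho undefined")
    pred, folds = _oof_predictions(X, y, k_folds, seed, n_trees)
    rho_obs = float(spearmanr(y, pred).statistic)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if _cv_rho(X, y_perm, folds, seed, n_trees) >= rho_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    name = factor or (target.name if isinstance(target, pd.Series) else "")
    return ImportanceResult(
        factor=str(name), rho=rho_obs, p_perm=p, n_perm=n_perm, k_folds=k_folds, seed=seed
    )


def rank_factor_importance(results: list[ImportanceResult]) -> list[ImportanceResult]:
    """BH-adjust the permutation P values and sort by rho descending."""
    if not results:
        raise ValueError("empty result list")
    qs = bh_adjust([r.p_perm for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return sorted(results, key=lambda r: -r.rho)


def results_frame(results: list[ImportanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": r.factor,
                "rho": r.rho,
                "p_perm": r.p_perm,
                "q": r.q,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for r in results
        ]
    )
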
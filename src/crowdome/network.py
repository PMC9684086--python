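"""Three-learner consensus association network with two-cohort replication.

Stage 1 preprocesses metadata (coding, missingness, outlier masking, median
imputation, near-zero-variance removal) and abundances (prevalence filter +
arcsine-sqrt). Stage 2 scores each (target, predictor) pair with Spearman
correlation, cross-validated random-forest importance, and bootstrapped
lasso coefficients. Stage 3 keeps, per target, the predictors with the
smallest average rank across the three methods, gated by Spearman Q;
replication across cohorts combines P values by the Edgington method and
requires sign agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from crowdome.io import AbundanceTable, MetadataTable, arcsine_sqrt, prevalence_filter
from crowdome.stats import bh_adjust, edgington_combine

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusConfig",
    "preprocess",
    "spearman_edges",
    "rf_edge_scores",
    "lasso_edge_scores",
    "consensus_edges",
    "build_network",
    "replicate_edges",
    "export_network",
]


@dataclass
class ConsensusConfig:
    top_k: int = 5
    q_max: float = 0.1
    n_boot: int = 100
    missing_sample_max: float = 0.70
    prevalence_min: float = 0.10
    central_interval: float = 0.95
    k_folds: int = 5
    rf_trees: int = 500
    nzv_eps: float = 1e-12
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _code_metadata(meta: MetadataTable) -> pd.DataFrame:
    """Dummy-code nominal columns, rank-code ordinal, pass the rest through."""
    cols = {}
    for name in meta.data.columns:
        kind = meta.kinds[name]
        col = meta.data[name]
        if kind == "nominal":
            for cat in sorted(col.dropna().unique()):
                dummy = (col == cat).astype(float)
                dummy[col.isna()] = np.nan
                cols[f"{name}={cat}"] = dummy
        elif kind == "ordinal":
            cats = sorted(col.dropna().unique())
            mapping = {c: i for i, c in enumerate(cats)}
            cols[name] = col.map(mapping).astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=meta.data.index)


def preprocess(meta: MetadataTable, abund: AbundanceTable, config: ConsensusConfig):
    """Stage-1 preprocessing; returns (coded metadata, transformed taxa, log).

    Order of operations: drop samples above the missingness cap, code
    variables, mask values outside the central percentile interval of each
    continuous variable, median-impute what remains, drop near-zero-variance
    columns; prevalence-filter the taxa and arcsine-sqrt transform them. A
    z-scored copy of the coded metadata is used by the lasso learner only
    (standardization happens inside :func:`lasso_edge_scores`).
    """
    log = {}
    frac_missing = meta.data.isna().mean(axis=1) if len(meta.data.columns) else pd.Series(0.0, index=meta.data.index)
    keep = frac_missing <= config.missing_sample_max
    log["samples_dropped_missing"] = sorted(meta.data.index[~keep])
    if not keep.any():
        raise ValueError("all samples dropped by the missingness cap")
    meta_kept = MetadataTable(meta.data.loc[keep], meta.kinds)
    coded = _code_metadata(meta_kept)

    lo = (1 - config.central_interval) / 2 * 100
    hi = 100 - lo
    n_masked = 0
    for name in coded.columns if config.central_interval < 1.0 else []:
        base = name.split("=")[0]
        if meta.kinds.get(base, meta.kinds.get(name)) != "continuous":
            continue
        col = coded[name]
        vals = col.dropna()
        if vals.empty:
            continue
        lo_v, hi_v = np.percentile(vals, [lo, hi])
        outlier = (col < lo_v) | (col > hi_v)
        n_masked += int(outlier.sum())
        coded.loc[outlier, name] = np.nan
    log["outliers_masked"] = n_masked

    coded = coded.fillna(coded.median(numeric_only=True))

    variances = coded.var(ddof=0)
    nzv = [c for c in coded.columns if not np.isfinite(variances[c]) or variances[c] <= config.nzv_eps]
    log["near_zero_variance_dropped"] = nzv
    coded = coded.drop(columns=nzv)

    filtered = prevalence_filter(
        AbundanceTable(abund.data.loc[coded.index], abund.lineages), config.prevalence_min
    )
    transformed = arcsine_sqrt(filtered.data)
    log["taxa_retained"] = list(transformed.columns)
    return coded, transformed, log


def spearman_edges(A: pd.DataFrame, B: pd.DataFrame, min_pairs: int = 4) -> pd.DataFrame:
    """Pairwise Spearman rho/p/q over the full A-columns x B-columns grid.

    Cells with fewer than ``min_pairs`` complete observations are NA. Q is
    BH across the entire grid.
    """
    records = []
    for a in A.columns:
        xa = A[a].to_numpy(dtype=float)
        for b in B.columns:
            yb = B[b].to_numpy(dtype=float)
            ok = ~(np.isnan(xa) | np.isnan(yb))
            if ok.sum() < min_pairs:
                records.append((a, b, np.nan, np.nan))
                continue
            res = spearmanr(xa[ok], yb[ok])
            records.append((a, b, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(records, columns=["target", "predictor", "rho", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def rf_edge_scores(features: pd.DataFrame, target, config: ConsensusConfig, seed: int = 0) -> pd.Series:
    """Impurity importances averaged over the k fold-wise random-forest fits."""
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    mtry = max(1, X.shape[1] // 3)
    folds = KFold(n_splits=config.k_folds, shuffle=True, random_state=seed).split(X)
    imp = np.zeros(X.shape[1])
    for i, (train, _) in enumerate(folds):
        rf = RandomForestRegressor(
            n_estimators=config.rf_trees, max_features=mtry, random_state=seed + i, n_jobs=1
        )
        rf.fit(X[train], y[train])
        imp += rf.feature_importances_
    return pd.Series(imp / config.k_folds, index=features.columns)


def lasso_edge_scores(
    features: pd.DataFrame, target, config: ConsensusConfig, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap-aggregated |lasso coefficient| per predictor.

    Lambda is chosen once by k-fold cross-validation on the full data, then
    frozen across ``n_boot`` bootstrap fits, each on a without-replacement
    resample of ceil(0.632 * n) distinct samples. Features are z-scored
    internally. Returns columns ``score`` (mean |coef| across bootstraps,
    the ranking default), ``score_median`` (median |coef|), and ``freq``
    (nonzero frequency).
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    n = len(y)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    cv = KFold(n_splits=config.k_folds, shuffle=True, random_state=seed)
    lcv = LassoCV(cv=cv, random_state=seed, alphas=50, max_iter=5000)
    with np.errstate(all="ignore"):
        lcv.fit(Xz, y)
    lam = float(lcv.alpha_)

    rng = np.random.default_rng(seed)
    m = int(np.ceil(0.632 * n))
    coefs = np.zeros((config.n_boot, X.shape[1]))
    for b in range(config.n_boot):
        idx = rng.choice(n, size=m, replace=False)
        model = Lasso(alpha=lam, max_iter=5000)
        with np.errstate(all="ignore"):
            model.fit(Xz[idx], y[idx])
        coefs[b] = model.coef_
    score = np.abs(coefs).mean(axis=0)
    if not score.any():
        logger.warning("lasso path degenerate: all bootstrap coefficients zero")
    return pd.DataFrame(
        {
            "score": score,
            "score_median": np.median(np.abs(coefs), axis=0),
            "freq": (coefs != 0).mean(axis=0),
        },
        index=features.columns,
    )


def _avg_ranks(scores: list[np.ndarray]) -> np.ndarray:
    """Average of per-method descending ranks (1 = strongest, ties averaged)."""
    ranks = [rankdata(-s, method="average") for s in scores]
    return np.mean(ranks, axis=0)


def consensus_edges(
    spearman: pd.DataFrame,
    rf_scores: dict,
    lasso_scores: dict,
    config: ConsensusConfig,
) -> pd.DataFrame:
    """Average-rank consensus over the three learners, Q-gated.

    Per target, each method ranks predictors descending by score; the
    ``top_k`` predictors with the smallest average rank are retained, and
    retained edges additionally require Spearman ``q < q_max``. Sign comes
    from the Spearman rho.
    """
    rows = []
    for target, grp in spearman.groupby("target", sort=False):
        preds = grp["predictor"].to_numpy()
        sp_score = np.abs(grp["rho"].to_numpy(dtype=float))
        methods = [np.nan_to_num(sp_score)]
        for scores, label in ((rf_scores, "rf"), (lasso_scores, "lasso")):
            ser = scores.get(target)
            if ser is None:
                logger.warning("no %s scores for target %s", label, target)
                continue
            if isinstance(ser, pd.DataFrame):
                ser = ser["score"]
            methods.append(ser.reindex(preds).to_numpy(dtype=float))
        avg_rank = _avg_ranks(methods)
        order = np.argsort(avg_rank, kind="mergesort")[: config.top_k]
        for i in order:
            q = grp["q"].iloc[i]
            if not np.isfinite(q) or q >= config.q_max:
                continue
            rho = float(grp["rho"].iloc[i])
            rows.append(
                {
                    "target": target,
                    "predictor": preds[i],
                    "avg_rank": float(avg_rank[i]),
                    "rho": rho,
                    "p": float(grp["p"].iloc[i]),
                    "q": float(q),
                    "sign": "+" if rho >= 0 else "-",
                }
            )
    return pd.DataFrame(
        rows, columns=["target", "predictor", "avg_rank", "rho", "p", "q", "sign"]
    )


def build_network(
    coded: pd.DataFrame,
    transformed: pd.DataFrame,
    config: ConsensusConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run stages 2-3 with metadata variables as targets, taxa as predictors.

    Returns the consensus edge table and a manifest with edge counts.
    """
    sp = spearman_edges(coded, transformed)
    rf = {}
    lasso = {}
    for j, target in enumerate(coded.columns):
        y = coded[target].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        rf[target] = rf_edge_scores(transformed, y, config, seed=seed + j)
        lasso[target] = lasso_edge_scores(transformed, y, config, seed=seed + j)
    edges = consensus_edges(sp, rf, lasso, config)
    manifest = {
        "associations_examined": int(len(sp)),
        "edges_retained": int(len(edges)),
        "seed": seed,
    }
    return edges, manifest


def replicate_edges(
    edges1: pd.DataFrame, edges2: pd.DataFrame, config: ConsensusConfig
) -> pd.DataFrame:
    """Cross-cohort replication of consensus edges.

    For (target, predictor) pairs retained in both cohorts: Edgington-
    combined P, BH across the shared family, and a sign-agreement gate.
    ``replicated`` requires ``q_combined < q_max`` and matching signs.
    """
    if edges1.empty or edges2.empty:
        return pd.DataFrame(
            columns=[
                "target", "predictor", "p_cohort1", "p_cohort2",
                "p_combined", "q_combined", "sign_agreement", "replicated",
            ]
        )
    merged = edges1.merge(
        edges2, on=["target", "predictor"], suffixes=("_1", "_2"), how="inner"
    )
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "target", "predictor", "p_cohort1", "p_cohort2",
                "p_combined", "q_combined", "sign_agreement", "replicated",
            ]
        )
    p_comb = [
        edgington_combine(min(p1, 1.0), min(p2, 1.0))
        for p1, p2 in zip(merged["p_1"], merged["p_2"])
    ]
    out = pd.DataFrame(
        {
            "target": merged["target"],
            "predictor": merged["predictor"],
            "p_cohort1": merged["p_1"],
            "p_cohort2": merged["p_2"],
            "p_combined": p_comb,
            "sign_agreement": merged["sign_1"] == merged["sign_2"],
        }
    )
    out["q_combined"] = bh_adjust(out["p_combined"].to_numpy())
    out["replicated"] = (out["q_combined"] < config.q_max) & out["sign_agreement"]
    return out


def export_network(edges: pd.DataFrame, graphml_path=None, tsv_path=None) -> nx.Graph:
    """Write the consensus edges as GraphML and/or edge-list TSV.

    Edge colors follow the sign convention: cyan for positive, red for
    negative associations.
    """
    G = nx.Graph()
    for _, row in edges.iterrows():
        G.add_node(str(row["target"]), kind="target")
        G.add_node(str(row["predictor"]), kind="predictor")
        G.add_edge(
            str(row["target"]),
            str(row["predictor"]),
            avg_rank=float(row["avg_rank"]),
            rho=float(row["rho"]),
            q=float(row["q"]),
            sign=str(row["sign"]),
            color="cyan" if row["sign"] == "+" else "red",
        )
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    if tsv_path is not None:
        edges.to_csv(tsv_path, sep="\t", index=False)
    return G
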
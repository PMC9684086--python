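"""Redundancy analysis with forward selection of predictors.

RDA here is multivariate least squares of a (column-centered) response
matrix on a predictor matrix; R-squared is the share of total response
variance captured by the fitted values, adjusted by the Ezekiel correction.
Forward selection greedily adds the candidate maximizing added R-squared,
testing each addition by a Freedman-Lane permutation of reduced-model
residuals, and stops on the double rule: permutation P >= alpha, or
cumulative adjusted R-squared exceeding the all-candidates global value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RdaFit", "ForwardSelResult", "rda_fit", "forward_select"]


@dataclass
class RdaFit:
    r2: float
    adj_r2: float
    n: int
    m: int
    dropped_collinear: list = field(default_factory=list)


@dataclass
class ForwardSelResult:
    selected: list
    added_r2: list
    cum_adj_r2: list
    step_p: list
    stop_reason: str
    global_adj_r2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.selected) + 1),
                "predictor": self.selected,
                "added_r2": self.added_r2,
                "cum_adj_r2": self.cum_adj_r2,
                "p": self.step_p,
            }
        )


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _drop_collinear(X: np.ndarray, names):
    """Greedily drop columns that do not increase the rank of centered X."""
    Xc = _center(X)
    keep, dropped = [], []
    rank = 0
    for j in range(Xc.shape[1]):
        trial = Xc[:, keep + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j] if names is not None else j)
    return keep, dropped


def _r2(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Fraction of total variance of Yc captured by projection onto Xc."""
    sst = float((Yc**2).sum())
    if sst <= 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    return float((fitted**2).sum()) / sst


def ezekiel_adjust(r2: float, n: int, m: int) -> float:
    """Ezekiel-adjusted R-squared: 1 - (1 - R2)(n - 1)/(n - m - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _coerce(mat):
    if isinstance(mat, (pd.DataFrame, pd.Series)):
        names = list(mat.columns) if isinstance(mat, pd.DataFrame) else [mat.name]
        arr = mat.to_numpy(dtype=float)
    else:
        arr = np.asarray(mat, dtype=float)
        names = None
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, names


def rda_fit(Y, X) -> RdaFit:
    """Fit the redundancy analysis of response matrix Y on predictors X.

    Both matrices are column-centered. Collinear predictor columns are
    dropped with a warning; ``m`` counts the retained columns.
    """
    Ya, _ = _coerce(Y)
    Xa, xnames = _coerce(X)
    if Ya.shape[0] != Xa.shape[0]:
        raise ValueError("Y and X must be row-aligned")
    if np.isnan(Ya).any() or np.isnan(Xa).any():
        raise ValueError("rda_fit requires complete data")
    n = Ya.shape[0]

    keep, dropped = _drop_collinear(Xa, xnames)
    if dropped:
        logger.warning("dropping collinear predictor columns: %s", dropped)
    m = len(keep)
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    r2 = _r2(_center(Ya), _center(Xa[:, keep]))
    return RdaFit(r2=r2, adj_r2=ezekiel_adjust(r2, n, m), n=n, m=m, dropped_collinear=dropped)


def forward_select(
    Y,
    candidates,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> ForwardSelResult:
    """Forward selection of RDA predictors with double stopping.

    At each step the candidate with the largest added R-squared is tested by
    a Freedman-Lane permutation: residuals of Y under the already-selected
    model are permuted, re-added to the reduced-model fit, and the added
    R-squared recomputed; P is the one-sided add-one estimate. Selection
    stops when P >= alpha, when the cumulative adjusted R-squared would
    exceed the global (all-candidates) adjusted R-squared, or when the
    candidates are exhausted.
    """
    Ya, _ = _coerce(Y)
    Xa, xnames = _coerce(candidates)
    if xnames is None:
        xnames = [f"x{j}" for j in range(Xa.shape[1])]
    n = Ya.shape[0]
    rng = np.random.default_rng(seed)

    result = ForwardSelResult([], [], [], [], "exhausted", np.nan)
    if Xa.shape[1] == 0:
        return result

    global_fit = rda_fit(Ya, Xa)
    result.global_adj_r2 = global_fit.adj_r2

    Yc = _center(Ya)
    remaining = list(range(Xa.shape[1]))
    selected: list[int] = []
    r2_sel = 0.0

    while remaining:
        Xsel = _center(Xa[:, selected]) if selected else np.empty((n, 0))

        def added_r2(Ymat, j):
            Xj = _center(Xa[:, selected + [j]])
            return _r2(Ymat, Xj) - (_r2(Ymat, Xsel) if selected else 0.0)

        gains = [added_r2(Yc, j) for j in remaining]
        best_pos = int(np.argmax(gains))
        best_j = remaining[best_pos]
        gain = gains[best_pos]

        # Freedman-Lane: permute reduced-model residuals
        if selected:
            coef, *_ = np.linalg.lstsq(Xsel, Yc, rcond=None)
            fitted = Xsel @ coef
            resid = Yc - fitted
        else:
            fitted = np.zeros_like(Yc)
            resid = Yc
        exceed = 0
        for _ in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            Yp = Yp - Yp.mean(axis=0, keepdims=True)
            if added_r2(Yp, best_j) >= gain:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)

        cum_adj = ezekiel_adjust(r2_sel + gain, n, len(selected) + 1)
        if cum_adj > result.global_adj_r2 + 1e-9:
            result.stop_reason = "global_adjR2"
            break
        if p >= alpha:
            result.stop_reason = "alpha"
            break

        selected.append(best_j)
        remaining.remove(best_j)
        r2_sel += gain
        result.selected.append(xnames[best_j])
        result.added_r2.append(gain)
        result.cum_adj_r2.append(cum_adj)
        result.step_p.append(p)
    else:
        result.stop_reason = "exhausted"

    return result
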
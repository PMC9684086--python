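"""Shared statistical primitives.

Benjamini-Hochberg step-up adjustment, the two-study Edgington (sum of
uniforms) P-value combination, and Fisher's exact test with the conditional
maximum-likelihood odds ratio for 2x2 co-occurrence tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy.optimize import brentq

__all__ = ["bh_adjust", "edgington_combine", "FisherResult", "fisher_cooccurrence"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (Q values).

    Parameters
    ----------
    pvalues : array-like
        Raw P values in [0, 1]. NaNs propagate and do not count toward the
        family size.

    Returns
    -------
    numpy.ndarray
        Q values in the input order, each capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    m = int(mask.sum())
    q = np.full(flat.shape, np.nan)
    if m == 0:
        return q.reshape(p.shape)
    pv = flat[mask]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest P downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q.reshape(p.shape)


def edgington_combine(p1: float, p2: float) -> float:
    """Combine two P values by the Edgington (sum of uniforms) method.

    With ``s = p1 + p2`` the combined P is the Irwin-Hall CDF of the sum of
    two independent uniforms: ``s**2 / 2`` for ``s <= 1`` and
    ``1 - (2 - s)**2 / 2`` otherwise.
    """
    p1 = float(p1)
    p2 = float(p2)
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("P values must lie in [0, 1]")
    s = p1 + p2
    if s <= 1.0:
        return s * s / 2.0
    return 1.0 - (2.0 - s) ** 2 / 2.0


@dataclass
class FisherResult:
    """Outcome of a 2x2 Fisher exact co-occurrence test.

    Attributes
    ----------
    table : numpy.ndarray
        The 2x2 count table ``[[n11, n10], [n01, n00]]``.
    odds_ratio : float
        Conditional maximum-likelihood odds ratio (may be ``inf`` or 0 for
        boundary tables, NaN when the margins are degenerate).
    odds_ratio_sample : float
        The unconditional cross-product ratio ``n11*n00 / (n10*n01)``.
    p_two_sided : float
        Two-sided P by summing hypergeometric probabilities not exceeding
        the observed table's probability.
    degenerate : bool
        True when a margin is zero, in which case P = 1 and the odds ratio
        is undefined (NaN).
    """

    table: np.ndarray
    odds_ratio: float
    odds_ratio_sample: float
    p_two_sided: float
    degenerate: bool = False


def _log_hyper_weights(r1: int, r2: int, c1: int):
    """Support and log weights C(r1, x) * C(r2, c1 - x) of the 2x2 table."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)

    def logc(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    logw = np.array([logc(r1, x) + logc(r2, c1 - x) for x in xs])
    return xs, logw


def _cond_mle_or(a: int, xs: np.ndarray, logw: np.ndarray) -> float:
    """Conditional MLE of the odds ratio: solves E[X; psi] = a on the support."""
    if a == xs[0]:
        return 0.0 if len(xs) > 1 else np.nan
    if a == xs[-1]:
        return np.inf if len(xs) > 1 else np.nan

    def mean_minus_a(log_psi):
        logp = logw + xs * log_psi
        logp -= logp.max()
        w = np.exp(logp)
        return float(np.dot(xs, w) / w.sum()) - a

    lo, hi = -1.0, 1.0
    while mean_minus_a(lo) > 0:
        lo *= 2
        if lo < -500:
            return 0.0
    while mean_minus_a(hi) < 0:
        hi *= 2
        if hi > 500:
            return np.inf
    log_psi = brentq(mean_minus_a, lo, hi, xtol=1e-12)
    return float(np.exp(log_psi))


def fisher_exact_2x2(table) -> FisherResult:
    """Fisher's exact test on a 2x2 table with conditional-MLE odds ratio.

    The two-sided P sums the central hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed one (with a 1 + 1e-7 relative slack, as R's ``fisher.test``).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    if r1 == 0 or r2 == 0 or c1 == 0 or int(t[:, 1].sum()) == 0:
        return FisherResult(t, np.nan, np.nan, 1.0, degenerate=True)

    xs, logw = _log_hyper_weights(r1, r2, c1)
    logw_norm = logw - logw.max()
    w = np.exp(logw_norm)
    probs = w / w.sum()
    p_obs = probs[a - xs[0]]
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        cross = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]) if t[0, 1] * t[1, 0] else np.inf
    return FisherResult(t, _cond_mle_or(a, xs, logw), float(cross), p)


def fisher_cooccurrence(pres_a, pres_b) -> FisherResult:
    """Fisher exact test of co-occurrence between two presence/absence vectors.

    Builds the 2x2 table [[both, a only], [b only, neither]] and delegates to
    :func:`fisher_exact_2x2`.
    """
    a = np.asarray(pres_a)
    b = np.asarray(pres_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("presence vectors must be equal-length 1-D arrays")
    if np.isnan(a.astype(float)).any() or np.isnan(b.astype(float)).any():
        raise ValueError("presence vectors must not contain missing values")
    a = a.astype(bool)
    b = b.astype(bool)
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    return fisher_exact_2x2(table)
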
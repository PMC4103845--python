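"""Storey q-value false-discovery-rate control.

The q-value of a test is the minimum FDR at which it would be called
significant.  Storey's estimator scales the Benjamini–Hochberg quantity by
an estimate of the proportion of true nulls,

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)),

smoothed over a grid of lambda and evaluated at the largest grid point; the
q-values are then the running minimum of ``pi0 * m * p_(j) / j`` from the
largest p downward.  With ``pi0 = 1`` the q-values coincide exactly with
Benjamini–Hochberg adjusted p-values.

The smoother here is a degree-3 least-squares polynomial in lambda; at the
table sizes this package targets (tens of tests) the difference from spline
smoothing is negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("famassoc")

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)
_MIN_M_FOR_SMOOTHING = 10
_PI0_FLOOR = 1e-8


def estimate_pi0(
    pvals: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> float:
    """Smoothed estimate of the null proportion pi0, clamped to (0, 1].

    Fewer than 10 p-values fall back to the conservative pi0 = 1.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < _MIN_M_FOR_SMOOTHING:
        return 1.0
    lam = np.asarray(lambda_grid, dtype=float)
    raw = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coefs = np.polyfit(lam, raw, deg=3)
    pi0 = float(np.polyval(coefs, lam.max()))
    if pi0 <= 0:
        logger.warning("pi0 estimate %.3g <= 0; clamping to %g", pi0, _PI0_FLOOR)
        pi0 = _PI0_FLOOR
    return min(pi0, 1.0)


@dataclass
class QvalueResult:
    pvals: np.ndarray
    pi0: float
    lambda_grid: np.ndarray
    qvalues: np.ndarray


def qvalues(pvals: np.ndarray, pi0: float | None = None,
            lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> QvalueResult:
    """q-values in the input order.

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` on the sorted scale, with
    ties broken stably so equal p-values keep their original relative
    order.  ``pi0 = None`` triggers :func:`estimate_pi0`.
    """
    p = np.asarray(pvals, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QvalueResult(pvals=p, pi0=pi0, lambda_grid=np.asarray(lambda_grid), qvalues=q)


def add_qvalues(
    table: pd.DataFrame,
    p_col: str = "p",
    by: str | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Append ``q`` and ``significant`` columns to a p-value table.

    ``by`` groups the correction (e.g. per trait); rows with missing p get
    missing q.  The significance flag marks q below ``threshold``.
    """
    out = table.copy()
    out["q"] = np.nan
    groups = [(None, out)] if by is None else list(out.groupby(by))
    for _, grp in groups:
        mask = grp[p_col].notna()
        if mask.sum() == 0:
            continue
        res = qvalues(grp.loc[mask, p_col].values)
        out.loc[grp.index[mask], "q"] = res.qvalues
    out["significant"] = out["q"] < threshold
    return out
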
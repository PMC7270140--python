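"""Elementary statistics used throughout the pipeline.

Two tests carry the whole analysis: the Pearson correlation with its
two-sided t-transform p-value (cell-cytokine edges, cytokine labelling,
module membership) and the Mann-Whitney U test (module score vs tumour
location).  Both are thin, validating wrappers around scipy with the exact
branch rules the pipeline relies on made explicit.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError


class CorrelationResult(NamedTuple):
    """Pearson correlation with two-sided p-value and sample count."""

    rho: float
    p: float
    n: int


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with two-sided t-transform p-value.

    The p-value is obtained from ``t = rho * sqrt((n-2) / (1-rho^2))`` with
    ``n - 2`` degrees of freedom (the classical exact test under bivariate
    normality).

    Raises
    ------
    DegenerateInputError
        If fewer than 3 paired observations or either vector has zero
        variance (never a silent NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DegenerateInputError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need n >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance vector: Pearson correlation undefined")
    res = sps.pearsonr(x, y)
    rho = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(rho=rho, p=float(res.pvalue), n=n)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Returns ``(U, p)`` where ``U`` is the statistic for group ``a``.  The
    exact null distribution (full enumeration) is used when the combined
    sample size is at most 20 and no ties are present; otherwise the normal
    approximation with tie-corrected variance and continuity correction.

    Raises
    ------
    DegenerateInputError
        If either group is empty.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("Mann-Whitney requires both groups non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0:
        # identical constant groups: no evidence of a shift
        return float(a.size * b.size / 2.0), 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
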
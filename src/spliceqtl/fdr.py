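"""False discovery rate machinery: Storey q-values with a BH alternative.

The primary method estimates the null proportion pi0 on the lambda grid
0.05..0.95 with a cubic smoother evaluated at the top of the grid, then maps
p-values to q-values by the usual step-down minimum. With fewer than 100
p-values the pi0 estimate is too noisy and is pinned at 1 (equivalent to BH).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    # cubic fit stands in for the df=3 smoothing spline; evaluated at max(lambda)
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """Per-test q-values. ``method`` is ``storey`` (default) or ``bh``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown FDR method {method!r}")
    m = p.size
    pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
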
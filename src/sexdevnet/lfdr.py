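"""Local false discovery rate from p-values.

Two-component model: the observed p-value density is
f(p) = pi0 * f0(p) + (1 - pi0) * f_alt(p), with f0 uniform.  The marginal
density f is estimated by the Grenander estimator (slope of the least
concave majorant of the empirical CDF), which is the nonparametric MLE among
decreasing densities; pi0 comes from the upper tail of the p-value
distribution.  Then lfdr(p) = min(1, pi0 / f(p)), the posterior probability
that a test with this p-value is null.

To stabilise the estimator at the extreme left tail (where the raw Grenander
slope is inconsistent), the empirical CDF is thinned so each knot spans a
block of ~10 observations before the majorant is taken.
"""

from __future__ import annotations

import warnings

import numpy as np


def estimate_pi0(pvalues: np.ndarray, lam: float = 0.75) -> float:
    """Upper-tail null-proportion estimate: #{p > lam} / ((1 - lam) n)."""
    p = np.asarray(pvalues, dtype=float)
    pi0 = (p > lam).mean() / (1.0 - lam)
    return float(np.clip(pi0, 1e-8, 1.0))


def _lcm_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least concave majorant of the points (x, y); returns knot x and
    per-segment slopes.  x must be increasing, with (x0, y0) = (0, 0)."""
    # upper convex hull scan (slopes must be non-increasing left to right)
    hx = [x[0]]
    hy = [y[0]]
    for xi, yi in zip(x[1:], y[1:]):
        while len(hx) >= 2:
            s_last = (hy[-1] - hy[-2]) / (hx[-1] - hx[-2])
            s_new = (yi - hy[-1]) / (xi - hx[-1]) if xi > hx[-1] else np.inf
            if s_new >= s_last:
                hx.pop()
                hy.pop()
            else:
                break
        if xi > hx[-1]:
            hx.append(xi)
            hy.append(yi)
        else:
            hy[-1] = max(hy[-1], yi)
    hx_arr = np.asarray(hx)
    hy_arr = np.asarray(hy)
    slopes = np.diff(hy_arr) / np.diff(hx_arr)
    return hx_arr, slopes


def grenander_density(
    pvalues: np.ndarray, block: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Decreasing density estimate of the p-value distribution.

    Returns (knots, slopes): the density equals ``slopes[i]`` on
    (knots[i], knots[i+1]].  By default the ECDF is thinned so each knot
    spans a block of ~10 observations before the least concave majorant is
    computed; ``block=1`` keeps the raw resolution (used when isolated
    discoveries are expected and an external null provides the calibration).
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    if block is None:
        block = min(10, max(1, n // 5))
    idx = np.arange(block - 1, n, block)
    if len(idx) == 0 or idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    x = np.concatenate([[0.0], p[idx], [1.0]])
    y = np.concatenate([[0.0], (idx + 1) / n, [1.0]])
    # collapse duplicate x (ties in p)
    keep = np.concatenate([[True], np.diff(x) > 0])
    x, y = x[keep], np.maximum.accumulate(y[keep])
    return _lcm_slopes(x, y)


def compute_lfdr(
    pvalues,
    threshold: float = 0.05,
    lam: float = 0.75,
    block: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local FDR per p-value plus significance calls (lfdr < threshold)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) < 50:
        warnings.warn(
            f"only {len(p)} p-values; lfdr density estimate may be unstable"
        )
    pi0 = estimate_pi0(p, lam=lam)
    knots, slopes = grenander_density(p, block=block)
    seg = np.clip(np.searchsorted(knots, p, side="left") - 1, 0, len(slopes) - 1)
    f = np.maximum(slopes[seg], 1e-12)
    lfdr = np.minimum(1.0, pi0 / f)
    return lfdr, lfdr < threshold
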
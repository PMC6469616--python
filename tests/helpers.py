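"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the major-axis
oracle minimises the perpendicular-distance objective numerically over
the line's angle, and the tau oracle counts concordant/discordant pairs
directly.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def perpendicular_ss(slope: float, x: np.ndarray, y: np.ndarray) -> float:
    """Sum of squared perpendicular distances to the best line of given slope."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum((yc - slope * xc) ** 2) / (1.0 + slope**2))


def ma_brute(x: np.ndarray, y: np.ndarray, n_grid: int = 2_000_001):
    """Brute-force major-axis fit: angle grid search plus local refinement."""
    thetas = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2 - 1e-9, n_grid)
    b = np.tan(thetas)
    xc = x - x.mean()
    yc = y - y.mean()
    syy = np.sum(yc**2)
    sxx = np.sum(xc**2)
    sxy = np.sum(xc * yc)
    obj = (syy - 2.0 * b * sxy + b**2 * sxx) / (1.0 + b**2)
    i = int(np.argmin(obj))
    lo, hi = thetas[max(i - 1, 0)], thetas[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda th: perpendicular_ss(math.tan(th), x, y),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-14},
    )
    slope = math.tan(res.x)
    return slope, float(y.mean() - slope * x.mean())


def tau_b_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-b by explicit pair counting with tie correction."""
    n = len(x)
    concordant = discordant = tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                tied_x += 1
            elif dy == 0:
                tied_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))
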
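"""Grenander estimator of a nonincreasing P-value density on [0, 1].

The estimator is the derivative of the least concave majorant (LCM) of
the empirical CDF.  ECDF heights use plotting positions c_k/(m+1) and
the curve is anchored at (0, 0) and (1, 1), so the density integrates to
one over [0, 1] and the terminal step stays strictly positive even when
the largest observed P-value is below 1.  The LCM derivative is computed
as the weighted antitonic regression of the raw ECDF slopes (weights =
knot spacings), which is the classical pool-adjacent-violators identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .pvalues import PValueVector

__all__ = ["GrenanderDensity", "grenander_fit"]


@dataclass(frozen=True)
class GrenanderDensity:
    """Nonincreasing step density on [0, 1] with its concave CDF.

    ``knots`` has K+1 points starting at 0 and ending at 1; ``density``
    holds the K step values, step j covering [knots[j], knots[j+1]);
    ``cdf`` holds the LCM values at the knots (cdf[0] = 0, cdf[-1] = 1).
    """

    knots: np.ndarray
    density: np.ndarray
    cdf: np.ndarray

    @property
    def terminal_step(self) -> float:
        """Density value on the rightmost step (the flattest one)."""
        return float(self.density[-1])

    def evaluate(self, p) -> np.ndarray:
        """Step-density value at ``p``, right-continuous on [0, 1).

        f(1) is the last step's value.
        """
        p = np.asarray(p, dtype=float)
        idx = np.searchsorted(self.knots, p, side="right") - 1
        idx = np.clip(idx, 0, self.density.size - 1)
        return self.density[idx]

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.knots)))


def _fit_from_weighted(u: np.ndarray, w: np.ndarray, m: int) -> GrenanderDensity:
    """Grenander fit from distinct sorted values ``u`` with counts ``w``.

    ``m`` is the total observation count (sum of w).
    """
    # knot spacings below TINY would overflow the slope computation;
    # cluster such (absurdly close) values onto the right edge of their
    # group and keep every knot at least TINY away from the origin
    TINY = 1e-290
    if u.size > 1 and np.any(np.diff(u) < TINY):
        groups = np.concatenate(([0], np.cumsum(np.diff(u) >= TINY)))
        w = np.bincount(groups, weights=w)
        u = u[np.flatnonzero(np.concatenate((np.diff(groups), [1])))]
    if u[0] == 0.0:
        # exact zeros would create a zero-width step at the origin; move
        # their knot to half the next distinct value (0.5 if all p are 0)
        u = u.copy()
        u[0] = u[1] / 2.0 if u.size > 1 else 0.5
    if u[0] < TINY:
        u = u.copy()
        u[0] = min(TINY, u[1] / 2.0) if u.size > 1 else TINY
    y = np.cumsum(w) / (m + 1.0)
    x = np.concatenate(([0.0], u))
    yy = np.concatenate(([0.0], y))
    if x[-1] < 1.0:
        x = np.concatenate((x, [1.0]))
        yy = np.concatenate((yy, [1.0]))
    else:
        yy[-1] = 1.0
    dx = np.diff(x)
    slopes = np.diff(yy) / dx
    dens = isotonic_regression(slopes, weights=dx, increasing=False).x
    cdf = np.concatenate(([0.0], np.cumsum(dens * dx)))
    return GrenanderDensity(knots=x, density=dens, cdf=cdf)


def grenander_fit(pv) -> GrenanderDensity:
    """Fit the Grenander density to a :class:`PValueVector` or array."""
    p = pv.p if isinstance(pv, PValueVector) else np.asarray(pv, dtype=float)
    u, w = np.unique(p, return_counts=True)
    return _fit_from_weighted(u, w.astype(float), p.size)
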
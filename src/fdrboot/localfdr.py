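"""Local FDR and q-value estimation under the two-component mixture.

P-values are modelled as a mixture f(p) = eta0 * 1 + (1 - eta0) * f1(p)
of a uniform null component (weight eta0) and a stochastically smaller
alternative.  The local FDR of a feature is the posterior null
probability at its P-value, fdr(p) = eta0 / f(p), with f estimated by
the Grenander (monotone nonincreasing) density.  The q-value of a
feature is the tail-area FDR: the average local FDR of all features
with P-values at or below its own.  This running-mean definition makes
the bootstrap's replicate-level q (mean bootstrapped local FDR over the
significant set) reduce exactly to q on the identity resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grenander import GrenanderDensity, _fit_from_weighted, grenander_fit
from .pvalues import PValueVector, validate_pvalues

__all__ = [
    "LocalFdrFit",
    "SignificanceSet",
    "estimate_eta0",
    "local_fdr",
    "q_values",
    "significant_set",
]


@dataclass(frozen=True)
class LocalFdrFit:
    """Fitted mixture: null proportion, per-feature local FDRs, q-values."""

    eta0: float
    fdr: np.ndarray
    q: np.ndarray
    density: GrenanderDensity
    pv: PValueVector


@dataclass(frozen=True)
class SignificanceSet:
    """Features declared significant at FDR level alpha: S = {i : q_i <= alpha}."""

    alpha: float
    members: np.ndarray  # indices into the original feature order

    @property
    def r(self) -> int:
        return self.members.size


def estimate_eta0(pv, density: GrenanderDensity, method: str = "storey",
                  lam: float = 0.5) -> float:
    """Estimate the null (uniform-component) proportion eta0.

    ``method="storey"`` (default): eta0 = #{p > lam} / (m * (1 - lam)),
    capped at 1 — the fixed-lambda tail-count estimator.  The uniform
    component dominates above lam, so the tail count is close to
    eta0 * m * (1 - lam).

    ``method="terminal"``: eta0 = min(1, density on the rightmost
    Grenander step).  Kept as an alternative; the Grenander density is
    inconsistent at the right boundary, which biases this rule downward
    (see the methods note), so it is not the default.
    """
    if method == "terminal":
        return min(1.0, density.terminal_step)
    if method == "storey":
        p = pv.p if isinstance(pv, PValueVector) else np.asarray(pv, float)
        if not 0.0 < lam < 1.0:
            raise ValueError(f"lambda must be in (0,1), got {lam}")
        eta0 = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
        return min(1.0, float(eta0)) if eta0 > 0 else 1.0 / (p.size * (1.0 - lam))
    raise ValueError(f"unknown eta0 method: {method!r}")


def _fdr_from_density(p: np.ndarray, eta0: float,
                      density: GrenanderDensity) -> np.ndarray:
    f = density.evaluate(p)
    with np.errstate(divide="ignore"):
        fdr = np.where(f > 0.0, eta0 / np.where(f > 0.0, f, 1.0), 1.0)
    return np.minimum(1.0, fdr)


def q_values(fdr: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Tail-area q-values: running mean of local FDRs sorted by p.

    With features sorted by p ascending, q_(k) = mean(fdr_(1..k)); tied
    P-values share the running mean at the last tied rank.  Returned in
    the original feature order.
    """
    p = np.asarray(p, float)
    fdr = np.asarray(fdr, float)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    running = np.cumsum(fdr[order]) / np.arange(1, p.size + 1)
    # ties share the value at the last tied rank
    boundary = np.empty(p.size, dtype=bool)
    boundary[:-1] = ps[1:] != ps[:-1]
    boundary[-1] = True
    idx = np.flatnonzero(boundary)  # last rank of each tie group
    last_of_group = idx[np.searchsorted(idx, np.arange(p.size))]
    q_sorted = running[last_of_group]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def local_fdr(pv, eta0_method: str = "storey", lam: float = 0.5) -> LocalFdrFit:
    """Full estimation pipeline: Grenander density, eta0, local FDRs, q-values."""
    if not isinstance(pv, PValueVector):
        p = np.asarray(pv, dtype=float)
        pv = validate_pvalues(np.array([f"f{i}" for i in range(p.size)],
                                       dtype=object), p)
    density = grenander_fit(pv)
    eta0 = estimate_eta0(pv, density, method=eta0_method, lam=lam)
    fdr = _fdr_from_density(pv.p, eta0, density)
    q = q_values(fdr, pv.p)
    return LocalFdrFit(eta0=eta0, fdr=fdr, q=q, density=density, pv=pv)


def significant_set(fit: LocalFdrFit, alpha: float = 0.05) -> SignificanceSet:
    """Features with q-value at most alpha (inclusive threshold)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    members = np.flatnonzero(fit.q <= alpha)
    return SignificanceSet(alpha=alpha, members=members)
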
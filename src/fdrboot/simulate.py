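"""Synthetic two-component P-value data with analytic ground truth.

Each feature carries a z-statistic z_i = mu * label_i + eps_i, where
label_i ~ Bernoulli(1 - eta0) marks alternatives and eps is standard
normal, optionally equicorrelated (correlation rho) within consecutive
blocks of ``block_size`` features.  One-sided P-values p = 1 - Phi(z)
make null P-values marginally uniform and give the mixture closed
forms:

    f1(p)      = phi(z_p - mu) / phi(z_p),      z_p = Phi^{-1}(1 - p)
    fdr(p)     = eta0 / (eta0 + (1 - eta0) f1(p))          (local FDR)
    q(p)       = eta0 p / (eta0 p + (1 - eta0) F1(p)),     (tail FDR)
    F1(p)      = 1 - Phi(z_p - mu)

so the estimators and the bootstrap intervals can be checked against
exact truth.  The coverage study repeats the full pipeline over many
simulated datasets and records how often the 95% percentile intervals
cover the analytic local FDR and q-value at P-value cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import bootstrap as bt
from . import localfdr as lf
from .localfdr import SignificanceSet
from .pvalues import PValueVector, validate_pvalues

__all__ = [
    "MixtureParams",
    "SyntheticTruth",
    "simulate_pvalues",
    "true_local_fdr",
    "true_tail_fdr",
    "coverage_study",
]


@dataclass(frozen=True)
class MixtureParams:
    """Generating model for synthetic P-values.

    m           number of features
    eta0        true null proportion, in (0, 1]
    mu          alternative mean shift of the z-statistic (>= 0)
    rho         equicorrelation of the noise within blocks, in [0, 1)
    block_size  features per correlated block (consecutive features)
    two_sided   map z to two-sided P-values instead of one-sided
    """

    m: int = 2000
    eta0: float = 0.9
    mu: float = 2.5
    rho: float = 0.0
    block_size: int = 50
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if not 0.0 < self.eta0 <= 1.0:
            raise ValueError(f"eta0 must be in (0,1], got {self.eta0}")
        if self.mu < 0.0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0,1), got {self.rho}")
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generated data plus the analytic truth at each P-value."""

    labels: np.ndarray    # True for alternatives
    p: np.ndarray
    true_fdr: np.ndarray
    true_q: np.ndarray

    def pvalue_vector(self) -> PValueVector:
        ids = np.array([f"g{i:05d}" for i in range(self.p.size)], dtype=object)
        return validate_pvalues(ids, self.p)


def true_local_fdr(params: MixtureParams, p) -> np.ndarray:
    """Analytic local FDR of the generating mixture at P-value(s) ``p``.

    Boundary limits (mu > 0, one-sided): fdr -> 0 as p -> 0 and
    fdr -> 1 as p -> 1 (the alternative density vanishes in the right
    tail); for mu = 0 the mixture is flat and fdr = eta0 everywhere.
    """
    p = np.asarray(p, dtype=float)
    if params.mu == 0.0 or params.eta0 == 1.0:
        return np.full_like(p, params.eta0 if params.mu == 0.0 else 1.0)
    out = np.empty_like(p)
    inner = (p > 0.0) & (p < 1.0)
    if params.two_sided:
        z = stats.norm.isf(p[inner] / 2.0)
        f1 = (stats.norm.pdf(z - params.mu) + stats.norm.pdf(z + params.mu)) \
            / (2.0 * stats.norm.pdf(z))
    else:
        z = stats.norm.isf(p[inner])
        f1 = np.exp(params.mu * z - 0.5 * params.mu ** 2)
    out[inner] = params.eta0 / (params.eta0 + (1.0 - params.eta0) * f1)
    out[p <= 0.0] = 0.0
    if params.two_sided:
        f1_at_1 = np.exp(-0.5 * params.mu ** 2)
        out[p >= 1.0] = params.eta0 / (params.eta0
                                       + (1.0 - params.eta0) * f1_at_1)
    else:
        out[p >= 1.0] = 1.0
    return out


def true_tail_fdr(params: MixtureParams, p) -> np.ndarray:
    """Analytic tail-area FDR (q-value) of the mixture at cutoff(s) ``p``."""
    p = np.asarray(p, dtype=float)
    if params.mu == 0.0 or params.eta0 == 1.0:
        return np.full_like(p, params.eta0 if params.mu == 0.0 else 1.0)
    if params.two_sided:
        z = stats.norm.isf(p / 2.0)
        F1 = stats.norm.sf(z - params.mu) + stats.norm.cdf(-z - params.mu)
    else:
        F1 = stats.norm.sf(stats.norm.isf(p) - params.mu)
    num = params.eta0 * p
    with np.errstate(invalid="ignore", divide="ignore"):
        q = num / (num + (1.0 - params.eta0) * F1)
    return np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, q))


def simulate_pvalues(params: MixtureParams, seed=None) -> SyntheticTruth:
    """Draw one synthetic dataset from the mixture model."""
    rng = np.random.default_rng(seed)
    m = params.m
    labels = rng.uniform(size=m) < (1.0 - params.eta0)
    eps = rng.standard_normal(m)
    if params.rho > 0.0:
        n_blocks = -(-m // params.block_size)
        shared = rng.standard_normal(n_blocks)
        block_of = np.arange(m) // params.block_size
        eps = (np.sqrt(params.rho) * shared[block_of]
               + np.sqrt(1.0 - params.rho) * eps)
    z = params.mu * labels + eps
    if params.two_sided:
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = stats.norm.sf(z)
    return SyntheticTruth(labels=labels, p=p,
                          true_fdr=true_local_fdr(params, p),
                          true_q=true_tail_fdr(params, p))


def coverage_study(params: MixtureParams = MixtureParams(),
                   cutoffs: Sequence[float] = (0.001, 0.01, 0.05),
                   n_sims: int = 200, B: int = 1000,
                   seed: Optional[int] = None,
                   eta0_method: str = "storey") -> pd.DataFrame:
    """Empirical coverage of the 95% percentile CIs against the truth.

    For each simulated dataset and each P-value cutoff, the significant
    set is {i : p_i <= cutoff}; the bootstrap runs on that set and we
    record whether (a) the CI of the boundary feature's local FDR (the
    feature with the largest P-value in the set) covers its analytic
    local FDR, and (b) the CI of the bootstrapped q-value covers the
    analytic tail FDR at the cutoff.  Cutoffs that leave a simulation
    with an empty set contribute an "undefined" count instead.

    Returns a DataFrame with columns cutoff, n_effective, n_undefined,
    coverage_lfdr, coverage_q, mc_se (binomial SE at nominal 0.95).
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    cutoffs = [float(c) for c in cutoffs]
    if any(not 0.0 < c < 1.0 for c in cutoffs):
        raise ValueError("cutoffs must lie strictly inside (0,1)")
    root = np.random.SeedSequence(seed)
    sim_seeds, boot_seeds = root.spawn(2)
    sim_children = sim_seeds.spawn(n_sims)
    boot_children = boot_seeds.spawn(n_sims * len(cutoffs))
    hits_l = np.zeros(len(cutoffs), dtype=int)
    hits_q = np.zeros(len(cutoffs), dtype=int)
    n_eff = np.zeros(len(cutoffs), dtype=int)
    n_undef = np.zeros(len(cutoffs), dtype=int)
    for s in range(n_sims):
        truth = simulate_pvalues(params, seed=sim_children[s])
        pv = truth.pvalue_vector()
        fit = lf.local_fdr(pv, eta0_method=eta0_method)
        for c, cut in enumerate(cutoffs):
            members = np.flatnonzero(pv.p <= cut)
            if members.size == 0:
                n_undef[c] += 1
                continue
            S = SignificanceSet(alpha=cut, members=members)
            bseed = boot_children[s * len(cutoffs) + c]
            summ = bt.run_bootstrap(pv, fit, S, B=B, seed=bseed,
                                    eta0_method=eta0_method)
            n_eff[c] += 1
            boundary = members[np.argmax(pv.p[members])]
            lo, hi = summ.ci_lfdr[boundary]
            tl = float(true_local_fdr(params, pv.p[boundary]))
            hits_l[c] += int(lo <= tl <= hi)
            tq = float(true_tail_fdr(params, cut))
            hits_q[c] += int(summ.ci_q[0] <= tq <= summ.ci_q[1])
    with np.errstate(invalid="ignore"):
        cov_l = hits_l / np.maximum(n_eff, 1)
        cov_q = hits_q / np.maximum(n_eff, 1)
        mc_se = np.sqrt(0.95 * 0.05 / np.maximum(n_eff, 1))
    return pd.DataFrame({
        "cutoff": cutoffs,
        "n_effective": n_eff,
        "n_undefined": n_undef,
        "coverage_lfdr": cov_l,
        "coverage_q": cov_q,
        "mc_se": mc_se,
    })
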
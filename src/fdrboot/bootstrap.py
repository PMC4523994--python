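"""P-value bootstrap for the variability of FDR control.

The unit of analysis is a P-value, so replicates resample the P-values
themselves with replacement (no test statistics are recomputed).  Each
replicate refits the local-FDR estimator on the resampled P-values,
imputes a bootstrapped local FDR ``fdrB_i`` for every original feature
(directly when the feature's P-value appears in the resample, by linear
interpolation between its flanking resampled P-values when it does
not), and summarizes the significant set S by

* ``qB``   — the mean bootstrapped local FDR over S, and
* ``fdpB`` — a simulated false discovery proportion: each feature in S
  contributes an independent Bernoulli(fdrB_i) false-discovery
  indicator; fdpB is the fraction of successes.

Across B replicates the sample standard deviations and 2.5/97.5
percentiles of fdrB_i (per feature), qB and fdpB give the bootstrap
standard errors and 95% percentile confidence intervals.

RNG policy: one seed; replicate b uses an independent substream spawned
from (seed, b) and consumes draws in a fixed order — (1) the m resample
indices, (2) one uniform pair per feature requiring interpolation (the
flank tie-breaks; tied flank members share one fdr*, so these draws can
never change the imputed value), (3) the r Bernoulli uniforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grenander import _fit_from_weighted
from .localfdr import LocalFdrFit, SignificanceSet, estimate_eta0
from .pvalues import PValueVector

__all__ = [
    "BootstrapReplicate",
    "BootstrapSummary",
    "FlankingPair",
    "draw_bootstrap_indices",
    "refit_star_fdr",
    "find_flanks",
    "interpolate_missing_fdr",
    "impute_all_fdrB",
    "replicate_summaries",
    "make_replicate",
    "run_bootstrap",
]


@dataclass(frozen=True)
class FlankingPair:
    """Interpolation anchors around a missing feature's P-value.

    An empty left flank is replaced by (p_L, fdr_L) = (0, 0); an empty
    right flank by (p_R, fdr_R) = (1, 1).
    """

    p_L: float
    fdr_L: float
    p_R: float
    fdr_R: float


@dataclass(frozen=True)
class BootstrapReplicate:
    """One resample: indices, refit local FDRs, imputed values, summaries."""

    G: np.ndarray
    p_star: np.ndarray
    fdr_star: np.ndarray
    missing: np.ndarray  # original indices absent from G
    fdrB: np.ndarray
    qB: float
    fdpB: float


@dataclass(frozen=True)
class BootstrapSummary:
    """SEs and 95% percentile CIs over B replicates."""

    B: int
    seed: Optional[int]
    se_lfdr: np.ndarray      # (m,)
    ci_lfdr: np.ndarray      # (m, 2)
    se_q: float
    ci_q: np.ndarray         # (2,)
    se_fdp: float
    ci_fdp: np.ndarray       # (2,)
    qB: np.ndarray           # (B,) replicate q values
    fdpB: np.ndarray         # (B,) replicate FDP values


def draw_bootstrap_indices(m: int, rng: np.random.Generator) -> np.ndarray:
    """m independent uniform draws over {0..m-1} (with replacement)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return rng.integers(0, m, size=m)


def _fdr_on_unique(u: np.ndarray, w: np.ndarray, m: int,
                   eta0_method: str, lam: float) -> tuple[np.ndarray, float]:
    """Local FDRs at distinct sorted values ``u`` with multiplicities ``w``."""
    density = _fit_from_weighted(u, w.astype(float), m)
    if eta0_method == "storey":
        tail = float(w[u > lam].sum())
        eta0 = tail / (m * (1.0 - lam))
        eta0 = min(1.0, eta0) if eta0 > 0 else 1.0 / (m * (1.0 - lam))
    else:
        eta0 = estimate_eta0(u, density, method=eta0_method, lam=lam)
    f = density.evaluate(u)
    with np.errstate(divide="ignore"):
        fdr_u = np.where(f > 0.0, eta0 / np.where(f > 0.0, f, 1.0), 1.0)
    return np.minimum(1.0, fdr_u), eta0


def refit_star_fdr(p_star, eta0_method: str = "storey",
                   lam: float = 0.5) -> np.ndarray:
    """Refit the local-FDR pipeline on resampled P-values.

    Exactly the estimator used on the original data (density and eta0
    re-estimated per replicate); tied p* share one fdr*.
    """
    p_star = np.asarray(p_star, dtype=float)
    u, inverse, w = np.unique(p_star, return_inverse=True, return_counts=True)
    fdr_u, _ = _fdr_on_unique(u, w, p_star.size, eta0_method, lam)
    return fdr_u[inverse]


def find_flanks(p_i: float, p_star, fdr_star,
                rng: Optional[np.random.Generator] = None) -> FlankingPair:
    """Left/right flanking resampled features around ``p_i``.

    Left flank: a random member of {j : p*_j = max{p*_k <= p_i}};
    right flank: a random member of {j : p*_j = min{p*_k >= p_i}}.
    Empty sets fall back to the (0, 0) / (1, 1) boundary anchors.
    """
    p_star = np.asarray(p_star, dtype=float)
    fdr_star = np.asarray(fdr_star, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    left = p_star[p_star <= p_i]
    if left.size:
        members = np.flatnonzero(p_star == left.max())
        u = members[rng.integers(0, members.size)]
        p_L, fdr_L = float(p_star[u]), float(fdr_star[u])
    else:
        p_L, fdr_L = 0.0, 0.0
    right = p_star[p_star >= p_i]
    if right.size:
        members = np.flatnonzero(p_star == right.min())
        v = members[rng.integers(0, members.size)]
        p_R, fdr_R = float(p_star[v]), float(fdr_star[v])
    else:
        p_R, fdr_R = 1.0, 1.0
    return FlankingPair(p_L=p_L, fdr_L=fdr_L, p_R=p_R, fdr_R=fdr_R)


def interpolate_missing_fdr(p_i: float, flanks: FlankingPair) -> float:
    """Linear interpolation of the bootstrapped local FDR at ``p_i``."""
    if flanks.p_L == flanks.p_R:
        return flanks.fdr_R
    return (flanks.fdr_R * (p_i - flanks.p_L)
            + flanks.fdr_L * (flanks.p_R - p_i)) / (flanks.p_R - flanks.p_L)


def _impute_from_unique(p: np.ndarray, u: np.ndarray, fdr_u: np.ndarray,
                        rng: Optional[np.random.Generator]) -> np.ndarray:
    """fdrB for every original feature given the resample's distinct values.

    Features whose P-value occurs in the resample (their own draw or a
    tied partner's) take fdr* at that value — for a tied partner this is
    exactly what the p_L = p_R branch of the interpolation yields.  The
    rest are interpolated between their flanking values.
    """
    pos = np.searchsorted(u, p)
    present = (pos < u.size) & (u[np.minimum(pos, u.size - 1)] == p)
    fdrB = np.empty(p.size)
    fdrB[present] = fdr_u[pos[present]]
    miss = ~present
    if miss.any():
        pm = p[miss]
        li = np.searchsorted(u, pm, side="right") - 1
        ri = np.searchsorted(u, pm, side="left")
        has_l = li >= 0
        has_r = ri < u.size
        pL = np.where(has_l, u[np.maximum(li, 0)], 0.0)
        fL = np.where(has_l, fdr_u[np.maximum(li, 0)], 0.0)
        pR = np.where(has_r, u[np.minimum(ri, u.size - 1)], 1.0)
        fR = np.where(has_r, fdr_u[np.minimum(ri, u.size - 1)], 1.0)
        if rng is not None:
            rng.random((pm.size, 2))  # flank tie-break draws (value-neutral)
        with np.errstate(invalid="ignore"):
            interp = (fR * (pm - pL) + fL * (pR - pm)) / (pR - pL)
        fdrB[miss] = np.where(pL == pR, fR, interp)
    return fdrB


def impute_all_fdrB(pv: PValueVector, G, fdr_star=None,
                    rng: Optional[np.random.Generator] = None,
                    eta0_method: str = "storey", lam: float = 0.5) -> np.ndarray:
    """Bootstrapped local FDR for all m original features of one resample."""
    p = pv.p if isinstance(pv, PValueVector) else np.asarray(pv, float)
    G = np.asarray(G, dtype=int)
    p_star = p[G]
    u, first = np.unique(p_star, return_index=True)
    if fdr_star is None:
        w = np.bincount(np.searchsorted(u, p_star), minlength=u.size).astype(float)
        fdr_u, _ = _fdr_on_unique(u, w, p_star.size, eta0_method, lam)
    else:
        fdr_star = np.asarray(fdr_star, dtype=float)
        order = np.argsort(p_star, kind="stable")
        grp = np.searchsorted(u, p_star[order])
        mins = np.full(u.size, np.inf)
        maxs = np.full(u.size, -np.inf)
        np.minimum.at(mins, grp, fdr_star[order])
        np.maximum.at(maxs, grp, fdr_star[order])
        if not np.allclose(mins, maxs, rtol=0, atol=0):
            raise ValueError("tied resampled P-values must share one fdr*")
        fdr_u = fdr_star[first]
    return _impute_from_unique(p, u, fdr_u, rng)


def replicate_summaries(fdrB: np.ndarray, S: SignificanceSet,
                        rng: np.random.Generator) -> tuple[float, float]:
    """(qB, fdpB) for one replicate over the significant set S."""
    if S.r == 0:
        raise ValueError("no significant features; bootstrap undefined")
    fs = np.asarray(fdrB, dtype=float)[S.members]
    qB = float(fs.mean())
    fdpB = float(np.count_nonzero(rng.random(fs.size) < fs)) / fs.size
    return qB, fdpB


def make_replicate(pv: PValueVector, S: SignificanceSet,
                   rng: np.random.Generator, eta0_method: str = "storey",
                   lam: float = 0.5) -> BootstrapReplicate:
    """Draw and fully evaluate a single bootstrap replicate."""
    p = pv.p
    G = draw_bootstrap_indices(p.size, rng)
    p_star = p[G]
    u, inverse, w = np.unique(p_star, return_inverse=True, return_counts=True)
    fdr_u, _ = _fdr_on_unique(u, w, p.size, eta0_method, lam)
    fdr_star = fdr_u[inverse]
    fdrB = _impute_from_unique(p, u, fdr_u, rng)
    qB, fdpB = replicate_summaries(fdrB, S, rng)
    in_G = np.zeros(p.size, dtype=bool)
    in_G[G] = True
    return BootstrapReplicate(G=G, p_star=p_star, fdr_star=fdr_star,
                              missing=np.flatnonzero(~in_G), fdrB=fdrB,
                              qB=qB, fdpB=fdpB)


def run_bootstrap(pv: PValueVector, fit: LocalFdrFit, S: SignificanceSet,
                  B: int = 10000, seed: Optional[int] = None,
                  eta0_method: str = "storey", lam: float = 0.5,
                  ) -> BootstrapSummary:
    """Generate B replicates and summarize SEs and percentile CIs.

    Standard errors use the sample standard deviation (B-1 denominator);
    intervals are the empirical 2.5% and 97.5% quantiles.  Per-feature
    local-FDR SEs use fdrB_i from all replicates, including those where
    feature i was imputed.
    """
    if B < 2:
        raise ValueError(f"need B >= 2 replicates, got {B}")
    if S.r == 0:
        raise ValueError("no significant features; bootstrap undefined")
    p = pv.p
    m = p.size
    members = S.members
    r = members.size
    fdrB_all = np.empty((B, m))
    qB = np.empty(B)
    fdpB = np.empty(B)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        G = draw_bootstrap_indices(m, rng)
        p_star = p[G]
        u, inverse, w = np.unique(p_star, return_inverse=True,
                                  return_counts=True)
        fdr_u, _ = _fdr_on_unique(u, w, m, eta0_method, lam)
        fdrB = _impute_from_unique(p, u, fdr_u, rng)
        fs = fdrB[members]
        fdrB_all[b] = fdrB
        qB[b] = fs.mean()
        fdpB[b] = np.count_nonzero(rng.random(r) < fs) / r
    return BootstrapSummary(
        B=B, seed=seed,
        se_lfdr=fdrB_all.std(axis=0, ddof=1),
        ci_lfdr=np.quantile(fdrB_all, [0.025, 0.975], axis=0).T,
        se_q=float(qB.std(ddof=1)),
        ci_q=np.quantile(qB, [0.025, 0.975]),
        se_fdp=float(fdpB.std(ddof=1)),
        ci_fdp=np.quantile(fdpB, [0.025, 0.975]),
        qB=qB, fdpB=fdpB,
    )
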
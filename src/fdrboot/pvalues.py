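"""Validated P-value input: the unit of analysis for every downstream step."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PValueVector:
    """A collection of m features with one P-value each.

    Attributes
    ----------
    ids : np.ndarray of str
        Unique feature identifiers, in input order.
    p : np.ndarray of float
        P-values in [0, 1], aligned with ``ids``.
    """

    ids: np.ndarray
    p: np.ndarray

    @property
    def m(self) -> int:
        return self.p.size

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=object))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))


def validate_pvalues(ids, raw_p) -> PValueVector:
    """Check and wrap raw input into a :class:`PValueVector`.

    P-values exactly 0 or 1 are retained as-is.  Raises ``ValueError``
    naming the first offending entry for: non-finite or out-of-range
    values, duplicated identifiers, or fewer than two features.
    """
    ids = np.asarray(ids, dtype=object)
    p = np.asarray(raw_p, dtype=float)
    if ids.ndim != 1 or p.ndim != 1:
        raise ValueError("ids and p-values must be one-dimensional")
    if ids.size != p.size:
        raise ValueError(
            f"length mismatch: {ids.size} ids vs {p.size} p-values"
        )
    if p.size < 2:
        raise ValueError(f"need at least 2 features, got {p.size}")
    bad = ~np.isfinite(p)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite p-value for id {ids[i]!r}: {p[i]!r}")
    bad = (p < 0.0) | (p > 1.0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"p-value out of [0,1] for id {ids[i]!r}: {p[i]}")
    uniq, counts = np.unique(ids.astype(str), return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"duplicate id: {uniq[counts > 1][0]!r}")
    return PValueVector(ids=ids, p=p)
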
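"""Convenience error-bar plot of significant-feature local FDRs."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .bootstrap import BootstrapSummary  # noqa: E402
from .localfdr import LocalFdrFit, SignificanceSet  # noqa: E402

__all__ = ["plot_lfdr_errorbars"]


def plot_lfdr_errorbars(fit: LocalFdrFit, S: SignificanceSet,
                        summary: BootstrapSummary,
                        path: Optional[str] = None, ax=None):
    """Local FDRs of the significant features with +/- 1 bootstrap SE.

    Features are ordered by P-value; the horizontal line marks the FDR
    control level alpha.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    members = S.members[np.argsort(fit.pv.p[S.members])]
    xs = np.arange(1, members.size + 1)
    ax.errorbar(xs, fit.fdr[members], yerr=summary.se_lfdr[members],
                fmt="o", ms=3, lw=1, capsize=2, color="black")
    ax.axhline(S.alpha, lw=2, color="black")
    ax.set_xlabel("significant features (ordered by P-value)")
    ax.set_ylabel("local FDR")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
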
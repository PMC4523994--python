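"""Readers/writers and the expression-matrix t-test front end.

Formats are plain TSV/CSV with headers; the dialect is chosen from the
file extension (``.csv`` = comma, anything else = tab) and can be
overridden with ``sep``.  Per-feature output preserves input feature
order; significance is a flag column, never a filter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import BootstrapSummary
from .localfdr import LocalFdrFit, SignificanceSet
from .pvalues import PValueVector, validate_pvalues

__all__ = [
    "ExpressionMatrix",
    "read_pvalue_table",
    "write_pvalue_table",
    "read_expression",
    "two_sample_t_pvalues",
    "write_gene_table",
    "write_summary",
]

_FLOAT_FMT = "%.8g"


def _sep_for(path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Feature-by-sample expression values with binary group labels."""

    ids: np.ndarray       # feature ids, rows
    samples: np.ndarray   # sample ids, columns
    values: np.ndarray    # (features, samples) float
    groups: np.ndarray    # per-sample labels, exactly two levels


def read_pvalue_table(path, sep: Optional[str] = None) -> PValueVector:
    """Read a table with columns ``id`` and ``pvalue``.

    Malformed numeric entries are reported with their line number
    (1-based, counting the header as line 1); unknown extra columns are
    warned about, not fatal.
    """
    sep = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("id", "pvalue"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in ("id", "pvalue")]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    raw = pd.to_numeric(df["pvalue"], errors="coerce")
    bad = raw.isna() & df["pvalue"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: line {line}: cannot parse p-value "
            f"{df['pvalue'][bad.idxmax()]!r}")
    missing = raw.isna()
    if missing.any():
        line = int(missing.idxmax()) + 2
        raise ValueError(f"{path}: line {line}: missing p-value")
    return validate_pvalues(df["id"].to_numpy(dtype=object),
                            raw.to_numpy(dtype=float))


def write_pvalue_table(pv: PValueVector, path, sep: Optional[str] = None) -> None:
    sep = _sep_for(path, sep)
    pd.DataFrame({"id": pv.ids, "pvalue": pv.p}).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_expression(path, groups_path, sep: Optional[str] = None
                    ) -> ExpressionMatrix:
    """Read a feature-by-sample matrix and a sample/group table.

    The expression table's first column holds feature ids; remaining
    columns are samples.  The group table has columns ``sample`` and
    ``group`` with exactly two group levels, each with >= 2 samples.
    Missing expression values are an error (no silent imputation).
    """
    sep_x = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep_x)
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    if pd.Series(ids).duplicated().any():
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value for feature {ids[i]!r}, "
            f"sample {df.columns[j + 1]!r}")
    samples = df.columns[1:].to_numpy(dtype=object)

    gdf = pd.read_csv(groups_path, sep=_sep_for(groups_path, sep))
    for col in ("sample", "group"):
        if col not in gdf.columns:
            raise ValueError(f"{groups_path}: missing required column {col!r}")
    gmap = dict(zip(gdf["sample"].astype(str), gdf["group"]))
    try:
        groups = np.array([gmap[str(s)] for s in samples], dtype=object)
    except KeyError as e:
        raise ValueError(f"{groups_path}: no group label for sample {e}") from e
    levels, counts = np.unique(groups.astype(str), return_counts=True)
    if levels.size != 2:
        raise ValueError(
            f"expected exactly 2 groups, got {levels.size}: {list(levels)}")
    if (counts < 2).any():
        small = levels[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    return ExpressionMatrix(ids=ids, samples=samples, values=values,
                            groups=groups)


def two_sample_t_pvalues(x: ExpressionMatrix, welch: bool = False
                         ) -> PValueVector:
    """Two-sided two-sample t-test P-value per feature.

    Pooled-variance Student's t by default (df = n1 + n2 - 2); Welch's
    unequal-variance test with ``welch=True``.  Degenerate features with
    zero within-group variance get p = 1 when the group means are equal
    and p = 0 otherwise.
    """
    levels = np.unique(x.groups.astype(str))
    a = x.values[:, x.groups.astype(str) == levels[0]]
    b = x.values[:, x.groups.astype(str) == levels[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[bad & equal_means] = 1.0
        p[bad & ~equal_means] = 0.0
    return validate_pvalues(x.ids, p)


def write_gene_table(path, pv: PValueVector, fit: LocalFdrFit,
                     S: SignificanceSet,
                     summary: Optional[BootstrapSummary] = None,
                     sep: Optional[str] = None) -> None:
    """Per-feature results table, one row per input feature in order.

    Columns: id, pvalue, lfdr, qvalue, significant (0/1); with a
    bootstrap summary also lfdr_se, lfdr_ci_lo, lfdr_ci_hi.
    """
    sig = np.zeros(pv.m, dtype=int)
    sig[S.members] = 1
    cols = {
        "id": pv.ids,
        "pvalue": pv.p,
        "lfdr": fit.fdr,
        "qvalue": fit.q,
        "significant": sig,
    }
    if summary is not None:
        cols["lfdr_se"] = summary.se_lfdr
        cols["lfdr_ci_lo"] = summary.ci_lfdr[:, 0]
        cols["lfdr_ci_hi"] = summary.ci_lfdr[:, 1]
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path, sep), index=False,
                              float_format=_FLOAT_FMT)


def write_summary(path, fit: LocalFdrFit, S: SignificanceSet,
                  summary: BootstrapSummary) -> None:
    """Run-level key-value summary as JSON."""
    doc = {
        "r": int(S.r),
        "alpha": float(S.alpha),
        "B": int(summary.B),
        "seed": summary.seed if isinstance(summary.seed, (int, type(None)))
        else str(summary.seed),
        "eta0": float(fit.eta0),
        "q_mean": float(summary.qB.mean()),
        "q_se": float(summary.se_q),
        "q_ci": [float(v) for v in summary.ci_q],
        "fdp_se": float(summary.se_fdp),
        "fdp_ci": [float(v) for v in summary.ci_fdp],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
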
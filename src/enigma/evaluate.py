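"""Companion analyses: cluster-vs-attribute independence and a per-taxon
rank-sum baseline.

These are the standard checks run around a community-typing model: a Pearson
chi-squared test that a host attribute (e.g. gender) is independent of the
inferred clusters, and the classical two-group Wilcoxon rank-sum test per
taxon as a baseline differential-abundance method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .model import OtuTable

__all__ = ["ContingencyTable", "chi_squared_independence", "wilcoxon_per_taxon"]


@dataclass(frozen=True)
class ContingencyTable:
    """R x C table of nonnegative integer cross-tabulated counts."""

    counts: np.ndarray
    row_labels: tuple = None
    col_labels: tuple = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be a 2-D nonnegative matrix")
        if counts.sum() <= 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(self, "counts", np.rint(counts).astype(np.int64))
        R, C = counts.shape
        rows = self.row_labels or tuple(f"row{i + 1}" for i in range(R))
        cols = self.col_labels or tuple(f"col{j + 1}" for j in range(C))
        object.__setattr__(self, "row_labels", tuple(rows))
        object.__setattr__(self, "col_labels", tuple(cols))


def chi_squared_independence(table: ContingencyTable):
    """Pearson chi-squared test of independence (no continuity correction).

    Returns ``(statistic, df, p_value)`` with ``df = (R-1)(C-1)`` and the
    p-value from the upper tail.  Zero marginal rows/columns are rejected.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal row or column")
    res = chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def wilcoxon_per_taxon(
    Y: OtuTable,
    group: np.ndarray,
    normalize: bool = True,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-sided rank-sum test of each taxon between two sample groups.

    Operates on relative abundances when ``normalize`` is set (the default,
    matching the normalization used for the divergence analyses).  Ties get
    midranks with the normal approximation; small tie-free groups are tested
    exactly.  A taxon constant across all samples gets p = 1 and a
    ``constant`` flag rather than an error.  ``adjust`` is a multiple-testing
    method name understood by statsmodels (``fdr_bh`` default, ``bonferroni``
    available); adjusted p-values are reported alongside the raw ones.
    """
    group = np.asarray(group)
    if group.shape != (Y.n_samples,):
        raise ValueError("group must be one label per sample")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must have exactly two levels, both nonempty")
    data = Y.relative_abundances() if normalize else Y.counts.astype(float)
    in_b = group == levels[1]
    stats, pvals, constant = [], [], []
    for k in range(Y.n_taxa):
        col = data[:, k]
        if np.all(col == col[0]):
            stats.append(np.nan)
            pvals.append(1.0)
            constant.append(True)
            continue
        res = mannwhitneyu(col[~in_b], col[in_b], alternative="two-sided")
        stats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
        constant.append(False)
    adjusted = multipletests(pvals, method=adjust)[1]
    return pd.DataFrame(
        {
            "taxon": list(Y.taxon_ids),
            "statistic": stats,
            "p_value": pvals,
            "p_adjusted": adjusted,
            "constant": constant,
        }
    )
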
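"""Per-ROI two-group discrimination: Mann-Whitney tests, AUROC effect sizes, ranks.

The AUROC here is the probability that a randomly chosen member of group A
has a *larger* measurement than a randomly chosen member of group B, ties
counted one half — i.e. U/(n_a*n_b) with U the Mann-Whitney statistic under
midranks.  By convention group A is the less-affected group, so AUROC > 0.5
means the affected group has reduced thickness/volume (atrophy).  Values are
invariant under any strictly monotone rescaling of the measurements.

No multiple-testing correction is applied to the per-ROI p-values: each ROI's
p is reported raw, as is conventional when the quantity of interest is the
effect-size ranking rather than family-wise significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["auroc", "auroc_matrix", "mann_whitney_p", "rank_rois", "rank_table"]

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (tie-free samples only); larger samples use the
#: tie-corrected normal approximation with continuity correction.
EXACT_COMBINED_N = 20


def _check_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise DataError(f"group {name!r} is empty")
    if not np.isfinite(arr).all():
        raise DataError(f"group {name!r} contains non-finite values")
    return arr


def auroc(group_a_values, group_b_values) -> float:
    """P(A > B) + 0.5*P(A == B), computed from midranks as U/(n_a*n_b)."""
    a = _check_group(group_a_values, "a")
    b = _check_group(group_b_values, "b")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_a = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u_a / (a.size * b.size))


def auroc_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise AUROC for (n_a x R) vs (n_b x R) matrices.

    Shares the rank computation across columns; used by the bootstrap where
    the same statistic is recomputed thousands of times.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise DataError(f"incompatible matrix shapes {a.shape} and {b.shape}")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise DataError("empty group in auroc_matrix")
    ranks = stats.rankdata(np.vstack([a, b]), axis=0)
    n_a, n_b = a.shape[0], b.shape[0]
    u_a = ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    return u_a / (n_a * n_b)


def mann_whitney_p(group_a_values, group_b_values, exact_combined_n: int = EXACT_COMBINED_N) -> float:
    """Two-sided Mann-Whitney p-value.

    Uses the exact null distribution when the combined sample size is at most
    ``exact_combined_n`` and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = _check_group(group_a_values, "a")
    b = _check_group(group_b_values, "b")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical in both groups; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_combined_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def rank_rois(aurocs: pd.Series) -> pd.Series:
    """Rank ROIs by AUROC, 1 = best (largest); exact ties get midranks."""
    s = pd.Series(aurocs, dtype=float)
    if s.empty:
        raise DataError("no ROIs to rank")
    return pd.Series(stats.rankdata(-s.to_numpy()), index=s.index, name="rank")


@dataclass
class RankTable:
    """Per-ROI discrimination summary for one group pair and one technique.

    ``table`` columns: auroc, p, rank, ci_low, ci_high (CI columns are NaN
    until filled by the rank bootstrap).
    """

    group_a: str
    group_b: str
    technique: str
    n_group_a: int
    n_group_b: int
    table: pd.DataFrame

    @property
    def aurocs(self) -> pd.Series:
        return self.table["auroc"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="roi")


def rank_table(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    group_a: str = "A",
    group_b: str = "B",
    technique: str = "",
) -> RankTable:
    """Build the per-ROI AUROC / p / rank table for two harmonized group matrices.

    ``values_a`` (less-affected group) and ``values_b`` must share the same
    ROI columns.
    """
    if list(values_a.columns) != list(values_b.columns):
        raise DataError("group tables have different ROI columns")
    aurocs = pd.Series(
        auroc_matrix(values_a.to_numpy(), values_b.to_numpy()), index=values_a.columns
    )
    pvals = pd.Series(
        [mann_whitney_p(values_a[c], values_b[c]) for c in values_a.columns],
        index=values_a.columns,
    )
    tbl = pd.DataFrame(
        {
            "auroc": aurocs,
            "p": pvals,
            "rank": rank_rois(aurocs),
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
    )
    tbl.index.name = "roi"
    return RankTable(
        group_a=group_a,
        group_b=group_b,
        technique=technique,
        n_group_a=len(values_a),
        n_group_b=len(values_b),
        table=tbl,
    )
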
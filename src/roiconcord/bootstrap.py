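"""Bootstrap confidence intervals for ROI ranks.

A point-estimate ranking of ROIs by AUROC hides substantial sampling
variability: with modest effects, which region ranks "best" can change from
sample to sample.  This module resamples subjects with replacement
(stratified within each group by default), recomputes every ROI's AUROC and
midrank per replicate, and reports a percentile interval of each ROI's rank
distribution.

Whole subject rows are resampled, so the cross-ROI correlation structure —
which is exactly what makes one ROI's rank depend on the others — is
preserved within each replicate.  Percentile bounds are rounded outward to
attainable integer ranks in [1, R], and widened if necessary to contain the
point-estimate rank (a pure percentile interval on a discrete scale cannot
guarantee that containment on its own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discrimination import auroc_matrix, rank_rois
from .errors import ConfigError, DataError

__all__ = ["BootstrapConfig", "bootstrap_rank_ci"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: B replicates, CI level, seed, stratified resampling."""

    B: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ConfigError(f"B must be >= 1, got {self.B}")
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")


def bootstrap_rank_ci(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    config: BootstrapConfig = BootstrapConfig(),
) -> pd.DataFrame:
    """Percentile CI for each ROI's rank under subject resampling.

    ``values_a`` / ``values_b`` are harmonized subjects x ROIs matrices for
    the two groups (same ROI columns).  Returns a DataFrame indexed by ROI
    with columns ``rank`` (point estimate), ``ci_low``, ``ci_high``.
    Deterministic given ``config.seed``.
    """
    if list(values_a.columns) != list(values_b.columns):
        raise DataError("group tables have different ROI columns")
    a = values_a.to_numpy(dtype=float)
    b = values_b.to_numpy(dtype=float)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a == 0 or n_b == 0:
        raise DataError("empty group")
    n_roi = a.shape[1]

    point_rank = rank_rois(pd.Series(auroc_matrix(a, b), index=values_a.columns))

    rng = np.random.default_rng(config.seed)
    rep_ranks = np.empty((config.B, n_roi))
    pooled = np.vstack([a, b])
    for rep in range(config.B):
        if config.stratified:
            ra = a[rng.integers(0, n_a, n_a)]
            rb = b[rng.integers(0, n_b, n_b)]
        else:
            # pooled resampling keeps labels attached to subject rows; redraw
            # in the (rare) event one group comes up empty
            while True:
                idx = rng.integers(0, n_a + n_b, n_a + n_b)
                ra, rb = pooled[idx[idx < n_a]], pooled[idx[idx >= n_a]]
                if len(ra) and len(rb):
                    break
        aur = auroc_matrix(ra, rb)
        rep_ranks[rep] = stats.rankdata(-aur)

    alpha = 1.0 - config.ci_level
    lo, hi = np.percentile(rep_ranks, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    lo = np.minimum(np.floor(lo), np.floor(point_rank.to_numpy()))
    hi = np.maximum(np.ceil(hi), np.ceil(point_rank.to_numpy()))
    lo = np.clip(lo, 1, n_roi)
    hi = np.clip(hi, 1, n_roi)
    return pd.DataFrame(
        {"rank": point_rank, "ci_low": lo, "ci_high": hi},
        index=pd.Index(values_a.columns, name="roi"),
    )
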
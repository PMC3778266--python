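"""Amyloid-status classification and propensity-score matching.

Subjects carry a continuous global amyloid-PET ratio (cortical-to-cerebellar
tracer retention).  A cut-point rule dichotomizes it into negative/positive,
optionally excluding an intermediate band of borderline values — the two
sensitivity variants being a lower cut-point (1.4) and removal of the
1.3-1.5 band.  A ratio exactly at the cut-point classifies as positive, and
the exclusion band is treated as a closed interval; both conventions are
deterministic tie-breaks for boundaries the negative/positive definitions
("< cut" / "> cut") leave open.

The amyloid-positive normals are then compared against an equally sized set
of amyloid-negative normals matched on age, sex and education via a logistic
propensity model and greedy 1:1 nearest-neighbor matching without
replacement on the logit of the propensity score, treated subjects processed
in descending propensity order (hardest-to-match first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, DataError

__all__ = ["CutpointRule", "classify_amyloid", "fit_propensity", "match_one_to_one", "MatchResult"]

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass(frozen=True)
class CutpointRule:
    """Amyloid positivity rule: cut-point plus optional closed exclusion band."""

    cutpoint: float = 1.5
    exclusion_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cutpoint <= 0:
            raise ConfigError(f"cutpoint must be > 0, got {self.cutpoint}")
        if self.exclusion_band is not None:
            lo, hi = self.exclusion_band
            if not lo < hi:
                raise ConfigError(f"exclusion_band low must be < high, got {self.exclusion_band}")


def classify_amyloid(pib_ratio, rule: CutpointRule = CutpointRule()):
    """Classify ratio(s) as 'negative' | 'positive' | 'excluded'.

    Scalar in, scalar out; array-like in, ndarray of strings out.  Values
    inside the exclusion band (inclusive bounds) are 'excluded'; otherwise
    positive iff ratio >= cutpoint.
    """
    arr = np.asarray(pib_ratio, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise DataError("pib_ratio must be positive and finite")
    out = np.where(arr >= rule.cutpoint, "positive", "negative").astype(object)
    if rule.exclusion_band is not None:
        lo, hi = rule.exclusion_band
        out[(arr >= lo) & (arr <= hi)] = "excluded"
    return out[0] if scalar else np.asarray(out, dtype=str)


def _design_matrix(subjects: pd.DataFrame, covariates) -> pd.DataFrame:
    missing = [c for c in covariates if c not in subjects.columns]
    if missing:
        raise DataError(f"missing covariate columns: {missing}")
    X = subjects[list(covariates)].copy()
    for c in covariates:
        if X[c].dtype == object or str(X[c].dtype) == "category":
            codes, _ = pd.factorize(X[c], sort=True)
            X[c] = codes.astype(float)
    X = X.astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise DataError(f"missing covariate values in columns: {bad}")
    return X


def fit_propensity(
    subjects: pd.DataFrame,
    treatment: pd.Series,
    covariates=DEFAULT_COVARIATES,
) -> pd.Series:
    """Fitted probability of treatment given covariates (logistic model).

    ``subjects`` is indexed by subject_id with covariate columns; categorical
    covariates (e.g. sex as 'F'/'M') are factor-coded.  Falls back to an
    L2-penalized fit with a warning if the MLE does not exist (perfect
    separation).
    """
    y = pd.Series(treatment).reindex(subjects.index).astype(float)
    if y.isna().any():
        raise DataError("treatment indicator missing for some subjects")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise DataError("need at least 2 subjects in each arm")
    X = _design_matrix(subjects, covariates)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0)
            prob = np.asarray(fit.predict(Xc))
        except Exception:
            warnings.simplefilter("always")
            warnings.warn(
                "logistic MLE failed (possible perfect separation); "
                "falling back to L2-penalized fit",
                stacklevel=2,
            )
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, max_iter=1000)
            lr.fit(X.to_numpy(), y.to_numpy())
            prob = lr.predict_proba(X.to_numpy())[:, 1]
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return pd.Series(prob, index=subjects.index, name="propensity")


@dataclass
class MatchResult:
    """1:1 matching outcome: (treated, control) pairs plus bookkeeping."""

    pairs: list[tuple[str, str]]
    propensity: pd.Series
    unmatched: list[str] = field(default_factory=list)

    @property
    def treated_ids(self) -> list[str]:
        return [t for t, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


def match_one_to_one(
    propensity: pd.Series,
    treated_ids,
    control_ids,
    seed: int = 0,
) -> MatchResult:
    """Greedy nearest-neighbor 1:1 matching without replacement on logit(propensity).

    Treated subjects are processed in descending propensity order; each takes
    the unused control with the smallest |logit difference|.  The seed only
    breaks exact distance (and ordering) ties, so re-running with the same
    seed reproduces the pairs exactly.
    """
    treated_ids = list(treated_ids)
    control_ids = list(control_ids)
    if not treated_ids or not control_ids:
        raise DataError("empty treated or control arm")
    p = propensity.reindex(treated_ids + control_ids)
    if p.isna().any():
        raise DataError("propensity missing for some subjects")
    logit = np.log(p / (1 - p))

    rng = np.random.default_rng(seed)
    # random secondary key -> seeded tie-break in both orderings
    t_tie = rng.random(len(treated_ids))
    order = sorted(
        range(len(treated_ids)),
        key=lambda i: (-p.loc[treated_ids[i]], t_tie[i]),
    )
    c_logit = logit.loc[control_ids].to_numpy()
    used = np.zeros(len(control_ids), dtype=bool)
    c_tie = rng.random(len(control_ids))

    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for i in order:
        if used.all():
            unmatched.append(treated_ids[i])
            continue
        d = np.abs(c_logit - logit.loc[treated_ids[i]])
        d[used] = np.inf
        best = np.flatnonzero(d == d.min())
        j = best[np.argmin(c_tie[best])] if len(best) > 1 else best[0]
        used[j] = True
        pairs.append((treated_ids[i], control_ids[j]))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} treated subjects unmatched (control pool exhausted)",
            stacklevel=2,
        )
    return MatchResult(pairs=pairs, propensity=p, unmatched=unmatched)
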
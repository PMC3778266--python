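import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from roiconcord import CutpointRule, classify_amyloid, fit_propensity, match_one_to_one
from roiconcord.errors import ConfigError, DataError


class TestClassifyAmyloid:
    @pytest.mark.parametrize(
        "ratio,rule,expected",
        [
            (1.62, CutpointRule(1.5), "positive"),
            (1.49, CutpointRule(1.5), "negative"),
            (1.40, CutpointRule(1.5, (1.3, 1.5)), "excluded"),
            (1.50, CutpointRule(1.5), "positive"),  # boundary -> positive
            (1.30, CutpointRule(1.5, (1.3, 1.5)), "excluded"),  # band bounds inclusive
            (1.29, CutpointRule(1.5, (1.3, 1.5)), "negative"),
            (1.45, CutpointRule(1.4), "positive"),
        ],
    )
    def test_rules(self, ratio, rule, expected):
        assert classify_amyloid(ratio, rule) == expected

    def test_vectorized(self):
        out = classify_amyloid([1.2, 1.4, 1.8], CutpointRule(1.5, (1.3, 1.5)))
        assert list(out) == ["negative", "excluded", "positive"]

    def test_nonpositive_ratio_raises(self):
        with pytest.raises(DataError):
            classify_amyloid(0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ConfigError):
            CutpointRule(1.5, (1.5, 1.3))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.5, 3.0), st.floats(0.5, 3.0))
    def test_monotone_in_ratio(self, r1, r2):
        rule = CutpointRule(1.5)
        lo, hi = sorted([r1, r2])
        order = {"negative": 0, "positive": 1}
        assert order[classify_amyloid(lo, rule)] <= order[classify_amyloid(hi, rule)]


class TestFitPropensity:
    def test_no_signal_gives_prevalence(self, rng):
        n = 200
        subj = pd.DataFrame(
            {
                "age": np.tile(rng.normal(75, 5, n // 2), 2),
                "sex": np.tile(rng.choice(["F", "M"], n // 2), 2),
                "education": np.tile(rng.normal(14, 2, n // 2), 2),
            },
            index=[f"s{i}" for i in range(n)],
        )
        treat = pd.Series([0] * (n // 2) + [1] * (n // 2), index=subj.index)
        prob = fit_propensity(subj, treat)
        assert prob.between(0, 1).all()
        assert prob.mean() == pytest.approx(0.5, abs=1e-6)
        assert prob.std() < 1e-6  # identical covariate distributions -> flat

    def test_matches_independent_optimizer(self):
        subj = pd.DataFrame({"age": [60.0, 75.0, 70.0, 85.0]}, index=list("abcd"))
        treat = pd.Series([0, 0, 1, 1], index=subj.index)
        prob = fit_propensity(subj, treat, covariates=("age",))
        X = np.column_stack([np.ones(4), subj["age"]])
        y = treat.to_numpy(float)

        def nll(beta):
            eta = X @ beta
            return np.sum(np.logaddexp(0.0, eta)) - y @ eta

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        expected = 1.0 / (1.0 + np.exp(-(X @ opt.x)))
        np.testing.assert_allclose(prob.to_numpy(), expected, atol=1e-6)
        assert (np.diff(prob.loc[subj.sort_values("age").index]) > 0).all()

    def test_perfect_separation_falls_back_with_warning(self):
        subj = pd.DataFrame({"age": [60.0, 65.0, 80.0, 85.0]}, index=list("abcd"))
        treat = pd.Series([0, 0, 1, 1], index=subj.index)
        with pytest.warns(UserWarning, match="separation"):
            prob = fit_propensity(subj, treat, covariates=("age",))
        assert prob.between(0, 1).all()

    def test_missing_covariate_raises(self):
        subj = pd.DataFrame({"age": [60.0, 61.0, 62.0, 63.0]}, index=list("abcd"))
        with pytest.raises(DataError, match="education"):
            fit_propensity(subj, pd.Series([0, 0, 1, 1], index=subj.index))


class TestMatchOneToOne:
    def test_equal_propensities_full_pairing_zero_distance(self):
        ids = [f"t{i}" for i in range(4)] + [f"c{i}" for i in range(6)]
        prop = pd.Series(0.4, index=ids)
        res = match_one_to_one(prop, ids[:4], ids[4:], seed=1)
        assert len(res.pairs) == 4
        assert len(set(res.control_ids)) == 4

    def test_equal_counts_every_control_used(self, rng):
        t_ids = [f"t{i}" for i in range(10)]
        c_ids = [f"c{i}" for i in range(10)]
        prop = pd.Series(rng.uniform(0.1, 0.9, 20), index=t_ids + c_ids)
        res = match_one_to_one(prop, t_ids, c_ids, seed=0)
        assert sorted(res.control_ids) == sorted(c_ids)

    def test_toy_matches_best_greedy_order(self):
        prop = pd.Series(
            {"t1": 0.80, "t2": 0.65, "t3": 0.55,
             "c1": 0.78, "c2": 0.70, "c3": 0.52, "c4": 0.45, "c5": 0.30}
        )
        logit = np.log(prop / (1 - prop))
        treated, controls = ["t1", "t2", "t3"], ["c1", "c2", "c3", "c4", "c5"]

        def greedy_total(order):
            used, total = set(), 0.0
            for t in order:
                best = min(
                    (c for c in controls if c not in used),
                    key=lambda c: abs(logit[c] - logit[t]),
                )
                used.add(best)
                total += abs(logit[best] - logit[t])
            return total

        best = min(greedy_total(p) for p in itertools.permutations(treated))
        res = match_one_to_one(prop, treated, controls, seed=0)
        mine = sum(abs(logit[c] - logit[t]) for t, c in res.pairs)
        assert mine == pytest.approx(best)

    def test_seed_reproducibility(self, rng):
        ids = [f"s{i}" for i in range(40)]
        prop = pd.Series(rng.uniform(0.2, 0.8, 40), index=ids)
        r1 = match_one_to_one(prop, ids[:15], ids[15:], seed=9)
        r2 = match_one_to_one(prop, ids[:15], ids[15:], seed=9)
        assert r1.pairs == r2.pairs

    def test_control_shortfall_warns(self, rng):
        ids = [f"s{i}" for i in range(10)]
        prop = pd.Series(rng.uniform(0.2, 0.8, 10), index=ids)
        with pytest.warns(UserWarning, match="unmatched"):
            res = match_one_to_one(prop, ids[:7], ids[7:], seed=0)
        assert len(res.pairs) == 3 and len(res.unmatched) == 4

    def test_empty_arm_raises(self):
        with pytest.raises(DataError):
            match_one_to_one(pd.Series({"a": 0.5}), [], ["a"])


def test_matching_reduces_covariate_imbalance(rng):
    """Matching on a cohort with a +3 year age imbalance shrinks the
    standardized mean difference relative to the unmatched comparison."""
    n = 500
    age_t = rng.normal(78, 5, n // 2)
    age_c = rng.normal(75, 5, n)
    subj = pd.DataFrame(
        {
            "age": np.concatenate([age_t, age_c]),
            "sex": rng.choice(["F", "M"], n // 2 + n),
            "education": rng.normal(14, 2.5, n // 2 + n),
        },
        index=[f"s{i}" for i in range(n // 2 + n)],
    )
    t_ids = list(subj.index[: n // 2])
    c_ids = list(subj.index[n // 2:])
    treat = pd.Series(subj.index.isin(t_ids), index=subj.index)
    prob = fit_propensity(subj, treat)
    res = match_one_to_one(prob, t_ids, c_ids, seed=3)

    def smd(a, b):
        return abs(a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)

    before = smd(subj.loc[t_ids, "age"], subj.loc[c_ids, "age"])
    after = smd(subj.loc[res.treated_ids, "age"], subj.loc[res.control_ids, "age"])
    assert after <= before
    assert after < 0.1  # well balanced after matching
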
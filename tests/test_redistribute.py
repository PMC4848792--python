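import numpy as np
import pandas as pd
import pytest

from gcredist.causes import CAUSE_IDS, garbage_id
from gcredist.model import FitResult, ModelParameters
from gcredist.redistribute import (
    StratumPrediction,
    counts_by_category,
    fallback_prediction,
    flow_table,
    integerize_counts,
    predict_probs,
    redistribute_hard,
    redistribute_proportional,
)
from gcredist.strata import Stratum

from conftest import make_dataset

J = len(CAUSE_IDS)


def _counts(garbage="heart_failure", n_garbage=10.0, valid=None):
    s = pd.Series({c: 0.0 for c in CAUSE_IDS}, dtype=float)
    for c, v in (valid or {}).items():
        s[c] = v
    s[garbage_id(garbage)] = n_garbage
    return s


def _prediction(probs, garbage="heart_failure", targets=("B.2", "B.3.1", "B.3.2"),
                sex="male"):
    probs = np.asarray(probs, dtype=float)
    return StratumPrediction(
        stratum=Stratum(10, sex, "70-74", garbage),
        ids=tuple(f"g{i}" for i in range(len(probs))),
        targets=tuple(targets),
        dropped_targets=(),
        probs=probs,
    )


class TestPredictProbs:
    def test_zero_params_uniform(self):
        ds = make_dataset(
            [0, 1], targets=("B.2", "B.3.1", "B.3.2", "B.3.3"),
            pred=(["p1"], [0.0], np.zeros((1, J)), [0], [0], [0]),
        )
        fit = FitResult(
            mode="MAP", stratum_key=ds.stratum.key, targets=ds.targets,
            params=ModelParameters.zeros(4, J, 1, 1, 1), seed=0,
        )
        sp = predict_probs(fit, ds)
        np.testing.assert_allclose(sp.probs, [[0.25] * 4])

    def test_large_gamma_concentrates_mass(self):
        jstar = 7
        M = np.zeros((1, J))
        M[0, jstar] = 1
        ds = make_dataset(
            [0, 1], targets=("B.2", "B.3.1"),
            pred=(["p1"], [0.0], M, [0], [0], [0]),
        )
        p = ModelParameters.zeros(2, J, 1, 1, 1)
        p.gamma[1, jstar] = 40.0
        fit = FitResult(mode="MAP", stratum_key=ds.stratum.key, targets=ds.targets,
                        params=p, seed=0)
        sp = predict_probs(fit, ds)
        np.testing.assert_allclose(sp.probs, [[0.0, 1.0]], atol=1e-12)

    def test_matches_hand_computed_softmax(self):
        # 3 prediction records; oracle computed with explicit exp sums
        jstar = 2
        M = np.zeros((3, J))
        M[1, jstar] = 1
        ds = make_dataset(
            [0, 1], targets=("B.2", "B.3.1"),
            pred=(["a", "b", "c"], [0.0, 0.0, 1.0], M, [0] * 3, [0] * 3, [0] * 3),
        )
        p = ModelParameters.zeros(2, J, 1, 1, 1)
        p.alpha[1] = 0.5
        p.beta[1] = -1.0
        p.gamma[1, jstar] = 2.0
        fit = FitResult(mode="MAP", stratum_key=ds.stratum.key, targets=ds.targets,
                        params=p, seed=0)
        sp = predict_probs(fit, ds)
        for i, theta2 in enumerate([0.5, 2.5, -0.5]):
            expected = np.exp(theta2) / (1 + np.exp(theta2))
            assert sp.probs[i, 1] == pytest.approx(expected, abs=1e-12)

    def test_stratum_mismatch_raises(self):
        ds = make_dataset([0, 1])
        fit = FitResult(mode="MAP", stratum_key="other", targets=ds.targets,
                        params=ModelParameters.zeros(2, J, 1, 1, 1), seed=0)
        with pytest.raises(ValueError, match="stratum"):
            predict_probs(fit, ds)


class TestProportional:
    def test_identical_deaths_linear(self):
        pred = _prediction(np.tile([0.5, 0.3, 0.2], (10, 1)))
        res = redistribute_proportional([pred], _counts(n_garbage=10))
        got = res.flows.set_index("target")["deaths"]
        np.testing.assert_allclose(got[["B.2", "B.3.1", "B.3.2"]], [5, 3, 2])

    def test_no_garbage_identity(self):
        counts = _counts(n_garbage=0, valid={"B.2": 7})
        res = redistribute_proportional([], counts)
        pd.testing.assert_series_equal(res.counts_after, counts.astype(float))

    def test_conservation_across_strata(self):
        p1 = _prediction(np.tile([1.0, 0.0, 0.0], (2, 1)), sex="male")
        p2 = _prediction(np.tile([0.0, 0.5, 0.5], (2, 1)), sex="female")
        counts = _counts(n_garbage=4)
        res = redistribute_proportional([p1, p2], counts)
        assert res.ledger["residual"] == pytest.approx(0.0, abs=1e-9)
        assert res.counts_after[garbage_id("heart_failure")] == 0.0
        per_stratum = res.flows.groupby("sex")["deaths"].sum()
        np.testing.assert_allclose(per_stratum, [2.0, 2.0])

    def test_bad_probability_rows_rejected(self):
        pred = _prediction([[0.5, 0.3, 0.1]])
        with pytest.raises(ValueError, match="sum to 1"):
            redistribute_proportional([pred], _counts(n_garbage=1))


class TestHard:
    def test_argmax_assignment(self):
        pred = _prediction(np.tile([0.5, 0.3, 0.2], (4, 1)))
        res = redistribute_hard([pred], _counts(n_garbage=4))
        got = res.flows.set_index("target")["deaths"]
        np.testing.assert_allclose(got[["B.2", "B.3.1", "B.3.2"]], [4, 0, 0])

    def test_tie_breaks_to_lower_canonical_index(self):
        pred = _prediction([[0.5, 0.5]], targets=("B.2", "B.3.1"))
        res = redistribute_hard([pred], _counts(n_garbage=1))
        got = res.flows.set_index("target")["deaths"]
        assert got["B.2"] == 1.0 and got["B.3.1"] == 0.0

    def test_hard_and_proportional_conserve_same_total(self):
        probs = np.array([[0.6, 0.3, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        counts = _counts(n_garbage=3, valid={"B.4": 5})
        prop = redistribute_proportional([_prediction(probs)], counts)
        hard = redistribute_hard([_prediction(probs)], counts)
        assert prop.counts_after.sum() == pytest.approx(hard.counts_after.sum())
        assert prop.counts_after.sum() == pytest.approx(8.0)


class TestFlowTable:
    def test_single_stratum_shares_equal_mean_probability(self):
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
        res = redistribute_proportional([_prediction(probs)], _counts(n_garbage=2))
        ft = flow_table(res)
        np.testing.assert_allclose(
            ft.set_index("target")["share_of_garbage"][["B.2", "B.3.1", "B.3.2"]],
            probs.mean(axis=0),
        )

    def test_two_equal_strata_pool_evenly(self):
        p1 = _prediction(np.tile([1.0, 0.0], (3, 1)), targets=("B.2", "B.3.1"), sex="male")
        p2 = _prediction(np.tile([0.0, 1.0], (3, 1)), targets=("B.2", "B.3.1"), sex="female")
        res = redistribute_proportional([p1, p2], _counts(n_garbage=6))
        pooled = flow_table(res).set_index("target")["share_of_garbage"]
        np.testing.assert_allclose(pooled[["B.2", "B.3.1"]], [0.5, 0.5])
        by_sex = flow_table(res, by=("sex",))
        males = by_sex[by_sex.sex == "male"].set_index("target")["share_of_garbage"]
        np.testing.assert_allclose(males[["B.2", "B.3.1"]], [1.0, 0.0])

    def test_invalid_grouping_key_raises(self):
        res = redistribute_proportional(
            [_prediction(np.tile([1.0, 0.0], (1, 1)), targets=("B.2", "B.3.1"))],
            _counts(n_garbage=1),
        )
        with pytest.raises(ValueError, match="group"):
            flow_table(res, by=("place",))


def test_proportional_equals_expected_hard_assignment_small_mc():
    # quick version of the categorical-resampling equivalence (fuller check
    # with 1e5 draws lives in the acceptance suite)
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.ones(3), size=5)
    pred = _prediction(probs)
    prop = redistribute_proportional([pred], _counts(n_garbage=5))
    draws = np.array([
        np.bincount([rng.choice(3, p=p) for p in probs], minlength=3)
        for _ in range(2000)
    ])
    mc = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
    expected = prop.flows.set_index("target")["deaths"][["B.2", "B.3.1", "B.3.2"]].values
    assert np.all(np.abs(mc - expected) < 4 * se + 1e-9)


def test_counts_by_category(icd10_map):
    from gcredist.records import ContributingEntry, DeathRecord, categorize

    records = [
        DeathRecord(id="a", year=2005, age=70, sex="male", state="WA", race="R1",
                    place="home", revision=10, underlying="I219", contributing=()),
        DeathRecord(id="b", year=2005, age=70, sex="male", state="WA", race="R1",
                    place="home", revision=10, underlying="I500", contributing=()),
    ]
    crs = [categorize(r, icd10_map) for r in records]
    counts = counts_by_category(crs)
    assert counts["B.3.1"] == 1.0
    assert counts[garbage_id("heart_failure")] == 1.0
    assert counts.sum() == 2.0


def test_integerize_preserves_total():
    counts = pd.Series({"a": 2.6, "b": 3.6, "c": 3.8})
    out = integerize_counts(counts)
    assert out.sum() == 10
    assert out["c"] == 4


def test_fallback_prediction_rows_are_shares():
    fp = fallback_prediction(
        Stratum(10, "male", "70-74", "heart_failure"),
        ids=("a", "b"), targets=("B.2", "B.3.1"), shares=np.array([0.25, 0.75]),
    )
    assert fp.source == "fallback"
    np.testing.assert_allclose(fp.probs.sum(axis=1), 1.0)
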
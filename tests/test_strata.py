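import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcredist.causes import garbage_id
from gcredist.records import ContributingEntry, DeathRecord, categorize
from gcredist.strata import (
    AGE_GROUPS,
    Stratum,
    age_group,
    build_stratum_dataset,
    fallback_shares,
    occupied_strata,
)


class TestAgeGroup:
    @pytest.mark.parametrize(
        "age,expected",
        [(0, "<1"), (1, "1-4"), (3, "1-4"), (4, "1-4"), (5, "5-9"),
         (72, "70-74"), (84, "80-84"), (85, "85+"), (103, "85+")],
    )
    def test_examples(self, age, expected):
        assert age_group(age) == expected

    def test_negative_age_raises(self):
        with pytest.raises(ValueError):
            age_group(-1)

    def test_nineteen_bins(self):
        assert len(AGE_GROUPS) == 19
        assert AGE_GROUPS[0] == "<1" and AGE_GROUPS[-1] == "85+"

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=120))
    def test_partition_and_monotone(self, age):
        label = age_group(age)
        assert label in AGE_GROUPS
        if age < 120:
            assert AGE_GROUPS.index(age_group(age + 1)) >= AGE_GROUPS.index(label)


def _rec(rid, underlying, contributing=(), sex="male", age=72, revision=10, year=2005):
    return DeathRecord(
        id=rid, year=year, age=age, sex=sex, state="WA", race="R1",
        place="inpatient", revision=revision, underlying=underlying,
        contributing=tuple(ContributingEntry(*c) for c in contributing),
    )


@pytest.fixture
def categorized(icd10_map):
    records = [
        # training candidate: IHD underlying, heart failure contributing
        _rec("t1", "I219", [(1, 1, "I500"), (2, 1, "J449")]),
        # training candidate: stroke underlying, heart failure contributing
        _rec("t2", "I639", [(1, 1, "I500")]),
        # lung-cancer underlying with HF contributing: not an HF target
        _rec("x1", "C349", [(1, 1, "I500")]),
        # HF contributing only on line 6: not in training
        _rec("x2", "I219", [(6, 1, "I500")]),
        # garbage underlying -> prediction set
        _rec("p1", "I500", [(1, 1, "E119")]),
        # garbage underlying, wrong sex -> different stratum
        _rec("x3", "I500", [], sex="female"),
        # valid underlying, no garbage listed -> nowhere
        _rec("x4", "I219", []),
    ]
    return [categorize(r, icd10_map) for r in records]


class TestBuildStratumDataset:
    def setup_method(self):
        self.stratum = Stratum(10, "male", "70-74", "heart_failure")

    def test_training_membership(self, categorized, target_matrix):
        ds = build_stratum_dataset(categorized, self.stratum, target_matrix, min_training=1)
        assert ds.n_train == 2          # t1, t2 only
        assert ds.n_pred == 1           # p1 only
        assert ds.pred_ids == ("p1",)

    def test_outcome_indices_map_to_surviving_targets(self, categorized, target_matrix):
        ds = build_stratum_dataset(categorized, self.stratum, target_matrix, min_training=1)
        # only B.3.1 and B.3.2 observed -> 2 surviving targets
        assert ds.targets == ("B.3.1", "B.3.2")
        assert set(ds.dropped_targets) == {"B.2", "B.3.3", "B.4", "B.5", "B.6", "B.7"}
        assert sorted(ds.y.tolist()) == [0, 1]

    def test_prediction_and_training_disjoint(self, categorized, target_matrix):
        ds = build_stratum_dataset(categorized, self.stratum, target_matrix, min_training=1)
        assert set(ds.pred_ids).isdisjoint({"t1", "t2"})

    def test_small_stratum_flagged_unfittable(self, categorized, target_matrix):
        ds = build_stratum_dataset(categorized, self.stratum, target_matrix, min_training=50)
        assert not ds.fittable
        assert "below threshold" in ds.unfittable_reason

    def test_line6_garbage_does_not_recruit_training(self, categorized, target_matrix):
        ds = build_stratum_dataset(categorized, self.stratum, target_matrix, min_training=1)
        # x2 lists heart failure only on line 6
        assert ds.n_train == 2

    def test_features_have_consistent_shapes(self, categorized, target_matrix):
        ds = build_stratum_dataset(categorized, self.stratum, target_matrix, min_training=1)
        assert ds.M.shape == (2, 25)
        assert ds.pred_M.shape == (1, 25)
        assert len(ds.state_levels) >= 1


def test_occupied_strata_covers_each_garbage_death_once(icd10_map):
    records = [
        _rec("g1", "I500"),
        _rec("g2", "I500", sex="female"),
        _rec("g3", "R99", age=3),
        _rec("v1", "I219"),
    ]
    crs = [categorize(r, icd10_map) for r in records]
    strata = occupied_strata(crs)
    keys = {s.key for s in strata}
    assert keys == {
        "icd10_male_70-74_heart_failure",
        "icd10_female_70-74_heart_failure",
        "icd10_male_1-4_ill_defined",
    }


def test_fallback_shares_pools_adjacent_ages(icd10_map, target_matrix):
    # all training deaths sit in the 75-79 bin; the 70-74 stratum is empty
    records = [
        _rec(f"t{i}", "I219", [(1, 1, "I500")], age=77) for i in range(4)
    ] + [_rec("t9", "I639", [(1, 1, "I500")], age=77)]
    crs = [categorize(r, icd10_map) for r in records]
    stratum = Stratum(10, "male", "70-74", "heart_failure")
    targets, shares = fallback_shares(crs, stratum, target_matrix)
    assert targets == ("B.3.1", "B.3.2")
    np.testing.assert_allclose(shares, [0.8, 0.2])


def test_fallback_shares_margin_when_band_empty(icd10_map, target_matrix):
    records = [_rec("t1", "I219", [(1, 1, "I500")], age=20)]
    crs = [categorize(r, icd10_map) for r in records]
    stratum = Stratum(10, "male", "85+", "heart_failure")
    targets, shares = fallback_shares(crs, stratum, target_matrix)
    assert targets == ("B.3.1",) and shares[0] == 1.0
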
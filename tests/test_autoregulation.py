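"""Nomogram expectation, impairment classification and group comparison."""
import numpy as np
import pandas as pd
import pytest

from neonoxy import autoregulation as ar
from neonoxy.errors import DegenerateInputError, DomainError
from neonoxy.simulate import single_cause_observations


def _obs(**kw):
    defaults = dict(
        mBP=70.0,
        PaO2=100.0,
        PaCO2=40.0,
        SaO2=0.97,
        rcSO2=50.0,
        baseline_rcSO2=50.0,
        baseline_mBP=70.0,
    )
    defaults.update(kw)
    return ar.AutoregObservation(**defaults)


def test_expected_equals_baseline_on_plateau(nomogram):
    for mbp in (40.0, 55.0, 70.0, 90.0):
        for pao2 in (50.0, 80.0, 300.0):
            assert (
                ar.expected_rcso2(nomogram, mbp, pao2, 40.0, 50.4) == 50.4
            )


@pytest.mark.parametrize(
    "mbp, pao2, expected",
    [(30.0, 100.0, 45.0), (70.0, 30.0, 62.0)],
)
def test_expected_rcso2_plug_in(nomogram, mbp, pao2, expected):
    assert ar.expected_rcso2(nomogram, mbp, pao2, 40.0, 50.0) == pytest.approx(
        expected
    )


def test_expected_requires_baseline(nomogram):
    with pytest.raises(DomainError):
        ar.expected_rcso2(nomogram, 70.0, 100.0, 40.0, float("nan"))


def test_classify_intact_when_matching_nomogram(nomogram):
    res = ar.classify(_obs(), nomogram)
    assert res.label == "intact"
    assert res.deviation == 0.0


def test_classify_attributes_bp(nomogram):
    expected = ar.expected_rcso2(nomogram, 28.0, 95.0, 40.0, 50.0)
    res = ar.classify(
        _obs(mBP=28.0, PaO2=95.0, rcSO2=expected * 0.70), nomogram
    )
    assert res.label == "impaired_bp"


def test_classify_attributes_o2_when_dominant(nomogram):
    expected = ar.expected_rcso2(nomogram, 75.0, 32.0, 42.0, 50.0)
    res = ar.classify(
        _obs(mBP=75.0, baseline_mBP=78.0, PaO2=32.0, PaCO2=42.0,
             rcSO2=expected * 0.65),
        nomogram,
    )
    assert res.label == "impaired_o2"


def test_classify_positive_deviation_is_intact(nomogram):
    res = ar.classify(_obs(rcSO2=70.0), nomogram)
    assert res.label == "intact"
    assert res.deviation > 0


def test_classify_scale_invariance(nomogram):
    a = ar.classify(_obs(mBP=30.0, rcSO2=25.0, baseline_rcSO2=45.0), nomogram)
    b = ar.classify(_obs(mBP=30.0, rcSO2=50.0, baseline_rcSO2=90.0), nomogram)
    assert a.label == b.label
    assert a.deviation == pytest.approx(b.deviation)


def test_normocapnic_normotensive_never_blamed_on_co2_or_bp(nomogram):
    """With PaCO2 at reference and no hypotension, impairment can only be
    attributed to oxygen (or left unattributed)."""
    for pao2 in (20.0, 35.0, 49.0):
        res = ar.classify(
            _obs(PaO2=pao2, rcSO2=20.0, baseline_rcSO2=55.0), nomogram
        )
        assert res.label not in ("impaired_co2", "impaired_bp")


def test_unattributed_impairment_warns(nomogram):
    with pytest.warns(UserWarning, match="unattributed"):
        res = ar.classify(_obs(rcSO2=30.0, baseline_rcSO2=55.0), nomogram)
    assert res.label == "impaired_unattributed"


def test_chi2_identical_tables():
    stat, df, p = ar.compare_groups_chi2([10, 5, 3], [10, 5, 3])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_perfect_separation():
    stat, df, p = ar.compare_groups_chi2([10, 0], [0, 10])
    assert stat == pytest.approx(20.0)
    assert df == 1


def test_chi2_2x3_hand_computed():
    # observed [[8,6,2],[2,6,8]]; expected per cell from margins
    obs = np.array([[8.0, 6.0, 2.0], [2.0, 6.0, 8.0]])
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    by_hand = float(((obs - expected) ** 2 / expected).sum())
    stat, df, _ = ar.compare_groups_chi2(obs[0], obs[1])
    assert stat == pytest.approx(by_hand)
    assert df == 2


def test_chi2_zero_marginal_raises():
    with pytest.raises(DegenerateInputError, match="column"):
        ar.compare_groups_chi2([5, 0], [3, 0])
    with pytest.raises(DegenerateInputError, match="control"):
        ar.compare_groups_chi2([0, 0], [3, 2])


def test_attribute_cohort_all_intact(nomogram):
    df = pd.DataFrame(
        {
            "group": ["control"] * 4,
            "period": ["post1h", "post1h", "fio2_40", "fio2_40"],
            "mbp": 70.0,
            "pao2": 100.0,
            "paco2": 40.0,
            "sao2": 0.97,
            "rcso2": 50.0,
            "baseline_rcso2": 50.0,
            "baseline_mbp": 70.0,
        }
    )
    counts = ar.attribute_cohort(df, nomogram)
    assert (counts["intact"] == 2).all()
    assert counts[["impaired_bp", "impaired_o2", "impaired_co2"]].sum().sum() == 0


def test_attribute_cohort_forced_hypotension(nomogram):
    obs = single_cause_observations("bp", n=30, seed=7)
    obs["group"] = "oa"
    obs["period"] = "fio2_30"
    counts = ar.attribute_cohort(obs, nomogram)
    row = counts.loc[("oa", "fio2_30")]
    assert row["impaired_bp"] > row.drop("impaired_bp").max()


def test_classifier_sklearn_api(nomogram):
    from sklearn.base import clone

    clf = ar.AutoregulationClassifier(deviation_cut=0.25)
    assert clone(clf).get_params()["deviation_cut"] == 0.25
    clf.fit()
    obs = single_cause_observations("o2", n=20, seed=3)
    labels = clf.predict(obs)
    assert set(labels) <= {"intact", "impaired_o2", "impaired_bp",
                           "impaired_co2", "impaired_unattributed"}
    dev = clf.deviation(obs)
    assert dev.shape == (20,)
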
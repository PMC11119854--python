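"""Fractional oxygen extraction, baseline deltas, risk flags and binning."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neonoxy import nirs
from neonoxy.errors import DomainError, InsufficientDataError, SchemaError


@pytest.mark.parametrize(
    "sao2, rso2, expected",
    [(0.96, 0.48, 0.5), (0.7, 0.7, 0.0), (1.0, 0.45, 0.55)],
)
def test_foe_from_nirs(sao2, rso2, expected):
    assert nirs.foe_from_nirs(sao2, rso2) == pytest.approx(expected)


def test_foe_from_gases_example():
    assert nirs.foe_from_gases(0.95, 0.70) == pytest.approx(0.263, abs=5e-4)


def test_foe_zero_sao2_rejected():
    with pytest.raises(DomainError):
        nirs.foe_from_nirs(0.0, 0.0)


@given(
    st.floats(min_value=0.05, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_foe_complement_identity(s, r):
    """FOE(s, r) + r/s = 1 for every valid pair."""
    assert nirs.foe_from_nirs(s, r) + r / s == pytest.approx(1.0, abs=1e-9)


def test_nirs_and_gas_foe_slopes_agree_with_offset_venous():
    """When rSO2 tracks SvO2 plus a constant offset at fixed SaO2, the two
    FOE series decline with identical slope across FiO2 steps."""
    steps = np.arange(5, dtype=float)
    sao2 = np.full(5, 0.96)
    svo2 = 0.70 - 0.05 * steps
    rso2 = svo2 + 0.08
    s_nirs, *_ = nirs.fit_linear_trend(steps, nirs.foe_from_nirs(sao2, rso2))
    s_gas, *_ = nirs.fit_linear_trend(steps, nirs.foe_from_gases(sao2, svo2))
    assert s_nirs == pytest.approx(s_gas, abs=1e-12)


def _series(values, baseline=50.4):
    periods = ["baseline", "post1h", "fio2_40", "fio2_30", "fio2_21"]
    return pd.DataFrame(
        {
            "animal_id": "a1",
            "site": "brain",
            "period": periods[: len(values) + 1],
            "value": [baseline] + list(values),
        }
    )


def test_delta_from_baseline_printed_values():
    out = nirs.delta_from_baseline(_series([48.3, 47.5, 46.3, 41.2]))
    assert out["delta_rel"].iloc[0] == 0.0
    # control cerebral saturation falls 18% by room air
    assert out["delta_rel"].iloc[-1] == pytest.approx(-0.1825, abs=5e-4)
    oa = nirs.delta_from_baseline(_series([27.9], baseline=54.6))
    assert oa["delta_rel"].iloc[-1] == pytest.approx(-0.489, abs=5e-4)


def test_delta_missing_baseline_names_animal():
    df = _series([48.0])
    df = df[df["period"] != "baseline"]
    with pytest.raises(DomainError, match="a1"):
        nirs.delta_from_baseline(df)


def test_delta_scale_invariance():
    base = _series([45.0, 40.0, 35.0, 30.0])
    scaled = base.assign(value=base["value"] * 3.7)
    d1 = nirs.delta_from_baseline(base)["delta_rel"]
    d2 = nirs.delta_from_baseline(scaled)["delta_rel"]
    assert np.allclose(d1, d2)


@pytest.mark.parametrize(
    "rso2, baseline, below, drop",
    [
        (44.9, 50.0, True, False),
        (45.0, 45.0, False, False),  # strict inequalities at both boundaries
        (39.0, 50.0, True, True),
        (40.0, 50.0, True, False),  # exactly a 20% drop is not flagged
    ],
)
def test_flag_risk(rso2, baseline, below, drop):
    flags = nirs.flag_risk(rso2, baseline)
    assert flags.below_45 is below
    assert flags.drop_gt20 is drop


def test_bin_assignment_boundaries():
    assert nirs.assign_sao2_bin(95.0) == "95-100"
    assert nirs.assign_sao2_bin(94.999) == "90-95"
    assert nirs.assign_sao2_bin(90.0) == "90-95"
    assert nirs.assign_sao2_bin(85.0) == "85-90"
    assert nirs.assign_sao2_bin(84.999) == "<85"
    assert nirs.assign_sao2_bin(100.0) == "95-100"


def test_bin_by_sao2_counts_partition(rng):
    n = 80
    obs = pd.DataFrame(
        {
            "sao2": rng.uniform(70.0, 100.0, n),
            "rcso2": rng.uniform(25.0, 60.0, n),
            "group": rng.choice(["control", "oa"], n),
            "baseline": 50.0,
        }
    )
    table = nirs.bin_by_sao2(obs)
    assert int(table[["n_control", "n_oa"]].to_numpy().sum()) == n


def test_bin_by_sao2_missing_column():
    with pytest.raises(SchemaError):
        nirs.bin_by_sao2(pd.DataFrame({"sao2": [95.0]}))


def test_linear_trend_exact_and_errors():
    x = np.arange(5.0)
    slope, intercept, r2 = nirs.fit_linear_trend(x, 2.0 * x + 1.0)
    assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))
    with pytest.raises(InsufficientDataError):
        nirs.fit_linear_trend([0.0, 1.0], [0.0, 1.0])
    with pytest.raises(DomainError):
        nirs.fit_linear_trend([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def test_linear_trend_against_closed_form():
    """Five-point slope cross-checked against the normal-equation formulas."""
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([2.1, 2.9, 4.2, 4.8, 6.1])
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope, intercept, _ = nirs.fit_linear_trend(x, y)
    assert slope == pytest.approx(sxy / sxx, abs=1e-12)
    assert intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)
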
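"""Gas-exchange calculators and the shunt/V:Q forward model and fit."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neonoxy import gas_exchange as gx
from neonoxy.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
)


@pytest.mark.parametrize(
    "fio2, paco2, expected",
    [
        (1.0, 0.0, 713.0),
        (0.21, 40.0, 99.73),
        (0.5, 40.0, 306.5),
    ],
)
def test_alveolar_gas_equation(fio2, paco2, expected):
    assert gx.alveolar_po2(fio2, paco2) == pytest.approx(expected, abs=1e-9)


def test_alveolar_po2_domain_and_clamp():
    with pytest.raises(DomainError):
        gx.alveolar_po2(0.0, 40.0)
    with pytest.raises(DomainError):
        gx.alveolar_po2(1.2, 40.0)
    with pytest.warns(UserWarning):
        assert gx.alveolar_po2(0.21, 400.0) == 0.0


@pytest.mark.parametrize(
    "pao2_alv, pao2_art, expected",
    [(100.0, 100.0, 0.0), (99.73, 60.0, 39.73), (306.5, 80.0, 226.5)],
)
def test_aa_difference(pao2_alv, pao2_art, expected):
    assert gx.aa_difference(pao2_alv, pao2_art) == pytest.approx(expected)


def test_aa_difference_negative_warns():
    with pytest.warns(UserWarning, match="inconsistency"):
        assert gx.aa_difference(90.0, 100.0) == pytest.approx(-10.0)


@pytest.mark.parametrize(
    "pao2, fio2, expected",
    [(100.0, 0.5, 200.0), (100.0, 1.0, 100.0), (63.0, 0.21, 300.0)],
)
def test_pf_ratio(pao2, fio2, expected):
    assert gx.pf_ratio(pao2, fio2) == pytest.approx(expected)


def test_pf_ratio_rejects_zero_fio2():
    with pytest.raises(DomainError):
        gx.pf_ratio(100.0, 0.0)


def test_dissociation_curve_anchor_points():
    assert gx.hb_saturation(0.0) == 0.0
    assert gx.hb_saturation(26.9) == pytest.approx(0.50, abs=0.01)
    assert gx.hb_saturation(150.0) >= 0.98


@given(st.floats(min_value=1.0, max_value=600.0))
def test_dissociation_round_trip(po2):
    s = gx.hb_saturation(po2)
    assert gx.hb_po2(s) == pytest.approx(po2, rel=1e-6)


def test_hb_po2_domain():
    for bad in (0.0, 1.0, -0.1, 1.1):
        with pytest.raises(DomainError):
            gx.hb_po2(bad)


@pytest.mark.parametrize(
    "hb, so2, po2, expected",
    [(0.0, 0.0, 0.0, 0.0), (12.0, 1.0, 100.0, 16.38), (10.0, 0.5, 40.0, 6.82)],
)
def test_o2_content(hb, so2, po2, expected):
    assert gx.o2_content(hb, so2, po2) == pytest.approx(expected)


@given(
    st.floats(min_value=0.0, max_value=20.0),
    st.floats(min_value=0.0, max_value=20.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=600.0),
)
def test_o2_content_linear_in_hb(hb1, hb2, so2, po2):
    """Bound-oxygen term is linear in hemoglobin at fixed SO2 and PO2."""
    c1 = gx.o2_content(hb1, so2, po2)
    c2 = gx.o2_content(hb2, so2, po2)
    csum = gx.o2_content(hb1 + hb2, so2, po2)
    dissolved = gx.o2_content(0.0, so2, po2)
    assert csum == pytest.approx(c1 + c2 - dissolved, abs=1e-9)


@pytest.mark.parametrize(
    "cc, ca, cv, expected",
    [(20.0, 20.0, 15.0, 0.0), (20.0, 15.0, 15.0, 1.0), (20.0, 18.0, 15.0, 0.4)],
)
def test_shunt_equation(cc, ca, cv, expected):
    assert gx.shunt_equation(cc, ca, cv) == pytest.approx(expected)


def test_shunt_equation_degenerate_and_scaling():
    with pytest.raises(DegenerateInputError):
        gx.shunt_equation(15.0, 18.0, 20.0)
    # invariant under common rescaling of all three contents
    for k in (0.5, 2.0, 7.3):
        assert gx.shunt_equation(20.0 * k, 18.0 * k, 15.0 * k) == pytest.approx(
            0.4
        )


def test_predict_sao2_no_defect_limit(constants):
    for fio2 in (0.21, 0.3, 0.5, 1.0):
        expected = gx.hb_saturation(gx.alveolar_po2(fio2, 40.0, constants))
        assert gx.predict_sao2(fio2, 0.0, 0.0, 40.0, constants) == pytest.approx(
            expected, abs=1e-8
        )


def test_predict_sao2_monotonicity(constants):
    """Non-decreasing in FiO2; non-increasing in shunt and in V:Q shift."""
    fio2s = np.array([0.21, 0.3, 0.4, 0.5, 0.7, 1.0])
    qs = np.array([0.0, 0.1, 0.2, 0.3, 0.5])
    vs = np.array([0.0, 10.0, 30.0, 60.0, 120.0])
    for q in qs:
        for v in vs:
            sa = np.array(
                [gx.predict_sao2(f, q, v, 40.0, constants) for f in fio2s]
            )
            assert np.all(np.diff(sa) >= -1e-12)
    for f in (0.21, 0.5):
        for v in (0.0, 30.0):
            sa = np.array(
                [gx.predict_sao2(f, q, v, 40.0, constants) for q in qs]
            )
            assert np.all(np.diff(sa) <= 1e-12)
        for q in (0.1, 0.3):
            sa = np.array(
                [gx.predict_sao2(f, q, v, 40.0, constants) for v in vs]
            )
            assert np.all(np.diff(sa) <= 1e-12)


def test_predict_sao2_monotone_in_shunt_example(constants):
    assert gx.predict_sao2(0.21, 0.4, 30.0, 45.0) < gx.predict_sao2(
        0.21, 0.2, 30.0, 45.0
    )


def test_predict_sao2_domain_errors():
    with pytest.raises(DomainError):
        gx.predict_sao2(0.0, 0.1, 0.0, 40.0)
    with pytest.raises(DomainError):
        gx.predict_sao2(0.5, 1.5, 0.0, 40.0)
    with pytest.raises(DomainError):
        gx.predict_sao2(0.5, 0.1, -5.0, 40.0)


_STEP_FIO2 = (0.5, 0.4, 0.3, 0.21)


def _noiseless_steps(q, v, paco2=40.0):
    return [(f, gx.predict_sao2(f, q, v, paco2), paco2) for f in _STEP_FIO2]


@pytest.mark.parametrize("q", [0.05, 0.2, 0.35])
@pytest.mark.parametrize("v", [0.0, 20.0, 60.0])
def test_fit_recovers_noiseless_parameters(q, v):
    """The fit inverts the forward model exactly on noiseless 4-step data."""
    fit = gx.fit_shunt_vq(_noiseless_steps(q, v))
    assert fit.converged
    assert fit.qs_qt == pytest.approx(q, abs=0.01)
    assert fit.vq_shift == pytest.approx(v, abs=2.0)


def test_fit_healthy_lung_limit():
    steps = [(f, 1.0, 40.0) for f in _STEP_FIO2]
    with pytest.warns(UserWarning, match="unidentifiable"):
        fit = gx.fit_shunt_vq(steps)
    assert fit.qs_qt == 0.0


def test_fit_requires_two_distinct_steps():
    with pytest.raises(InsufficientDataError):
        gx.fit_shunt_vq([(0.5, 0.95, 40.0)])
    with pytest.raises(InsufficientDataError):
        gx.ShuntVQEstimator().fit(
            [[0.5, 40.0], [0.5, 40.0]], [0.95, 0.95]
        )


def test_fit_accepts_percent_scale():
    steps = _noiseless_steps(0.2, 20.0)
    percent = [(f, s * 100.0, p) for f, s, p in steps]
    fit = gx.fit_shunt_vq(percent)
    assert fit.qs_qt == pytest.approx(0.2, abs=0.01)


def test_estimator_sklearn_api():
    from sklearn.base import clone

    est = gx.ShuntVQEstimator(qs_qt_max=0.5)
    assert clone(est).get_params()["qs_qt_max"] == 0.5
    steps = np.asarray(_noiseless_steps(0.25, 10.0))
    est.fit(steps[:, [0, 2]], steps[:, 1])
    pred = est.predict(steps[:, [0, 2]])
    assert pred == pytest.approx(steps[:, 1], abs=1e-4)
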
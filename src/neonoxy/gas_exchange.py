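"""Oxygen transport calculators and shunt/V:Q estimation from FiO2 step-downs.

The centrepiece is a two-parameter forward model of the classic shunt
diagram: arterial saturation as a function of inspired oxygen, given an
intrapulmonary right-to-left shunt fraction (Qs/Qt) and a rightward
displacement of the FiO2-SaO2 curve standing in for reduced ventilation:
perfusion matching. Fitting that model to a small number of FiO2 steps
(typically 50 -> 40 -> 30 -> 21%) recovers both parameters, which is how
oxygenation defects are quantified from step-down protocols when direct
multi-gas techniques are unavailable.

Model outline
-------------
1. Alveolar PO2 from the simplified alveolar gas equation
   ``PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ``.
2. End-capillary PO2 of ventilated lung ``Pc = max(PAO2 - vq_shift, 0)``;
   end-capillary content via the Severinghaus dissociation curve.
3. Mixed arterial content ``Ca = (1 - Qs/Qt) * Cc + (Qs/Qt) * Cv`` with the
   venous content closed by an assumed arteriovenous difference,
   ``Cv = max(Ca - avDO2, 0)``, solved by damped fixed-point iteration.
4. Arterial SaO2 back-computed by inverting the content relation
   ``Ca = 1.34 * Hb * S(P) + 0.003 * P`` for P (monotone; bisection).
"""
from __future__ import annotations

import warnings
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "GasSample",
    "OxygenationIndices",
    "ShuntFit",
    "SampleSite",
    "alveolar_po2",
    "aa_difference",
    "pf_ratio",
    "hb_saturation",
    "hb_po2",
    "o2_content",
    "shunt_equation",
    "predict_sao2",
    "fit_shunt_vq",
    "ShuntVQEstimator",
    "normalize_so2",
]

_FIXED_POINT_TOL = 1e-8  # mL O2/dL, on successive arterial-content updates
_FIXED_POINT_MAX_ITER = 100
_FIXED_POINT_DAMPING = 0.7
_BISECT_ITER = 90


class SampleSite(str, Enum):
    arterial = "arterial"
    svc_venous = "svc_venous"
    ivc_venous = "ivc_venous"


#: NIRS region validated by venous samples from each site: SVC drains the
#: brain; IVC drains gut and kidney.
SITE_NIRS_REGIONS = {
    SampleSite.arterial: (),
    SampleSite.svc_venous: ("brain",),
    SampleSite.ivc_venous: ("gut", "kidney"),
}


class GasSample(BaseModel):
    """One blood-gas panel at one measurement period."""

    site: SampleSite
    pH: float
    PO2: float = Field(gt=0, description="mmHg")
    PCO2: float = Field(gt=0, description="mmHg")
    SO2: float = Field(ge=0, le=1, description="fraction")
    HCO3: float = Field(description="mmol/L")
    Hb: Optional[float] = Field(default=None, gt=0, description="g/dL")

    model_config = {"frozen": True}


class OxygenationIndices(BaseModel):
    """Alveolar PO2, A-a difference and P/F ratio for one period."""

    PAO2: float
    AaDiff: float
    PFratio: float
    period: str = ""


class ShuntFit(BaseModel):
    """Result of fitting the two-parameter shunt/V:Q forward model."""

    qs_qt: float = Field(ge=0, le=1)
    vq_shift: float = Field(ge=0, description="mmHg")
    rss: float = Field(ge=0)
    n_points: int = Field(ge=2)
    converged: bool


def normalize_so2(values) -> np.ndarray:
    """Normalize saturations given as percent or fraction to fraction.

    Values <= 1 are taken as fractions, values > 2 as percent. Values in
    (1, 2] are ambiguous on either scale and rejected.
    """
    arr = np.asarray(values, dtype=float)
    if np.any((arr > 1.0) & (arr <= 2.0)):
        raise DomainError(
            "saturation values in (1, 2] are ambiguous: neither a valid "
            "fraction nor a plausible percent"
        )
    if np.any(arr < 0) or np.any(arr > 100.0):
        raise DomainError("saturation values must lie in [0, 1] or [0, 100]")
    return np.where(arr > 2.0, arr / 100.0, arr)


def _maybe_scalar(x, template):
    return float(x) if np.ndim(template) == 0 else x


def alveolar_po2(
    fio2, paco2, constants: PhysioConstants = DEFAULT_CONSTANTS
):
    """Alveolar PO2 (mmHg) from the simplified alveolar gas equation.

    ``PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ``, clamped at zero with a
    warning when the formula goes negative (severe hypercapnia at low FiO2).
    """
    fio2_a = np.asarray(fio2, dtype=float)
    paco2_a = np.asarray(paco2, dtype=float)
    if np.any(fio2_a <= 0) or np.any(fio2_a > 1):
        raise DomainError("fio2 must lie in (0, 1]")
    if np.any(paco2_a < 0):
        raise DomainError("paco2 must be non-negative")
    pao2 = fio2_a * (constants.Pb - constants.PH2O) - paco2_a / constants.RQ
    if np.any(pao2 < 0):
        warnings.warn(
            "alveolar gas equation produced negative PAO2; clamped to 0",
            stacklevel=2,
        )
        pao2 = np.maximum(pao2, 0.0)
    return _maybe_scalar(pao2, fio2)


def aa_difference(pao2_alveolar, pao2_arterial):
    """Alveolar-arterial PO2 difference (mmHg).

    Negative values (arterial exceeding alveolar) are physically
    inconsistent measurements and flagged with a warning but returned.
    """
    a = np.asarray(pao2_alveolar, dtype=float)
    b = np.asarray(pao2_arterial, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("PO2 values must be non-negative")
    diff = a - b
    if np.any(diff < 0):
        warnings.warn(
            "negative A-a difference: arterial PO2 exceeds alveolar PO2 "
            "(measurement inconsistency)",
            stacklevel=2,
        )
    return _maybe_scalar(diff, pao2_alveolar)


def pf_ratio(pao2, fio2):
    """PaO2:FiO2 ratio (mmHg), FiO2 as fraction."""
    fio2_a = np.asarray(fio2, dtype=float)
    if np.any(fio2_a <= 0) or np.any(fio2_a > 1):
        raise DomainError("fio2 must lie in (0, 1]")
    return _maybe_scalar(np.asarray(pao2, float) / fio2_a, pao2)


def _sat_severinghaus(po2: np.ndarray) -> np.ndarray:
    po2 = np.asarray(po2, dtype=float)
    denom = po2**3 + 150.0 * po2
    with np.errstate(divide="ignore"):
        s = 1.0 / (1.0 + 23400.0 / denom)
    return np.where(denom > 0, s, 0.0)


def hb_saturation(po2):
    """Oxyhemoglobin saturation (fraction) at a given PO2 (mmHg).

    Severinghaus closed form ``S = 1 / (1 + 23400 / (P^3 + 150 P))``:
    monotone increasing, S(0) = 0, S -> 1 as P -> infinity.
    """
    if np.any(np.asarray(po2, float) < 0):
        raise DomainError("po2 must be non-negative")
    return _maybe_scalar(_sat_severinghaus(po2), po2)


def hb_po2(so2):
    """Inverse dissociation curve: PO2 (mmHg) at a given saturation.

    Closed-form real root of the Severinghaus cubic; round-trips with
    :func:`hb_saturation` to better than 1e-6 relative on (0, 1).
    """
    s = np.asarray(so2, dtype=float)
    if np.any(s <= 0) or np.any(s >= 1):
        raise DomainError("so2 must lie strictly inside (0, 1)")
    a = 23400.0 * s / (1.0 - s)
    # depressed cubic P^3 + 150 P - a = 0; single real root via Cardano
    u = np.cbrt(a / 2.0 + np.sqrt(a * a / 4.0 + 125000.0))
    p = u - 50.0 / u
    return _maybe_scalar(p, so2)


def o2_content(
    hb, so2, po2, constants: PhysioConstants = DEFAULT_CONSTANTS
):
    """Oxygen content of blood (mL O2/dL): bound plus dissolved."""
    hb_a = np.asarray(hb, float)
    so2_a = np.asarray(so2, float)
    po2_a = np.asarray(po2, float)
    if np.any(hb_a < 0) or np.any(po2_a < 0):
        raise DomainError("hb and po2 must be non-negative")
    if np.any(so2_a < 0) or np.any(so2_a > 1):
        raise DomainError("so2 must lie in [0, 1]")
    content = (
        constants.hb_O2_capacity * hb_a * so2_a
        + constants.dissolved_O2_coeff * po2_a
    )
    return _maybe_scalar(content, hb)


def shunt_equation(cc_o2, ca_o2, cv_o2):
    """Berggren shunt fraction ``Qs/Qt = (Cc - Ca) / (Cc - Cv)``.

    Clamped to [0, 1] with a warning when the raw ratio falls outside.
    """
    cc = float(cc_o2)
    ca = float(ca_o2)
    cv = float(cv_o2)
    if cc <= cv:
        raise DegenerateInputError(
            "end-capillary content must exceed mixed-venous content "
            f"(cc={cc}, cv={cv})"
        )
    q = (cc - ca) / (cc - cv)
    if q < 0 or q > 1:
        warnings.warn(
            f"shunt fraction {q:.3f} outside [0, 1]; clamped", stacklevel=2
        )
        q = min(max(q, 0.0), 1.0)
    return q


def _invert_content(
    ca: np.ndarray, hb: float, constants: PhysioConstants
) -> np.ndarray:
    """Solve Ca = cap*Hb*S(P) + alpha*P for P >= 0 (vectorized bisection)."""
    ca = np.asarray(ca, dtype=float)
    lo = np.zeros_like(ca)
    hi = np.maximum(700.0, ca / constants.dissolved_O2_coeff + 1.0)
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        f = (
            constants.hb_O2_capacity * hb * _sat_severinghaus(mid)
            + constants.dissolved_O2_coeff * mid
            - ca
        )
        hi = np.where(f >= 0, mid, hi)
        lo = np.where(f >= 0, lo, mid)
    return np.where(ca <= 0, 0.0, 0.5 * (lo + hi))


def _predict_core(
    fio2,
    qs_qt,
    vq_shift,
    paco2,
    constants: PhysioConstants,
):
    """Vectorized forward model. Returns (sao2, pao2) arrays."""
    fio2, qs_qt, vq_shift, paco2 = np.broadcast_arrays(
        np.asarray(fio2, float),
        np.asarray(qs_qt, float),
        np.asarray(vq_shift, float),
        np.asarray(paco2, float),
    )
    pao2_alv = np.maximum(
        fio2 * (constants.Pb - constants.PH2O) - paco2 / constants.RQ, 0.0
    )
    pc = np.maximum(pao2_alv - vq_shift, 0.0)
    hb = constants.Hb_default
    cc = (
        constants.hb_O2_capacity * hb * _sat_severinghaus(pc)
        + constants.dissolved_O2_coeff * pc
    )
    # damped fixed point on arterial content
    ca = cc.copy()
    converged = False
    for _ in range(_FIXED_POINT_MAX_ITER):
        cv = np.maximum(ca - constants.avDO2, 0.0)
        ca_next = (1.0 - qs_qt) * cc + qs_qt * cv
        step = ca_next - ca
        if np.max(np.abs(step)) < _FIXED_POINT_TOL:
            ca = ca_next
            converged = True
            break
        ca = ca + _FIXED_POINT_DAMPING * step
    if not converged:
        raise ConvergenceError(
            "arterial-content fixed point failed to converge in "
            f"{_FIXED_POINT_MAX_ITER} iterations"
        )
    pa = _invert_content(ca, hb, constants)
    sa = _sat_severinghaus(pa)
    return np.clip(sa, 0.0, 1.0), pa


def predict_sao2(
    fio2,
    qs_qt,
    vq_shift,
    paco2,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
):
    """Predicted arterial saturation (fraction) under the forward model.

    Monotone non-decreasing in ``fio2`` and non-increasing in ``qs_qt``
    and ``vq_shift``. Accepts scalars or broadcastable arrays.
    """
    fio2_a = np.asarray(fio2, float)
    q_a = np.asarray(qs_qt, float)
    v_a = np.asarray(vq_shift, float)
    p_a = np.asarray(paco2, float)
    if np.any(fio2_a <= 0) or np.any(fio2_a > 1):
        raise DomainError("fio2 must lie in (0, 1]")
    if np.any(q_a < 0) or np.any(q_a > 1):
        raise DomainError("qs_qt must lie in [0, 1]")
    if np.any(v_a < 0):
        raise DomainError("vq_shift must be non-negative")
    if np.any(p_a < 0):
        raise DomainError("paco2 must be non-negative")
    sa, _ = _predict_core(fio2_a, q_a, v_a, p_a, constants)
    if all(np.ndim(x) == 0 for x in (fio2, qs_qt, vq_shift, paco2)):
        return float(sa)
    return sa


def predict_sao2_pao2(
    fio2,
    qs_qt,
    vq_shift,
    paco2,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward model returning both SaO2 (fraction) and arterial PO2 (mmHg)."""
    return _predict_core(fio2, qs_qt, vq_shift, paco2, constants)


class ShuntVQEstimator(RegressorMixin, BaseEstimator):
    """Estimate shunt fraction and V:Q shift from FiO2-SaO2 observations.

    sklearn-style regressor. ``X`` has two columns ``(fio2, paco2)`` and
    ``y`` holds the measured SaO2 at each step (fraction or percent; percent
    is normalized at fit time). The loss surface over
    ``(qs_qt, vq_shift)`` is scanned exhaustively on a grid and the best
    cell refined by Nelder-Mead; the procedure is deterministic.

    Parameters
    ----------
    constants : PhysioConstants, optional
        Gas-exchange constants of the forward model.
    qs_qt_max, qs_qt_step : float
        Grid extent and spacing for the shunt fraction.
    vq_shift_max, vq_shift_step : float
        Grid extent (mmHg) and spacing for the V:Q displacement.
    refine : bool
        Run local Nelder-Mead refinement from the best grid cell.

    Attributes
    ----------
    qs_qt_ : float
        Estimated intrapulmonary shunt fraction.
    vq_shift_ : float
        Estimated rightward FiO2-SaO2 curve displacement, mmHg.
    rss_ : float
        Residual sum of squares on SaO2 (fraction scale).
    n_points_ : int
        Number of FiO2 steps used.
    converged_ : bool
        Whether the refinement converged (always True for pure grid search).
    """

    def __init__(
        self,
        constants: Optional[PhysioConstants] = None,
        qs_qt_max: float = 0.6,
        qs_qt_step: float = 0.01,
        vq_shift_max: float = 200.0,
        vq_shift_step: float = 2.0,
        refine: bool = True,
    ):
        self.constants = constants
        self.qs_qt_max = qs_qt_max
        self.qs_qt_step = qs_qt_step
        self.vq_shift_max = vq_shift_max
        self.vq_shift_step = vq_shift_step
        self.refine = refine

    def _constants(self) -> PhysioConstants:
        return self.constants if self.constants is not None else DEFAULT_CONSTANTS

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (fio2, paco2)")
        y = normalize_so2(np.asarray(y, dtype=float).ravel())
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        fio2, paco2 = X[:, 0], X[:, 1]
        if np.unique(fio2).size < 2:
            raise InsufficientDataError(
                "at least 2 distinct FiO2 steps are required to fit the "
                "shunt/V:Q model"
            )
        c = self._constants()

        if np.all(y >= 1.0 - 1e-12):
            warnings.warn(
                "all SaO2 readings at 1.0: shunt fraction unidentifiable; "
                "returning qs_qt = 0",
                stacklevel=2,
            )
            self.qs_qt_, self.vq_shift_ = 0.0, 0.0
            pred, _ = _predict_core(fio2, 0.0, 0.0, paco2, c)
            self.rss_ = float(np.sum((pred - y) ** 2))
            self.n_points_ = int(y.size)
            self.converged_ = True
            return self

        q_grid = np.arange(0.0, self.qs_qt_max + 1e-12, self.qs_qt_step)
        v_grid = np.arange(0.0, self.vq_shift_max + 1e-12, self.vq_shift_step)
        qq, vv = np.meshgrid(q_grid, v_grid, indexing="ij")
        sse = np.zeros_like(qq)
        for f_i, p_i, s_i in zip(fio2, paco2, y):
            pred, _ = _predict_core(f_i, qq, vv, p_i, c)
            sse += (pred - s_i) ** 2
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best_q, best_v, best_sse = q_grid[i], v_grid[j], sse[i, j]
        converged = True

        if self.refine:

            def objective(theta):
                q, v = theta
                if not (0.0 <= q <= 1.0) or v < 0.0:
                    return 1e6 + q * q + v * v
                pred, _ = _predict_core(fio2, q, v, paco2, c)
                return float(np.sum((pred - y) ** 2))

            res = minimize(
                objective,
                x0=[best_q, best_v],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400},
            )
            if res.fun <= best_sse:
                best_q, best_v = float(res.x[0]), float(res.x[1])
                best_sse = float(res.fun)
            converged = bool(res.success) or res.fun <= best_sse

        self.qs_qt_ = float(np.clip(best_q, 0.0, 1.0))
        self.vq_shift_ = float(max(best_v, 0.0))
        self.rss_ = float(best_sse)
        self.n_points_ = int(y.size)
        self.converged_ = bool(converged)
        return self

    def predict(self, X):
        if not hasattr(self, "qs_qt_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        sa, _ = _predict_core(
            X[:, 0], self.qs_qt_, self.vq_shift_, X[:, 1], self._constants()
        )
        return sa

    def result_(self) -> ShuntFit:
        """Fitted parameters packaged as a :class:`ShuntFit`."""
        return ShuntFit(
            qs_qt=self.qs_qt_,
            vq_shift=self.vq_shift_,
            rss=self.rss_,
            n_points=self.n_points_,
            converged=self.converged_,
        )


def fit_shunt_vq(
    steps: Iterable[Sequence[float]],
    constants: PhysioConstants = DEFAULT_CONSTANTS,
) -> ShuntFit:
    """Fit the shunt/V:Q model to ``(fio2, sao2, paco2)`` step observations."""
    steps = list(steps)
    if len(steps) < 2:
        raise InsufficientDataError(
            "at least 2 FiO2 steps are required; got %d" % len(steps)
        )
    arr = np.asarray(steps, dtype=float)
    est = ShuntVQEstimator(constants=constants)
    est.fit(arr[:, [0, 2]], arr[:, 1])
    return est.result_()


def oxygenation_indices(
    fio2,
    pao2_arterial,
    paco2,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    period: str = "",
) -> OxygenationIndices:
    """Bundle PAO2, A-a difference and P/F ratio for one measurement period."""
    pao2_alv = alveolar_po2(fio2, paco2, constants)
    return OxygenationIndices(
        PAO2=pao2_alv,
        AaDiff=aa_difference(pao2_alv, pao2_arterial),
        PFratio=pf_ratio(pao2_arterial, fio2),
        period=period,
    )
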
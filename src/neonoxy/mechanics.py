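"""Respiratory-system mechanics from ventilator waveforms and settings.

A passive ventilated breath obeys the single-compartment equation of
motion ``Paw(t) = V(t)/C + R * V'(t) + P0``: airway pressure decomposes
into an elastic term (volume over compliance), a resistive term (flow
times airway resistance) and the end-expiratory pressure. With pressure,
volume and flow sampled on a common grid, (1/C, R, P0) drop out of an
ordinary least-squares fit on the design matrix [V, V', 1].

Units are fixed throughout: volume mL, flow L/s, pressure cmH2O, so
C is mL/cmH2O and R is cmH2O.s/L; convert at ingest.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, IdentifiabilityError, InsufficientDataError

__all__ = [
    "VentWaveform",
    "MechanicsFit",
    "VentSettings",
    "fit_single_compartment",
    "static_compliance",
    "airway_resistance",
    "minute_ventilation",
    "synthetic_breath",
    "RespiratoryMechanicsEstimator",
]

_MIN_SAMPLES = 20


class VentWaveform(BaseModel):
    """One breath (or several) of airway pressure/flow/volume samples."""

    time: list[float]  # s, uniform grid
    flow: list[float]  # L/s
    volume: list[float]  # mL, zeroed at end-expiration
    paw: list[float]  # cmH2O

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "flow_lps": self.flow,
                "volume_ml": self.volume,
                "paw_cmh2o": self.paw,
            }
        )


class MechanicsFit(BaseModel):
    """Least-squares single-compartment fit."""

    C: float = Field(description="mL/cmH2O")
    R: float = Field(description="cmH2O.s/L")
    P0: float = Field(description="cmH2O")
    rss: float = Field(ge=0)
    n_samples: int


class VentSettings(BaseModel):
    """Ventilator settings / measured pressures for one period."""

    VT: float = Field(default=6.0, gt=0, description="mL/kg")
    PEEP: float = Field(default=6.0, gt=0, description="cmH2O")
    FiO2: float = Field(gt=0, le=1)
    Ti: float = Field(default=0.3, gt=0, description="s")
    RR: float = Field(gt=0, description="breaths/min")
    PIP: Optional[float] = Field(default=None, gt=0)
    MAP: Optional[float] = Field(default=None, gt=0)


def fit_single_compartment(waveform) -> MechanicsFit:
    """Fit (C, R, P0) to a sampled breath by ordinary least squares.

    ``waveform`` is a :class:`VentWaveform` or a DataFrame with columns
    ``flow_lps``, ``volume_ml``, ``paw_cmh2o``. A rank-deficient design
    (e.g. flow identically zero, or constant volume) raises
    :class:`IdentifiabilityError`.
    """
    if isinstance(waveform, VentWaveform):
        df = waveform.frame()
    else:
        df = pd.DataFrame(waveform)
    for col in ("flow_lps", "volume_ml", "paw_cmh2o"):
        if col not in df.columns:
            raise DomainError(f"waveform missing column {col!r}")
    v = np.asarray(df["volume_ml"], dtype=float)
    q = np.asarray(df["flow_lps"], dtype=float)
    p = np.asarray(df["paw_cmh2o"], dtype=float)
    n = v.size
    if n < _MIN_SAMPLES:
        raise InsufficientDataError(
            f"waveform has {n} samples; need >= {_MIN_SAMPLES}"
        )
    design = np.column_stack([v, q, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise IdentifiabilityError(
            "rank-deficient design: volume and flow do not independently "
            "vary (constant flow/volume?)"
        )
    beta, _, _, _ = np.linalg.lstsq(design, p, rcond=None)
    elastance, resistance, p0 = beta
    if elastance <= 0:
        raise IdentifiabilityError(
            "fitted elastance is non-positive; waveform is not consistent "
            "with a passive single-compartment breath"
        )
    residuals = p - design @ beta
    return MechanicsFit(
        C=float(1.0 / elastance),
        R=float(max(resistance, 0.0)),
        P0=float(p0),
        rss=float(residuals @ residuals),
        n_samples=int(n),
    )


def static_compliance(vt: float, pplat: float, peep: float) -> float:
    """Quasi-static compliance ``VT / (Pplat - PEEP)`` in mL/cmH2O."""
    if vt <= 0:
        raise DomainError("tidal volume must be positive")
    if pplat <= peep:
        raise DomainError(
            f"plateau pressure ({pplat}) must exceed PEEP ({peep})"
        )
    return vt / (pplat - peep)


def airway_resistance(pip: float, pplat: float, peak_flow: float) -> float:
    """Airway resistance ``(PIP - Pplat) / peak inspiratory flow``."""
    if peak_flow <= 0:
        raise DomainError("peak flow must be positive")
    if pip < pplat:
        raise DomainError("PIP must be >= plateau pressure")
    return (pip - pplat) / peak_flow


def minute_ventilation(vt_ml: float, rr: float) -> float:
    """Minute ventilation in L/min from tidal volume (mL) and rate (/min)."""
    if vt_ml <= 0 or rr <= 0:
        raise DomainError("tidal volume and rate must be positive")
    return vt_ml * rr / 1000.0


def synthetic_breath(
    c: float,
    r: float,
    p0: float,
    vt_ml: float = 12.6,
    ti: float = 0.3,
    te: float = 0.6,
    fs: float = 200.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Generate one passive breath obeying the equation of motion.

    Half-sine inspiratory flow delivering ``vt_ml`` over ``ti`` seconds,
    then passive exponential expiration with time constant R*C. Pressure is
    computed exactly from (C, R, P0), with optional Gaussian noise of SD
    ``noise_sd`` cmH2O added to the pressure channel only.
    """
    if c <= 0 or r < 0:
        raise DomainError("need C > 0 and R >= 0")
    t = np.arange(0.0, ti + te, 1.0 / fs)
    flow_ml_s = np.where(
        t < ti, vt_ml * np.pi / (2.0 * ti) * np.sin(np.pi * t / ti), 0.0
    )
    tau = max(r * c / 1000.0, 1e-6)  # s; R.C with mL/L conversion
    exp_mask = t >= ti
    volume = np.empty_like(t)
    insp = ~exp_mask
    volume[insp] = vt_ml * 0.5 * (1.0 - np.cos(np.pi * t[insp] / ti))
    volume[exp_mask] = vt_ml * np.exp(-(t[exp_mask] - ti) / tau)
    flow = np.where(exp_mask, -volume / tau, flow_ml_s) / 1000.0  # L/s
    paw = volume / c + r * flow + p0
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        paw = paw + rng.normal(0.0, noise_sd, size=paw.shape)
    return pd.DataFrame(
        {"time_s": t, "flow_lps": flow, "volume_ml": volume, "paw_cmh2o": paw}
    )


class RespiratoryMechanicsEstimator(RegressorMixin, BaseEstimator):
    """sklearn-style regressor for the single-compartment fit.

    ``X`` has columns ``(volume_ml, flow_lps)`` and ``y`` is airway
    pressure (cmH2O).

    Attributes
    ----------
    C_ : float
        Compliance, mL/cmH2O.
    R_ : float
        Resistance, cmH2O.s/L.
    P0_ : float
        End-expiratory pressure estimate, cmH2O.
    rss_ : float
        Residual sum of squares.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (volume_ml, flow_lps)")
        df = pd.DataFrame(
            {"volume_ml": X[:, 0], "flow_lps": X[:, 1], "paw_cmh2o": y}
        )
        res = fit_single_compartment(df)
        self.C_ = res.C
        self.R_ = res.R
        self.P0_ = res.P0
        self.rss_ = res.rss
        self.n_samples_ = res.n_samples
        return self

    def predict(self, X):
        if not hasattr(self, "C_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        return X[:, 0] / self.C_ + self.R_ * X[:, 1] + self.P0_
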
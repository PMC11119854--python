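"""Physiological constants used by the gas-exchange computations.

All values are standard clinical gas-exchange constants; every one is
configurable because the package targets neonatal piglets, whose hemoglobin
and barometric context may differ from adult-human textbook values.
"""
from __future__ import annotations

from pydantic import BaseModel, model_validator


class PhysioConstants(BaseModel):
    """Constants of the oxygen-transport model.

    Parameters
    ----------
    Pb : float
        Barometric pressure, mmHg.
    PH2O : float
        Saturated water vapour pressure at body temperature, mmHg.
    RQ : float
        Respiratory quotient (CO2 production / O2 consumption), unitless.
    Hb_default : float
        Hemoglobin concentration assumed when a sample does not carry one,
        g/dL. 10 g/dL is typical for a 5-day-old piglet.
    avDO2 : float
        Assumed whole-body arteriovenous oxygen content difference used to
        close the shunt forward model, mL O2/dL.
    hb_O2_capacity : float
        Oxygen-carrying capacity of hemoglobin (Hufner constant), mL O2/g.
    dissolved_O2_coeff : float
        Solubility of oxygen in plasma, mL O2/dL/mmHg.
    """

    Pb: float = 760.0
    PH2O: float = 47.0
    RQ: float = 0.8
    Hb_default: float = 10.0
    avDO2: float = 2.3
    hb_O2_capacity: float = 1.34
    dissolved_O2_coeff: float = 0.003

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_positive(self) -> "PhysioConstants":
        for name in type(self).model_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.Pb <= self.PH2O:
            raise ValueError("Pb must exceed PH2O")
        return self


DEFAULT_CONSTANTS = PhysioConstants()
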
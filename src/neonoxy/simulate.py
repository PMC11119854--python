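"""Synthetic piglet-cohort generator.

Simulates the study design the package analyzes: two groups (sham control
and oleic-acid lung injury), about 6-7 animals per group, ventilated at
fixed tidal volume with an FiO2 step-down 50 -> 40 -> 30 -> 21% and PaCO2
held near-constant. Injury is expressed mechanistically: an increased
intrapulmonary shunt fraction and right-shifted V:Q feeding the
gas-exchange forward model, reduced compliance and raised resistance
feeding the equation-of-motion waveform generator, and a cerebral
autoregulation deficit applied on top of the nomogram expectation for the
NIRS channels. Every generating parameter is exported as ground truth so
each upstream estimator can be tested by parameter recovery.

The generator emulates between-animal dispersion with independent Gaussian
draws whose defaults were sanity-checked against the between-animal
standard errors of the study tables; it does not emulate within-period
temporal dynamics, autocorrelated NIRS drift, or hemodynamic reflexes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .autoregulation import AutoregNomogram, expected_rcso2
from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .gas_exchange import hb_po2, predict_sao2_pao2
from .mechanics import synthetic_breath

__all__ = [
    "PERIODS",
    "PERIOD_FIO2",
    "AnimalConfig",
    "CohortDataset",
    "generate_animal",
    "generate_cohort",
    "single_cause_observations",
]

PERIODS = ("baseline", "post1h", "fio2_40", "fio2_30", "fio2_21")
PERIOD_FIO2 = {
    "baseline": 0.50,
    "post1h": 0.50,
    "fio2_40": 0.40,
    "fio2_30": 0.30,
    "fio2_21": 0.21,
}

# Group-level generating means. mBP follows the study's hemodynamics table;
# shunt/mechanics magnitudes are a moderate oleic-acid injury; cerebral
# deficits track the relative rcSO2 drops of the NIRS table.
_MBP_MEAN = {
    "control": (84.3, 81.7, 78.8, 74.8, 74.0),
    "oa": (77.3, 70.7, 68.4, 71.6, 70.3),
}
# anesthetized supine piglets carry a modest baseline V:Q defect, which is
# what lets healthy controls drift below 95% SaO2 at room air
_QS_QT = {"control": (0.05,) * 5, "oa": (0.05, 0.30, 0.30, 0.30, 0.30)}
_VQ_SHIFT = {"control": (20.0,) * 5, "oa": (20.0, 35.0, 35.0, 35.0, 35.0)}
_COMPLIANCE = {"control": (2.0,) * 5, "oa": (2.0, 1.0, 1.0, 1.0, 1.0)}
_RESISTANCE = {"control": (50.0,) * 5, "oa": (50.0, 80.0, 80.0, 80.0, 80.0)}
_PACO2_MEAN = {"control": 40.0, "oa": 45.0}
_BASELINE_RCSO2 = {"control": (50.4, 6.6), "oa": (54.6, 6.9)}  # mean, SD
_BASELINE_RGSO2 = {"control": (66.5, 10.0), "oa": (61.9, 10.0)}
_BASELINE_RRSO2 = {"control": (47.7, 8.0), "oa": (60.6, 8.0)}
_CEREBRAL_DEFICIT = {
    "control": (0.0, 0.03, 0.04, 0.07, 0.18),
    "oa": (0.0, 0.18, 0.22, 0.30, 0.49),
}
_GUT_DEFICIT = {
    "control": (0.0, 0.13, 0.13, 0.20, 0.30),
    "oa": (0.0, 0.14, 0.18, 0.28, 0.48),
}
_KIDNEY_DEFICIT = {
    "control": (0.0, 0.0, 0.0, 0.0, 0.05),
    "oa": (0.0, 0.13, 0.17, 0.22, 0.44),
}


class AnimalConfig(BaseModel):
    """Generating parameters for one simulated animal."""

    animal_id: str
    group: Literal["control", "oa"]
    weight: float = Field(default=2.1, gt=0, description="kg")
    qs_qt: Dict[str, float]
    vq_shift: Dict[str, float]
    compliance: Dict[str, float]
    resistance: Dict[str, float]
    p0: float = 6.0  # cmH2O, PEEP
    mbp: Dict[str, float]
    paco2: Dict[str, float]
    baseline_rcso2: float = Field(gt=0, le=100)
    baseline_rgso2: float = Field(gt=0, le=100)
    baseline_rrso2: float = Field(gt=0, le=100)
    cerebral_deficit: Dict[str, float]
    gut_deficit: Dict[str, float]
    kidney_deficit: Dict[str, float]
    nomogram: AutoregNomogram = AutoregNomogram()
    noise_sao2: float = 0.01  # SD, fraction
    noise_rso2: float = 2.0  # SD, percentage points
    noise_paw: float = 0.2  # SD, cmH2O
    seed: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_periods(self) -> "AnimalConfig":
        for name in (
            "qs_qt",
            "vq_shift",
            "compliance",
            "resistance",
            "mbp",
            "paco2",
            "cerebral_deficit",
            "gut_deficit",
            "kidney_deficit",
        ):
            mapping = getattr(self, name)
            if set(mapping) != set(PERIODS):
                raise ValueError(f"{name} must be keyed by the 5 periods")
        if self.group == "oa":
            if self.qs_qt["post1h"] <= self.qs_qt["baseline"]:
                raise ValueError(
                    "oa config must have qs_qt(post1h) > qs_qt(baseline)"
                )
            if self.compliance["post1h"] >= self.compliance["baseline"]:
                raise ValueError(
                    "oa config must have compliance(post1h) < baseline"
                )
        return self


@dataclass
class CohortDataset:
    """A simulated (or ingested) multi-animal dataset.

    ``data`` is wide-form, one row per (animal, period); ``waveforms`` maps
    (animal_id, period) to a breath DataFrame; ``ground_truth`` maps
    animal_id to its generating parameters (absent for ingested data).
    """

    data: pd.DataFrame
    waveforms: Dict[Tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    ground_truth: Dict[str, dict] = field(default_factory=dict)
    configs: List[AnimalConfig] = field(default_factory=list)


def _lus_scores(rng: np.random.Generator, injured: bool) -> int:
    if injured:
        zone_scores = rng.choice([1, 2, 3], size=8, p=[0.3, 0.5, 0.2])
    else:
        zone_scores = rng.choice([0, 1], size=8, p=[0.8, 0.2])
    return int(zone_scores.sum())


def generate_animal(
    config: AnimalConfig,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    with_waveforms: bool = True,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], pd.DataFrame], dict]:
    """Simulate one animal's records across the five measurement periods.

    Returns ``(rows, waveforms, truth)``. With all noise SDs at zero the
    stored SaO2 equals the gas-exchange forward model exactly and the
    cerebral NIRS equals the nomogram expectation scaled by the injected
    deficit.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    waveforms: Dict[Tuple[str, str], pd.DataFrame] = {}
    truth = {
        "group": config.group,
        "qs_qt": dict(config.qs_qt),
        "vq_shift": dict(config.vq_shift),
        "compliance": dict(config.compliance),
        "resistance": dict(config.resistance),
        "cerebral_deficit": dict(config.cerebral_deficit),
        "sao2_true": {},
        "rcso2_true": {},
    }
    for period in PERIODS:
        fio2 = PERIOD_FIO2[period]
        paco2 = config.paco2[period]
        mbp = config.mbp[period]
        sa_true_arr, pa_true_arr = predict_sao2_pao2(
            fio2,
            config.qs_qt[period],
            config.vq_shift[period],
            paco2,
            constants,
        )
        sa_true = float(sa_true_arr)
        pa_true = float(pa_true_arr)
        sao2 = float(
            np.clip(sa_true + rng.normal(0.0, config.noise_sao2), 0.01, 1.0)
        ) if config.noise_sao2 > 0 else sa_true
        pao2 = float(max(pa_true + rng.normal(0.0, 2.0), 5.0)) if config.noise_sao2 > 0 else pa_true

        expected = expected_rcso2(
            config.nomogram, mbp, pa_true, paco2, config.baseline_rcso2
        )
        rc_true = expected * (1.0 - config.cerebral_deficit[period])
        rg_true = config.baseline_rgso2 * (1.0 - config.gut_deficit[period])
        rr_true = config.baseline_rrso2 * (1.0 - config.kidney_deficit[period])
        noise = (
            rng.normal(0.0, config.noise_rso2, size=3)
            if config.noise_rso2 > 0
            else np.zeros(3)
        )
        rc = float(np.clip(rc_true + noise[0], 5.0, 95.0))
        rg = float(np.clip(rg_true + noise[1], 5.0, 95.0))
        rr = float(np.clip(rr_true + noise[2], 5.0, 95.0))

        # regional venous saturations: NIRS is venous-weighted, so the
        # noiseless regional saturation stands in for SvO2 of that bed
        svo2_svc = float(np.clip(rc_true / 100.0, 0.02, 0.98))
        svo2_ivc = float(np.clip((rg_true + rr_true) / 200.0, 0.02, 0.98))

        row = {
            "animal_id": config.animal_id,
            "group": config.group,
            "period": period,
            "fio2": fio2,
            "weight_kg": config.weight,
            "sao2": sao2,
            "pao2": pao2,
            "paco2": paco2,
            "ph": float(7.38 + rng.normal(0.0, 0.02)),
            "hco3": float(22.0 + rng.normal(0.0, 1.0)),
            "svo2_svc": svo2_svc,
            "pvo2_svc": hb_po2(svo2_svc),
            "svo2_ivc": svo2_ivc,
            "pvo2_ivc": hb_po2(svo2_ivc),
            "nirs_brain": rc,
            "nirs_gut": rg,
            "nirs_kidney": rr,
            "mbp": mbp,
            "hr": float(155.0 + rng.normal(0.0, 10.0)),
            "cvp": float(7.0 + rng.normal(0.0, 0.5)),
            "temp": float(37.4 + rng.normal(0.0, 0.2)),
            "lus_score": (
                float(
                    _lus_scores(
                        rng,
                        injured=(config.group == "oa" and period != "baseline"),
                    )
                )
                if period in ("baseline", "post1h")
                else np.nan
            ),
        }
        rows.append(row)
        truth["sao2_true"][period] = sa_true
        truth["rcso2_true"][period] = rc_true
        if with_waveforms:
            waveforms[(config.animal_id, period)] = synthetic_breath(
                config.compliance[period],
                config.resistance[period],
                config.p0,
                vt_ml=6.0 * config.weight,
                noise_sd=config.noise_paw,
                rng=rng,
            )
    return pd.DataFrame(rows), waveforms, truth


def _draw_config(
    group: str, animal_id: str, rng: np.random.Generator, seed: int
) -> AnimalConfig:
    mbp_offset = rng.normal(0.0, 7.0)
    deficit_jitter = rng.uniform(-0.03, 0.03, size=5)
    rc_mean, rc_sd = _BASELINE_RCSO2[group]
    rg_mean, rg_sd = _BASELINE_RGSO2[group]
    rr_mean, rr_sd = _BASELINE_RRSO2[group]

    def per_period(values, jitter=0.0):
        return {
            p: float(v) + (float(jitter[i]) if np.ndim(jitter) else 0.0)
            for i, (p, v) in enumerate(zip(PERIODS, values))
        }

    deficits = np.clip(
        np.asarray(_CEREBRAL_DEFICIT[group]) + deficit_jitter, 0.0, 0.9
    )
    deficits[0] = 0.0
    qjit = rng.normal(0.0, 0.02, size=5)
    qs = np.clip(np.asarray(_QS_QT[group]) + qjit, 0.01, 0.6)
    if group == "oa":
        qs[1:] = np.maximum(qs[1:], qs[0] + 0.05)
    vjit = rng.normal(0.0, 6.0)
    vq = np.clip(np.asarray(_VQ_SHIFT[group]) + vjit, 0.0, 200.0)
    return AnimalConfig(
        animal_id=animal_id,
        group=group,
        weight=float(np.clip(rng.normal(2.1, 0.25), 1.4, 3.0)),
        qs_qt={p: float(v) for p, v in zip(PERIODS, qs)},
        vq_shift={p: float(v) for p, v in zip(PERIODS, vq)},
        compliance=per_period(_COMPLIANCE[group]),
        resistance=per_period(_RESISTANCE[group]),
        mbp={
            p: float(m + mbp_offset + rng.normal(0.0, 2.0))
            for p, m in zip(PERIODS, _MBP_MEAN[group])
        },
        paco2={
            p: float(_PACO2_MEAN[group] + rng.normal(0.0, 1.5))
            for p in PERIODS
        },
        baseline_rcso2=float(np.clip(rng.normal(rc_mean, rc_sd), 40.0, 70.0)),
        baseline_rgso2=float(np.clip(rng.normal(rg_mean, rg_sd), 41.0, 90.0)),
        baseline_rrso2=float(np.clip(rng.normal(rr_mean, rr_sd), 40.0, 80.0)),
        cerebral_deficit={p: float(d) for p, d in zip(PERIODS, deficits)},
        gut_deficit=per_period(_GUT_DEFICIT[group]),
        kidney_deficit=per_period(_KIDNEY_DEFICIT[group]),
        seed=seed,
    )


def generate_cohort(
    n_control: int = 6,
    n_oa: int = 7,
    master_seed: int = 0,
    constants: PhysioConstants = DEFAULT_CONSTANTS,
    with_waveforms: bool = True,
) -> CohortDataset:
    """Simulate a full cohort; default sizes follow the study (6 + 7).

    Per-animal randomness derives deterministically from ``master_seed``
    via ``numpy.random.SeedSequence([master_seed, index])``; two cohorts
    generated with the same arguments are identical.
    """
    if n_control < 1 or n_oa < 1:
        raise ValueError("need at least one animal per group")
    frames, waveforms, truth, configs = [], {}, {}, []
    index = 0
    for group, n in (("control", n_control), ("oa", n_oa)):
        prefix = "c" if group == "control" else "o"
        for i in range(n):
            ss = np.random.SeedSequence([int(master_seed), index])
            rng = np.random.default_rng(ss)
            seed = int(ss.generate_state(2)[1] % (2**31))
            cfg = _draw_config(group, f"{prefix}{i + 1}", rng, seed)
            df, wf, tr = generate_animal(
                cfg, constants, with_waveforms=with_waveforms
            )
            frames.append(df)
            waveforms.update(wf)
            truth[cfg.animal_id] = tr
            configs.append(cfg)
            index += 1
    data = pd.concat(frames, ignore_index=True)
    return CohortDataset(
        data=data, waveforms=waveforms, ground_truth=truth, configs=configs
    )


def single_cause_observations(
    cause: Literal["bp", "o2", "co2"],
    n: int = 50,
    seed: int = 0,
    nomogram: AutoregNomogram = AutoregNomogram(),
) -> pd.DataFrame:
    """Observations with a single injected impairment cause, for recovery tests.

    Each row carries one physiological excursion (hypotension, hypoxemia or
    hypercapnia), all other factors held near nominal with measurement
    noise, and a cerebral deficit of 25-40% below the nomogram expectation.
    Columns match :class:`~neonoxy.autoregulation.AutoregulationClassifier`
    input plus ``true_cause``.
    """
    if cause not in ("bp", "o2", "co2"):
        raise ValueError("cause must be one of 'bp', 'o2', 'co2'")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        baseline_mbp = 75.0
        mbp = float(rng.normal(70.0, 3.0))
        pao2 = float(rng.normal(90.0, 8.0))
        paco2 = float(rng.normal(40.0, 1.0))
        if cause == "bp":
            mbp = float(rng.uniform(22.0, 34.0))
        elif cause == "o2":
            pao2 = float(rng.uniform(25.0, 42.0))
        else:
            paco2 = float(rng.uniform(48.0, 60.0))
        baseline = float(rng.normal(50.0, 5.0))
        expected = expected_rcso2(nomogram, mbp, pao2, paco2, baseline)
        deficit = float(rng.uniform(0.25, 0.40))
        rcso2 = max(expected * (1.0 - deficit) + rng.normal(0.0, 1.0), 5.0)
        rows.append(
            {
                "mbp": mbp,
                "pao2": pao2,
                "paco2": paco2,
                "sao2": float(np.clip(rng.normal(0.95, 0.02), 0.5, 1.0)),
                "rcso2": rcso2,
                "baseline_rcso2": baseline,
                "baseline_mbp": baseline_mbp,
                "true_cause": cause,
            }
        )
    return pd.DataFrame(rows)
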
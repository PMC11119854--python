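"""Cohort CSV schema, packaged reference tables, and the end-to-end report.

Interchange format is a single tidy long-form CSV, one row per
(animal, period, variable):

    animal_id,group,period,variable,value

Period labels come from the fixed five-element vocabulary
``baseline, post1h, fio2_40, fio2_30, fio2_21``. Saturation variables are
stored as fractions; NIRS variables as percent. ``read_cohort`` and
``write_cohort`` round-trip exactly.

The packaged reference tables (hemodynamics, regional NIRS means, and the
rcSO2-by-SaO2-range summary) are transcriptions of the study's printed
aggregate tables; ``load_table3_observations`` additionally provides a
synthetic observation-level reconstruction whose per-bin counts match the
printed summary, for exercising the binning pipeline end to end.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import gas_exchange, nirs
from .autoregulation import AutoregNomogram, attribute_cohort, compare_groups_chi2
from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .errors import DegenerateInputError, SchemaError
from .mechanics import fit_single_compartment
from .simulate import PERIOD_FIO2, PERIODS, CohortDataset

__all__ = [
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_table3_observations",
    "run_report",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("animal_id", "group", "period", "variable", "value")

#: variables holding saturations on the fraction scale
_FRACTION_VARS = ("sao2", "svo2_svc", "svo2_ivc", "fio2")
#: variables on the percent scale
_PERCENT_VARS = ("nirs_brain", "nirs_gut", "nirs_kidney")

_POST_PERIODS = ("post1h", "fio2_40", "fio2_30", "fio2_21")


def write_cohort(dataset: "CohortDataset | pd.DataFrame", path) -> Path:
    """Write a cohort to the tidy long-form CSV."""
    df = dataset.data if isinstance(dataset, CohortDataset) else dataset
    value_cols = [
        c for c in df.columns if c not in ("animal_id", "group", "period")
    ]
    long = df.melt(
        id_vars=["animal_id", "group", "period"],
        value_vars=value_cols,
        var_name="variable",
        value_name="value",
    ).sort_values(["animal_id", "period", "variable"], kind="stable")
    path = Path(path)
    long.to_csv(path, index=False)
    return path


def read_cohort(path, schema_version: int = 1) -> CohortDataset:
    """Read and validate a tidy long-form cohort CSV.

    Raises :class:`SchemaError` for missing mandatory columns (listing
    them), non-numeric values (with the offending row number), unknown
    period labels, and out-of-range saturations. Unknown variables are
    preserved with a warning.
    """
    if schema_version != 1:
        raise SchemaError(f"unknown schema version {schema_version}")
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    values = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw["value"]):
        if v == "":
            values[i] = np.nan
            continue
        try:
            values[i] = float(v)
        except ValueError:
            raise SchemaError(
                f"non-numeric value {v!r} in row {i + 2} of {path.name}"
            ) from None
    raw = raw.assign(value=values)

    bad_periods = set(raw["period"]) - set(PERIODS)
    if bad_periods:
        raise SchemaError(
            f"unknown period label(s) {sorted(bad_periods)}; "
            f"expected one of {list(PERIODS)}"
        )
    known = set(_FRACTION_VARS) | set(_PERCENT_VARS) | {
        "pao2", "paco2", "ph", "hco3", "pvo2_svc", "pvo2_ivc", "mbp", "hr",
        "cvp", "temp", "weight_kg", "lus_score",
    }
    unknown = set(raw["variable"]) - known
    if unknown:
        warnings.warn(
            f"unknown variable(s) preserved: {sorted(unknown)}", stacklevel=2
        )
    for var in _FRACTION_VARS:
        vals = raw.loc[raw["variable"] == var, "value"].dropna()
        if len(vals):
            try:
                gas_exchange.normalize_so2(vals.to_numpy())
            except Exception as err:
                raise SchemaError(f"variable {var!r}: {err}") from None
    for var in _PERCENT_VARS:
        vals = raw.loc[raw["variable"] == var, "value"].dropna()
        if len(vals) and (vals.min() < 0 or vals.max() > 100):
            raise SchemaError(f"variable {var!r} outside [0, 100] percent")

    wide = (
        raw.pivot_table(
            index=["animal_id", "group", "period"],
            columns="variable",
            values="value",
            aggfunc="first",
        )
        .reset_index()
        .rename_axis(columns=None)
    )
    for var in ("sao2", "svo2_svc", "svo2_ivc"):
        if var in wide.columns:
            wide[var] = gas_exchange.normalize_so2(wide[var].to_numpy())
    dup = wide.duplicated(subset=["animal_id", "period"])
    if dup.any():
        raise SchemaError("more than one record per (animal, period)")
    return CohortDataset(data=wide)


def _fixture(name: str) -> pd.DataFrame:
    with resources.as_file(
        resources.files("neonoxy.data").joinpath(name)
    ) as p:
        return pd.read_csv(p)


def load_table1() -> pd.DataFrame:
    """Group hemodynamic characteristics (mean/SE per group and period)."""
    return _fixture("table1_hemodynamics.csv")


def load_table2() -> pd.DataFrame:
    """Regional NIRS means (SE) per site, group and period."""
    return _fixture("table2_nirs.csv")


def load_table3() -> pd.DataFrame:
    """rcSO2 by SaO2 range: printed aggregate summary."""
    return _fixture("table3_sao2_bins.csv")


def load_table3_observations() -> pd.DataFrame:
    """Synthetic observation-level reconstruction of the SaO2-range table.

    Engineered so that per-(group, bin) N and >20%-drop counts equal the
    printed summary; individual saturations are synthetic.
    """
    return _fixture("table3_observations_synthetic.csv")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_report(
    cohort: CohortDataset,
    nomogram: Optional[AutoregNomogram] = None,
    constants: Optional[PhysioConstants] = None,
    outdir=None,
) -> dict:
    """Chain all analysis stages over a cohort and bundle the outputs.

    Stages: oxygenation indices per (animal, period); shunt/V:Q fit per
    animal over the post-injury FiO2 steps; FOE, baseline deltas and risk
    flags for the NIRS channels; the SaO2-range summary table;
    autoregulation attribution with per-step chi-squared group comparison;
    respiratory-mechanics fits where waveforms are present; and a
    lung-ultrasound summary. Deterministic given its inputs. With
    ``outdir`` set, every table is written as CSV/JSON alongside a manifest
    with content hashes.
    """
    nomogram = nomogram or AutoregNomogram()
    constants = constants or DEFAULT_CONSTANTS
    data = cohort.data
    report: dict = {}
    timings: dict = {}

    t0 = time.perf_counter()
    oxy = data.dropna(subset=["fio2", "pao2", "paco2"]).copy()
    pao2_alv = gas_exchange.alveolar_po2(
        oxy["fio2"].to_numpy(), oxy["paco2"].to_numpy(), constants
    )
    oxy["pao2_alveolar"] = pao2_alv
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oxy["aa_diff"] = pao2_alv - oxy["pao2"].to_numpy()
    oxy["pf_ratio"] = oxy["pao2"].to_numpy() / oxy["fio2"].to_numpy()
    report["oxygenation"] = oxy[
        ["animal_id", "group", "period", "fio2", "pao2_alveolar", "aa_diff",
         "pf_ratio"]
    ].reset_index(drop=True)
    timings["oxygenation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = []
    for animal, grp in data.groupby("animal_id", sort=True):
        steps = grp[grp["period"].isin(_POST_PERIODS)].dropna(
            subset=["fio2", "sao2", "paco2"]
        )
        if steps["fio2"].nunique() < 2:
            continue
        try:
            fit = gas_exchange.fit_shunt_vq(
                steps[["fio2", "sao2", "paco2"]].to_numpy(), constants
            )
        except Exception as err:  # propagate with stage context
            raise RuntimeError(f"shunt-fit stage failed for {animal}: {err}")
        fits.append(
            {
                "animal_id": animal,
                "group": grp["group"].iloc[0],
                "qs_qt": fit.qs_qt,
                "vq_shift": fit.vq_shift,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )
    report["shunt_fits"] = pd.DataFrame(fits)
    timings["shunt_fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    site_cols = {"brain": "nirs_brain", "gut": "nirs_gut", "kidney": "nirs_kidney"}
    foe_rows = []
    for _, row in data.iterrows():
        if not np.isfinite(row.get("sao2", np.nan)):
            continue
        for site, col in site_cols.items():
            rso2 = row.get(col, np.nan)
            if not np.isfinite(rso2):
                continue
            foe_rows.append(
                {
                    "animal_id": row["animal_id"],
                    "group": row["group"],
                    "period": row["period"],
                    "site": site,
                    "value": nirs.foe_from_nirs(row["sao2"], rso2 / 100.0),
                }
            )
    foe = pd.DataFrame(foe_rows)
    if not foe.empty:
        foe = nirs.delta_from_baseline(foe)
    report["foe"] = foe
    timings["foe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    baselines = (
        data[data["period"] == "baseline"]
        .set_index("animal_id")["nirs_brain"]
        .to_dict()
    )
    obs = data[data["period"].isin(_POST_PERIODS)].dropna(
        subset=["sao2", "nirs_brain"]
    )
    obs_tbl = pd.DataFrame(
        {
            "sao2": obs["sao2"].to_numpy() * 100.0,
            "rcso2": obs["nirs_brain"].to_numpy(),
            "group": obs["group"].to_numpy(),
            "baseline": [baselines[a] for a in obs["animal_id"]],
        }
    )
    flags = [
        nirs.flag_risk(r, b)
        for r, b in zip(obs_tbl["rcso2"], obs_tbl["baseline"])
    ]
    risk = obs[["animal_id", "group", "period"]].reset_index(drop=True).assign(
        rcso2=obs_tbl["rcso2"].to_numpy(),
        below_45=[f.below_45 for f in flags],
        drop_gt20=[f.drop_gt20 for f in flags],
        relative_drop=[f.relative_drop for f in flags],
    )
    report["risk_flags"] = risk
    report["sao2_bins"] = nirs.bin_by_sao2(obs_tbl)
    timings["binning"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    base_mbp = (
        data[data["period"] == "baseline"]
        .set_index("animal_id")["mbp"]
        .to_dict()
    )
    autoreg_obs = obs.reset_index(drop=True).assign(
        rcso2=obs["nirs_brain"].to_numpy(),
        baseline_rcso2=[baselines[a] for a in obs["animal_id"]],
        baseline_mbp=[base_mbp.get(a) for a in obs["animal_id"]],
    )
    counts = attribute_cohort(
        autoreg_obs[
            ["animal_id", "group", "period", "mbp", "pao2", "paco2", "sao2",
             "rcso2", "baseline_rcso2", "baseline_mbp"]
        ],
        nomogram,
    )
    report["autoreg_counts"] = counts
    chi2 = {}
    for period in _POST_PERIODS:
        try:
            c = counts.loc[("control", period)]
            o = counts.loc[("oa", period)]
        except KeyError:
            continue
        impaired_cols = [col for col in counts.columns if col != "intact"]
        table_c = {"intact": int(c.get("intact", 0)),
                   "impaired": int(sum(c.get(k, 0) for k in impaired_cols))}
        table_o = {"intact": int(o.get("intact", 0)),
                   "impaired": int(sum(o.get(k, 0) for k in impaired_cols))}
        try:
            stat, df_, p = compare_groups_chi2(table_c, table_o)
            chi2[period] = {"statistic": stat, "df": df_, "p": p}
        except DegenerateInputError as err:
            chi2[period] = {"statistic": None, "df": None, "p": None,
                            "note": str(err)}
    report["autoreg_chi2"] = chi2
    timings["autoregulation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mech_rows = []
    for (animal, period), wf in sorted(cohort.waveforms.items()):
        fit = fit_single_compartment(wf)
        mech_rows.append(
            {"animal_id": animal, "period": period, "C": fit.C, "R": fit.R,
             "P0": fit.P0, "rss": fit.rss}
        )
    report["mechanics"] = pd.DataFrame(mech_rows)
    timings["mechanics"] = time.perf_counter() - t0

    if "lus_score" in data.columns:
        lus = data.dropna(subset=["lus_score"])
        report["lus_summary"] = (
            lus.groupby(["group", "period"])["lus_score"]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )

    for stage, dt in timings.items():
        logger.info("stage %-14s %.3f s", stage, dt)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts = []
        for name, obj in report.items():
            if isinstance(obj, pd.DataFrame):
                p = outdir / f"{name}.csv"
                obj.to_csv(p)
            else:
                p = outdir / f"{name}.json"
                p.write_text(json.dumps(obj, indent=2, sort_keys=True))
            artifacts.append(
                {"name": name, "path": p.name, "sha256": _sha256(p)}
            )
        manifest = {"artifacts": artifacts}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        report["manifest"] = manifest
    return report
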
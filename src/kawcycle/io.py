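"""Table I/O with schema validation, bundled fixtures, and the pipeline.

All tables are comma-separated UTF-8 with mandatory headers and decimal
points (no locale handling).  Missing values are empty fields,
normalized to NaN on load.  Five schemas exist:

============  =================================================================
schema        columns
============  =================================================================
registry      abbreviation,name,cas,smiles,group,n_pfc,n_ch2
measurements  compound,method,replicate,mass,v_water,v_hxd,v_air,c_water,ph
headspace     compound,kind,v_tot,v_phase,peak_area
predictions   compound,model,log_kaw_pred,ad_flag
values        compound,quantity,method,log_k,ci_low,ci_high
============  =================================================================

The package ships the published measurement summary for the 21 PFAS as
a ``values`` fixture, the compound registry, and the five
batch/shared-headspace droplet pairs.

``run_pipeline`` binds everything: per-compound replicate inversion,
headspace fits, final-value selection, and the thermodynamic cycle to
log K_aw given a K_Hxd/air table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    LogPartitionCoefficient,
    Method,
    PhaseSystem,
    Quantity,
    ReplicateSet,
    SelectionPolicy,
    batch_k_from_water_conc,
    cycle_log_kaw,
    replicate_mean_ci,
    select_final_value,
    shared_headspace_k_from_water_conc,
)
from .exceptions import SchemaError
from .headspace import HeadspaceSeries, fit_modified_vprhs, fit_standard_vprhs

logger = logging.getLogger("kawcycle")

SCHEMAS: Dict[str, List[str]] = {
    "registry": ["abbreviation", "name", "cas", "smiles", "group",
                 "n_pfc", "n_ch2"],
    "measurements": ["compound", "method", "replicate", "mass", "v_water",
                     "v_hxd", "v_air", "c_water", "ph"],
    "headspace": ["compound", "kind", "v_tot", "v_phase", "peak_area"],
    "predictions": ["compound", "model", "log_kaw_pred", "ad_flag"],
    "values": ["compound", "quantity", "method", "log_k", "ci_low",
               "ci_high"],
}

_NUMERIC = {
    "registry": ["n_pfc", "n_ch2"],
    "measurements": ["replicate", "mass", "v_water", "v_hxd", "v_air",
                     "c_water", "ph"],
    "headspace": ["v_tot", "v_phase", "peak_area"],
    "predictions": ["log_kaw_pred"],
    "values": ["log_k", "ci_low", "ci_high"],
}

_KEYS = {
    "registry": ["abbreviation"],
    "measurements": ["compound", "method", "replicate"],
    "predictions": ["compound", "model"],
    "values": ["compound", "quantity", "method"],
}


def load_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`SchemaError` naming the offending row and column on
    header mismatch, non-numeric numeric fields, or duplicate keys.
    "NA" strings and empty fields load as NaN.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     na_values=["", "NA"])
    expected = SCHEMAS[schema]
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: header {list(df.columns)} != expected {expected}"
        )
    for col in _NUMERIC[schema]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}, line {row}"
            )
        df[col] = converted
    keys = _KEYS.get(schema)
    if keys and len(df):
        dup = df.duplicated(subset=keys)
        if dup.any():
            row = int(dup.idxmax()) + 2
            raise SchemaError(
                f"{path}: duplicate {tuple(keys)} key at line {row}"
            )
    return df


def save_table(df: pd.DataFrame, path, schema: Optional[str] = None) -> None:
    """Write a table as CSV; if ``schema`` is given, validate columns."""
    if schema is not None and list(df.columns) != SCHEMAS[schema]:
        raise SchemaError(
            f"columns {list(df.columns)} do not match schema {schema!r}"
        )
    df.to_csv(path, index=False)


def _fixture(name: str) -> pd.DataFrame:
    with resources.as_file(
        resources.files("kawcycle.data").joinpath(name)
    ) as p:
        schema = {
            "registry.csv": "registry",
            "partition_values.csv": "values",
        }.get(name)
        if schema:
            return load_table(p, schema)
        return pd.read_csv(p)


def load_registry() -> pd.DataFrame:
    """The bundled 21-compound PFAS registry."""
    return _fixture("registry.csv")


def load_measured_values() -> pd.DataFrame:
    """The bundled per-method measured log K table for the 21 PFAS.

    ``quantity`` is ``hxd/w`` for the hexadecane/water determinations
    (methods batch, shared_headspace, modified_vprhs) and ``aw`` for the
    derived (method cycle) and directly measured (standard_vprhs)
    air/water values.
    """
    return _fixture("partition_values.csv")


def load_droplet_pairs() -> pd.DataFrame:
    """The five (accurate, apparent) log K_Hxd/w pairs for droplet fitting."""
    return _fixture("droplet_pairs.csv")


@dataclass
class StudyBundle:
    """Everything one study run needs, bound together.

    Any component may be empty; the pipeline uses what is present.
    ``khxdair`` is a ``values`` table with quantity ``hxd/air`` feeding
    the thermodynamic cycle.
    """

    registry: pd.DataFrame
    measurements: Optional[pd.DataFrame] = None
    headspace: Optional[Sequence[HeadspaceSeries]] = None
    values: Optional[pd.DataFrame] = None
    predictions: Optional[pd.DataFrame] = None
    khxdair: Optional[pd.DataFrame] = None

    def validate(self) -> None:
        known = set(self.registry["abbreviation"])
        for name in ("measurements", "values", "predictions", "khxdair"):
            df = getattr(self, name)
            if df is None or not len(df):
                continue
            unknown = set(df["compound"]) - known
            if unknown:
                raise SchemaError(
                    f"{name}: unresolved compounds {sorted(unknown)}"
                )


@dataclass
class PipelineReport:
    """Side-channel of a pipeline run: warnings and skipped compounds."""

    warnings: List[str] = field(default_factory=list)
    skipped: List[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)


_METHOD_STR = {m.value for m in Method}


def _per_method_from_measurements(
    df: pd.DataFrame, compound: str, khxdair: Optional[float],
    confidence: float, report: PipelineReport,
) -> List[LogPartitionCoefficient]:
    out = []
    sub = df[df["compound"] == compound]
    for method_name, grp in sub.groupby("method"):
        if method_name not in (Method.BATCH.value,
                               Method.SHARED_HEADSPACE.value):
            report.warn(f"{compound}: unsupported method {method_name!r}")
            continue
        log_ks = []
        for _, row in grp.iterrows():
            system = PhaseSystem(
                v_water=row["v_water"], v_hxd=row["v_hxd"],
                v_air=0.0 if np.isnan(row["v_air"]) else row["v_air"],
                mass=row["mass"],
                ph=7.0 if np.isnan(row["ph"]) else row["ph"],
            )
            if method_name == Method.BATCH.value:
                k = batch_k_from_water_conc(system, row["c_water"])
            else:
                k = shared_headspace_k_from_water_conc(
                    system, row["c_water"], khxdair
                )
            log_ks.append(np.log10(k))
        if len(log_ks) >= 2:
            out.append(replicate_mean_ci(
                ReplicateSet(log_ks), confidence,
                quantity=Quantity.HXD_W, method=Method(method_name),
                compound=compound,
            ))
        else:
            out.append(LogPartitionCoefficient(
                quantity=Quantity.HXD_W, value=float(log_ks[0]),
                method=Method(method_name), compound=compound,
            ))
    return out


def _per_method_from_values(
    values: pd.DataFrame, compound: str
) -> List[LogPartitionCoefficient]:
    out = []
    sub = values[(values["compound"] == compound)
                 & (values["quantity"] == Quantity.HXD_W.value)]
    for _, row in sub.iterrows():
        ci_low = None if pd.isna(row["ci_low"]) else float(row["ci_low"])
        ci_high = None if pd.isna(row["ci_high"]) else float(row["ci_high"])
        out.append(LogPartitionCoefficient(
            quantity=Quantity.HXD_W, value=float(row["log_k"]),
            ci_low=ci_low, ci_high=ci_high,
            method=Method(row["method"]), compound=compound,
        ))
    return out


def backcompute_khxdair(
    values: pd.DataFrame,
    policy: SelectionPolicy = SelectionPolicy(),
) -> pd.DataFrame:
    """Recover a K_Hxd/air table from final K_Hxd/w and cycled K_aw values.

    For each compound with both a selectable K_Hxd/w and a
    method=``cycle`` K_aw entry, K_Hxd/air = K_Hxd/w / K_aw (log
    subtraction) — the inverse of the thermodynamic cycle under the
    same selection policy.
    """
    rows = []
    for compound in values["compound"].unique():
        per_method = _per_method_from_values(values, compound)
        kaw = values[(values["compound"] == compound)
                     & (values["quantity"] == Quantity.AW.value)
                     & (values["method"] == Method.CYCLE.value)]
        if not per_method or kaw.empty:
            continue
        final_hxdw = select_final_value(per_method, policy)
        rows.append({
            "compound": compound,
            "quantity": Quantity.HXD_AIR.value,
            "method": Method.CYCLE.value,
            "log_k": final_hxdw.value - float(kaw["log_k"].iloc[0]),
            "ci_low": np.nan,
            "ci_high": np.nan,
        })
    return pd.DataFrame(rows, columns=SCHEMAS["values"])


@dataclass
class PipelineConfig:
    """Tunable knobs of the pipeline, all with working defaults."""

    confidence: float = 0.95
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    seed: int = 0
    n_bootstrap: int = 999


def run_pipeline(
    bundle: StudyBundle,
    config: PipelineConfig = PipelineConfig(),
):
    """Per-compound: replicate stats -> selection -> thermodynamic cycle.

    Sources of per-method K_Hxd/w estimates, in combination:
    raw replicate measurements (inverted through the mass balance),
    VPR-HS headspace series (nonlinear fit), and pre-aggregated
    ``values`` rows.  The selected final K_Hxd/w is cycled to K_aw
    where a K_Hxd/air entry exists; compounds lacking one are skipped
    with a warning.

    Returns ``(results, report)`` where ``results`` has one row per
    compound with the per-method values, the selected final log
    K_Hxd/w, and log K_aw.
    """
    bundle.validate()
    report = PipelineReport()
    khxdair_map: Dict[str, float] = {}
    if bundle.khxdair is not None:
        khxdair_map = dict(zip(bundle.khxdair["compound"],
                               bundle.khxdair["log_k"]))

    fits_by_compound: Dict[str, List[LogPartitionCoefficient]] = {}
    for series in bundle.headspace or []:
        if series.kind == "modified":
            fit = fit_modified_vprhs(series, seed=config.seed,
                                     n_bootstrap=config.n_bootstrap)
            lp = LogPartitionCoefficient(
                quantity=Quantity.HXD_W, value=fit.log_k,
                ci_low=fit.ci_low, ci_high=fit.ci_high,
                method=Method.MODIFIED_VPRHS, compound=series.compound,
            )
            fits_by_compound.setdefault(series.compound, []).append(lp)
        else:
            # standard series measure K_aw directly; reported separately
            fit = fit_standard_vprhs(series, seed=config.seed,
                                     n_bootstrap=config.n_bootstrap)
            report.warn(
                f"{series.compound}: standard VPR-HS log K_aw = "
                f"{fit.log_k:.2f} (comparison only, not cycled)"
            )

    rows = []
    for compound in bundle.registry["abbreviation"]:
        per_method: List[LogPartitionCoefficient] = []
        if bundle.measurements is not None and len(bundle.measurements):
            per_method += _per_method_from_measurements(
                bundle.measurements, compound, khxdair_map.get(compound),
                config.confidence, report,
            )
        per_method += fits_by_compound.get(compound, [])
        if bundle.values is not None and len(bundle.values):
            have = {v.method for v in per_method}
            per_method += [
                v for v in _per_method_from_values(bundle.values, compound)
                if v.method not in have
            ]
        if not per_method:
            report.skipped.append(compound)
            continue
        final = select_final_value(per_method, config.policy)
        row = {
            "compound": compound,
            "log_khxdw": final.value,
            "khxdw_ci_low": final.ci_low,
            "khxdw_ci_high": final.ci_high,
            "khxdw_method": final.method.value,
            "log_kaw": np.nan,
        }
        for v in per_method:
            row[f"log_khxdw_{v.method.value}"] = v.value
        if compound in khxdair_map:
            row["log_kaw"] = cycle_log_kaw(
                final.value, khxdair_map[compound]
            ).value
        else:
            report.warn(f"{compound}: no K_Hxd/air value; K_aw not derived")
        rows.append(row)

    if not rows:
        report.warn("no compound produced any partition estimate")
        return pd.DataFrame(columns=["compound", "log_khxdw", "log_kaw"]), report
    return pd.DataFrame(rows), report


def run_manifest(inputs: Dict[str, str], config: PipelineConfig) -> Dict:
    """Machine-readable record of a run: inputs, config hash, version."""
    cfg = {
        "confidence": config.confidence,
        "batch_limit": config.policy.batch_limit,
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
    }
    return {
        "package": "kawcycle",
        "version": __version__,
        "inputs": inputs,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:12],
        "python": sys.version.split()[0],
    }
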
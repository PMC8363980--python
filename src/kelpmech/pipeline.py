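"""Full-analysis orchestration: mechanics → scaling → breakpoint → report.

:func:`run_full_analysis` takes validated morphometric and tensile inputs
and produces an :class:`AnalysisReport` holding the per-specimen material
properties, the nine-row scaling table, the segmented breakpoint fit on the
pooled log-log bulb-vs-stipe data, and an exclusion log naming every
specimen that was dropped and why.  The run is deterministic: identical
inputs and config yield byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .errors import KelpmechError
from .scaling import (
    ADULT_MIN_CM,
    JUVENILE_MAX_CM,
    RegressionSpec,
    ScalingFit,
    default_regression_specs,
    run_scaling_table,
)
from .segmented import BreakpointFit, segmented_fit
from .tensile import MaterialProperties, TensileRecord, extract_properties

__all__ = ["AnalysisConfig", "AnalysisReport", "read_inputs", "run_full_analysis", "write_report"]

log = logging.getLogger("kelpmech")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the analysis in one place."""

    alpha: float = 0.05                 # two-sided CI level
    drop_fraction: float = 0.5          # force-drop failure criterion
    log_base: int = 10                  # fixed; slope/CI/R² are base-invariant
    modulus_window: int | None = None   # None = auto (10% of pre-peak samples)
    juvenile_max_cm: float = JUVENILE_MAX_CM
    adult_min_cm: float = ADULT_MIN_CM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.juvenile_max_cm >= self.adult_min_cm:
            raise ValueError("juvenile_max_cm must be < adult_min_cm")
        if self.log_base != 10:
            raise ValueError("only log base 10 is supported")


@dataclass
class AnalysisReport:
    """Everything one analysis run produced."""

    scaling_rows: list[ScalingFit]
    breakpoint: BreakpointFit | None
    properties: list[MaterialProperties]
    exclusions: list[tuple[str, str]]          # (specimen_id, reason)
    infeasible: list[tuple[str, str]] = field(default_factory=list)  # (regression, reason)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    diagnostics: list[str] = field(default_factory=list)


def read_inputs(
    morphometrics_path: str | Path,
    tensile_samples_path: str | Path | None = None,
    tensile_metadata_path: str | Path | None = None,
) -> tuple[pd.DataFrame, list[TensileRecord], list[str]]:
    """Read and validate all input files; tensile files are optional."""
    morph, diags = kio.read_morphometrics(morphometrics_path)
    records: list[TensileRecord] = []
    if tensile_samples_path is not None and tensile_metadata_path is not None:
        records, tdiags = kio.read_tensile_records(tensile_samples_path, tensile_metadata_path)
        diags += tdiags
    return morph, records, diags


def run_full_analysis(
    morphometrics: pd.DataFrame,
    tensile_records: list[TensileRecord],
    config: AnalysisConfig | None = None,
    specs: list[RegressionSpec] | None = None,
) -> AnalysisReport:
    """Run the complete analysis on validated inputs.

    Per-specimen and per-regression failures are logged and isolated; the
    run aborts only when no regression at all is feasible.
    """
    config = config or AnalysisConfig()
    properties: list[MaterialProperties] = []
    exclusions: list[tuple[str, str]] = []
    for rec in tensile_records:
        if rec.excluded:
            exclusions.append((rec.specimen_id, "flagged excluded (clamp/cradle failure)"))
            continue
        try:
            properties.append(extract_properties(
                rec, drop_fraction=config.drop_fraction, window=config.modulus_window,
            ))
        except KelpmechError as exc:
            exclusions.append((rec.specimen_id, f"{type(exc).__name__}: {exc}"))
    for sid, reason in exclusions:
        log.info("excluded %s: %s", sid, reason)

    data = morphometrics.copy()
    if properties:
        props_df = kio.properties_frame(properties)
        area = pd.DataFrame(
            {"specimen_id": [r.specimen_id for r in tensile_records if not r.excluded],
             "fracture_area_mm2": [r.fracture_area_mm2 for r in tensile_records if not r.excluded]}
        )
        props_df = props_df.merge(area, on="specimen_id", how="left")
        data = data.merge(props_df, on="specimen_id", how="left")

    infeasible: list[tuple[str, str]] = []

    def on_error(spec: RegressionSpec, exc: Exception) -> None:
        infeasible.append((spec.name, f"{type(exc).__name__}: {exc}"))
        log.warning("regression %s infeasible: %s", spec.name, exc)

    fits = run_scaling_table(data, specs=specs, alpha=config.alpha, on_error=on_error)
    n_specs = len(specs) if specs is not None else len(default_regression_specs())
    if n_specs and not fits:
        raise KelpmechError("every regression infeasible; nothing to report")

    bp: BreakpointFit | None = None
    pooled = morphometrics[["stipe_length_cm", "bulb_width_mm"]].dropna()
    pooled = pooled[(pooled > 0).all(axis=1)]
    if len(pooled) >= 6:
        try:
            bp = segmented_fit(
                np.log10(pooled["stipe_length_cm"].to_numpy()),
                np.log10(pooled["bulb_width_mm"].to_numpy()),
            )
        except KelpmechError as exc:
            infeasible.append(("breakpoint", f"{type(exc).__name__}: {exc}"))

    return AnalysisReport(
        scaling_rows=fits,
        breakpoint=bp,
        properties=properties,
        exclusions=exclusions,
        infeasible=infeasible,
        config=config,
    )


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a report to CSV/JSON files under ``out_dir``.

    Returns a name → path map.  Re-running on identical inputs produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaling": out / "scaling_table.csv",
        "properties": out / "material_properties.csv",
        "exclusions": out / "exclusions.csv",
        "config": out / "config.json",
    }
    kio.write_scaling_csv(report.scaling_rows, paths["scaling"])
    kio.write_properties_csv(report.properties, paths["properties"])
    pd.DataFrame(report.exclusions, columns=["specimen_id", "reason"]).to_csv(
        paths["exclusions"], index=False)
    if report.breakpoint is not None:
        paths["breakpoint"] = out / "breakpoint.csv"
        kio.write_breakpoint_csv(report.breakpoint, paths["breakpoint"])
    if report.infeasible:
        paths["infeasible"] = out / "infeasible.csv"
        pd.DataFrame(report.infeasible, columns=["regression", "reason"]).to_csv(
            paths["infeasible"], index=False)
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(report.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
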
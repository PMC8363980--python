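"""CSV input/output for the pipeline's fixed file dialects.

All files are UTF-8, comma-separated, with a mandatory header row:

* morphometrics: ``specimen_id, life_stage, stipe_length_cm, bulb_width_mm,
  stipe_width_below_bulb_mm, stipe_width_narrowest_mm,
  stipe_width_above_holdfast_mm``
* tensile samples (long): ``specimen_id, time_s, extension_mm, force_N``
* tensile metadata: ``specimen_id, stipe_length_mm, fracture_area_mm2,
  excluded`` (excluded in {true, false})

Rows violating record invariants are rejected with row-level diagnostics
(collected, not fatal); specimens flagged ``excluded`` are retained but
marked so the pipeline can count them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .scaling import ScalingFit
from .segmented import BreakpointFit
from .tensile import MaterialProperties, TensileRecord

__all__ = [
    "MORPHOMETRIC_COLUMNS",
    "TENSILE_SAMPLE_COLUMNS",
    "TENSILE_META_COLUMNS",
    "REPORT_COLUMNS",
    "read_morphometrics",
    "read_tensile_records",
    "write_properties_csv",
    "write_scaling_csv",
    "write_breakpoint_csv",
]

MORPHOMETRIC_COLUMNS = [
    "specimen_id", "life_stage", "stipe_length_cm", "bulb_width_mm",
    "stipe_width_below_bulb_mm", "stipe_width_narrowest_mm",
    "stipe_width_above_holdfast_mm",
]
TENSILE_SAMPLE_COLUMNS = ["specimen_id", "time_s", "extension_mm", "force_N"]
TENSILE_META_COLUMNS = ["specimen_id", "stipe_length_mm", "fracture_area_mm2", "excluded"]
REPORT_COLUMNS = [
    "regression", "h0", "method", "n", "slope", "ci_low", "ci_high",
    "classification", "intercept", "r_squared",
]

_MEASURE_COLS = MORPHOMETRIC_COLUMNS[2:]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_morphometrics(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a morphometric table.

    Returns the valid rows and a list of row-level diagnostics for the
    rejected ones (non-positive measurements).
    """
    df = _read_csv(path, MORPHOMETRIC_COLUMNS[:4])
    diagnostics: list[str] = []
    keep = pd.Series(True, index=df.index)
    for col in [c for c in _MEASURE_COLS if c in df.columns]:
        bad = df[col].notna() & (df[col] <= 0)
        for i in df.index[bad]:
            diagnostics.append(
                f"{path}:row {i + 2}: {col} = {df.at[i, col]} violates '> 0'"
            )
        keep &= ~bad
    return df.loc[keep].reset_index(drop=True), diagnostics


def _parse_excluded(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def read_tensile_records(
    samples_path: str | Path,
    metadata_path: str | Path,
) -> tuple[list[TensileRecord], list[str]]:
    """Assemble per-specimen tensile records from the long table + metadata.

    Invalid specimens (bad geometry, too few samples, non-monotone
    extension) are dropped with a diagnostic; ``excluded`` specimens are
    returned with the flag set so downstream stages can log them.
    """
    samples = _read_csv(samples_path, TENSILE_SAMPLE_COLUMNS)
    meta = _read_csv(metadata_path, TENSILE_META_COLUMNS)
    diagnostics: list[str] = []
    records: list[TensileRecord] = []
    grouped = dict(tuple(samples.groupby("specimen_id", sort=False)))
    for _, row in meta.iterrows():
        sid = str(row["specimen_id"])
        grp = grouped.get(sid)
        if grp is None:
            diagnostics.append(f"{samples_path}: no samples for specimen {sid!r}")
            continue
        grp = grp.sort_values("time_s") if grp["time_s"].notna().all() else grp
        try:
            records.append(TensileRecord(
                specimen_id=sid,
                initial_length_mm=float(row["stipe_length_mm"]),
                fracture_area_mm2=float(row["fracture_area_mm2"]),
                extension_mm=grp["extension_mm"].to_numpy(dtype=float),
                force_N=grp["force_N"].to_numpy(dtype=float),
                excluded=_parse_excluded(row["excluded"]),
            ))
        except Exception as exc:  # invariant violations become diagnostics
            diagnostics.append(f"{metadata_path}: specimen {sid!r} rejected: {exc}")
    return records, diagnostics


def properties_frame(props: list[MaterialProperties]) -> pd.DataFrame:
    """Material properties as a tidy one-row-per-specimen frame."""
    cols = ["specimen_id", "F_max_N", "F_fail_N", "W_fail_J", "epsilon_fail",
            "sigma_max_Pa", "youngs_modulus_Pa", "toughness_MJ_m3",
            "failure_index", "peak_index"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in props], columns=cols)


def write_properties_csv(props: list[MaterialProperties], path: str | Path) -> None:
    properties_frame(props).to_csv(path, index=False)


def scaling_frame(fits: list[ScalingFit]) -> pd.DataFrame:
    """Scaling fits in the standard report layout."""
    rows = [{
        "regression": f.name, "h0": f.h0_slope, "method": f.method, "n": f.n,
        "slope": f.slope, "ci_low": f.ci_low, "ci_high": f.ci_high,
        "classification": f.classification, "intercept": f.intercept,
        "r_squared": f.r_squared,
    } for f in fits]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_scaling_csv(fits: list[ScalingFit], path: str | Path) -> None:
    scaling_frame(fits).to_csv(path, index=False)


def write_breakpoint_csv(fit: BreakpointFit, path: str | Path) -> None:
    pd.DataFrame([{
        "psi_cm": fit.psi_raw, "se_cm": fit.se_psi_raw,
        "slope_left": fit.slope_left, "slope_right": fit.slope_right,
        "converged": fit.converged, "iterations": fit.iterations, "sse": fit.sse,
    }]).to_csv(path, index=False)
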
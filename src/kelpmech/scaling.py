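"""Allometric scaling: Model II (standard major axis) and OLS line fitting.

Scaling relationships between body dimensions are fitted on log-transformed
data, ``log10(y) = a + b·log10(x)``, and the fitted slope ``b`` is compared
with the geometric null slope expected under isometry: 1 for a length vs a
length, 2 for an area vs a length, 3 for a volume (or work) vs a length, and
0 for a size-independent material property.  Because both variables carry
biological and measurement error, the slope is estimated by the standard
major axis (SMA) method,

    b_SMA = sign(r) · s_y / s_x,

with the classical analytic confidence interval based on
``B = F(1−α; 1, n−2)·(1−r²)/(n−2)`` and bounds ``b·(√(B+1) ± √B)``.
Dimensionless calculated quantities (strain at failure) are fitted by
ordinary least squares with the usual t-based CI instead.

Classification is purely CI-based: the relationship is isometric
(or "independent" when the null slope is 0) if the null slope lies inside
the 95% CI, positive allometry if the whole CI lies above it, negative
allometry if below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AmbiguousSign, DegenerateInput, MissingVariable, TooFewPoints

__all__ = [
    "ScalingFit",
    "RegressionSpec",
    "sma_fit",
    "ols_fit",
    "classify_scaling",
    "run_scaling_table",
    "default_regression_specs",
    "JUVENILE_MAX_CM",
    "ADULT_MIN_CM",
]

#: life-stage conventions: juveniles have stipe length < 40 cm, adults > 200 cm
JUVENILE_MAX_CM = 40.0
ADULT_MIN_CM = 200.0

Classification = Literal["isometric", "independent", "positive_allometry", "negative_allometry"]


@dataclass
class ScalingFit:
    """One fitted scaling relationship with its CI and classification."""

    method: str                       # "SMA" or "OLS"
    slope: float
    ci_low: float
    ci_high: float
    intercept: float                  # log10 units for log-log fits
    r_squared: float
    n: int
    h0_slope: float | None = None
    classification: Classification | None = None
    name: str = ""
    n_dropped: int = 0                # listwise-deleted rows

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("CI must bracket the slope")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.n < 3:
            raise TooFewPoints(f"n = {self.n} < 3")


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise TooFewPoints(f"n = {x.size} < 3")
    return x, y


def sma_fit(x_log, y_log, alpha: float = 0.05, h0_slope: float | None = None,
            name: str = "") -> ScalingFit:
    """Standard major axis fit of ``y_log`` on ``x_log``.

    Slope is ``sign(r)·s_y/s_x``; the ``1−alpha`` CI uses the analytic
    formula ``b·(√(B+1) ± √B)`` with ``B = F(1−alpha; 1, n−2)·(1−r²)/(n−2)``,
    with the bounds ordered so ``ci_low ≤ ci_high`` for slopes of either
    sign.  Raises :class:`DegenerateInput` for constant variables and
    :class:`AmbiguousSign` when ``r`` is numerically zero (the SMA slope
    sign is then undefined).
    """
    x, y = _validate_xy(x_log, y_log)
    n = x.size
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise DegenerateInput("constant variable: SMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < 1e-12:
        raise AmbiguousSign("correlation is zero: SMA slope sign undefined")
    b = float(np.sign(r) * sy / sx)
    a = float(np.mean(y) - b * np.mean(x))
    r2 = r * r
    if r2 >= 1.0:
        lo = hi = b
    else:
        B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r2) / (n - 2)
        b1 = b * (np.sqrt(B + 1) + np.sqrt(B))
        b2 = b * (np.sqrt(B + 1) - np.sqrt(B))
        lo, hi = (b2, b1) if b > 0 else (b1, b2)
    fit = ScalingFit(method="SMA", slope=b, ci_low=float(lo), ci_high=float(hi),
                     intercept=a, r_squared=r2, n=n, h0_slope=h0_slope, name=name)
    if h0_slope is not None:
        fit.classification = classify_scaling(fit)
    return fit


def ols_fit(x, y, alpha: float = 0.05, h0_slope: float | None = None,
            name: str = "") -> ScalingFit:
    """Ordinary least squares fit with a two-sided t-based CI on the slope."""
    x, y = _validate_xy(x, y)
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateInput("constant x: OLS slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    sse = float(np.sum((y - intercept - slope * x) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0      # constant y: no variance explained
    se = float(np.sqrt(sse / (n - 2) / sxx))
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    half = tcrit * se
    fit = ScalingFit(
        method="OLS",
        slope=slope,
        ci_low=slope - half,
        ci_high=slope + half,
        intercept=intercept,
        r_squared=r2,
        n=n,
        h0_slope=h0_slope,
        name=name,
    )
    if h0_slope is not None:
        fit.classification = classify_scaling(fit)
    return fit


def classify_scaling(fit: ScalingFit) -> Classification:
    """Classify a fit against its null slope using the confidence interval.

    The null slope inside the CI means isometry (labelled "independent" when
    the null slope is 0, i.e. the trait does not change with size); a CI
    entirely above the null slope is positive allometry, entirely below is
    negative allometry.
    """
    h0 = fit.h0_slope
    if h0 is None:
        raise ValueError("fit has no null slope set")
    if fit.ci_low <= h0 <= fit.ci_high:
        return "independent" if h0 == 0 else "isometric"
    return "positive_allometry" if fit.ci_low > h0 else "negative_allometry"


@dataclass(frozen=True)
class RegressionSpec:
    """Declarative description of one row of the scaling table.

    ``y`` and ``x`` name columns of the merged morphometrics/properties
    frame; ``subset`` restricts by life stage ("juvenile", "adult" or None
    for all rows).  ``log_x``/``log_y`` control log10 transformation.
    """

    name: str
    y: str
    x: str = "stipe_length_cm"
    h0_slope: float = 0.0
    method: Literal["SMA", "OLS"] = "SMA"
    log_x: bool = True
    log_y: bool = True
    subset: str | None = None


def default_regression_specs() -> list[RegressionSpec]:
    """The nine standard regressions of the scaling analysis.

    Morphology: bulb width vs stipe length (adult and juvenile subsets,
    null slope 1).  Structure (juveniles): break surface area (null 2),
    force at failure (null 2), work to failure (null 3).  Material
    properties (juveniles): Young's modulus, maximum stress and toughness
    (SMA, null 0) and strain at failure (OLS on the untransformed strain,
    null 0, since strain is a dimensionless calculated value).
    """
    return [
        RegressionSpec("Bulb~Stipe (adult)", "bulb_width_mm", h0_slope=1, subset="adult"),
        RegressionSpec("Bulb~Stipe (juvenile)", "bulb_width_mm", h0_slope=1, subset="juvenile"),
        RegressionSpec("BreakSurfaceArea~Stipe", "fracture_area_mm2", h0_slope=2, subset="juvenile"),
        RegressionSpec("YoungsModulus~Stipe", "youngs_modulus_Pa", h0_slope=0, subset="juvenile"),
        RegressionSpec("MaxStress~Stipe", "sigma_max_Pa", h0_slope=0, subset="juvenile"),
        RegressionSpec("ConventionalStrainFail~Stipe", "epsilon_fail", h0_slope=0,
                       method="OLS", log_y=False, subset="juvenile"),
        RegressionSpec("Toughness~Stipe", "toughness_MJ_m3", h0_slope=0, subset="juvenile"),
        RegressionSpec("F_fail~Stipe", "F_fail_N", h0_slope=2, subset="juvenile"),
        RegressionSpec("W_fail~Stipe", "W_fail_J", h0_slope=3, subset="juvenile"),
    ]


def life_stage_mask(stipe_length_cm: pd.Series, subset: str | None) -> pd.Series:
    """Stage subsetting by stipe length: juvenile < 40 cm, adult > 200 cm."""
    if subset is None:
        return pd.Series(True, index=stipe_length_cm.index)
    if subset == "juvenile":
        return stipe_length_cm < JUVENILE_MAX_CM
    if subset == "adult":
        return stipe_length_cm > ADULT_MIN_CM
    raise ValueError(f"unknown subset {subset!r}")


def run_scaling_table(
    data: pd.DataFrame,
    specs: Sequence[RegressionSpec] | None = None,
    alpha: float = 0.05,
    on_error: Callable[[RegressionSpec, Exception], None] | None = None,
) -> list[ScalingFit]:
    """Fit every regression spec against a merged per-specimen frame.

    ``data`` must hold one row per specimen with the columns the specs name
    (morphometrics merged with extracted material properties).  Rows with
    missing values are dropped per regression (listwise deletion) and
    counted in ``n_dropped``.  A failing spec is reported through
    ``on_error`` (or silently skipped) without aborting the other rows.
    """
    if specs is None:
        specs = default_regression_specs()
    fits: list[ScalingFit] = []
    for spec in specs:
        try:
            fits.append(_fit_one(data, spec, alpha))
        except Exception as exc:  # noqa: BLE001 - per-row isolation is the contract
            if on_error is not None:
                on_error(spec, exc)
    return fits


def _fit_one(data: pd.DataFrame, spec: RegressionSpec, alpha: float) -> ScalingFit:
    for col in (spec.x, spec.y):
        if col not in data.columns:
            raise MissingVariable(f"{spec.name}: column {col!r} absent")
    mask = life_stage_mask(data["stipe_length_cm"], spec.subset)
    sub = data.loc[mask, [spec.x, spec.y]]
    n_total = len(sub)
    sub = sub.dropna()
    x = sub[spec.x].to_numpy(dtype=float)
    y = sub[spec.y].to_numpy(dtype=float)
    if spec.log_x:
        if np.any(x <= 0):
            raise DegenerateInput(f"{spec.name}: non-positive x for log transform")
        x = np.log10(x)
    if spec.log_y:
        if np.any(y <= 0):
            raise DegenerateInput(f"{spec.name}: non-positive y for log transform")
        y = np.log10(y)
    fitter = sma_fit if spec.method == "SMA" else ols_fit
    fit = fitter(x, y, alpha=alpha, h0_slope=spec.h0_slope, name=spec.name)
    fit.n_dropped = n_total - len(sub)
    return fit
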
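"""Synthetic datasets with known ground truth for every pipeline stage.

Two generators mirror the two kinds of field/lab data the pipeline
consumes:

* :func:`simulate_morphometrics` draws a two-regime log-log bulb-vs-stipe
  relationship — isometric below a breakpoint, hypoallometric above it,
  continuous at the knot — with multiplicative (Gaussian-on-log10) noise.
  Defaults encode the study design the pipeline targets: 22 juveniles on
  2.1–36.1 cm, 27 adults on 200–3000 cm, slopes 1.19 / 0.70, breakpoint
  33.2 cm, log10 noise sd 0.08.

* :func:`simulate_tensile_test` builds a force–extension record with a
  quadratic toe joined C¹ to a linear elastic region that reaches the
  target strength at the failure strain, followed by a catastrophic force
  drop to 10% of peak, plus additive Gaussian load-cell noise.  The curve
  shape makes (E, σ_max, ε_fail, toe_fraction) redundant — consistency
  requires σ_max = E·ε_fail·(1 − toe_fraction/2) — and inconsistent specs
  raise rather than silently rescale.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InconsistentSpec, InvalidSpec
from .tensile import MaterialProperties, TensileRecord

__all__ = [
    "MorphometricSimSpec",
    "TensileSimSpec",
    "simulate_morphometrics",
    "simulate_tensile_test",
    "simulate_property_scaling",
]


@dataclass(frozen=True)
class MorphometricSimSpec:
    """Design of a synthetic morphometric survey.

    Stipe lengths are drawn log-uniformly within each life-stage range;
    log10 bulb width follows a continuous piecewise-linear function of
    log10 stipe length with a slope change at ``psi_cm``, plus Gaussian
    noise on the log10 scale.  Defaults reproduce the sampling design and
    parameter estimates the pipeline is validated against.
    """

    n_juvenile: int = 22
    n_adult: int = 27
    psi_cm: float = 33.2
    slope_juvenile: float = 1.19
    slope_adult: float = 0.70
    intercept_log: float = -1.0          # log10(bulb mm) at stipe = 1 cm, juvenile branch
    noise_sd_log: float = 0.08
    stipe_range_juvenile_cm: tuple[float, float] = (2.1, 36.1)
    stipe_range_adult_cm: tuple[float, float] = (200.0, 3000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_juvenile < 0 or self.n_adult < 0:
            raise InvalidSpec("negative sample size")
        if self.noise_sd_log < 0:
            raise InvalidSpec("noise_sd_log must be >= 0")
        if self.psi_cm <= 0:
            raise InvalidSpec("psi_cm must be > 0")
        for lo, hi in (self.stipe_range_juvenile_cm, self.stipe_range_adult_cm):
            if not 0 < lo < hi:
                raise InvalidSpec("stipe ranges must be positive and ordered")
        if not np.isfinite([self.slope_juvenile, self.slope_adult]).all():
            raise InvalidSpec("slopes must be finite")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)


def bulb_width_model(stipe_cm: np.ndarray, spec: MorphometricSimSpec) -> np.ndarray:
    """Noiseless log10 bulb width (mm) under the two-regime model."""
    lx = np.log10(np.asarray(stipe_cm, dtype=float))
    lpsi = np.log10(spec.psi_cm)
    juv = spec.intercept_log + spec.slope_juvenile * lx
    # continuity at the knot pins the adult branch intercept
    adult = (spec.intercept_log + spec.slope_juvenile * lpsi
             + spec.slope_adult * (lx - lpsi))
    return np.where(lx <= lpsi, juv, adult)


def simulate_morphometrics(
    spec: MorphometricSimSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a morphometric table plus its generating parameters.

    Returns a frame with the standard morphometric columns (one row per
    specimen, juveniles first) and a ground-truth dict holding the spec
    parameters and the noiseless bulb widths.
    """
    spec = spec or MorphometricSimSpec()
    rng = np.random.default_rng(spec.seed)
    stipe = np.concatenate([
        np.sort(_log_uniform(rng, *spec.stipe_range_juvenile_cm, spec.n_juvenile)),
        np.sort(_log_uniform(rng, *spec.stipe_range_adult_cm, spec.n_adult)),
    ])
    log_bulb_true = bulb_width_model(stipe, spec)
    noise = rng.normal(0.0, spec.noise_sd_log, size=stipe.size)
    bulb = 10.0 ** (log_bulb_true + noise)
    # stipe widths: near-isometric companions with their own mild noise,
    # plausible but not part of the validated ground truth
    def width(base: float) -> np.ndarray:
        return base * (stipe / 10.0) ** 0.9 * 10.0 ** rng.normal(0.0, 0.05, stipe.size)

    stage = np.where(np.arange(stipe.size) < spec.n_juvenile, "juvenile", "adult")
    df = pd.DataFrame({
        "specimen_id": [f"sim{_i:03d}" for _i in range(stipe.size)],
        "life_stage": stage,
        "stipe_length_cm": stipe,
        "bulb_width_mm": bulb,
        "stipe_width_below_bulb_mm": width(3.0),
        "stipe_width_narrowest_mm": width(2.0),
        "stipe_width_above_holdfast_mm": width(2.5),
    })
    truth = {
        "psi_cm": spec.psi_cm,
        "slope_juvenile": spec.slope_juvenile,
        "slope_adult": spec.slope_adult,
        "intercept_log": spec.intercept_log,
        "noise_sd_log": spec.noise_sd_log,
        "log_bulb_true": log_bulb_true,
        "seed": spec.seed,
    }
    return df, truth


@dataclass(frozen=True)
class TensileSimSpec:
    """Design of one synthetic tensile pull.

    The noiseless stress–strain curve is a quadratic toe on
    [0, toe_fraction·ε_fail] joined with continuous slope to a linear
    region of slope ``youngs_modulus_Pa`` that reaches ``sigma_max_Pa`` at
    ``epsilon_fail``; force then collapses to 10% of peak.  These four
    parameters are redundant: consistency requires
    σ_max = E·ε_fail·(1 − toe_fraction/2) (relative tolerance 1e-6), and
    violations raise :class:`InconsistentSpec`.
    """

    youngs_modulus_Pa: float = 5.0e6
    sigma_max_Pa: float = 1.8e6
    epsilon_fail: float = 0.40
    toe_fraction: float = 0.20
    L0_mm: float = 150.0
    area_mm2: float = 3.0
    sampling_rate_hz: float = 100.0
    crosshead_rate_mm_min: float = 50.8
    noise_sd_N: float = 0.0
    seed: int = 0
    specimen_id: str = "sim-tensile"

    def __post_init__(self) -> None:
        for name in ("youngs_modulus_Pa", "sigma_max_Pa", "epsilon_fail", "L0_mm",
                     "area_mm2", "sampling_rate_hz", "crosshead_rate_mm_min"):
            if getattr(self, name) <= 0:
                raise InvalidSpec(f"{name} must be > 0")
        if not 0.0 <= self.toe_fraction < 0.5:
            raise InvalidSpec("toe_fraction must be in [0, 0.5)")
        if self.noise_sd_N < 0:
            raise InvalidSpec("noise_sd_N must be >= 0")
        implied = self.youngs_modulus_Pa * self.epsilon_fail * (1 - self.toe_fraction / 2)
        if abs(implied - self.sigma_max_Pa) > 1e-6 * self.sigma_max_Pa:
            raise InconsistentSpec(
                f"sigma_max {self.sigma_max_Pa:.6g} Pa inconsistent with "
                f"E*eps_fail*(1 - toe/2) = {implied:.6g} Pa"
            )


def stress_curve(strain: np.ndarray, spec: TensileSimSpec) -> np.ndarray:
    """Noiseless pre-failure stress at the given strains (Pa)."""
    E = spec.youngs_modulus_Pa
    eps_t = spec.toe_fraction * spec.epsilon_fail
    if eps_t > 0:
        c = E / (2 * eps_t)                      # C1 join: 2 c eps_t = E
        toe = c * strain**2
    else:
        toe = np.zeros_like(strain)
    linear = spec.sigma_max_Pa - E * (spec.epsilon_fail - strain)
    return np.where(strain <= eps_t, toe, linear)


def analytic_toughness(spec: TensileSimSpec) -> float:
    """Closed-form area under the noiseless σ(ε) curve to ε_fail, MJ m⁻³."""
    E = spec.youngs_modulus_Pa
    eps_t = spec.toe_fraction * spec.epsilon_fail
    sigma_t = E * eps_t / 2
    toe_area = E * eps_t**2 / 6                   # ∫ c ε² dε = c εt³/3
    lin_area = (sigma_t + spec.sigma_max_Pa) / 2 * (spec.epsilon_fail - eps_t)
    return (toe_area + lin_area) * 1e-6


def simulate_tensile_test(
    spec: TensileSimSpec | None = None,
) -> tuple[TensileRecord, MaterialProperties]:
    """Generate one tensile record plus the ground-truth properties.

    Extension advances by ``crosshead_rate / sampling_rate`` per sample.
    Ground truth records the generating E, σ_max, ε_fail and the analytic
    toughness / work of the noiseless curve; noise (if any) is additive
    Gaussian on force only.
    """
    spec = spec or TensileSimSpec()
    rng = np.random.default_rng(spec.seed)
    dx = spec.crosshead_rate_mm_min / 60.0 / spec.sampling_rate_hz
    x_fail = spec.epsilon_fail * spec.L0_mm
    # short settling hold at zero load before the crosshead engages
    n_hold = 5
    ramp = dx * np.arange(1, int(np.floor(x_fail / dx)) + 1)
    if ramp.size and ramp[-1] >= x_fail:
        ramp = ramp[:-1]
    ext = np.concatenate([
        np.zeros(n_hold),
        ramp,
        [x_fail],                     # fracture exactly at the failure strain
        x_fail + dx * np.arange(1, 4),
    ])
    strain = ext / spec.L0_mm
    peak_index = n_hold + ramp.size
    stress = np.zeros_like(strain)
    stress[n_hold:peak_index + 1] = stress_curve(strain[n_hold:peak_index + 1], spec)
    # catastrophic failure: force collapses to 10% of peak within 3 samples
    peak = float(stress[peak_index])
    stress[peak_index + 1:] = [0.45 * peak, 0.10 * peak, 0.10 * peak]
    force = stress * spec.area_mm2 * 1e-6
    if spec.noise_sd_N > 0:
        force = force + rng.normal(0.0, spec.noise_sd_N, size=force.size)
    record = TensileRecord(
        specimen_id=spec.specimen_id,
        initial_length_mm=spec.L0_mm,
        fracture_area_mm2=spec.area_mm2,
        extension_mm=ext,
        force_N=force,
        sampling_rate_hz=spec.sampling_rate_hz,
        crosshead_rate_mm_min=spec.crosshead_rate_mm_min,
    )
    tough = analytic_toughness(spec)
    f_max = spec.sigma_max_Pa * spec.area_mm2 * 1e-6
    truth = MaterialProperties(
        specimen_id=spec.specimen_id,
        F_max_N=f_max,
        F_fail_N=f_max,
        W_fail_J=tough * spec.area_mm2 * spec.L0_mm * 1e-3,
        epsilon_fail=spec.epsilon_fail,
        sigma_max_Pa=spec.sigma_max_Pa,
        youngs_modulus_Pa=spec.youngs_modulus_Pa,
        toughness_MJ_m3=tough,
        failure_index=peak_index + 1,
        peak_index=peak_index,
    )
    return record, truth


def simulate_property_scaling(
    n: int,
    slope: float,
    intercept_log: float = 0.0,
    noise_sd_log: float = 0.1,
    seed: int = 0,
    x_range_cm: tuple[float, float] = (2.1, 36.1),
) -> tuple[np.ndarray, np.ndarray]:
    """Power-law property-vs-length pairs on the juvenile size range.

    Returns raw (untransformed) vectors ``(x, y)`` with
    ``log10 y = intercept_log + slope·log10 x + N(0, noise_sd_log)``.
    """
    if n < 3:
        raise InvalidSpec("n must be >= 3")
    if noise_sd_log < 0:
        raise InvalidSpec("noise_sd_log must be >= 0")
    rng = np.random.default_rng(seed)
    x = _log_uniform(rng, *x_range_cm, n)
    ly = intercept_log + slope * np.log10(x) + rng.normal(0.0, noise_sd_log, n)
    return x, 10.0**ly
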
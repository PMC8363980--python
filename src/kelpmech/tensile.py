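"""Tensile-test mechanics: from force–extension records to material properties.

A specimen is loaded in uniaxial tension at constant crosshead speed while a
load cell samples force at ~100 Hz.  From the resulting force–extension
record and two pieces of geometry — the initial stipe length ``L0`` (mm) and
the fracture surface area ``A`` (mm²) — this module derives the structural
and material properties used in the scaling analysis:

========================  =========  =====================================
quantity                  unit       definition
========================  =========  =====================================
``F_max``                 N          peak force before catastrophic failure
``F_fail``                N          running-max force at the failure event
``W_fail``                J          work to failure, ∫ F dΔL
``epsilon_fail``          —          conventional strain at peak force
``sigma_max``             Pa         F_max / A
``youngs_modulus``        Pa         steepest local slope of σ(ε) pre-peak
``toughness``             MJ m⁻³     ∫ σ dε to peak
========================  =========  =====================================

Failure is operationalised as the first sample whose force has dropped by at
least ``drop_fraction`` (default 50%) below the running maximum, so that
post-failure noise cannot retrigger the event, and is armed only above a
small absolute force floor so noise around zero load cannot.  In the
composite :func:`extract_properties` the force is first tared by the mean
of the first few samples and floored at zero; strain is measured from the
first sample.  A centred median filter (width 5) is applied to force only
for failure *detection*; property values always come from the unfiltered
signal.

Unit conventions are fixed: inputs mm / N / mm², outputs J / Pa / MJ m⁻³
(conversion factors 1e-3, 1e6, 1e-6 respectively).  With these the energy
identity ``toughness × (A × L0) = W_fail`` holds exactly because both
integrals share bounds and integrand up to the unit algebra.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .errors import (
    DegenerateRecord,
    ExcludedSpecimen,
    NoFailureDetected,
    ZeroStrainRange,
)

__all__ = [
    "TensileRecord",
    "MaterialProperties",
    "detect_failure",
    "work_to_failure",
    "to_stress_strain",
    "estimate_modulus",
    "compute_toughness",
    "extract_properties",
    "default_modulus_window",
]

#: number of leading samples averaged to tare the force signal
TARE_SAMPLES = 5
#: width (samples) of the median filter used only for failure detection
DETECTION_FILTER_WIDTH = 5
#: running max must exceed this before the drop criterion can fire (N)
MIN_ARMING_FORCE_N = 0.1


@dataclass(frozen=True)
class TensileRecord:
    """One specimen's tensile pull: geometry plus the sampled curve.

    Parameters
    ----------
    specimen_id
        Free-text identifier, unique within a dataset.
    initial_length_mm
        Stipe length ``L0`` before loading, mm (> 0).
    fracture_area_mm2
        Cross-sectional area of the break, mm² (> 0).
    extension_mm, force_N
        Equal-length sample arrays; extension must be non-decreasing and
        forces finite.
    sampling_rate_hz, crosshead_rate_mm_min
        Nominal instrument settings (100 Hz, 50.8 mm/min).
    excluded
        True when failure occurred at the clamp or cradle; such specimens
        are kept in the dataset but never analysed.
    """

    specimen_id: str
    initial_length_mm: float
    fracture_area_mm2: float
    extension_mm: np.ndarray
    force_N: np.ndarray
    sampling_rate_hz: float = 100.0
    crosshead_rate_mm_min: float = 50.8
    excluded: bool = False

    def __post_init__(self) -> None:
        ext = np.asarray(self.extension_mm, dtype=float)
        frc = np.asarray(self.force_N, dtype=float)
        object.__setattr__(self, "extension_mm", ext)
        object.__setattr__(self, "force_N", frc)
        if self.initial_length_mm <= 0:
            raise ValueError(f"{self.specimen_id}: initial_length_mm must be > 0")
        if self.fracture_area_mm2 <= 0:
            raise ValueError(f"{self.specimen_id}: fracture_area_mm2 must be > 0")
        if ext.shape != frc.shape or ext.ndim != 1:
            raise ValueError(f"{self.specimen_id}: extension/force must be equal-length 1-D arrays")
        if ext.size < 3:
            raise DegenerateRecord(f"{self.specimen_id}: need >= 3 samples, got {ext.size}")
        if not np.all(np.isfinite(frc)) or not np.all(np.isfinite(ext)):
            raise ValueError(f"{self.specimen_id}: non-finite samples")
        if np.any(np.diff(ext) < 0):
            raise ValueError(f"{self.specimen_id}: extension must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return int(self.extension_mm.size)

    def tared_force(self, n_tare: int = TARE_SAMPLES) -> np.ndarray:
        """Force with the baseline (mean of first ``n_tare`` samples) removed,
        floored at zero."""
        n_tare = min(n_tare, self.n_samples)
        tare = float(np.mean(self.force_N[:n_tare]))
        return np.maximum(self.force_N - tare, 0.0)


@dataclass(frozen=True)
class MaterialProperties:
    """Derived structural and material properties of one specimen."""

    specimen_id: str
    F_max_N: float
    F_fail_N: float
    W_fail_J: float
    epsilon_fail: float
    sigma_max_Pa: float
    youngs_modulus_Pa: float
    toughness_MJ_m3: float
    failure_index: int
    peak_index: int
    extras: dict = field(default_factory=dict, compare=False)


def detect_failure(
    record: TensileRecord,
    drop_fraction: float = 0.5,
    smooth: bool = True,
    min_force_N: float = MIN_ARMING_FORCE_N,
) -> tuple[int, float]:
    """Locate the catastrophic failure event in a force record.

    Failure is the first sample ``i`` whose force has fallen to at most
    ``(1 - drop_fraction)`` of the running maximum of the force over
    ``[0, i]``.  Returns ``(failure_index, F_fail)`` with ``F_fail`` the raw
    running-max (peak) force preceding the qualifying drop.

    With ``smooth=True`` a centred width-5 median filter is applied to the
    force before evaluating the criterion, so single-sample load-cell
    glitches cannot trigger a spurious event; ``F_fail`` is always read
    from the unfiltered signal.  The criterion is armed only once the
    running maximum exceeds ``min_force_N`` (default 0.1 N), because near
    zero load any noise excursion is a "50% drop" of nothing.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in (0, 1)")
    if record.n_samples < 3:
        raise DegenerateRecord(f"{record.specimen_id}: need >= 3 samples")

    raw = record.force_N
    sig = raw
    if smooth and record.n_samples >= DETECTION_FILTER_WIDTH:
        sig = median_filter(raw, size=DETECTION_FILTER_WIDTH, mode="nearest")

    run_max = np.maximum.accumulate(sig)
    with np.errstate(invalid="ignore"):
        dropped = sig <= (1.0 - drop_fraction) * run_max
    # arm only above the noise floor; a drop of ~nothing is not failure
    dropped &= run_max > max(min_force_N, 0.0)
    idx = np.flatnonzero(dropped)
    if idx.size == 0:
        raise NoFailureDetected(
            f"{record.specimen_id}: no {drop_fraction:.0%} drop below the running maximum"
        )
    failure_index = int(idx[0])
    f_fail = float(np.max(raw[: failure_index + 1]))
    return failure_index, f_fail


def work_to_failure(record: TensileRecord, peak_index: int) -> float:
    """Trapezoidal work ∫ F dΔL (N·mm → J) from sample 0 to ``peak_index``."""
    if peak_index < 1:
        raise DegenerateRecord(f"{record.specimen_id}: peak_index must be >= 1")
    if peak_index >= record.n_samples:
        raise IndexError(f"peak_index {peak_index} out of range")
    f = record.force_N[: peak_index + 1]
    x = record.extension_mm[: peak_index + 1]
    return float(np.trapezoid(f, x)) * 1e-3


def to_stress_strain(record: TensileRecord) -> tuple[np.ndarray, np.ndarray]:
    """Engineering stress and conventional strain for every sample.

    ``sigma = F / A`` in Pa (N/mm² × 1e6);
    ``epsilon = (x - x0) / L0`` with the strain origin at the first sample.
    Returns ``(strain, stress_Pa)``.
    """
    stress = record.force_N / record.fracture_area_mm2 * 1e6
    strain = (record.extension_mm - record.extension_mm[0]) / record.initial_length_mm
    return strain, stress


def default_modulus_window(n_prepeak: int) -> int:
    """Default modulus window: 10% of the pre-peak samples, at least 5."""
    return max(5, round(0.1 * n_prepeak))


def estimate_modulus(
    strain: np.ndarray,
    stress: np.ndarray,
    peak_index: int,
    window: int | None = None,
) -> float:
    """Tangent Young's modulus: the steepest local OLS slope of σ on ε.

    All contiguous windows of ``window`` samples within ``[0, peak_index]``
    are fitted by ordinary least squares and the maximum slope returned.
    On a noiseless linear curve this recovers the modulus exactly for any
    window; on a toe-then-linear curve it returns the linear-region slope.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    n = peak_index + 1
    if window is None:
        window = default_modulus_window(n)
    if window < 3:
        raise ValueError("window must be >= 3")
    if n < window:
        raise DegenerateRecord(
            f"only {n} pre-peak samples for modulus window {window}"
        )
    e = strain[:n]
    s = stress[:n]
    w = window
    # rolling OLS slope via cumulative sums: slope = (w Σxy − Σx Σy) / (w Σx² − (Σx)²)
    def roll(a: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[w:] - c[:-w]

    sx, sy = roll(e), roll(s)
    sxx, sxy = roll(e * e), roll(e * s)
    denom = w * sxx - sx * sx
    valid = denom > 1e-30 * np.maximum(sxx, 1e-300) * w
    if not np.any(valid):
        raise ZeroStrainRange("strain is constant within every window")
    slopes = np.full_like(denom, -np.inf)
    slopes[valid] = (w * sxy[valid] - sx[valid] * sy[valid]) / denom[valid]
    return float(np.max(slopes))


def compute_toughness(strain: np.ndarray, stress: np.ndarray, peak_index: int) -> float:
    """Trapezoidal area under σ(ε) to ``peak_index``, Pa → MJ m⁻³ (× 1e-6)."""
    if peak_index < 1:
        raise DegenerateRecord("peak_index must be >= 1")
    s = np.asarray(stress, dtype=float)[: peak_index + 1]
    e = np.asarray(strain, dtype=float)[: peak_index + 1]
    return float(np.trapezoid(s, e)) * 1e-6


def extract_properties(
    record: TensileRecord,
    drop_fraction: float = 0.5,
    window: int | None = None,
    smooth: bool = True,
    tare: bool = True,
) -> MaterialProperties:
    """Run the full per-specimen property extraction.

    With ``tare=True`` (the pipeline default) the force baseline — the mean
    of the first few samples, i.e. the load-cell offset before the crosshead
    engages — is subtracted and the signal floored at zero before any
    computation.  Detects failure, takes the peak force over the pre-failure
    samples as the integration bound, and computes all seven properties.
    Raises :class:`ExcludedSpecimen` for records flagged as clamp/cradle
    failures and propagates :class:`NoFailureDetected` from detection.
    """
    if record.excluded:
        raise ExcludedSpecimen(f"{record.specimen_id}: flagged excluded")
    if tare:
        record = dataclasses.replace(record, force_N=record.tared_force())
    failure_index, f_fail = detect_failure(record, drop_fraction, smooth=smooth)
    force = record.force_N
    peak_index = int(np.argmax(force[: failure_index + 1]))
    if peak_index < 1:
        raise DegenerateRecord(f"{record.specimen_id}: peak at first sample")
    f_max = float(force[peak_index])

    strain, stress = to_stress_strain(record)
    w_fail = work_to_failure(record, peak_index)
    toughness = compute_toughness(strain, stress, peak_index)
    modulus = estimate_modulus(strain, stress, peak_index, window)
    eps_fail = float(strain[peak_index])
    sigma_max = f_max / record.fracture_area_mm2 * 1e6

    return MaterialProperties(
        specimen_id=record.specimen_id,
        F_max_N=f_max,
        F_fail_N=f_fail,
        W_fail_J=w_fail,
        epsilon_fail=eps_fail,
        sigma_max_Pa=sigma_max,
        youngs_modulus_Pa=modulus,
        toughness_MJ_m3=toughness,
        failure_index=failure_index,
        peak_index=peak_index,
    )
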
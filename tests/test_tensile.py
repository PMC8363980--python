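"""Tensile-mechanics unit and property tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kelpmech as km
from kelpmech.errors import (
    DegenerateRecord,
    ExcludedSpecimen,
    NoFailureDetected,
)
from kelpmech.tensile import TensileRecord


def make_record(forces, extensions=None, L0=100.0, area=1.0, **kw) -> TensileRecord:
    forces = np.asarray(forces, dtype=float)
    if extensions is None:
        extensions = np.arange(forces.size, dtype=float)
    return TensileRecord("t", L0, area, np.asarray(extensions, float), forces, **kw)


class TestDetectFailure:
    def test_single_peak_instant_drop(self):
        rec = make_record([1, 2, 3, 1.4])
        idx, f_fail = km.detect_failure(rec, 0.5, smooth=False)
        assert idx == 3
        assert f_fail == 3.0

    def test_strictly_increasing_has_no_failure(self):
        rec = make_record([1, 2, 3])
        with pytest.raises(NoFailureDetected):
            km.detect_failure(rec, 0.5, smooth=False)

    def test_two_peak_series_matches_brute_force(self):
        # 40% dip (not qualifying at 50%), recovery to a higher peak, 60% drop
        forces = np.array([1.0, 2.0, 3.0, 1.8, 2.5, 3.5, 1.4])
        rec = make_record(forces)
        idx, f_fail = km.detect_failure(rec, 0.5, smooth=False)
        # independent brute-force scan of the running-max criterion
        expect = None
        for i in range(forces.size):
            if forces[i] <= 0.5 * forces[: i + 1].max():
                expect = i
                break
        assert expect == 6
        assert idx == expect
        assert f_fail == forces[: idx + 1].max() == 3.5

    def test_median_filter_ignores_single_sample_glitch(self):
        forces = np.array([1.0, 2.0, 3.0, 0.1, 3.1, 3.2, 3.3, 1.0, 1.0, 1.0])
        rec = make_record(forces)
        idx, f_fail = km.detect_failure(rec, 0.5, smooth=True)
        assert idx > 3          # the one-sample dropout is not the failure
        assert f_fail == pytest.approx(3.3)

    def test_too_short_record_is_degenerate(self):
        with pytest.raises(DegenerateRecord):
            make_record([1.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(tail=st.lists(st.floats(0.0, 1.4), min_size=0, max_size=10))
    def test_appending_post_failure_samples_changes_nothing(self, tail):
        base = [1.0, 2.0, 3.0, 1.4]
        rec0 = make_record(base)
        rec1 = make_record(base + tail)
        assert km.detect_failure(rec0, 0.5, smooth=False) == \
            km.detect_failure(rec1, 0.5, smooth=False)


class TestWorkAndStressStrain:
    def test_rectangle_and_triangle(self):
        rect = make_record([2.0] * 11, np.linspace(0, 10, 11))
        assert km.work_to_failure(rect, 10) == pytest.approx(0.02)
        tri = make_record(np.linspace(0, 10, 6), np.linspace(0, 5, 6))
        assert km.work_to_failure(tri, 5) == pytest.approx(0.025)

    def test_work_matches_panel_by_panel_sum(self):
        rng = np.random.default_rng(3)
        f = np.abs(rng.normal(5, 1, 50))
        x = np.cumsum(rng.uniform(0, 0.2, 50))
        rec = make_record(f, x)
        manual = sum((f[i] + f[i + 1]) / 2 * (x[i + 1] - x[i]) for i in range(49))
        assert km.work_to_failure(rec, 49) == pytest.approx(manual * 1e-3, rel=1e-12)

    def test_stress_strain_units(self):
        rec = make_record([3.0, 3.0, 3.0], [0.0, 5.0, 10.0], L0=100.0, area=2.0)
        strain, stress = km.to_stress_strain(rec)
        assert stress[0] == pytest.approx(1.5e6)
        assert strain[0] == 0.0
        assert strain[2] == pytest.approx(0.1)
        assert strain.size == stress.size == rec.n_samples


class TestModulus:
    def test_exact_on_noiseless_linear_curve_any_window(self):
        strain = np.linspace(0, 0.2, 100)
        stress = 5e6 * strain
        for w in (3, 5, 20, 100):
            assert km.estimate_modulus(strain, stress, 99, w) == pytest.approx(5e6, rel=1e-9)

    def test_toe_then_linear_returns_linear_slope(self):
        E, eps_t = 8e6, 0.05
        strain = np.linspace(0, 0.2, 200)
        c = E / (2 * eps_t)
        stress = np.where(strain <= eps_t, c * strain**2,
                          c * eps_t**2 + E * (strain - eps_t))
        w = 20
        est = km.estimate_modulus(strain, stress, 199, w)
        # oracle: enumerate every window's OLS slope
        slopes = [np.polyfit(strain[i:i + w], stress[i:i + w], 1)[0]
                  for i in range(200 - w + 1)]
        assert est == pytest.approx(max(slopes), rel=1e-9)
        assert est == pytest.approx(E, rel=1e-6)

    def test_too_few_prepeak_samples(self):
        strain = np.linspace(0, 0.1, 10)
        with pytest.raises(DegenerateRecord):
            km.estimate_modulus(strain, strain * 1e6, 3, 10)


class TestToughnessAndComposite:
    def test_linear_curve_triangle_area(self):
        strain = np.linspace(0, 0.1, 50)
        stress = 10e6 * strain            # sigma_max = 1 MPa at eps = 0.1
        tough = km.compute_toughness(strain, stress, 49)
        assert tough == pytest.approx(0.5 * 1e6 * 0.1 * 1e-6, rel=1e-12)

    def test_zero_force_record_has_zero_toughness(self):
        strain = np.linspace(0, 0.1, 10)
        assert km.compute_toughness(strain, np.zeros(10), 9) == 0.0

    def test_energy_identity_on_noisy_records(self, tensile_noisy_batch):
        for rec, _ in tensile_noisy_batch:
            p = km.extract_properties(rec)
            lhs = p.toughness_MJ_m3 * rec.fracture_area_mm2 * rec.initial_length_mm * 1e-3
            assert lhs == pytest.approx(p.W_fail_J, rel=1e-9)

    def test_excluded_specimen_raises(self, tensile_noiseless):
        rec, _ = tensile_noiseless
        flagged = dataclasses.replace(rec, excluded=True)
        with pytest.raises(ExcludedSpecimen):
            km.extract_properties(flagged)

    def test_force_scaling_invariance(self, tensile_noiseless):
        """Scaling forces by c scales sigma_max/toughness/W_fail by c, not eps_fail."""
        rec, _ = tensile_noiseless
        p1 = km.extract_properties(rec)
        c = 3.0
        p2 = km.extract_properties(dataclasses.replace(rec, force_N=c * rec.force_N))
        assert p2.sigma_max_Pa == pytest.approx(c * p1.sigma_max_Pa, rel=1e-12)
        assert p2.toughness_MJ_m3 == pytest.approx(c * p1.toughness_MJ_m3, rel=1e-12)
        assert p2.W_fail_J == pytest.approx(c * p1.W_fail_J, rel=1e-12)
        assert p2.epsilon_fail == p1.epsilon_fail

    def test_doubling_L0_halves_strain_doubles_modulus(self, tensile_noiseless):
        rec, _ = tensile_noiseless
        p1 = km.extract_properties(rec)
        p2 = km.extract_properties(dataclasses.replace(
            rec, initial_length_mm=2 * rec.initial_length_mm))
        assert p2.epsilon_fail == pytest.approx(p1.epsilon_fail / 2, rel=1e-12)
        assert p2.youngs_modulus_Pa == pytest.approx(2 * p1.youngs_modulus_Pa, rel=1e-6)
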
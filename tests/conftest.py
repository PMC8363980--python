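"""Shared fixtures: synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import kelpmech as km
from kelpmech.simulate import TensileSimSpec, simulate_tensile_test


def consistent_tensile_spec(**overrides) -> TensileSimSpec:
    """Build a TensileSimSpec whose redundant parameters are consistent.

    ``sigma_max_Pa`` is derived from (E, eps_fail, toe_fraction) unless
    explicitly supplied.
    """
    kw = dict(youngs_modulus_Pa=5.0e6, epsilon_fail=0.40, toe_fraction=0.20)
    kw.update(overrides)
    if "sigma_max_Pa" not in kw:
        kw["sigma_max_Pa"] = (
            kw["youngs_modulus_Pa"] * kw["epsilon_fail"] * (1 - kw["toe_fraction"] / 2)
        )
    return TensileSimSpec(**kw)


@pytest.fixture(scope="session")
def morph_default() -> tuple[pd.DataFrame, dict]:
    return km.simulate_morphometrics(km.MorphometricSimSpec(seed=11))


@pytest.fixture(scope="session")
def tensile_noiseless():
    return simulate_tensile_test(consistent_tensile_spec(seed=42))


@pytest.fixture(scope="session")
def tensile_noisy_batch():
    """Ten noisy tensile records with their ground truths."""
    out = []
    for seed in range(10):
        spec = consistent_tensile_spec(noise_sd_N=0.02, seed=seed,
                                       specimen_id=f"noisy{seed:02d}")
        out.append(simulate_tensile_test(spec))
    return out


@pytest.fixture()
def juvenile_tensile_records(morph_default):
    """One tensile record per juvenile specimen with size-dependent stiffness."""
    df, _ = morph_default
    rng = np.random.default_rng(99)
    records = []
    for _, row in df[df.life_stage == "juvenile"].iterrows():
        E = 5.0e6 * (row.stipe_length_cm / 10.0) ** -1.2
        spec = consistent_tensile_spec(
            youngs_modulus_Pa=E,
            L0_mm=row.stipe_length_cm * 10.0,
            area_mm2=2.0 * (row.stipe_length_cm / 10.0) ** 0.8,
            noise_sd_N=0.005,
            seed=int(rng.integers(2**31)),
            specimen_id=row.specimen_id,
        )
        records.append(simulate_tensile_test(spec)[0])
    return records
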
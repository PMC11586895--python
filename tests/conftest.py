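import numpy as np
import pytest

from pepdimer.synthetic import NoiseSpec, TwoRegimeThermo, generate_vant_hoff_intensities

# Reference two-regime dimerization parameters used across tests:
# breakpoint 293 K, regime enthalpies -26.4 / -71.1 kJ/mol, and an
# entropic term of +53.6 kJ/mol at 293 K in the high-temperature regime.
REF_BREAKPOINT = 293.0
REF_DH_LOW = -26.4
REF_DH_HIGH = -71.1
REF_MTDS_HIGH = 53.6
REF_TREF = 293.0


@pytest.fixture
def ref_thermo() -> TwoRegimeThermo:
    return TwoRegimeThermo(
        breakpoint_temperature=REF_BREAKPOINT,
        dH_low=REF_DH_LOW,
        dH_high=REF_DH_HIGH,
        mTdS_ref_high=REF_MTDS_HIGH,
        reference_temperature_high=REF_TREF,
        reference_temperature_low=REF_TREF,
    )


@pytest.fixture
def high_regime_thermo() -> TwoRegimeThermo:
    return TwoRegimeThermo.single_regime(REF_DH_HIGH, REF_MTDS_HIGH, REF_TREF)


@pytest.fixture
def noiseless_two_regime_table(ref_thermo):
    temps = np.arange(278.0, 358.0 + 1e-9, 5.0)
    return generate_vant_hoff_intensities(
        ref_thermo, temps, noise=NoiseSpec(replicates=1, cv=0.0, seed=0)
    )


@pytest.fixture
def noiseless_high_regime_table(high_regime_thermo):
    temps = np.arange(298.0, 358.0 + 1e-9, 5.0)
    return generate_vant_hoff_intensities(
        high_regime_thermo, temps, noise=NoiseSpec(replicates=1, cv=0.0, seed=0)
    )
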
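import pytest

from rhcmr.synthetic import (
    PhantomSpec,
    make_velocity_phantom,
    make_ventricle_phantom,
)


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Default two-ventricle cylinder phantom with closed-form ground truth."""
    return make_ventricle_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def velocity_phantom():
    """80 mL/beat antegrade, 10% retrograde, RR 1 s, BSA 2 m² velocity series."""
    return make_velocity_phantom(
        antegrade_ml_per_beat=80.0,
        retrograde_fraction=0.1,
        rr_interval=1.0,
        bsa=2.0,
        mean_velocity=7.6,
        area_pulsatility_pct=15.0,
        seed=11,
    )
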
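import numpy as np
import pytest

from holdoutcca.synthio import (
    PlantedDimension,
    RiskFactorBlock,
    SynthConfig,
    generate_cohort,
    generate_parcel_geometry,
)


@pytest.fixture(scope="session")
def geometry148():
    return generate_parcel_geometry(148, seed=0)


@pytest.fixture(scope="session")
def single_dim_cohort():
    """n=2,000 cohort with one planted dimension at r = 0.5."""
    cfg = SynthConfig(
        n_subjects=2000,
        n_risk_factors=20,
        n_parcels=40,
        planted_dims=(PlantedDimension(0.5, 0.5, (3.0, 0.0)),),
        rf_blocks=(RiskFactorBlock(6, 0.6), RiskFactorBlock(5, 0.6)),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted association between X and Y."""
    cfg = SynthConfig(
        n_subjects=800,
        n_risk_factors=12,
        n_parcels=24,
        planted_dims=(PlantedDimension(0.0, 0.5, (0.0,)),),
        rf_blocks=(RiskFactorBlock(4, 0.6),),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
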
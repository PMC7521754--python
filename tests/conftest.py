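import numpy as np
import pytest

from otolithbc import (
    AnalysisConfig,
    SimConfig,
    add_year_labels,
    analyze_cohorts,
    back_calculate_all,
    fit,
    pool_by_age,
    simulate_population,
)
from otolithbc.data_model import FishRecord


def make_fish(
    fish_id="F1",
    status="MR",
    site="MR1",
    capture_year=2015,
    age=3,
    length=80.0,
    radius=0.55,
    radii=(0.2, 0.35, 0.5),
):
    return FishRecord(
        fish_id=fish_id, status=status, site=site, capture_year=capture_year,
        age=age, length_capture=length, radius_capture=radius,
        radii=tuple(radii),
    )


@pytest.fixture
def fish_factory():
    return make_fish


@pytest.fixture(scope="session")
def default_sim():
    """One realisation of the default survey (noisy, with injected effects)."""
    return simulate_population(SimConfig(), seed=7)


@pytest.fixture(scope="session")
def noise_free_sim():
    """Survey generated exactly on the allometry (no noise anywhere)."""
    cfg = SimConfig(noise_sd_radius=0.0, cv_length_capture=0.0)
    records, truth = simulate_population(cfg, seed=11)
    return cfg, records, truth


@pytest.fixture(scope="session")
def analyzed(default_sim):
    """Full downstream analysis of the default survey."""
    records, truth = default_sim
    params = fit(records)
    obs = add_year_labels(back_calculate_all(records, params))
    datasets = pool_by_age(obs)
    results = analyze_cohorts(datasets)
    return dict(
        records=records, truth=truth, params=params, obs=obs,
        datasets=datasets, results=results,
    )
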
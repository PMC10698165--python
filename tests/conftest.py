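import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trophlink import AnnualSeries, CalibrationConstants, simulate_latent_walk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib() -> CalibrationConstants:
    return CalibrationConstants.default()


def make_reference_series(
    seed: int,
    n_years: int = 45,
    q: float = 0.04,
    r: float = 0.25,
    obs_per_year: int = 5,
    missing_fraction: float = 0.40,
    x1: float = 3.0,
) -> tuple[AnnualSeries, dict[int, float]]:
    """Reference study design: random-walk truth observed with replicates,
    a fraction of years unsampled.  Returns (series, latent truth)."""
    rng = np.random.default_rng(seed)
    truth = simulate_latent_walk(n_years, q, x1, seed=rng)
    years = sorted(truth)
    n_missing = round(missing_fraction * n_years)
    missing = set(rng.choice(years, size=n_missing, replace=False).tolist())
    obs = [
        (y, truth[y] + rng.normal(0.0, np.sqrt(r)), f"r{i}")
        for y in years
        if y not in missing
        for i in range(obs_per_year)
    ]
    series = AnnualSeries("reference", obs, year_range=(years[0], years[-1]))
    return series, truth


@pytest.fixture(scope="session")
def reference_series():
    return make_reference_series(seed=20260925)
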
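"""Shared fixtures and scaled study conditions for the test suite."""

import numpy as np
import pytest

from nircal.io import SpectraSet
from nircal.pipeline import PipelineConfig
from nircal.selection import CarsConfig, GaConfig
from nircal.synthetic import SyntheticConfig, simulate

# Scaled selector settings used for fixture studies: the CARS Monte Carlo
# budget matches the full protocol (100 runs); the GA budget is reduced
# (10 runs x 10 generations, population 16, one repeat) with the frequency
# threshold scaled to 2 of 10 runs, so multi-seed studies stay tractable.
FIXTURE_CARS = dict(n_runs=100, cv_folds=10, max_lvs=15)
FIXTURE_GA = dict(
    n_runs=10,
    population=16,
    generations=10,
    n_repeats=1,
    frequency_threshold=2,
    cv_folds=5,
    max_lvs=10,
)


def fixture_pipeline_config(seed: int, analytes=("abts",), **kwargs) -> PipelineConfig:
    return PipelineConfig(
        analytes=analytes,
        ga=GaConfig(**FIXTURE_GA),
        cars=CarsConfig(**FIXTURE_CARS),
        n_perm=10,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default study conditions (111 samples, 1557 vars)."""
    return simulate(SyntheticConfig(seed=42))


@pytest.fixture()
def small_spectra():
    """A well-behaved 8-sample, 40-wavelength spectra set."""
    rng = np.random.default_rng(7)
    lam = np.linspace(1000.0, 2500.0, 40)
    base = np.exp(-((lam - 1700.0) ** 2) / (2 * 150.0**2))
    X = np.outer(rng.uniform(0.5, 2.0, 8), base) + rng.normal(0, 0.01, (8, 40))
    return SpectraSet(lam, X, [f"S{i}" for i in range(8)])
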
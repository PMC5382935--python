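"""Shared fixtures: one toy genome, one trained model set, and the standard
validation cohorts, all seeded and session-scoped so the expensive fits run
once."""

from __future__ import annotations

import numpy as np
import pytest

from cfnips.pipeline import call_cohort, train_models
from cfnips.report import reports_to_frame
from cfnips.simulate import (
    SimConfig,
    make_bins,
    simulate_cohort,
    training_scenarios,
)

BINS_SEED = 1
TRAIN_SEED = 2
SEPARATION_SEED = 3


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def bins(sim_config):
    return make_bins(sim_config, seed=BINS_SEED)


@pytest.fixture(scope="session")
def training(bins, sim_config):
    counts, truth = simulate_cohort(
        bins, training_scenarios(n_euploid=200, n_adult=15), sim_config,
        seed=TRAIN_SEED, prefix="T")
    return counts, truth


@pytest.fixture(scope="session")
def models(training, bins):
    counts, _ = training
    return train_models(counts, bins, seed=0)


@pytest.fixture(scope="session")
def separation_cohort(bins, sim_config):
    """The seeded verification cohort: 100 euploid + 20 T21 + 10 T18 + 10 T13
    singletons at FF ~ Uniform(0.08, 0.15) and 1.2e7 reads."""
    scen = [("euploid_female", 50), ("euploid_male", 50),
            ("t21", 20), ("t18", 10), ("t13", 10)]
    return simulate_cohort(bins, scen, sim_config, seed=SEPARATION_SEED,
                           prefix="C")


@pytest.fixture(scope="session")
def separation_reports(separation_cohort, models):
    cohort, truth = separation_cohort
    reports = call_cohort(cohort, models)
    return reports, reports_to_frame(reports), truth


@pytest.fixture(scope="session")
def sexaneu_cohort(bins, models):
    """20 samples per sex karyotype at FF ~ Uniform(0.08, 0.20)."""
    config = SimConfig(ff_range=(0.08, 0.20))
    scen = [(k, 20) for k in ["XX", "XY", "45X", "XXX", "XXY", "XYY"]]
    cohort, truth = simulate_cohort(bins, scen, config, seed=9, prefix="S")
    df = reports_to_frame(call_cohort(cohort, models))
    return df, truth


@pytest.fixture(scope="session")
def male_ff_cohort(bins, models):
    """60 male-fetus samples across the wide FF grid 0.04-0.25."""
    config = SimConfig(ff_range=(0.04, 0.25))
    cohort, truth = simulate_cohort(bins, [("euploid_male", 60)], config,
                                    seed=8, prefix="M")
    df = reports_to_frame(call_cohort(cohort, models))
    return df, truth
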
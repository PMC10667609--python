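"""Shared fixtures: one simulated cohort and one desk-scale growth fit
are reused across the suite (session scope) so the MCMC runs once."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import medaka_ipm as m
from medaka_ipm.growth import PARAM_NAMES


@pytest.fixture(scope="session")
def default_cfg() -> m.CohortConfig:
    return m.default_config()


@pytest.fixture(scope="session")
def cohort(default_cfg) -> m.SimulatedCohort:
    return m.simulate_experiment(default_cfg, seed=1)


@pytest.fixture(scope="session")
def fitted_draws(cohort) -> m.PosteriorDraws:
    """Desk-scale hierarchical growth fit on the shared cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.fit_growth(cohort.growth, m.McmcConfig.test_scale(seed=3))


@pytest.fixture(scope="session")
def demography(cohort, fitted_draws) -> dict:
    """Per-treatment vital rates, grids and demographic estimates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.demography_from_fit(cohort, fitted_draws, n_mesh=400)


def make_draws(param_sets: dict[str, np.ndarray]) -> m.PosteriorDraws:
    """Fabricate a PosteriorDraws from explicit (n, 3) parameter arrays
    keyed by treatment; used to test posterior consumers in isolation."""
    data = {}
    n = None
    for key, th in param_sets.items():
        th = np.asarray(th, dtype=float)
        n = th.shape[0]
        for j, pname in enumerate(PARAM_NAMES):
            data[f"{pname}[{key}]"] = th[:, j]
    data["chain"] = np.zeros(n, dtype=int)
    data["draw"] = np.arange(n)
    return m.PosteriorDraws(
        samples=pd.DataFrame(data), treatments=list(param_sets), tanks=[]
    )
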
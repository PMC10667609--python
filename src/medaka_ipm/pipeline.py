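"""End-to-end convenience chain: cohort data -> growth posterior ->
vital rates -> IPM demography, per treatment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import (
    McmcConfig,
    PosteriorDraws,
    VBParams,
    fit_growth,
    treatment_key,
    vb_length,
)
from .ipm import DemographicEstimates, IPMGrid, assemble_kernels, asymptotic_lambda, build_grid, generation_time
from .synthetic import CohortConfig, SimulatedCohort, default_config, simulate_experiment
from .vitals import (
    VitalRates,
    age_to_size,
    fit_fecundity,
    fit_survival_logistic,
    growth_residual_sd,
    kaplan_meier,
    reproduction_probability,
)

__all__ = ["TreatmentDemography", "PipelineResult", "build_vital_rates", "run_pipeline", "demography_from_fit"]


@dataclass
class TreatmentDemography:
    treatment: str
    params: VBParams
    vitals: VitalRates
    grid: IPMGrid
    estimates: DemographicEstimates


@dataclass
class PipelineResult:
    cohort: SimulatedCohort
    draws: PosteriorDraws
    treatments: dict[str, TreatmentDemography]

    def summary(self) -> pd.DataFrame:
        rows = [
            (
                k,
                d.estimates.lam,
                d.estimates.R0,
                d.estimates.T,
                d.estimates.converged,
            )
            for k, d in self.treatments.items()
        ]
        return pd.DataFrame(rows, columns=["treatment", "lambda", "R0", "T", "converged"])


def build_vital_rates(
    draws: PosteriorDraws,
    treatment: str,
    survival: pd.DataFrame,
    clutch: pd.DataFrame,
    recruits,
    maturity_age: float,
    female_fraction: float = 0.5,
    steepness: float = 50.0,
    survival_mode: str = "per_step",
    residual_ages=None,
) -> tuple[VBParams, VitalRates]:
    """Point-estimate vital rates for one treatment from posterior means
    and the treatment's survival / clutch tables."""
    params = draws.mean_params(treatment)
    if residual_ages is None:
        residual_ages = np.arange(30.0, 351.0)
    key_s = [
        treatment_key(t, f)
        for t, f in zip(survival["treatment_temp"], survival["treatment_food"])
    ]
    key_c = [
        treatment_key(t, f)
        for t, f in zip(clutch["treatment_temp"], clutch["treatment_food"])
    ]
    surv_t = survival[np.asarray(key_s) == treatment]
    clutch_t = clutch[np.asarray(key_c) == treatment]
    km = kaplan_meier(surv_t)
    s = fit_survival_logistic(km, params, mode=survival_mode)
    fec = fit_fecundity(clutch_t)
    sd_g = growth_residual_sd(draws, treatment, residual_ages)
    z_mat = age_to_size(params, maturity_age)
    vit = VitalRates(
        survival=s,
        growth_params=params,
        growth_sd_log=sd_g,
        reproduction=reproduction_probability(z_mat, steepness),
        fecundity=fec,
        recruits=recruits,
        female_fraction=female_fraction,
    )
    return params, vit


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 0,
    mcmc: McmcConfig | None = None,
    n_mesh: int = 400,
    steepness: float = 50.0,
    survival_mode: str = "per_step",
    global_upper: bool = False,
) -> PipelineResult:
    """Simulate a cohort, fit growth, build vital rates and solve the
    IPM for every treatment.

    The size domain runs from the predicted log size at 30 days to the
    maximum observed log size, per treatment by default (one shared
    upper bound with ``global_upper=True``).
    """
    if config is None:
        config = default_config()
    if mcmc is None:
        mcmc = McmcConfig.test_scale(seed=seed)
    cohort = simulate_experiment(config, seed)
    draws = fit_growth(cohort.growth, mcmc)
    out = demography_from_fit(
        cohort,
        draws,
        n_mesh=n_mesh,
        steepness=steepness,
        survival_mode=survival_mode,
        global_upper=global_upper,
    )
    return PipelineResult(cohort=cohort, draws=draws, treatments=out)


def demography_from_fit(
    cohort: SimulatedCohort,
    draws: PosteriorDraws,
    n_mesh: int = 400,
    steepness: float = 50.0,
    survival_mode: str = "per_step",
    global_upper: bool = False,
) -> dict[str, TreatmentDemography]:
    """Vital rates, kernels and demography per treatment from an
    already-fitted growth posterior."""
    config = cohort.config
    growth = cohort.growth.copy()
    growth["treatment"] = [
        treatment_key(t, f)
        for t, f in zip(growth["treatment_temp"], growth["treatment_food"])
    ]
    u_global = float(np.log(growth["length_mm"].max()))

    out: dict[str, TreatmentDemography] = {}
    for key in draws.treatments:
        truth = config.treatments[key]
        params, vit = build_vital_rates(
            draws,
            key,
            cohort.survival,
            cohort.clutch,
            cohort.recruits,
            maturity_age=truth.maturity_age_days,
            female_fraction=config.female_fraction,
            steepness=steepness,
            survival_mode=survival_mode,
        )
        L = float(np.log(vb_length(params, 30.0)))
        U = u_global if global_upper else float(
            np.log(growth.loc[growth["treatment"] == key, "length_mm"].max())
        )
        grid = build_grid(L, U, n_mesh)
        kern = assemble_kernels(grid, vit)
        est = asymptotic_lambda(kern)
        est = generation_time(kern, est)
        out[key] = TreatmentDemography(
            treatment=key, params=params, vitals=vit, grid=grid, estimates=est
        )
    return out
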
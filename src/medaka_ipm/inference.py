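"""Uncertainty propagation and sensitivity analysis for the demography.

Bootstrap: each replicate pairs one posterior draw of the growth
parameters (sampled with replacement) with nonparametric case resamples
of the survival and clutch tables, refits every size-based vital rate,
reassembles the kernel and records lambda and the generation time T.
Percentile 95% confidence intervals are taken over the replicates and
treatments are compared by interval overlap.

Sensitivity: central finite differences of lambda and T with respect to
each scalar vital-rate parameter, with elasticities alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .growth import PosteriorDraws, VBParams, treatment_key, vb_length
from .ipm import IPMGrid, assemble_kernels, asymptotic_lambda, build_grid, generation_time
from .synthetic import RecruitParams
from .vitals import (
    LogisticCurve,
    VitalRates,
    age_to_size,
    fit_fecundity,
    fit_survival_logistic,
    kaplan_meier,
    reproduction_probability,
)

__all__ = [
    "BootstrapResult",
    "bootstrap_demography",
    "compare_by_ci",
    "sensitivity_analysis",
]


@dataclass
class BootstrapResult:
    """Bootstrap replicate values of lambda and T for one treatment."""

    treatment: str
    lam: np.ndarray
    T: np.ndarray
    n_requested: int
    n_failures: int
    seed: int

    def ci(self, quantity: str) -> tuple[float, float]:
        vals = self._values(quantity)
        return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))

    def median(self, quantity: str) -> float:
        return float(np.median(self._values(quantity)))

    def _values(self, quantity: str) -> np.ndarray:
        if quantity == "lambda":
            return self.lam
        if quantity == "T":
            return self.T
        raise ValueError("quantity must be 'lambda' or 'T'")


def _residual_sd_from_draws(th: np.ndarray, ages: np.ndarray) -> float:
    """Average over ages of the across-draw sd of log size after one
    daily growth step (see vitals.growth_residual_sd)."""
    L, K, t0 = th[:, 0:1], th[:, 1:2], th[:, 2:3]
    Lt = L * (1.0 - np.exp(-K * (ages[None, :] - t0)))
    decay = np.exp(-K)
    Lt1 = Lt * decay + L * (1.0 - decay)
    ok = np.all(Lt1 > 0, axis=0)
    if not ok.any():
        raise ValueError("no age with positive predicted lengths")
    return float(np.log(Lt1[:, ok]).std(axis=0, ddof=0).mean())


def _with_key(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["treatment"] = [
        treatment_key(t, f) for t, f in zip(df["treatment_temp"], df["treatment_food"])
    ]
    return df


def bootstrap_demography(
    draws: PosteriorDraws,
    survival: pd.DataFrame,
    clutch: pd.DataFrame,
    recruits: RecruitParams,
    maturity_age: dict[str, float],
    n_boot: int = 1000,
    seed: int = 0,
    n_mesh: int = 400,
    grid_upper: dict[str, float] | None = None,
    female_fraction: float = 0.5,
    steepness: float = 50.0,
    survival_mode: str = "per_step",
    resample: bool = True,
    block_by_tank: bool = False,
    residual_ages=None,
    residual_subsample: int = 500,
    max_failure_frac: float = 0.10,
    treatments: list[str] | None = None,
) -> dict[str, BootstrapResult]:
    """Bootstrap distributions of lambda and T, per treatment.

    Per replicate: one (L_inf, K, t0) draw is sampled with replacement
    from the posterior; the survival and clutch tables are case-
    resampled with replacement at the record level (or by whole tanks
    with ``block_by_tank``); s, f_p, f_n and the growth residual sd are
    refit; the IPM is assembled on a grid from the predicted 30-day log
    size to ``grid_upper`` (default: largest observed log size in the
    treatment's clutch table) and solved.  Replicates whose refits
    degenerate are recorded as failures and excluded; more than
    ``max_failure_frac`` failures is a hard error.
    """
    survival = _with_key(survival)
    clutch = _with_key(clutch)
    if residual_ages is None:
        residual_ages = np.arange(30.0, 351.0)
    else:
        residual_ages = np.asarray(residual_ages, dtype=float)

    results: dict[str, BootstrapResult] = {}
    keys = treatments if treatments is not None else draws.treatments
    for k_idx, key in enumerate(keys):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k_idx]))
        th_all = draws.treatment_draws(key)
        surv_t = survival[survival["treatment"] == key].reset_index(drop=True)
        clutch_t = clutch[clutch["treatment"] == key].reset_index(drop=True)
        if len(surv_t) == 0 or len(clutch_t) == 0:
            raise ValueError(f"no survival or clutch data for treatment {key}")
        upper = (
            grid_upper[key]
            if grid_upper is not None
            else float(np.log(clutch_t["female_length_mm"].max()))
        )
        lam_vals, T_vals, failures = [], [], 0
        for _ in range(n_boot):
            try:
                params = VBParams(*th_all[rng.integers(len(th_all))])
                if resample:
                    surv_r = _resample(surv_t, rng, block_by_tank)
                    clutch_r = _resample(clutch_t, rng, block_by_tank)
                    sub = rng.integers(len(th_all), size=min(len(th_all), residual_subsample))
                    th_sub = th_all[sub]
                else:
                    surv_r, clutch_r, th_sub = surv_t, clutch_t, th_all
                km = kaplan_meier(surv_r)
                s = fit_survival_logistic(km, params, mode=survival_mode)
                fec = fit_fecundity(clutch_r)
                sd_g = _residual_sd_from_draws(th_sub, residual_ages)
                z_mat = age_to_size(params, maturity_age[key])
                L = float(np.log(vb_length(params, 30.0)))
                if not L < upper:
                    raise ValueError("degenerate grid bounds")
                grid = build_grid(L, upper, n_mesh)
                vit = VitalRates(
                    survival=s,
                    growth_params=params,
                    growth_sd_log=sd_g,
                    reproduction=reproduction_probability(z_mat, steepness),
                    fecundity=fec,
                    recruits=recruits,
                    female_fraction=female_fraction,
                )
                kern = assemble_kernels(grid, vit)
                est = generation_time(kern)
                if est.T is None or not np.isfinite(est.lam):
                    raise ValueError("undefined demography")
                lam_vals.append(est.lam)
                T_vals.append(est.T)
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
        if failures > max_failure_frac * n_boot:
            raise ValueError(
                f"treatment {key}: {failures}/{n_boot} bootstrap replicates failed"
            )
        results[key] = BootstrapResult(
            treatment=key,
            lam=np.asarray(lam_vals),
            T=np.asarray(T_vals),
            n_requested=n_boot,
            n_failures=failures,
            seed=seed,
        )
    return results


def _resample(df: pd.DataFrame, rng: np.random.Generator, block_by_tank: bool) -> pd.DataFrame:
    if block_by_tank:
        tanks = df["tank_id"].unique()
        chosen = rng.choice(tanks, size=len(tanks), replace=True)
        parts = [df[df["tank_id"] == t] for t in chosen]
        return pd.concat(parts, ignore_index=True)
    idx = rng.integers(0, len(df), size=len(df))
    return df.iloc[idx].reset_index(drop=True)


def compare_by_ci(a: BootstrapResult, b: BootstrapResult, quantity: str) -> bool:
    """True when the two 95% bootstrap intervals are disjoint
    (closed-interval convention: touching endpoints overlap)."""
    lo_a, hi_a = a.ci(quantity)
    lo_b, hi_b = b.ci(quantity)
    return hi_a < lo_b or hi_b < lo_a


# ---------------------------------------------------------------------------
# Sensitivity analysis

_PROB_PARAMS = {"f_g", "female_fraction"}


def _get_params(vitals: VitalRates) -> dict[str, float]:
    fp = vitals.reproduction
    return {
        "survival_intercept": vitals.survival.intercept,
        "survival_slope": vitals.survival.slope,
        "fp_midpoint": -fp.intercept / fp.slope if fp.slope != 0 else 0.0,
        "fp_steepness": fp.slope,
        "fecundity_a": vitals.fecundity.a,
        "fecundity_b": vitals.fecundity.b,
        "f_g": vitals.recruits.f_g,
        "female_fraction": vitals.female_fraction,
        "juvenile_mean": vitals.recruits.juvenile_logsize_mean,
        "juvenile_sd": vitals.recruits.juvenile_logsize_sd,
        "growth_sd": vitals.growth_sd_log,
        "L_inf": vitals.growth_params.L_inf,
        "K": vitals.growth_params.K,
    }


def _set_param(vitals: VitalRates, name: str, value: float) -> VitalRates:
    v = replace(vitals)
    if name == "survival_intercept":
        v.survival = LogisticCurve(value, vitals.survival.slope)
    elif name == "survival_slope":
        v.survival = LogisticCurve(vitals.survival.intercept, value)
    elif name in ("fp_midpoint", "fp_steepness"):
        fp = vitals.reproduction
        mid = -fp.intercept / fp.slope if fp.slope != 0 else 0.0
        steep = fp.slope
        if name == "fp_midpoint":
            mid = value
        else:
            steep = value
        v.reproduction = LogisticCurve(-steep * mid, steep)
    elif name == "fecundity_a":
        v.fecundity = replace(vitals.fecundity, a=value)
    elif name == "fecundity_b":
        v.fecundity = replace(vitals.fecundity, b=value)
    elif name == "f_g":
        v.recruits = replace(vitals.recruits, f_g=value)
    elif name == "female_fraction":
        v.female_fraction = value
    elif name == "juvenile_mean":
        v.recruits = replace(vitals.recruits, juvenile_logsize_mean=value)
    elif name == "juvenile_sd":
        v.recruits = replace(vitals.recruits, juvenile_logsize_sd=value)
    elif name == "growth_sd":
        v.growth_sd_log = value
    elif name == "L_inf":
        v.growth_params = replace(vitals.growth_params, L_inf=value)
    elif name == "K":
        v.growth_params = replace(vitals.growth_params, K=value)
    else:
        raise KeyError(name)
    return v


def _demography(vitals: VitalRates, grid: IPMGrid) -> tuple[float, float]:
    kern = assemble_kernels(grid, vitals)
    est = asymptotic_lambda(kern)
    est = generation_time(kern, est)
    return est.lam, (est.T if est.T is not None else np.nan)


def sensitivity_analysis(
    vitals: VitalRates,
    grid: IPMGrid,
    delta: float = 0.01,
) -> pd.DataFrame:
    """Central-finite-difference sensitivities of lambda and T.

    Each scalar vital-rate parameter theta is perturbed to
    theta * (1 +/- delta) (an absolute step delta when theta = 0); the
    grid is held fixed.  Probability parameters pushed outside [0, 1]
    are clamped on that side and flagged.  Returns a table with
    d_lambda/d_theta, d_T/d_theta and the corresponding elasticities
    (theta / lambda) * d_lambda / d_theta.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    lam0, T0 = _demography(vitals, grid)
    rows = []
    for name, theta in _get_params(vitals).items():
        step = delta * abs(theta) if theta != 0 else delta
        lo, hi = theta - step, theta + step
        clamped = False
        if name in _PROB_PARAMS:
            lo_c, hi_c = max(lo, 0.0), min(hi, 1.0)
            clamped = (lo_c != lo) or (hi_c != hi)
            lo, hi = lo_c, hi_c
        if hi == lo:
            rows.append((name, theta, 0.0, 0.0, 0.0, 0.0, clamped))
            continue
        lam_hi, T_hi = _demography(_set_param(vitals, name, hi), grid)
        lam_lo, T_lo = _demography(_set_param(vitals, name, lo), grid)
        d_lam = (lam_hi - lam_lo) / (hi - lo)
        d_T = (T_hi - T_lo) / (hi - lo)
        rows.append(
            (
                name,
                theta,
                d_lam,
                d_T,
                theta / lam0 * d_lam if lam0 != 0 else np.nan,
                theta / T0 * d_T if T0 not in (0.0, np.nan) and np.isfinite(T0) else np.nan,
                clamped,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "value",
            "d_lambda",
            "d_T",
            "elasticity_lambda",
            "elasticity_T",
            "clamped",
        ],
    )
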
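"""Size-based vital rates on the log-length domain.

Builds the six demographic ingredients of the daily-step projection
kernel from data and the fitted growth model:

* ``s``  — size-dependent daily survival, a logistic curve obtained by
  mapping Kaplan–Meier survival through the age–size relationship;
* ``g``  — growth transition inputs (Von Bertalanffy parameters plus the
  residual spread of the one-day growth update, on the log scale);
* ``f_p`` — probability of reproducing, a steep logistic at the size
  reached at maturity age;
* ``f_n`` — expected daily egg number, Poisson regression on log length;
* ``f_g`` — egg hatching x juvenile survival probability;
* ``f_d`` — juvenile log-size distribution (Normal).

The state variable z is the natural log of total length in mm; the
projection time step is one day, so all rates here are per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.special import expit, logit

import statsmodels.api as sm

from .growth import PosteriorDraws, VBParams, vb_length
from .synthetic import RecruitParams

__all__ = [
    "KMCurve",
    "LogisticCurve",
    "FecundityModel",
    "VitalRates",
    "kaplan_meier",
    "age_to_size",
    "fit_survival_logistic",
    "reproduction_probability",
    "fit_fecundity",
    "growth_residual_sd",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate from the entry day.

    ``times`` are the distinct observed event/censoring ages,
    ``survival`` the estimate S(t) (non-increasing, S(entry) = 1),
    ``at_risk`` / ``events`` the risk-set size and death count at each
    time.
    """

    entry: float
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """Step-function value of S at arbitrary ages."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out


@dataclass
class LogisticCurve:
    """p(z) = expit(intercept + slope * z); used for s and f_p.

    Fitted curves carry Wald standard errors; constructed curves (f_p)
    leave them at None.
    """

    intercept: float
    slope: float
    degenerate: bool = False  # flat fallback fit
    intercept_se: float | None = None
    slope_se: float | None = None

    def __call__(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = expit(self.intercept + self.slope * z)
        return out if out.ndim else float(out)


@dataclass
class FecundityModel:
    """Expected eggs per female per day: exp(a + b * z)."""

    a: float
    b: float
    a_se: float | None = None
    b_se: float | None = None

    def __call__(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.exp(self.a + self.b * z)
        return out if out.ndim else float(out)


@dataclass
class VitalRates:
    """Everything the kernel assembly needs for one treatment."""

    survival: LogisticCurve
    growth_params: VBParams
    growth_sd_log: float
    reproduction: LogisticCurve
    fecundity: FecundityModel
    recruits: RecruitParams
    female_fraction: float = 0.5


def kaplan_meier(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimator for survival records.

    ``records`` needs columns entry_day, exit_day, event (values
    'death' / 'censored').  Censored fish leave the risk set after
    their exit day.
    """
    if records is None or len(records) == 0:
        raise ValueError("no survival records")
    entry = records["entry_day"].to_numpy(dtype=float)
    exit_ = records["exit_day"].to_numpy(dtype=float)
    if np.any(exit_ < entry):
        raise ValueError("exit before entry in survival records")
    observed = (records["event"] == "death").to_numpy()

    kmf = KaplanMeierFitter()
    # lifelines requires durations strictly after entry; exits recorded on
    # the entry day get a half-day offset so they stay in the risk set.
    exit_adj = np.where(exit_ <= entry, entry + 0.5, exit_)
    kmf.fit(exit_adj, event_observed=observed, entry=entry)
    table = kmf.event_table.iloc[1:]  # drop the entry row
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        entry=float(entry.min()),
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        events=table["observed"].to_numpy(dtype=float),
    )


def age_to_size(params: VBParams, age) -> np.ndarray:
    """Log length at a given age under the fitted growth curve."""
    L = vb_length(params, age)
    if np.any(np.asarray(L) <= 0):
        raise ValueError("predicted length is non-positive at this age (age too close to t0)")
    out = np.log(L)
    return out if np.ndim(out) else float(out)


def _flat_logistic(p: float) -> LogisticCurve:
    p = float(np.clip(p, 1e-9, 1.0 - 1e-9))
    return LogisticCurve(intercept=float(logit(p)), slope=0.0, degenerate=True)


def fit_survival_logistic(
    km: KMCurve,
    params: VBParams,
    mode: str = "per_step",
) -> LogisticCurve:
    """Logistic regression of survival on log size.

    In ``per_step`` mode (default, demographically consistent with a
    daily-step kernel) the daily survival probability p_t = S(t)/S(t-1)
    is computed on the daily grid spanned by the Kaplan–Meier curve,
    paired with z(t) from the age–size relationship, and fit by a
    binomial GLM weighted by the numbers at risk.  In ``cumulative``
    mode the cumulative S(t) itself is regressed on z(t).

    A degenerate fit (no deaths, or perfectly separated outcomes) falls
    back to a flat curve at the observed mean with a warning flag.
    """
    if mode not in ("per_step", "cumulative"):
        raise ValueError("mode must be 'per_step' or 'cumulative'")
    if km.times.size == 0:
        raise ValueError("empty Kaplan-Meier curve")

    days = np.arange(int(km.entry) + 1, int(km.times.max()) + 1, dtype=float)
    S_now = km.evaluate(days)
    S_prev = km.evaluate(days - 1.0)
    weights = np.interp(days, km.times, km.at_risk)
    keep = S_prev > 0
    days, S_now, S_prev, weights = days[keep], S_now[keep], S_prev[keep], weights[keep]
    if days.size < 2:
        raise ValueError("not enough ages with positive survival to fit")
    if mode == "per_step":
        p = S_now / S_prev
    else:
        p = S_now
    z = np.log(np.maximum(vb_length(params, days), 1e-12))

    if np.allclose(p, p[0], atol=1e-12) or np.ptp(z) < 1e-12:
        return _flat_logistic(np.average(p, weights=weights))
    X = sm.add_constant(z)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(p, X, family=sm.families.Binomial(), var_weights=weights).fit()
        if not np.all(np.isfinite(fit.params)) or abs(fit.params[1]) > 1e3:
            raise ValueError("degenerate logistic fit")
        return LogisticCurve(
            float(fit.params[0]),
            float(fit.params[1]),
            intercept_se=float(fit.bse[0]),
            slope_se=float(fit.bse[1]),
        )
    except Exception:
        warnings.warn("survival logistic fit degenerated; using flat curve", RuntimeWarning)
        return _flat_logistic(np.average(p, weights=weights))


def reproduction_probability(z_mat: float, steepness: float = 50.0) -> LogisticCurve:
    """Steep logistic switching on at the maturity size.

    f_p(z) = 1 / (1 + exp(-steepness * (z - z_mat))); all fish are
    assumed to reproduce once past their treatment's maturity size, so
    the default steepness (50 per log-length unit) approximates a step
    while staying differentiable.
    """
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    return LogisticCurve(intercept=-steepness * z_mat, slope=steepness)


def fit_fecundity(clutch: pd.DataFrame) -> FecundityModel:
    """Poisson regression of daily egg count on log female length."""
    if clutch is None or len(clutch) < 2:
        raise ValueError("need at least two clutch observations")
    counts = clutch["egg_count"].to_numpy(dtype=float)
    sizes = clutch["female_length_mm"].to_numpy(dtype=float)
    if np.unique(sizes).size < 2:
        raise ValueError("need at least two distinct female sizes")
    if not np.any(counts > 0):
        raise ValueError("all egg counts are zero; log-link mean undefined")
    z = np.log(sizes)
    X = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return FecundityModel(
        a=float(fit.params[0]),
        b=float(fit.params[1]),
        a_se=float(fit.bse[0]),
        b_se=float(fit.bse[1]),
    )


def growth_residual_sd(
    draws: PosteriorDraws,
    treatment: str,
    ages,
    log_scale: bool = True,
) -> float:
    """Residual spread of the one-day growth update from the posterior.

    For each age, every retained draw is propagated through the growth
    curve and then advanced one day; the standard deviation of the
    resulting sizes across draws is taken (on the log scale by default,
    so it plugs directly into the kernel on the z-domain) and the
    per-age sds are averaged.  Ages whose predicted lengths are not
    strictly positive for every draw are skipped.
    """
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    th = draws.treatment_draws(treatment)
    L, K, t0 = th[:, 0:1], th[:, 1:2], th[:, 2:3]
    ages = np.asarray(ages, dtype=float)[None, :]
    Lt = L * (1.0 - np.exp(-K * (ages - t0)))
    decay = np.exp(-K)
    Lt1 = Lt * decay + L * (1.0 - decay)
    ok = np.all(Lt1 > 0, axis=0)
    if not ok.any():
        raise ValueError("no age with positive predicted lengths for all draws")
    Lt1 = Lt1[:, ok]
    vals = np.log(Lt1) if log_scale else Lt1
    sds = vals.std(axis=0, ddof=0)
    return float(sds.mean())
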
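"""Hierarchical Bayesian Von Bertalanffy growth model.

The growth of a fish cohort is described by the Von Bertalanffy curve

    L(t) = L_inf * (1 - exp(-K * (t - t0)))

with treatment-level parameters (L_inf, K, t0), correlated tank-level
random effects eps ~ MVN(0, Sigma), and Normal observation noise with
residual standard deviation sigma.  Priors: unconstrained Normal with
precision 0.001 on the treatment-level parameters, uniform on the
components of Sigma (standard deviations on (0, upper), correlations on
(-1, 1), subject to positive definiteness) and sigma ~ Uniform(0, upper).

The posterior is sampled with the adaptive blockwise Metropolis sampler
in :mod:`medaka_ipm._mcmc`; split-R-hat diagnostics are computed with
arviz.  The fitted draws feed the size-based vital-rate construction and
the integral projection model downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._mcmc import BlockModel, BlockSpec, run_sampler

__all__ = [
    "VBParams",
    "McmcConfig",
    "PosteriorDraws",
    "GrowthBand",
    "vb_length",
    "vb_step",
    "fit_growth",
    "sample_prior",
    "posterior_growth_bands",
    "compare_growth_curves",
    "treatment_key",
]

PARAM_NAMES = ("L_inf", "K", "t0")


@dataclass(frozen=True)
class VBParams:
    """Von Bertalanffy growth parameters.

    L_inf: asymptotic total length (mm); K: growth-rate coefficient
    (per day); t0: theoretical age at zero length (days).
    """

    L_inf: float
    K: float
    t0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L_inf, self.K, self.t0], dtype=float)


def vb_length(params: VBParams, t):
    """Length at age ``t`` (days).  May be negative for t < t0."""
    t = np.asarray(t, dtype=float)
    out = params.L_inf * (1.0 - np.exp(-params.K * (t - params.t0)))
    return out if out.ndim else float(out)


def vb_step(params: VBParams, length):
    """Length one time unit (day) after having length ``length``.

    Algebraically identical to advancing the growth curve by one day:
    L_{t+1} = L_t e^{-K} + L_inf (1 - e^{-K}).
    """
    length = np.asarray(length, dtype=float)
    decay = np.exp(-params.K)
    out = length * decay + params.L_inf * (1.0 - decay)
    return out if out.ndim else float(out)


def treatment_key(temp: str, food: str) -> str:
    """Canonical treatment identifier, e.g. 'warm_continuous'."""
    return f"{temp}_{food}"


@dataclass
class McmcConfig:
    """Sampling schedule and prior settings for :func:`fit_growth`.

    Defaults follow the reference schedule (5 chains, 50,000 burn-in,
    400,000 iterations, thin 200 -> 10,000 retained draws).  Use
    :meth:`test_scale` for a desk-scale schedule.
    """

    n_chains: int = 5
    n_burnin: int = 50_000
    n_iterations: int = 400_000
    thin: int = 200
    prior_precision: float = 0.001
    sigma_upper: float = 10.0
    re_sd_upper: np.ndarray | tuple = (10.0, 10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.re_sd_upper = np.asarray(self.re_sd_upper, dtype=float)
        if self.n_iterations % self.thin != 0:
            raise ValueError("thin must divide n_iterations evenly")
        for name in ("n_chains", "n_burnin", "n_iterations", "thin"):
            if getattr(self, name) < (0 if name == "n_burnin" else 1):
                raise ValueError(f"{name} must be positive")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iterations // self.thin)

    @classmethod
    def test_scale(cls, seed: int = 0) -> "McmcConfig":
        """Reduced schedule for interactive work and the test suite."""
        return cls(n_chains=4, n_burnin=2_000, n_iterations=5_000, thin=10, seed=seed)


@dataclass
class GrowthBand:
    """Posterior mean growth curve with pointwise 95% credibility band."""

    treatment: str
    ages: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus bookkeeping and diagnostics.

    ``samples`` has one row per retained draw with ``chain`` / ``draw``
    indices and one column per quantity: treatment-level parameters
    (``L_inf[<treatment>]`` etc.), random-effect covariance components
    (``sd_L_inf``, ..., ``r1``..``r3``), residual ``sigma`` and per-tank
    random effects (``eps_L_inf[<tank>]`` etc.).
    """

    samples: pd.DataFrame
    treatments: list[str]
    tanks: list[str]
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def treatment_draws(self, treatment: str) -> np.ndarray:
        """(n_draws, 3) array of (L_inf, K, t0) draws for a treatment."""
        cols = [f"{p}[{treatment}]" for p in PARAM_NAMES]
        return self.samples[cols].to_numpy()

    def mean_params(self, treatment: str) -> VBParams:
        m = self.treatment_draws(treatment).mean(axis=0)
        return VBParams(*m)


def sample_prior(n: int, prior_precision: float = 0.001, seed: int = 0) -> np.ndarray:
    """Draw (L_inf, K, t0) triples from the treatment-level prior.

    Used for prior-predictive checks: each component is Normal with mean
    0 and the stated precision (variance = 1/precision).
    """
    rng = np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(prior_precision)
    return rng.normal(0.0, sd, size=(n, 3))


# ---------------------------------------------------------------------------
# Hierarchical model internals


def _corr_det(r: np.ndarray) -> np.ndarray:
    """Determinant of the 3x3 correlation matrix built from (r1, r2, r3)."""
    r1, r2, r3 = r[..., 0], r[..., 1], r[..., 2]
    return 1.0 + 2.0 * r1 * r2 * r3 - r1**2 - r2**2 - r3**2


def _build_corr(r: np.ndarray) -> np.ndarray:
    """(C, 3) correlations -> (C, 3, 3) correlation matrices."""
    C = r.shape[0]
    R = np.empty((C, 3, 3))
    R[:, 0, 0] = R[:, 1, 1] = R[:, 2, 2] = 1.0
    R[:, 0, 1] = R[:, 1, 0] = r[:, 0]
    R[:, 0, 2] = R[:, 2, 0] = r[:, 1]
    R[:, 1, 2] = R[:, 2, 1] = r[:, 2]
    return R


class _GrowthModel(BlockModel):
    """Blockwise sampler target for the hierarchical growth model."""

    def __init__(self, growth: pd.DataFrame, cfg: McmcConfig):
        self.cfg = cfg
        df = growth.copy()
        df["treatment"] = [
            treatment_key(t, f) for t, f in zip(df["treatment_temp"], df["treatment_food"])
        ]
        self.treatments = sorted(df["treatment"].unique())
        self.tanks = sorted(df["tank_id"].unique())
        self.tank_treat = {
            t: df.loc[df["tank_id"] == t, "treatment"].iloc[0] for t in self.tanks
        }
        self.tank_cidx = {
            t: self.treatments.index(self.tank_treat[t]) for t in self.tanks
        }
        # per-tank data arrays
        self.tank_ages, self.tank_obs = [], []
        for t in self.tanks:
            sub = df[df["tank_id"] == t]
            self.tank_ages.append(sub["age_days"].to_numpy(dtype=float))
            self.tank_obs.append(sub["length_mm"].to_numpy(dtype=float))
        self.n_obs = sum(a.size for a in self.tank_ages)
        self.treat_tanks = {
            c: [i for i, t in enumerate(self.tanks) if self.tank_cidx[t] == c]
            for c in range(len(self.treatments))
        }
        self._init_points(df)

    def _init_points(self, df: pd.DataFrame) -> None:
        """Least-squares starting values: pooled fit per treatment, spread
        of per-tank fits for the random-effect scales."""

        def vb(t, L, K, t0):
            return L * (1.0 - np.exp(-K * (t - t0)))

        self.beta0 = np.zeros((len(self.treatments), 3))
        for c, key in enumerate(self.treatments):
            sub = df[df["treatment"] == key]
            ages, obs = sub["age_days"].to_numpy(float), sub["length_mm"].to_numpy(float)
            p0 = (obs.max() * 1.2, 0.01, 0.0)
            try:
                popt, _ = curve_fit(vb, ages, obs, p0=p0, maxfev=20_000)
            except RuntimeError:
                popt = p0
            self.beta0[c] = popt
        tank_fits = []
        resid = []
        for i, t in enumerate(self.tanks):
            ages, obs = self.tank_ages[i], self.tank_obs[i]
            try:
                popt, _ = curve_fit(vb, ages, obs, p0=tuple(self.beta0[self.tank_cidx[t]]), maxfev=20_000)
                tank_fits.append(popt - self.beta0[self.tank_cidx[t]])
                resid.append(obs - vb(ages, *popt))
            except RuntimeError:
                pass
        if len(tank_fits) >= 2:
            spread = np.std(np.array(tank_fits), axis=0, ddof=1)
        else:
            spread = np.zeros(3)
        self.re_sd0 = np.clip(spread, [0.3, 3e-4, 0.5], self.cfg.re_sd_upper * 0.5)
        if resid:
            self.sigma0 = float(np.clip(np.concatenate(resid).std(), 0.1, self.cfg.sigma_upper * 0.9))
        else:
            self.sigma0 = 1.0

    # -- BlockModel interface ------------------------------------------------

    def init_state(self, n_chains: int, rng: np.random.Generator):
        nT, nC = len(self.tanks), len(self.treatments)
        s = SimpleNamespace()
        jitter = 1.0 + 0.02 * rng.standard_normal((n_chains, nC, 3))
        s.beta = self.beta0[None, :, :] * jitter
        s.beta[..., 2] += 0.5 * rng.standard_normal((n_chains, nC))  # t0 may be ~0
        s.eps = 0.1 * self.re_sd0[None, None, :] * rng.standard_normal((n_chains, nT, 3))
        s.cov = np.empty((n_chains, 6))
        s.cov[:, :3] = self.re_sd0[None, :] * np.exp(0.1 * rng.standard_normal((n_chains, 3)))
        s.cov[:, 3:] = 0.0
        s.sigma = self.sigma0 * np.exp(0.1 * rng.standard_normal(n_chains))
        s.ssr = np.empty((n_chains, nT))
        for i in range(nT):
            s.ssr[:, i] = self._tank_ssr(i, s.beta[:, self.tank_cidx[self.tanks[i]], :] + s.eps[:, i, :])
        s.mvn_cache = None  # (logdet, inv, valid) for the current s.cov
        return s

    def blocks(self) -> list[BlockSpec]:
        specs = []
        for c, key in enumerate(self.treatments):
            k0 = max(abs(self.beta0[c, 1]), 1e-3)
            specs.append(BlockSpec(f"treat:{key}", np.array([0.3, 0.05 * k0, 1.0])))
        for i, t in enumerate(self.tanks):
            specs.append(
                BlockSpec(f"tank:{t}", np.maximum(0.5 * self.re_sd0, [0.05, 5e-5, 0.1]))
            )
        for c, key in enumerate(self.treatments):
            # likelihood-invariant translation along the beta/eps ridge
            specs.append(
                BlockSpec(f"shift:{key}", np.maximum(self.re_sd0, [0.1, 1e-4, 0.3]))
            )
        cov_scale = np.concatenate([np.maximum(0.5 * self.re_sd0, [0.05, 5e-5, 0.1]), [0.15, 0.15, 0.15]])
        for j, cname in enumerate(("sd_L_inf", "sd_K", "sd_t0", "r1", "r2", "r3")):
            specs.append(BlockSpec(f"cov{j}:{cname}", np.array([cov_scale[j]])))
        specs.append(BlockSpec("sigma", np.array([0.1 * self.sigma0])))
        return specs

    def block_values(self, s, name):
        kind, _, rest = name.partition(":")
        if kind in ("treat", "shift"):
            return s.beta[:, self.treatments.index(rest), :]
        if kind == "tank":
            return s.eps[:, self.tanks.index(rest), :]
        if kind.startswith("cov"):
            return s.cov[:, int(kind[3:])][:, None]
        return s.sigma[:, None]

    def _mvn_cached(self, s):
        if s.mvn_cache is None:
            s.mvn_cache = self._mvn_terms(s.cov)
        return s.mvn_cache

    def _tank_ssr(self, i: int, params: np.ndarray) -> np.ndarray:
        """Sum of squared residuals for tank i given (C, 3) curve params."""
        ages, obs = self.tank_ages[i], self.tank_obs[i]
        L, K, t0 = params[:, 0:1], params[:, 1:2], params[:, 2:3]
        pred = L * (1.0 - np.exp(-K * (ages[None, :] - t0)))
        return np.square(obs[None, :] - pred).sum(axis=1)

    def _mvn_terms(self, cov: np.ndarray):
        """Log-det and inverse of Sigma for (C, 6) covariance components.

        Returns (logdet (C,), inv (C,3,3), valid (C,)).
        """
        sds, rs = cov[:, :3], cov[:, 3:]
        valid = np.all((sds > 0) & (sds <= self.cfg.re_sd_upper[None, :]), axis=1)
        valid &= np.all(np.abs(rs) < 1.0, axis=1)
        detR = _corr_det(rs)
        valid &= detR > 1e-12
        safe = np.where(valid[:, None], cov[:, :3], 1.0)
        R = _build_corr(np.where(valid[:, None], rs, 0.0))
        Rinv = np.linalg.inv(R)
        Dinv = 1.0 / safe
        inv = Rinv * Dinv[:, :, None] * Dinv[:, None, :]
        logdet = np.log(np.where(valid, detR, 1.0)) + 2.0 * np.log(safe).sum(axis=1)
        return logdet, inv, valid

    def block_logpost(self, s, name, values):
        kind, _, rest = name.partition(":")
        inv_2var = 1.0 / (2.0 * s.sigma**2)
        if kind == "treat":
            c = self.treatments.index(rest)
            ssr = np.zeros(values.shape[0])
            for i in self.treat_tanks[c]:
                ssr += self._tank_ssr(i, values + s.eps[:, i, :])
            prior = -0.5 * self.cfg.prior_precision * np.square(values).sum(axis=1)
            return -ssr * inv_2var + prior
        if kind == "tank":
            i = self.tanks.index(rest)
            c = self.tank_cidx[self.tanks[i]]
            ssr = self._tank_ssr(i, s.beta[:, c, :] + values)
            logdet, inv, valid = self._mvn_cached(s)
            quad = np.einsum("ci,cij,cj->c", values, inv, values)
            prior = np.where(valid, -0.5 * (logdet + quad), -np.inf)
            return -ssr * inv_2var + prior
        if kind == "shift":
            # translate beta_c by delta and every eps in the treatment by
            # -delta: tank-level curves (hence the likelihood) are
            # unchanged, only the priors move.
            c = self.treatments.index(rest)
            delta = values - s.beta[:, c, :]
            logdet, inv, valid = self._mvn_cached(s)
            lp = -0.5 * self.cfg.prior_precision * np.square(values).sum(axis=1)
            for i in self.treat_tanks[c]:
                e = s.eps[:, i, :] - delta
                quad = np.einsum("ci,cij,cj->c", e, inv, e)
                lp = lp + np.where(valid, -0.5 * (logdet + quad), -np.inf)
            return lp
        if kind.startswith("cov"):
            cov = s.cov.copy()
            cov[:, int(kind[3:])] = values[:, 0]
            logdet, inv, valid = self._mvn_terms(cov)
            nT = len(self.tanks)
            quad = np.einsum("cti,cij,ctj->c", s.eps, inv, s.eps)
            return np.where(valid, -0.5 * (nT * logdet + quad), -np.inf)
        # sigma
        sig = values[:, 0]
        ok = (sig > 0) & (sig < self.cfg.sigma_upper)
        safe = np.where(ok, sig, 1.0)
        ssr_tot = s.ssr.sum(axis=1)
        return np.where(ok, -self.n_obs * np.log(safe) - ssr_tot / (2.0 * safe**2), -np.inf)

    def set_block(self, s, name, values, accept):
        kind, _, rest = name.partition(":")
        if kind == "treat":
            c = self.treatments.index(rest)
            s.beta[accept, c, :] = values[accept]
            for i in self.treat_tanks[c]:
                s.ssr[:, i] = self._tank_ssr(i, s.beta[:, c, :] + s.eps[:, i, :])
        elif kind == "tank":
            i = self.tanks.index(rest)
            c = self.tank_cidx[self.tanks[i]]
            s.eps[accept, i, :] = values[accept]
            s.ssr[:, i] = self._tank_ssr(i, s.beta[:, c, :] + s.eps[:, i, :])
        elif kind == "shift":
            c = self.treatments.index(rest)
            delta = values - s.beta[:, c, :]
            s.beta[accept, c, :] = values[accept]
            for i in self.treat_tanks[c]:
                s.eps[accept, i, :] -= delta[accept]
            # likelihood and ssr unchanged by construction
        elif kind.startswith("cov"):
            s.cov[accept, int(kind[3:])] = values[accept, 0]
            s.mvn_cache = None
        else:
            s.sigma[accept] = values[accept, 0]

    def extract(self, s):
        out = {}
        for c, key in enumerate(self.treatments):
            for p, pname in enumerate(PARAM_NAMES):
                out[f"{pname}[{key}]"] = s.beta[:, c, p].copy()
        for p, pname in enumerate(PARAM_NAMES):
            out[f"sd_{pname}"] = s.cov[:, p].copy()
        for j, rname in enumerate(("r1", "r2", "r3")):
            out[rname] = s.cov[:, 3 + j].copy()
        out["sigma"] = s.sigma.copy()
        for i, t in enumerate(self.tanks):
            for p, pname in enumerate(PARAM_NAMES):
                out[f"eps_{pname}[{t}]"] = s.eps[:, i, p].copy()
        return out


def fit_growth(growth: pd.DataFrame, mcmc: McmcConfig | None = None) -> PosteriorDraws:
    """Sample the posterior of the hierarchical growth model.

    ``growth`` must have columns tank_id, treatment_temp, treatment_food,
    age_days, length_mm.  Raises ``ValueError`` on degenerate input
    (empty table, a single tank, or fewer than two distinct ages); a
    convergence failure (any split-R-hat > 1.1) sets ``converged=False``
    and emits a warning instead of raising.
    """
    if mcmc is None:
        mcmc = McmcConfig.test_scale()
    if growth is None or len(growth) == 0:
        raise ValueError("growth table is empty")
    required = {"tank_id", "treatment_temp", "treatment_food", "age_days", "length_mm"}
    missing = required - set(growth.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    if growth["tank_id"].nunique() < 2:
        raise ValueError("at least 2 tanks are required to identify the random-effect covariance")
    if growth["age_days"].nunique() < 2:
        raise ValueError("at least 2 distinct ages are required")

    model = _GrowthModel(growth, mcmc)
    result = run_sampler(
        model,
        n_chains=mcmc.n_chains,
        n_burnin=mcmc.n_burnin,
        n_iterations=mcmc.n_iterations,
        thin=mcmc.thin,
        seed=mcmc.seed,
    )

    rhat = _split_rhat(result.draws)
    converged = all(v <= 1.1 for v in rhat.values() if np.isfinite(v))
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v > 1.1}
        warnings.warn(f"MCMC did not converge (split R-hat > 1.1): {bad}", RuntimeWarning)

    frames = {k: v.reshape(-1) for k, v in result.draws.items()}
    n_per = result.n_retained_per_chain
    frames["chain"] = np.repeat(np.arange(result.n_chains), n_per)
    frames["draw"] = np.tile(np.arange(n_per), result.n_chains)
    samples = pd.DataFrame(frames)
    return PosteriorDraws(
        samples=samples,
        treatments=model.treatments,
        tanks=model.tanks,
        rhat=rhat,
        converged=converged,
    )


def _split_rhat(draws: dict[str, np.ndarray]) -> dict[str, float]:
    """Split-R-hat per quantity via arviz (treatment-level and variance
    parameters only; per-tank effects are nuisance bookkeeping)."""
    import arviz as az

    monitored = {
        k: v for k, v in draws.items() if not k.startswith("eps_")
    }
    ds = az.from_dict(posterior={k: v for k, v in monitored.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(ds)
    return {k: float(r[k].values) for k in monitored}


def posterior_growth_bands(draws: PosteriorDraws, ages) -> dict[str, GrowthBand]:
    """Pointwise posterior mean and 2.5/97.5% quantiles of the treatment
    growth curves, evaluated per retained draw."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    bands = {}
    for key in draws.treatments:
        th = draws.treatment_draws(key)  # (n, 3)
        L, K, t0 = th[:, 0:1], th[:, 1:2], th[:, 2:3]
        curves = L * (1.0 - np.exp(-K * (ages[None, :] - t0)))
        bands[key] = GrowthBand(
            treatment=key,
            ages=ages,
            mean=curves.mean(axis=0),
            lower=np.quantile(curves, 0.025, axis=0),
            upper=np.quantile(curves, 0.975, axis=0),
        )
    return bands


def compare_growth_curves(a: GrowthBand, b: GrowthBand) -> list[tuple[float, float]]:
    """Age intervals where the two 95% credibility bands do not overlap.

    Closed-interval convention: bands that merely touch at an endpoint
    count as overlapping (not significant).  Contiguous flagged ages are
    merged into (start_age, end_age) intervals.
    """
    if not np.array_equal(a.ages, b.ages):
        raise ValueError("bands must share the same age vector")
    disjoint = (a.upper < b.lower) | (b.upper < a.lower)
    intervals: list[tuple[float, float]] = []
    start = None
    for age, flag in zip(a.ages, disjoint):
        if flag and start is None:
            start = age
        elif not flag and start is not None:
            intervals.append((float(start), float(prev)))
            start = None
        prev = age
    if start is not None:
        intervals.append((float(start), float(a.ages[-1])))
    return intervals
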
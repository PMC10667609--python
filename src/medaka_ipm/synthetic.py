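"""Synthetic 2x2 temperature x feeding-frequency medaka experiment.

Generates tidy cross-sectional growth measurements, individual survival
records from day 60, and daily clutch counts with the statistical
structure the downstream analysis assumes: treatment-level Von
Bertalanffy growth with correlated tank-level random effects, Normal
measurement noise rounded to the 0.5 mm instrument resolution,
piecewise-constant daily mortality hazards with right-censoring at the
study end, and size-dependent Poisson fecundity on the log scale.

Fish in the growth table are not individually identified (the sampling
is cross-sectional, one curve per treatment); survival records do carry
fish ids because the product-limit estimator needs event times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import VBParams, treatment_key

__all__ = [
    "TreatmentTruth",
    "RecruitParams",
    "CohortConfig",
    "SimulatedCohort",
    "InvalidConfigError",
    "default_config",
    "simulate_experiment",
    "write_dataset",
    "read_dataset",
    "TREATMENTS",
]

# The four experimental treatments: 20C / 30C crossed with continuous /
# intermittent feeding.
TREATMENTS = (
    ("cold", "continuous"),
    ("cold", "intermittent"),
    ("warm", "continuous"),
    ("warm", "intermittent"),
)


class InvalidConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class TreatmentTruth:
    """Generating truth for one treatment."""

    vb: VBParams
    maturity_age_days: float
    maturity_length_mm: float
    daily_hazard: float  # constant mortality hazard from the entry day


@dataclass(frozen=True)
class RecruitParams:
    """Egg-to-recruit survival and the juvenile log-size distribution.

    f_g is the combined egg hatching x juvenile survival probability;
    the juvenile size distribution (f_d) is Normal on log length (mm).
    """

    f_g: float
    juvenile_logsize_mean: float
    juvenile_logsize_sd: float


@dataclass
class CohortConfig:
    """Full description of the synthetic experiment.

    Measurement days, tank counts and treatment maturity values follow
    the experimental design; growth truths, hazards, fecundity
    coefficients and recruit parameters are documented synthetic
    choices (see docs/methods.md).
    """

    treatments: dict[str, TreatmentTruth]
    re_sd: tuple[float, float, float] = (0.8, 0.0008, 2.0)
    re_corr: tuple[float, float, float] = (0.3, 0.3, 0.3)
    residual_sd_mm: float = 1.0
    tanks_per_treatment: dict[str, int] = field(default_factory=dict)
    fish_per_tank: int = 27
    measurement_days: tuple[int, ...] = (30, 45, 60, 100, 150, 200, 300, 350)
    measured_per_tank_per_day: tuple[int, int] = (12, 17)
    fecundity_a: float = -3.0
    fecundity_b: float = 1.5
    recruits: RecruitParams = field(
        default_factory=lambda: RecruitParams(0.2, float(np.log(8.0)), 0.15)
    )
    female_fraction: float = 0.5
    spawning_fraction: float = 0.8
    entry_day: int = 60
    study_end_day: int = 350
    clutch_layout: str = "per_female"  # or "tank_day"
    seed: int = 0

    def sigma_matrix(self) -> np.ndarray:
        """Assemble the 3x3 random-effect covariance from sds and
        correlations (r1: L_inf-K, r2: L_inf-t0, r3: K-t0)."""
        s = np.asarray(self.re_sd, dtype=float)
        r1, r2, r3 = self.re_corr
        R = np.array([[1.0, r1, r2], [r1, 1.0, r3], [r2, r3, 1.0]])
        return R * np.outer(s, s)

    def validate(self) -> None:
        if set(self.treatments) != {treatment_key(t, f) for t, f in TREATMENTS}:
            raise InvalidConfigError("config must define exactly the four treatments")
        if any(s < 0 for s in self.re_sd):
            raise InvalidConfigError("random-effect sds must be non-negative")
        if any(abs(r) > 1 for r in self.re_corr):
            raise InvalidConfigError("correlations must lie in [-1, 1]")
        eig = np.linalg.eigvalsh(self.sigma_matrix())
        if eig.min() < -1e-10:
            raise InvalidConfigError("random-effect covariance is not positive semi-definite")
        if any(t.daily_hazard < 0 for t in self.treatments.values()):
            raise InvalidConfigError("hazards must be non-negative")
        if not 0.0 <= self.recruits.f_g <= 1.0:
            raise InvalidConfigError("f_g must be a probability")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidConfigError("female fraction must be a probability")
        if list(self.measurement_days) != sorted(set(self.measurement_days)):
            raise InvalidConfigError("measurement days must be strictly increasing")
        if self.clutch_layout not in ("per_female", "tank_day"):
            raise InvalidConfigError("clutch_layout must be 'per_female' or 'tank_day'")
        if any(self.tanks_per_treatment.get(k, 0) < 1 for k in self.treatments):
            raise InvalidConfigError("every treatment needs at least one tank")


def default_config() -> CohortConfig:
    """Default synthetic experiment.

    Maturity ages/lengths and the experimental layout (tank counts,
    measurement days, 0.5 mm rounding, day-60 survival entry) follow the
    2x2 medaka design; growth truths are chosen so each treatment curve
    passes close to its observed maturity size, warming speeds up early
    growth while lowering asymptotic size (crossed curves), and
    intermittent feeding nests the curve below its continuous
    counterpart.  Warm treatments carry higher mortality hazards,
    intermittent feeding lower ones.
    """
    treatments = {
        treatment_key("cold", "continuous"): TreatmentTruth(
            VBParams(32.0, 0.010, -12.0), 169.7, 26.3, 0.002
        ),
        treatment_key("cold", "intermittent"): TreatmentTruth(
            VBParams(31.0, 0.0095, -10.0), 186.5, 25.7, 0.0015
        ),
        treatment_key("warm", "continuous"): TreatmentTruth(
            VBParams(25.0, 0.017, -6.0), 67.3, 16.8, 0.004
        ),
        treatment_key("warm", "intermittent"): TreatmentTruth(
            VBParams(24.0, 0.017, -5.0), 60.0, 17.2, 0.003
        ),
    }
    tanks = {
        treatment_key("cold", "continuous"): 3,
        treatment_key("cold", "intermittent"): 2,  # only 54 fish in two tanks
        treatment_key("warm", "continuous"): 3,
        treatment_key("warm", "intermittent"): 3,
    }
    return CohortConfig(treatments=treatments, tanks_per_treatment=tanks)


@dataclass
class SimulatedCohort:
    """Output tables of one simulated experiment."""

    growth: pd.DataFrame
    survival: pd.DataFrame
    clutch: pd.DataFrame
    recruits: RecruitParams
    config: CohortConfig


def _round_half_mm(x: np.ndarray) -> np.ndarray:
    """Instrument resolution: lengths recorded to the nearest 0.5 mm."""
    return np.maximum(np.round(np.asarray(x) * 2.0) / 2.0, 0.5)


def simulate_experiment(config: CohortConfig, seed: int) -> SimulatedCohort:
    """Simulate one realisation of the experiment.

    Per tank, a random-effect vector eps ~ MVN(0, Sigma) shifts the
    treatment growth parameters; measured lengths are the tank curve
    plus Normal(0, sigma) noise rounded to 0.5 mm for a per-day
    subsample; death times are exponential with the treatment's daily
    hazard starting at the entry day, right-censored at the study end;
    clutches are observed daily after maturity with Poisson egg counts
    whose log-mean is linear in log female length.  Identical
    (config, seed) pairs give identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sigma_mat = config.sigma_matrix()

    growth_rows, survival_rows, clutch_rows = [], [], []
    fish_counter = 0
    for temp, food in TREATMENTS:
        key = treatment_key(temp, food)
        truth = config.treatments[key]
        n_tanks = config.tanks_per_treatment[key]
        for it in range(n_tanks):
            tank_id = f"{key}_t{it + 1}"
            eps = rng.multivariate_normal(np.zeros(3), sigma_mat, method="svd")
            tank_vb = VBParams(*(truth.vb.as_array() + eps))

            # --- survival: one record per fish, from the entry day
            n_fish = config.fish_per_tank
            if truth.daily_hazard > 0:
                durations = rng.exponential(1.0 / truth.daily_hazard, size=n_fish)
            else:
                durations = np.full(n_fish, np.inf)
            exit_days = config.entry_day + np.ceil(durations)
            censored = exit_days > config.study_end_day
            exit_days = np.where(censored, config.study_end_day, exit_days).astype(int)
            for j in range(n_fish):
                survival_rows.append(
                    (
                        f"f{fish_counter + j:04d}",
                        tank_id,
                        temp,
                        food,
                        config.entry_day,
                        int(exit_days[j]),
                        "censored" if censored[j] else "death",
                    )
                )
            fish_counter += n_fish
            # fish alive in the tank at a given day (deaths start at entry day)
            def alive_at(day: int) -> int:
                if day <= config.entry_day:
                    return n_fish
                return int(np.sum(exit_days >= day))

            # --- growth: cross-sectional subsample per measurement day
            lo, hi = config.measured_per_tank_per_day
            for day in config.measurement_days:
                n_meas = min(int(rng.integers(lo, hi + 1)), alive_at(day))
                mu = tank_vb.L_inf * (1.0 - np.exp(-tank_vb.K * (day - tank_vb.t0)))
                lengths = _round_half_mm(
                    mu + config.residual_sd_mm * rng.standard_normal(n_meas)
                )
                for L in lengths:
                    growth_rows.append((tank_id, temp, food, int(day), float(L)))

            # --- clutches: daily after maturity, female reference length
            # from the treatment growth curve (females not tracked
            # individually)
            first_day = int(np.ceil(truth.maturity_age_days))
            for day in range(first_day, config.study_end_day + 1):
                n_fem = int(round(alive_at(day) * config.female_fraction))
                n_spawn = int(rng.binomial(n_fem, config.spawning_fraction)) if n_fem else 0
                if n_spawn == 0:
                    continue
                mu = truth.vb.L_inf * (
                    1.0 - np.exp(-truth.vb.K * (day - truth.vb.t0))
                )
                lengths = _round_half_mm(
                    mu + config.residual_sd_mm * rng.standard_normal(n_spawn)
                )
                eggs = rng.poisson(
                    np.exp(config.fecundity_a + config.fecundity_b * np.log(lengths))
                )
                if config.clutch_layout == "per_female":
                    for L, e in zip(lengths, eggs):
                        clutch_rows.append((tank_id, temp, food, day, float(L), int(e)))
                else:  # tank-day aggregate divided by female count
                    clutch_rows.append(
                        (
                            tank_id,
                            temp,
                            food,
                            day,
                            float(lengths.mean()),
                            int(round(eggs.sum() / n_spawn)),
                        )
                    )

    growth = pd.DataFrame(
        growth_rows,
        columns=["tank_id", "treatment_temp", "treatment_food", "age_days", "length_mm"],
    )
    survival = pd.DataFrame(
        survival_rows,
        columns=[
            "fish_id",
            "tank_id",
            "treatment_temp",
            "treatment_food",
            "entry_day",
            "exit_day",
            "event",
        ],
    )
    clutch = pd.DataFrame(
        clutch_rows,
        columns=["tank_id", "treatment_temp", "treatment_food", "day", "female_length_mm", "egg_count"],
    )
    return SimulatedCohort(growth, survival, clutch, config.recruits, config)


def write_dataset(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write growth.csv, survival.csv, clutch.csv and recruits.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.growth.to_csv(outdir / "growth.csv", index=False)
    cohort.survival.to_csv(outdir / "survival.csv", index=False)
    cohort.clutch.to_csv(outdir / "clutch.csv", index=False)
    r = cohort.recruits
    (outdir / "recruits.json").write_text(
        json.dumps(
            {
                "f_g": r.f_g,
                "juvenile_logsize_mean": r.juvenile_logsize_mean,
                "juvenile_logsize_sd": r.juvenile_logsize_sd,
            },
            indent=2,
        )
    )


def read_dataset(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, RecruitParams]:
    """Read the four files written by :func:`write_dataset`."""
    indir = Path(indir)
    growth = pd.read_csv(indir / "growth.csv")
    survival = pd.read_csv(indir / "survival.csv")
    clutch = pd.read_csv(indir / "clutch.csv")
    d = json.loads((indir / "recruits.json").read_text())
    recruits = RecruitParams(
        d["f_g"], d["juvenile_logsize_mean"], d["juvenile_logsize_sd"]
    )
    return growth, survival, clutch, recruits
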
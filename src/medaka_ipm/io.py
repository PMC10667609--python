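"""File formats for the pipeline stages.

Posterior draws and bands go to CSV (one row per retained draw /
per treatment-age), vital rates and demography to JSON keyed by
treatment, bootstrap replicates to CSV plus a JSON summary with the
pairwise CI-overlap significance matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthBand, McmcConfig, PosteriorDraws, VBParams
from .inference import BootstrapResult, compare_by_ci
from .ipm import IPMGrid
from .synthetic import RecruitParams
from .vitals import FecundityModel, LogisticCurve, VitalRates

__all__ = [
    "write_posterior",
    "read_posterior",
    "write_bands",
    "write_vitals",
    "read_vitals",
    "write_demography",
    "write_bootstrap",
    "write_sensitivity",
]


def write_posterior(draws: PosteriorDraws, outdir: str | Path, mcmc: McmcConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    draws.samples.to_csv(outdir / "posterior.csv", index=False)
    meta = {
        "treatments": draws.treatments,
        "tanks": draws.tanks,
        "rhat": draws.rhat,
        "converged": draws.converged,
        "n_draws": draws.n_draws,
    }
    if mcmc is not None:
        meta["schedule"] = {
            "n_chains": mcmc.n_chains,
            "n_burnin": mcmc.n_burnin,
            "n_iterations": mcmc.n_iterations,
            "thin": mcmc.thin,
            "seed": mcmc.seed,
        }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))


def read_posterior(indir: str | Path) -> PosteriorDraws:
    indir = Path(indir)
    samples = pd.read_csv(indir / "posterior.csv")
    meta = json.loads((indir / "run_meta.json").read_text())
    return PosteriorDraws(
        samples=samples,
        treatments=meta["treatments"],
        tanks=meta["tanks"],
        rhat=meta.get("rhat", {}),
        converged=meta.get("converged", True),
    )


def write_bands(bands: dict[str, GrowthBand], path: str | Path) -> None:
    rows = []
    for key, b in bands.items():
        for age, mean, lo, hi in zip(b.ages, b.mean, b.lower, b.upper):
            rows.append((key, age, mean, lo, hi))
    pd.DataFrame(rows, columns=["treatment", "age", "mean", "lo", "hi"]).to_csv(
        path, index=False
    )


def _vitals_to_dict(v: VitalRates, grid: IPMGrid | None = None) -> dict:
    d = {
        "survival": {
            "intercept": v.survival.intercept,
            "slope": v.survival.slope,
            "degenerate": v.survival.degenerate,
        },
        "growth": {
            "L_inf": v.growth_params.L_inf,
            "K": v.growth_params.K,
            "t0": v.growth_params.t0,
            "sd_log": v.growth_sd_log,
        },
        "reproduction": {
            "intercept": v.reproduction.intercept,
            "slope": v.reproduction.slope,
        },
        "fecundity": {"a": v.fecundity.a, "b": v.fecundity.b},
        "recruits": {
            "f_g": v.recruits.f_g,
            "juvenile_logsize_mean": v.recruits.juvenile_logsize_mean,
            "juvenile_logsize_sd": v.recruits.juvenile_logsize_sd,
        },
        "female_fraction": v.female_fraction,
    }
    if grid is not None:
        d["grid"] = {"L": grid.L, "U": grid.U, "n_mesh": grid.n_mesh}
    return d


def _vitals_from_dict(d: dict) -> tuple[VitalRates, dict | None]:
    v = VitalRates(
        survival=LogisticCurve(
            d["survival"]["intercept"],
            d["survival"]["slope"],
            d["survival"].get("degenerate", False),
        ),
        growth_params=VBParams(
            d["growth"]["L_inf"], d["growth"]["K"], d["growth"]["t0"]
        ),
        growth_sd_log=d["growth"]["sd_log"],
        reproduction=LogisticCurve(
            d["reproduction"]["intercept"], d["reproduction"]["slope"]
        ),
        fecundity=FecundityModel(d["fecundity"]["a"], d["fecundity"]["b"]),
        recruits=RecruitParams(
            d["recruits"]["f_g"],
            d["recruits"]["juvenile_logsize_mean"],
            d["recruits"]["juvenile_logsize_sd"],
        ),
        female_fraction=d.get("female_fraction", 0.5),
    )
    return v, d.get("grid")


def write_vitals(vitals: dict[str, VitalRates], path: str | Path, grids: dict[str, IPMGrid] | None = None) -> None:
    out = {
        k: _vitals_to_dict(v, grids.get(k) if grids else None)
        for k, v in vitals.items()
    }
    Path(path).write_text(json.dumps(out, indent=2))


def read_vitals(path: str | Path) -> dict[str, tuple[VitalRates, dict | None]]:
    raw = json.loads(Path(path).read_text())
    return {k: _vitals_from_dict(d) for k, d in raw.items()}


def write_demography(estimates: dict, path: str | Path) -> None:
    """``estimates`` maps treatment -> (DemographicEstimates, IPMGrid)."""
    out = {}
    for key, (est, grid) in estimates.items():
        out[key] = {
            "lambda": est.lam,
            "R0": est.R0,
            "T": est.T,
            "converged": bool(est.converged),
            "grid": {"L": grid.L, "U": grid.U, "n_mesh": grid.n_mesh},
        }
    Path(path).write_text(json.dumps(out, indent=2))


def write_bootstrap(results: dict[str, BootstrapResult], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for key, b in results.items():
        for i, (lam, T) in enumerate(zip(b.lam, b.T)):
            rows.append((key, i, lam, T, False))
    pd.DataFrame(
        rows, columns=["treatment", "replicate", "lambda", "T", "failed_flag"]
    ).to_csv(outdir / "bootstrap.csv", index=False)

    keys = list(results)
    summary = {}
    for key, b in results.items():
        summary[key] = {
            "lambda_median": b.median("lambda"),
            "lambda_ci": list(b.ci("lambda")),
            "T_median": b.median("T"),
            "T_ci": list(b.ci("T")),
            "n_replicates": int(b.lam.size),
            "n_failures": b.n_failures,
        }
    sig = {
        q: {
            a: {bk: compare_by_ci(results[a], results[bk], q) for bk in keys if bk != a}
            for a in keys
        }
        for q in ("lambda", "T")
    }
    (outdir / "summary.json").write_text(
        json.dumps({"treatments": summary, "significant": sig}, indent=2)
    )


def write_sensitivity(reports: dict[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for key, df in reports.items():
        df = df.copy()
        df.insert(0, "treatment", key)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
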
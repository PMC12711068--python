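"""Synthetic thermal-degradation data and replicated simulation studies.

``generate_degradation_fixture`` emulates an accelerated-stability
experiment: a degradation index measured on samples held at 70, 85 and
100 degrees Celsius for 10-120 minutes, 100 samples per temperature, with the
index drawn from a per-temperature Inverse Weibull whose scale shifts right
as temperature rises.  The default parameters are illustrative (no real
per-temperature calibration exists), and the fixture is synthetic by
construction — it reproduces the shape of such data, not any laboratory
measurement.

``run_mle_simulation`` and ``run_bayes_simulation`` run the replicated
estimation studies: record samples of several sizes are simulated at known
true parameters, each replicate is fitted, and the estimates are averaged.
The SE column of the MLE study is the standard error of the Monte-Carlo mean
(sd of the estimates divided by sqrt(replications)).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .bayes import GammaPrior, MHConfig, mh_sample, posterior_summary
from .distribution import IWDParams, quantile
from .model import InverseWeibullRecords
from .records import RecordSample, simulate_records_quantile

__all__ = [
    "DEFAULT_TEMP_PARAMS",
    "generate_degradation_fixture",
    "run_mle_simulation",
    "run_bayes_simulation",
]

# Illustrative per-temperature parameters: scale lam = phi**(1/gamma) grows
# with temperature (2, 3, 4), so the index distribution shifts right as the
# thermal stress increases while keeping a heavy upper tail (gamma = 3).
DEFAULT_TEMP_PARAMS: dict[int, IWDParams] = {
    70: IWDParams(8.0, 3.0),
    85: IWDParams(27.0, 3.0),
    100: IWDParams(64.0, 3.0),
}


def generate_degradation_fixture(
    seed: int = 0,
    temps=(70, 85, 100),
    times=None,
    samples_per_temp: int = 100,
    params_per_temp: dict | None = None,
) -> pd.DataFrame:
    """Synthetic degradation-index dataset, one row per tested sample.

    Columns: temperature (C), time (minutes on the 10-120 grid), replicate,
    degradation_index (positive, Inverse-Weibull distributed per temperature).
    Deterministic given the seed.
    """
    params_per_temp = params_per_temp if params_per_temp is not None else DEFAULT_TEMP_PARAMS
    times = np.asarray(times if times is not None else np.arange(10, 121, 10), dtype=float)
    if samples_per_temp < 1:
        raise ValueError("samples_per_temp must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for temp in temps:
        if temp not in params_per_temp:
            raise KeyError(f"no Inverse Weibull parameters supplied for temperature {temp}")
        p = IWDParams(*params_per_temp[temp]).validated()
        u = rng.uniform(size=samples_per_temp)
        frames.append(
            pd.DataFrame(
                {
                    "temperature": temp,
                    "time": times[np.arange(samples_per_temp) % times.size],
                    "replicate": np.arange(samples_per_temp),
                    "degradation_index": quantile(u, p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_mle_simulation(
    n_list=(10, 20, 30, 40, 50),
    true_params: IWDParams = IWDParams(1.0, 1.0),
    reps: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated record-sample MLE study.

    For each n, ``reps`` record samples are simulated at the true parameters
    and fitted; the table reports the Monte-Carlo mean of each estimate and
    its standard error sd/sqrt(reps).  Replicates whose fit fails to converge
    are excluded and counted in ``failure_rate``.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    true_params = IWDParams(*true_params).validated()
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_list:
        est = np.empty((reps, 2))
        failed = 0
        kept = 0
        for _ in range(reps):
            sample = simulate_records_quantile(n, true_params, rng)
            try:
                fit = InverseWeibullRecords(sample).fit()
            except Exception:
                failed += 1
                continue
            if not fit.converged:
                failed += 1
                continue
            est[kept] = fit.params
            kept += 1
        e = est[:kept]
        rows.append(
            {
                "n": n,
                "mean_phi": e[:, 0].mean(),
                "se_phi": e[:, 0].std(ddof=1) / math.sqrt(kept),
                "mean_gamma": e[:, 1].mean(),
                "se_gamma": e[:, 1].std(ddof=1) / math.sqrt(kept),
                "reps_used": kept,
                "failure_rate": failed / reps,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs.update({"seed": seed, "reps": reps, "true_params": tuple(true_params)})
    return report


def run_bayes_simulation(
    n_list=(10, 20, 30, 40, 50),
    prior: GammaPrior = GammaPrior(3.0, 3.0, 3.0, 3.0),
    cfg: MHConfig = MHConfig(),
    reps: int = 200,
    true_params: IWDParams = IWDParams(1.0, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated Bayesian estimation study.

    For each n, ``reps`` record samples are simulated, an MH chain is run on
    each, and the per-replicate posterior summaries are averaged (the
    averaging is over replicate datasets, column by column).  n = 0 is
    allowed and runs the sampler on an empty sample, which must reproduce the
    prior moments — a sampler-validation mode.
    """
    if reps < 10:
        raise ValueError("reps must be at least 10")
    prior = GammaPrior(*prior).validated()
    true_params = IWDParams(*true_params).validated()
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_list:
        acc = {name: np.zeros((reps, 6)) for name in ("phi", "gamma")}
        for j in range(reps):
            sample = (
                simulate_records_quantile(n, true_params, rng)
                if n > 0
                else RecordSample(np.empty(0))
            )
            chain_seed = int(rng.integers(0, 2**31 - 1))
            draws = mh_sample(sample, prior, replace(cfg, seed=chain_seed))
            summ = posterior_summary(draws)
            for name in ("phi", "gamma"):
                acc[name][j] = np.asarray(summ[name], dtype=float)
        for name in ("phi", "gamma"):
            mean = acc[name].mean(axis=0)
            rows.append(
                {
                    "n": n,
                    "parameter": name,
                    "estimate": mean[0],
                    "se": mean[1],
                    "mc_error": mean[2],
                    "q2.5": mean[3],
                    "median": mean[4],
                    "q97.5": mean[5],
                }
            )
    report = pd.DataFrame(rows)
    report.attrs.update(
        {"seed": seed, "reps": reps, "prior": tuple(prior), "true_params": tuple(true_params)}
    )
    return report
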
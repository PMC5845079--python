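"""Replicate statistics and derived metrics.

Per replicate, the derived metrics are the *immune response time* (first
time after tumor initiation at which the cancer count returns to zero;
censored at t_end when the tumor is never cleared) and the *maximum
cancer fraction* over the time series.  Across replicates, uncertainty
is summarised with the normal-approximation 95% confidence interval

    (xbar - 1.96 sigma / sqrt(n),  xbar + 1.96 sigma / sqrt(n)),

with sigma the sample standard deviation - the plain z-interval, kept
deliberately instead of a t-interval.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ScenarioConfig

__all__ = ["CIResult", "RunSummary", "confidence_interval",
           "summarize_run", "cancer_fraction_series"]

_Z95 = 1.96


@dataclass(frozen=True)
class CIResult:
    """Normal-approximation 95% confidence interval."""

    mean: float
    lower: float
    upper: float
    n: int


@dataclass(frozen=True)
class RunSummary:
    """Per-replicate time series and derived metrics."""

    series: pd.DataFrame          # time_min, n_epithelial, n_cancer, n_tcell, cancer_fraction
    immune_response_time: float   # min; t_end when censored
    censored: bool                # True when cancer never cleared (or never appeared)
    max_cancer_fraction: float
    seed: int
    scenario: dict

    def to_json(self) -> str:
        payload = {
            "immune_response_time": self.immune_response_time,
            "censored": self.censored,
            "max_cancer_fraction": self.max_cancer_fraction,
            "seed": self.seed,
            "scenario": self.scenario,
            "final_counts": {k: int(self.series.iloc[-1][k])
                             for k in ("n_epithelial", "n_cancer", "n_tcell")},
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def confidence_interval(samples) -> CIResult:
    """95% z-interval xbar +/- 1.96 sigma / sqrt(n) (sample std, ddof=1).

    A single sample yields a degenerate zero-width interval (with a
    warning); identical samples collapse to the mean.
    """
    x = np.asarray(list(samples), dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("confidence interval of an empty sample")
    mean = float(x.mean())
    if n == 1:
        warnings.warn("confidence interval of a single sample is degenerate",
                      stacklevel=2)
        return CIResult(mean, mean, mean, 1)
    sigma = float(x.std(ddof=1))
    half = _Z95 * sigma / math.sqrt(n)
    return CIResult(mean, mean - half, mean + half, n)


def summarize_run(series: pd.DataFrame, seed: int,
                  scenario: ScenarioConfig) -> RunSummary:
    """Derive the replicate metrics from a recorded time series."""
    if series.empty:
        raise ValueError("empty time series")
    cancer = series["n_cancer"].to_numpy()
    times = series["time_min"].to_numpy()
    max_fraction = float(series["cancer_fraction"].max())

    first_tumor = np.nonzero(cancer > 0)[0]
    response_time = float(scenario.t_end)
    censored = True
    if first_tumor.size:
        after = np.nonzero((cancer == 0) & (np.arange(len(cancer)) > first_tumor[0]))[0]
        if after.size:
            response_time = float(times[after[0]])
            censored = False
    sc_dict = dataclasses.asdict(scenario)
    sc_dict["snapshot_times"] = list(sc_dict["snapshot_times"])
    return RunSummary(series=series.reset_index(drop=True),
                      immune_response_time=response_time, censored=censored,
                      max_cancer_fraction=max_fraction, seed=seed,
                      scenario=sc_dict)


def cancer_fraction_series(summaries: list[RunSummary],
                           grid: np.ndarray | None = None) -> pd.DataFrame:
    """Mean cancer fraction with a 95% CI band over replicates.

    Replicate series are resampled onto a common time grid by
    previous-value (step) interpolation; mixing scenarios in one
    aggregate is an error.
    """
    if not summaries:
        raise ValueError("no replicates to aggregate")
    reference = {k: v for k, v in summaries[0].scenario.items() if k != "seed"}
    for s in summaries[1:]:
        if {k: v for k, v in s.scenario.items() if k != "seed"} != reference:
            raise ValueError("cannot aggregate replicates from different scenarios")

    if grid is None:
        t_max = min(float(s.series["time_min"].iloc[-1]) for s in summaries)
        grid = np.unique(np.concatenate(
            [s.series["time_min"].to_numpy() for s in summaries]))
        grid = grid[grid <= t_max]
    resampled = np.empty((len(summaries), len(grid)))
    for i, s in enumerate(summaries):
        t = s.series["time_min"].to_numpy()
        f = s.series["cancer_fraction"].to_numpy()
        idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(t) - 1)
        resampled[i] = f[idx]

    rows = []
    for j, tj in enumerate(grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = confidence_interval(resampled[:, j])
        rows.append({"time_min": float(tj), "mean": ci.mean,
                     "lower": ci.lower, "upper": ci.upper, "n": ci.n})
    return pd.DataFrame(rows)
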
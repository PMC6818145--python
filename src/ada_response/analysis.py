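"""Summary statistics of single-cell Ada-response traces.

Turns per-cell time series (stochastic simulations, synthetic fluorescence
or degenerate deterministic trajectories) into the standard single-cell observables:
threshold-crossing activation and deactivation times, cumulative activation
distributions, first-meAda delays conditional on the initial Ada count,
exponential fits of delay distributions, and simple parameter-recovery
estimators for the inactivation rate rho and basal expression rate.

Threshold crossings are evaluated on the sampled totals (matching the
3-min experimental sampling), not on exact event times: the crossing time
is the first at-or-above sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import LN2

#: Activation threshold in molecules per cell, close to the experimental
#: single-cell detection limit.
DEFAULT_THRESHOLD = 23.0

#: Initial-count groups used for conditional delay analysis.
DELAY_GROUPS = ("0", "1", "2", ">2")


@dataclass(frozen=True)
class ActivationSummary:
    """Per-cell activation statistics (times in generations since MMS on)."""

    cell_id: int
    activation_time: float | None
    deactivation_time: float | None
    initial_n_ada: int
    first_meada_time: float | None
    threshold_used: float

    def __post_init__(self) -> None:
        if self.threshold_used <= 0:
            raise ValueError("threshold must be > 0")
        if self.activation_time is not None and self.activation_time < 0:
            raise ValueError("activation_time must be >= 0")


def _times_totals(trace) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(trace.times, dtype=float), np.asarray(trace.total, dtype=float)


def activation_time(
    trace, threshold: float = DEFAULT_THRESHOLD, t_mms_on: float = 0.0
) -> float | None:
    """Time after MMS onset of the first sample with total >= threshold.

    ``trace`` is anything with ``times`` and ``total`` attributes (a
    ``CellTrace``, a ``DeterministicTrajectory``, or a plain record).
    Returns ``None`` if the threshold is never crossed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    times, totals = _times_totals(trace)
    if times[-1] < t_mms_on:
        raise ValueError("trace does not cover t_mms_on")
    mask = (times >= t_mms_on) & (totals >= threshold)
    if not mask.any():
        return None
    return float(times[mask][0] - t_mms_on)


def deactivation_time(
    trace,
    t_mms_off: float,
    threshold: float = DEFAULT_THRESHOLD,
    sustain: float = 1.0,
) -> float | None:
    """Time after MMS removal at which the total falls and stays below
    threshold for at least ``sustain`` generations.

    The sustained window may be truncated by the end of the trace (a trace
    that ends below threshold deactivates at the first sub-threshold sample
    of its final excursion).  Returns 0.0 if already below at removal.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    times, totals = _times_totals(trace)
    if times[-1] < t_mms_off:
        raise ValueError("trace does not cover t_mms_off")
    sel = times >= t_mms_off
    t, x = times[sel], totals[sel]
    below = x < threshold
    i = 0
    n = len(t)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j == n or t[j - 1] - t[i] >= sustain - 1e-9:
                return float(t[i] - t_mms_off)
            i = j
        else:
            i += 1
    return None


def summarize_trace(
    trace,
    cell_id: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    t_mms_on: float = 0.0,
    t_mms_off: float | None = None,
) -> ActivationSummary:
    """Build the per-cell ActivationSummary from a simulated trace."""
    act = activation_time(trace, threshold=threshold, t_mms_on=t_mms_on)
    deact = (
        deactivation_time(trace, t_mms_off, threshold=threshold)
        if t_mms_off is not None
        else None
    )
    first_me = getattr(trace, "first_me_time", None)
    if first_me is not None:
        first_me = max(float(first_me) - t_mms_on, 0.0)
    return ActivationSummary(
        cell_id=cell_id,
        activation_time=act,
        deactivation_time=deact,
        initial_n_ada=int(getattr(trace, "initial_n_ada", 0)),
        first_meada_time=first_me,
        threshold_used=threshold,
    )


def summarize_population(
    traces: Sequence, threshold: float = DEFAULT_THRESHOLD,
    t_mms_on: float = 0.0, t_mms_off: float | None = None,
) -> list[ActivationSummary]:
    return [
        summarize_trace(tr, cell_id=i, threshold=threshold,
                        t_mms_on=t_mms_on, t_mms_off=t_mms_off)
        for i, tr in enumerate(traces)
    ]


def activation_cdf(
    summaries: Sequence[ActivationSummary], t_grid: Sequence[float]
) -> np.ndarray:
    """Cumulative fraction of cells activated by each time in ``t_grid``.

    Cells that never activated count as not-yet-activated at every time.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one summary")
    t_grid = np.asarray(t_grid, dtype=float)
    times = np.array(
        [s.activation_time for s in summaries if s.activation_time is not None]
    )
    if len(times) == 0:
        return np.zeros_like(t_grid)
    return np.searchsorted(np.sort(times), t_grid, side="right") / len(summaries)


def _delay_group(n0: int) -> str:
    return str(n0) if n0 <= 2 else ">2"


def conditional_delay(
    summaries_by_mms: Mapping[float, Sequence[ActivationSummary]]
) -> pd.DataFrame:
    """Mean first-meAda delay per (initial Ada count group, MMS dose).

    Groups are {0, 1, 2, >2}.  Cells whose trace produced no meAda are
    excluded from the mean; a group with no cells is reported as missing
    (NaN mean, n=0), never as zero.
    """
    rows = []
    for mms, summaries in summaries_by_mms.items():
        delays: dict[str, list[float]] = {g: [] for g in DELAY_GROUPS}
        counts: dict[str, int] = {g: 0 for g in DELAY_GROUPS}
        for s in summaries:
            g = _delay_group(s.initial_n_ada)
            counts[g] += 1
            if s.first_meada_time is not None:
                delays[g].append(s.first_meada_time)
        for g in DELAY_GROUPS:
            rows.append(
                {
                    "mms": mms,
                    "group": g,
                    "mean_delay": float(np.mean(delays[g])) if delays[g] else math.nan,
                    "n_cells": counts[g],
                    "n_with_meada": len(delays[g]),
                }
            )
    return pd.DataFrame(rows)


def fit_exponential_delay(delays: Sequence[float]) -> tuple[float, float]:
    """Maximum-likelihood exponential fit of a delay sample.

    Returns ``(rate, ks_pvalue)``: rate = 1/mean, and the Kolmogorov-
    Smirnov goodness-of-fit p-value against Exp(rate).  Requires >= 20
    delays.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size < 20:
        raise ValueError("need at least 20 delays for a stable fit")
    if (delays < 0).any():
        raise ValueError("delays must be >= 0")
    mean = delays.mean()
    if mean <= 0:
        raise ValueError("delays are all zero; exponential fit undefined")
    rate = 1.0 / mean
    res = stats.kstest(delays, "expon", args=(0.0, mean))
    return rate, float(res.pvalue)


@dataclass(frozen=True)
class RhoEstimate:
    """Inactivation-rate estimate from post-removal meAda decay."""

    rho: float
    slope: float
    in_range: bool


def recover_rho(times: Sequence[float], me_values: Sequence[float]) -> RhoEstimate:
    """Estimate rho from the exponential decay of meAda after MMS removal.

    After removal, meAda decays at rate ln2 + rho (dilution plus
    inactivation), so the log-linear slope of meAda versus time gives
    rho = -slope - ln2.  Input is the post-removal time series of meAda
    (deterministic, or a population mean for stochastic data); at least
    5 strictly positive samples are required.  ``in_range`` is False when
    the estimate is negative (e.g., flat input gives rho ~ -ln2).
    """
    times = np.asarray(times, dtype=float)
    me = np.asarray(me_values, dtype=float)
    if times.size != me.size:
        raise ValueError("times and me_values must have equal length")
    if times.size < 5:
        raise ValueError("need at least 5 post-removal samples")
    if (me <= 0).any():
        raise ValueError("meAda samples must be positive for a log-linear fit")
    slope = float(np.polyfit(times, np.log(me), 1)[0])
    rho = -slope - LN2
    return RhoEstimate(rho=rho, slope=slope, in_range=rho >= 0.0)


def recover_k_basal(
    counts: Sequence[int], ages: Sequence[float] | None = None
) -> float:
    """Moment estimator of the basal expression rate from a damage-free
    snapshot.

    In the basal regime the copy-number at cell age a is Poisson with mean
    k_basal·(1 + a), so k_basal = mean(count) / (1 + mean(age)).  With no
    age annotations the mid-cycle mean age 0.5 is assumed (with a warning).
    Requires >= 100 cells.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 100:
        raise ValueError("need at least 100 cells")
    if ages is None:
        warnings.warn(
            "no cell ages provided; assuming mean age 0.5", stacklevel=2
        )
        mean_age = 0.5
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.size != counts.size:
            raise ValueError("ages must match counts in length")
        mean_age = float(ages.mean())
    return float(counts.mean() / (1.0 + mean_age))


def summaries_to_dataframe(summaries: Sequence[ActivationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "activation_time": [s.activation_time for s in summaries],
            "deactivation_time": [s.deactivation_time for s in summaries],
            "initial_n_ada": [s.initial_n_ada for s in summaries],
            "first_meada_time": [s.first_meada_time for s in summaries],
            "threshold_used": [s.threshold_used for s in summaries],
        }
    )
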
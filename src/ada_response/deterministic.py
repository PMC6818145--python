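"""Deterministic (mean-field) model of the Ada circuit.

State variables are concentrations per reference cell: unmethylated Ada,
methylated Ada (meAda, the transcriptional activator) and inactivated Ada
(inAda).  With time in generations, dilution by growth is a first-order
loss at rate ln 2.  Methylation converts Ada to meAda at rate
k_me·[MMS]; meAda drives induced production through noncooperative
promoter occupancy f([meAda]) = k_ind·[meAda]/(K + [meAda]) with
K = k_off/k_on; and meAda is additionally lost to the inactive species at
rate rho.  The conversion flux k_me·[MMS]·[Ada] is debited from the Ada
balance so that methylation and inactivation cancel in the total-Ada
budget (d total/dt = production − ln2·total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import LN2, ModelParams, MMSSchedule


@dataclass(frozen=True)
class DeterministicState:
    """Concentrations (molecules per reference cell) of the three species."""

    ada: float
    me_ada: float = 0.0
    in_ada: float = 0.0

    def __post_init__(self) -> None:
        if self.ada < 0 or self.me_ada < 0 or self.in_ada < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def total(self) -> float:
        return self.ada + self.me_ada + self.in_ada

    def as_array(self) -> np.ndarray:
        return np.array([self.ada, self.me_ada, self.in_ada], dtype=float)


def basal_state(params: ModelParams) -> DeterministicState:
    """Damage-free fixed point: [Ada] = g·k_basal/ln2, no meAda or inAda."""
    return DeterministicState(params.gene_copies * params.k_basal / LN2, 0.0, 0.0)


def induced_production(me_ada: float, params: ModelParams) -> float:
    """Per-copy induced production k_ind·[meAda]/(K + [meAda])."""
    if me_ada <= 0:
        return 0.0
    return params.k_ind * me_ada / (params.K + me_ada)


def rate_equations(
    state: DeterministicState, mms: float, params: ModelParams
) -> tuple[float, float, float]:
    """Time derivatives (d[Ada]/dt, d[meAda]/dt, d[inAda]/dt).

    Raises ``ValueError`` for negative inputs.
    """
    if mms < 0:
        raise ValueError("mms must be >= 0")
    ada, me, inact = state.ada, state.me_ada, state.in_ada
    g = params.gene_copies
    production = g * (params.k_basal + induced_production(me, params))
    methylation = params.k_me * mms * ada
    d_ada = production - LN2 * ada - methylation
    d_me = methylation - (LN2 + params.rho) * me
    d_in = params.rho * me - LN2 * inact
    return (d_ada, d_me, d_in)


def _rhs(t: float, y: np.ndarray, mms: float, params: ModelParams) -> np.ndarray:
    ada, me, inact = y
    g = params.gene_copies
    me_pos = me if me > 0 else 0.0
    production = g * (params.k_basal + params.k_ind * me_pos / (params.K + me_pos))
    methylation = params.k_me * mms * ada
    return np.array(
        [
            production - LN2 * ada - methylation,
            methylation - (LN2 + params.rho) * me,
            params.rho * me - LN2 * inact,
        ]
    )


def steady_state(params: ModelParams, mms: float) -> DeterministicState:
    """Analytic steady state at constant MMS.

    [Ada] solves a·x² + b·x + c = 0 with

        a = k_me·M / (ln2 + rho)
        b = K − g·(k_basal + k_ind)·k_me·M / ((ln2 + k_me·M)(ln2 + rho))
        c = −g·k_basal·K / (ln2 + k_me·M)

    taking the unique non-negative root; then
    [meAda] = k_me·M·[Ada]/(ln2 + rho) and [inAda] = rho/ln2·[meAda].
    At M = 0 the quadratic degenerates and the basal fixed point applies.
    """
    if mms < 0:
        raise ValueError("mms must be >= 0")
    g = params.gene_copies
    if mms == 0 or params.k_me == 0:
        return basal_state(params)
    K = params.K
    kmM = params.k_me * mms
    a = kmM / (LN2 + params.rho)
    b = K - g * (params.k_basal + params.k_ind) * kmM / ((LN2 + kmM) * (LN2 + params.rho))
    c = -g * params.k_basal * K / (LN2 + kmM)
    disc = b * b - 4 * a * c
    assert disc >= 0, "steady-state discriminant negative; invalid parameters"
    s = math.sqrt(disc)
    # numerically stable positive root (c <= 0, a > 0): avoid cancellation
    # between -b and s when b > 0 (the near-degenerate low-dose limit)
    ada = 2 * c / (-b - s) if b > 0 else (-b + s) / (2 * a)
    me = kmM * ada / (LN2 + params.rho)
    inact = params.rho / LN2 * me
    return DeterministicState(max(ada, 0.0), max(me, 0.0), max(inact, 0.0))


@dataclass(frozen=True)
class DeterministicTrajectory:
    """ODE solution sampled on a regular output grid (time in generations)."""

    times: np.ndarray
    ada: np.ndarray
    me_ada: np.ndarray
    in_ada: np.ndarray
    schedule: MMSSchedule
    params: ModelParams

    @property
    def total(self) -> np.ndarray:
        return self.ada + self.me_ada + self.in_ada

    @property
    def mms(self) -> np.ndarray:
        return np.array([self.schedule.concentration(t) for t in self.times])

    def state_at(self, index: int) -> DeterministicState:
        return DeterministicState(
            float(self.ada[index]), float(self.me_ada[index]), float(self.in_ada[index])
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "ada": self.ada,
                "me_ada": self.me_ada,
                "in_ada": self.in_ada,
                "total": self.total,
                "mms": self.mms,
            }
        )


def integrate(
    params: ModelParams,
    schedule: MMSSchedule,
    t_end: float,
    init: DeterministicState | None = None,
    dt_out: float = 0.05,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> DeterministicTrajectory:
    """Integrate the rate equations under a piecewise-constant MMS schedule.

    The integration restarts at every schedule breakpoint so the input
    discontinuities are handled exactly; output is sampled on a regular
    grid of spacing ``dt_out`` (breakpoints are included in the grid when
    they fall on it).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if init is None:
        init = basal_state(params)

    grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    grid[-1] = min(grid[-1], t_end)
    edges = [0.0] + schedule.breakpoints(t_end) + [t_end]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = init.as_array()
    for lo, hi in zip(edges, edges[1:]):
        mms = schedule.concentration(lo)
        mask = (grid >= lo) & (grid <= hi) if hi == t_end else (grid >= lo) & (grid < hi)
        t_eval = np.unique(np.concatenate([grid[mask], [lo, hi]]))
        sol = solve_ivp(
            _rhs,
            (lo, hi),
            y,
            t_eval=t_eval,
            args=(mms, params),
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{lo}, {hi}] at {mms} mM MMS: {sol.message}"
            )
        keep = np.isin(sol.t, grid[mask])
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])
        y = sol.y[:, -1]

    times = np.concatenate(times_out)
    states = np.clip(np.concatenate(states_out, axis=1), 0.0, None)
    order = np.argsort(times)
    times, states = times[order], states[:, order]
    # drop duplicated grid points at segment edges
    uniq = np.concatenate([[True], np.diff(times) > 0])
    times, states = times[uniq], states[:, uniq]
    return DeterministicTrajectory(
        times=times,
        ada=states[0],
        me_ada=states[1],
        in_ada=states[2],
        schedule=schedule,
        params=params,
    )


def dose_response(
    params: ModelParams, mms_values: Sequence[float]
) -> list[tuple[float, float]]:
    """Steady-state total Ada abundance for each MMS dose (mM)."""
    return [(float(m), steady_state(params, m).total) for m in mms_values]


def convert_rates_for_generation_time(
    params: ModelParams, new_generation_time_min: float
) -> ModelParams:
    """Re-express the rate set per a different generation time.

    Real-time (per-minute) rates are held fixed: every production and
    conversion rate k per generation becomes k·(T_new/T_old), and dilution
    remains ln2 per (new) generation.  Slower growth therefore increases
    per-generation production relative to dilution.
    """
    if new_generation_time_min <= 0:
        raise ValueError("generation time must be > 0")
    f = new_generation_time_min / params.generation_time_min
    return params.with_(
        k_basal=params.k_basal * f,
        k_ind=params.k_ind * f,
        k_on=params.k_on * f,
        k_off=params.k_off * f,
        k_me=params.k_me * f,
        rho=params.rho * f,
        generation_time_min=new_generation_time_min,
    )
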
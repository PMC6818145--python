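"""Exact stochastic simulation of single-cell Ada-response lineages.

The deterministic rate equations are unfolded into elementary reactions on
integer molecule counts:

    basal production     k_basal          per free promoter copy
    induced production   k_ind            per meAda-bound promoter copy
    methylation          k_me * [MMS]     per free Ada molecule
    inactivation         rho              per free meAda molecule
    promoter binding     k_on / volume    per (meAda, free copy) pair
    promoter unbinding   k_off            per bound copy

There is no explicit dilution reaction: molecule loss arises solely from
deterministic exponential volume growth (volume = 2^age over one
generation) combined with binomial partitioning at division, mirroring a
mother-machine experiment that follows one daughter per division.  The
promoter association propensity is the only volume-dependent rate, so
waiting times are drawn exactly while it is zero and with a short step cap
(re-evaluating the volume) while it is active.

Perturbation modes mirror three experimental perturbations of the circuit:
division inhibition (cephalexin-like filamentation with gene-copy
amplification), constitutive *ada* duplication (low-copy plasmid), and a
modified generation time at fixed real-time expression rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .deterministic import convert_rates_for_generation_time, steady_state
from .params import LN2, ModelParams, MMSSchedule

#: Maximum Gillespie step (generations) while a volume-dependent propensity
#: is active; bounds the error of treating volume as constant within a step.
BIND_STEP_CAP = 0.01

_EPS = 1e-12


def _volume(cell_age: float) -> float:
    # float exponent guard: beyond ~1000 generations of unbroken growth the
    # volume-scaled binding propensity is zero anyway
    return 2.0 ** cell_age if cell_age < 1000.0 else math.inf

REACTIONS = (
    "basal_production",
    "induced_production",
    "methylation",
    "inactivation",
    "binding",
    "unbinding",
)


@dataclass(frozen=True)
class PerturbationMode:
    """One of the experimental perturbations (mutually exclusive).

    ``kind`` is one of ``"none"``, ``"no_division"``, ``"gene_duplication"``
    or ``"growth_time"`` (the latter with ``growth_time_min`` set).
    """

    kind: str = "none"
    growth_time_min: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "no_division", "gene_duplication", "growth_time"):
            raise ValueError(f"unknown perturbation mode {self.kind!r}")
        if self.kind == "growth_time":
            if self.growth_time_min is None or self.growth_time_min <= 0:
                raise ValueError("growth_time mode requires growth_time_min > 0")
        elif self.growth_time_min is not None:
            raise ValueError("growth_time_min only valid with kind='growth_time'")

    @classmethod
    def none(cls) -> "PerturbationMode":
        return cls("none")

    @classmethod
    def no_division(cls) -> "PerturbationMode":
        return cls("no_division")

    @classmethod
    def gene_duplication(cls) -> "PerturbationMode":
        return cls("gene_duplication")

    @classmethod
    def growth_time(cls, minutes: float) -> "PerturbationMode":
        return cls("growth_time", growth_time_min=minutes)


def apply_perturbation(
    mode: PerturbationMode, params: ModelParams
) -> tuple[ModelParams, bool]:
    """Resolve a perturbation into (effective parameters, divisions suppressed?)."""
    if mode.kind == "none":
        return params, False
    if mode.kind == "no_division":
        return params, True
    if mode.kind == "gene_duplication":
        return params.with_(gene_copies=2 * params.gene_copies), False
    if mode.kind == "growth_time":
        return convert_rates_for_generation_time(params, mode.growth_time_min), False
    raise ValueError(f"unknown perturbation mode {mode.kind!r}")


class CellState:
    """Mutable integer-count state of one cell (volume in birth-volume units)."""

    __slots__ = (
        "n_ada",
        "n_me",
        "n_in",
        "n_bound",
        "promoter_free",
        "gene_copies",
        "cell_age",
        "time",
    )

    def __init__(
        self,
        n_ada: int = 0,
        n_me: int = 0,
        n_in: int = 0,
        n_bound: int = 0,
        gene_copies: int = 1,
        cell_age: float = 0.0,
        time: float = 0.0,
    ):
        if min(n_ada, n_me, n_in, n_bound) < 0:
            raise ValueError("counts must be non-negative")
        if n_bound > gene_copies:
            raise ValueError("n_bound cannot exceed gene_copies")
        self.n_ada = n_ada
        self.n_me = n_me
        self.n_in = n_in
        self.n_bound = n_bound
        self.gene_copies = gene_copies
        self.promoter_free = gene_copies - n_bound
        self.cell_age = cell_age
        self.time = time

    @property
    def volume(self) -> float:
        return _volume(self.cell_age)

    @property
    def total(self) -> int:
        """Total Ada abundance: free Ada + free meAda + bound meAda + inAda."""
        return self.n_ada + self.n_me + self.n_in + self.n_bound

    def copy(self) -> "CellState":
        c = CellState.__new__(CellState)
        for name in self.__slots__:
            setattr(c, name, getattr(self, name))
        return c

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CellState(t={self.time:.3f}, age={self.cell_age:.3f}, "
            f"ada={self.n_ada}, me={self.n_me}, in={self.n_in}, "
            f"bound={self.n_bound}/{self.gene_copies})"
        )


def propensities(
    state: CellState, mms: float, params: ModelParams
) -> tuple[float, float, float, float, float, float]:
    """Reaction propensities (per generation) in REACTIONS order."""
    return (
        params.k_basal * state.promoter_free,
        params.k_ind * state.n_bound,
        params.k_me * mms * state.n_ada,
        params.rho * state.n_me,
        (params.k_on / state.volume) * state.n_me * state.promoter_free,
        params.k_off * state.n_bound,
    )


def _fire(state: CellState, reaction: int) -> None:
    if reaction == 0 or reaction == 1:
        state.n_ada += 1
    elif reaction == 2:
        state.n_ada -= 1
        state.n_me += 1
    elif reaction == 3:
        state.n_me -= 1
        state.n_in += 1
    elif reaction == 4:
        state.n_me -= 1
        state.promoter_free -= 1
        state.n_bound += 1
    else:
        state.n_me += 1
        state.promoter_free += 1
        state.n_bound -= 1


def gillespie_step(
    state: CellState,
    mms: float,
    params: ModelParams,
    rng: np.random.Generator,
    t_max: float = math.inf,
) -> tuple[int | None, float]:
    """Advance the cell by one stochastic event (or to ``t_max``).

    Draws an exponential waiting time from the total propensity and fires
    one reaction chosen in proportion to the individual rates.  The step is
    truncated (no reaction fired) at ``t_max`` — used by the simulator for
    division boundaries, MMS switches and sampling times — and at the
    volume-resolution cap while the binding channel is active.  Returns
    ``(reaction_index or None, elapsed)`` with the state mutated in place.
    """
    t0 = state.time
    a0 = params.k_basal * state.promoter_free
    a1 = params.k_ind * state.n_bound
    a2 = params.k_me * mms * state.n_ada
    a3 = params.rho * state.n_me
    a4 = (params.k_on / _volume(state.cell_age)) * state.n_me * state.promoter_free
    a5 = params.k_off * state.n_bound
    total = a0 + a1 + a2 + a3 + a4 + a5

    cap = min(t_max, t0 + BIND_STEP_CAP) if a4 > 0.0 else t_max
    if total <= 0.0:
        if cap == math.inf:
            raise ValueError("zero total propensity with no scheduled boundary")
        elapsed = cap - t0
        state.time = cap
        state.cell_age += elapsed
        return None, elapsed

    wait = -math.log(1.0 - rng.random()) / total
    if t0 + wait >= cap:
        elapsed = cap - t0
        state.time = cap
        state.cell_age += elapsed
        return None, elapsed

    state.time = t0 + wait
    state.cell_age += wait
    u = rng.random() * total
    if u < a0:
        reaction = 0
    elif u < a0 + a1:
        reaction = 1
    elif u < a0 + a1 + a2:
        reaction = 2
    elif u < a0 + a1 + a2 + a3:
        reaction = 3
    elif u < a0 + a1 + a2 + a3 + a4:
        reaction = 4
    else:
        reaction = 5
    _fire(state, reaction)
    return reaction, wait


def divide(state: CellState, rng: np.random.Generator) -> CellState:
    """Divide the cell and follow one daughter.

    The volume is halved (reset to 1); promoter-bound meAda is released
    into the free pool before partitioning and the promoter reset to free;
    each species is then thinned by an independent Binomial(n, 1/2) draw.
    """
    if abs(state.cell_age - 1.0) > 1e-6:
        raise ValueError(f"divide() called at cell_age={state.cell_age}, expected 1")
    state.n_me += state.n_bound
    state.n_bound = 0
    state.promoter_free = state.gene_copies
    state.n_ada = int(rng.binomial(state.n_ada, 0.5)) if state.n_ada else 0
    state.n_me = int(rng.binomial(state.n_me, 0.5)) if state.n_me else 0
    state.n_in = int(rng.binomial(state.n_in, 0.5)) if state.n_in else 0
    state.cell_age = 0.0
    return state


@dataclass
class CellTrace:
    """Sampled lineage of one simulated cell (times in generations)."""

    times: np.ndarray
    n_ada: np.ndarray
    n_me: np.ndarray
    n_in: np.ndarray
    n_bound: np.ndarray
    volume: np.ndarray
    division_times: list
    first_me_time: float | None
    initial_n_ada: int
    params: ModelParams
    schedule: MMSSchedule
    mode: PerturbationMode
    seed: object = None
    stopped_early: bool = False

    @property
    def total(self) -> np.ndarray:
        return self.n_ada + self.n_me + self.n_in + self.n_bound

    @property
    def concentration(self) -> np.ndarray:
        return self.total / self.volume

    @property
    def times_min(self) -> np.ndarray:
        return self.times * self.params.generation_time_min

    def to_dataframe(self, cell_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "time_generations": self.times,
                "time_min": self.times_min,
                "n_ada": self.n_ada,
                "n_me": self.n_me,
                "n_in": self.n_in,
                "n_bound": self.n_bound,
                "volume": self.volume,
                "total": self.total,
                "concentration": self.concentration,
                "mms": [self.schedule.concentration(t) for t in self.times],
            }
        )


def initial_state(
    params: ModelParams,
    rng: np.random.Generator,
    init_ada_mean: float = 1.0,
    init: str = "poisson",
    mms: float = 0.0,
) -> CellState:
    """Draw a starting state.

    ``init="poisson"`` (default): n_ada ~ Poisson(init_ada_mean), no other
    species — the pre-damage condition.  ``init="steady_state"``: counts
    drawn as Poissons around the deterministic steady state at ``mms``,
    for starting a population in the induced regime without simulating the
    approach.
    """
    if init == "poisson":
        return CellState(n_ada=int(rng.poisson(init_ada_mean)), gene_copies=params.gene_copies)
    if init == "steady_state":
        ss = steady_state(params, mms)
        return CellState(
            n_ada=int(rng.poisson(ss.ada)),
            n_me=int(rng.poisson(ss.me_ada)),
            n_in=int(rng.poisson(ss.in_ada)),
            gene_copies=params.gene_copies,
        )
    raise ValueError(f"unknown init mode {init!r}")


def simulate_cell(
    params: ModelParams,
    schedule: MMSSchedule,
    t_end: float,
    mode: PerturbationMode | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    sample_interval_min: float = 3.0,
    init_ada_mean: float = 1.0,
    init: str = "poisson",
    init_mms: float | None = None,
    stop_at_total: int | None = None,
) -> CellTrace:
    """Simulate one mother-machine-style cell lineage.

    The cell is born at volume 1 and grows exponentially to volume 2 over
    one generation; divisions occur at integer generation times (except in
    no-division mode, where volume grows unboundedly and the gene copy
    number doubles at each nominal generation boundary).  Counts are
    recorded on a regular sampling grid (default 3-min equivalent).
    ``stop_at_total`` ends the simulation early once the total-Ada count
    reaches that value (useful for activation-delay studies where the
    induced regime itself is not needed).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    mode = mode or PerturbationMode.none()
    if rng is None:
        rng = np.random.default_rng(seed)
    eff_params, no_div = apply_perturbation(mode, params)

    state = initial_state(
        eff_params, rng, init_ada_mean=init_ada_mean, init=init,
        mms=schedule.concentration(0.0) if init_mms is None else init_mms,
    )
    initial_n_ada = state.n_ada

    dt = sample_interval_min / eff_params.generation_time_min
    n_samples = int(math.floor(t_end / dt + 1e-9)) + 1
    sample_times = np.arange(n_samples) * dt
    rec = {
        k: np.zeros(n_samples, dtype=np.int64)
        for k in ("n_ada", "n_me", "n_in", "n_bound")
    }
    vol_rec = np.zeros(n_samples, dtype=float)
    breakpoints = list(schedule.breakpoints(t_end))
    division_times: list[float] = []
    first_me: float | None = None

    def record(i: int) -> None:
        rec["n_ada"][i] = state.n_ada
        rec["n_me"][i] = state.n_me
        rec["n_in"][i] = state.n_in
        rec["n_bound"][i] = state.n_bound
        vol_rec[i] = state.volume

    record(0)
    si = 1
    next_gen_boundary = 1.0
    bp_i = 0
    stopped = False
    while state.time < t_end - _EPS:
        next_sample = sample_times[si] if si < n_samples else t_end
        next_bp = breakpoints[bp_i] if bp_i < len(breakpoints) else math.inf
        boundary = min(next_sample, next_gen_boundary, next_bp, t_end)
        mms = schedule.concentration(state.time)
        reaction, _ = gillespie_step(state, mms, eff_params, rng, t_max=boundary)
        if reaction == 2 and first_me is None:
            first_me = state.time
        if reaction is not None:
            if stop_at_total is not None and state.total >= stop_at_total:
                stopped = True
            else:
                continue
        # at a boundary (or early stop): handle events in order
        t = state.time
        if t >= next_gen_boundary - _EPS and not stopped:
            if no_div:
                # replication without division: copies double, promoter stays
                added = state.gene_copies
                state.gene_copies += added
                state.promoter_free += added
            else:
                state.cell_age = 1.0
                divide(state, rng)
                division_times.append(next_gen_boundary)
            next_gen_boundary += 1.0
        if bp_i < len(breakpoints) and t >= next_bp - _EPS:
            bp_i += 1
        if si < n_samples and t >= next_sample - _EPS:
            record(si)
            si += 1
        if stopped:
            # expose the crossing at the next sample slot (the first
            # at-or-above sample under the sampled-crossing convention)
            if si < n_samples:
                record(si)
                si += 1
            break

    if stopped and si < n_samples:
        # truncate the grid at the last recorded sample
        sample_times = sample_times[:si]
        for k in rec:
            rec[k] = rec[k][:si]
        vol_rec = vol_rec[:si]

    return CellTrace(
        times=sample_times,
        n_ada=rec["n_ada"],
        n_me=rec["n_me"],
        n_in=rec["n_in"],
        n_bound=rec["n_bound"],
        volume=vol_rec,
        division_times=division_times,
        first_me_time=first_me,
        initial_n_ada=initial_n_ada,
        params=params,
        schedule=schedule,
        mode=mode,
        seed=seed,
        stopped_early=stopped,
    )


def simulate_population(
    n_cells: int,
    params: ModelParams,
    schedule: MMSSchedule,
    t_end: float,
    mode: PerturbationMode | None = None,
    seed: int = 0,
    **kwargs,
) -> list[CellTrace]:
    """Simulate independent lineages with per-cell RNG streams.

    Streams are spawned deterministically from ``seed`` so the population
    is reproducible from ``(seed, n_cells)`` and cell *i* is identical
    regardless of how many other cells are simulated.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_cells)
    traces = []
    for i, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        tr = simulate_cell(params, schedule, t_end, mode=mode, rng=rng, **kwargs)
        tr.seed = (seed, i)
        traces.append(tr)
    return traces


def traces_to_dataframe(traces: Sequence[CellTrace]) -> pd.DataFrame:
    """Concatenate traces into one tidy long-format table."""
    return pd.concat(
        [tr.to_dataframe(cell_id=i) for i, tr in enumerate(traces)],
        ignore_index=True,
    )
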
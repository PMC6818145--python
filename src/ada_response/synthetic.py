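"""Synthetic microscopy-like observables from simulated lineages.

Emulates what the time-lapse experiment actually records: a fluorescence
signal proportional to the matured fraction of Ada-mYPet per unit cell
volume, sampled at 3-min intervals, on top of camera background, with the
per-cell background subtraction the experimental pipeline applies.
Maturation is modeled as a static detection fraction 1/(1 + t_half/T)
(the steady-state matured fraction for a maturation half-time t_half and
generation time T), matching the correction applied to the experimental
data rather than an explicit maturation reaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gillespie import CellTrace, PerturbationMode, simulate_cell, simulate_population
from .params import ModelParams, MMSSchedule


@dataclass(frozen=True)
class FluorescenceSettings:
    """Detection model for emulated fluorescence.

    ``maturation_half_time_min`` and the generation time set the detected
    fraction; ``extrinsic_cv`` adds an optional per-cell log-normal
    intensity factor (default off — the circuit model itself contains only
    intrinsic noise); background is additive Gaussian per sample.
    """

    maturation_half_time_min: float = 9.7
    sampling_interval_min: float = 3.0
    background_mean: float = 0.0
    background_sd: float = 0.0
    extrinsic_cv: float = 0.0
    intensity_per_molecule: float = 1.0

    def __post_init__(self) -> None:
        if self.maturation_half_time_min < 0:
            raise ValueError("maturation half-time must be >= 0")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling interval must be > 0")
        if min(self.background_sd, self.extrinsic_cv, self.intensity_per_molecule) < 0:
            raise ValueError("noise and intensity settings must be >= 0")


def detection_fraction(
    maturation_half_time_min: float, generation_time_min: float
) -> float:
    """Fraction of molecules that are fluorescently detectable.

    At balanced growth a protein with maturation half-time t_half in a
    cell with generation time T is matured (detectable) with probability
    1/(1 + t_half/T).
    """
    if generation_time_min <= 0:
        raise ValueError("generation time must be > 0")
    if maturation_half_time_min < 0:
        raise ValueError("maturation half-time must be >= 0")
    return 1.0 / (1.0 + maturation_half_time_min / generation_time_min)


def emulate_fluorescence(
    trace: CellTrace,
    settings: FluorescenceSettings,
    rng: np.random.Generator,
    t_mms_on: float | None = None,
) -> pd.DataFrame:
    """Convert a count trace into an experiment-like fluorescence trace.

    signal = intensity_per_molecule · detection_fraction · total/volume,
    scaled by a per-cell extrinsic factor (if enabled) and summed with
    Gaussian background per sample; the trace is resampled to the
    detection interval.  A background-subtracted channel is computed from
    the per-cell pre-MMS mean signal when ``t_mms_on`` is given (the
    experimental per-cell correction), else from the background mean.
    """
    T = trace.params.generation_time_min
    if trace.mode.kind == "growth_time":
        T = trace.mode.growth_time_min
    frac = detection_fraction(settings.maturation_half_time_min, T)

    dt_native = float(trace.times[1] - trace.times[0]) if len(trace.times) > 1 else None
    dt_target = settings.sampling_interval_min / T
    if dt_native is None or dt_native > dt_target * (1 + 1e-9):
        raise ValueError("trace must be sampled at least as finely as the "
                         "fluorescence sampling interval")
    stride = max(int(round(dt_target / dt_native)), 1)
    idx = np.arange(0, len(trace.times), stride)

    conc = trace.total[idx] / trace.volume[idx]
    cell_factor = 1.0
    if settings.extrinsic_cv > 0:
        sigma2 = np.log1p(settings.extrinsic_cv**2)
        cell_factor = float(
            rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2))
        )
    background = settings.background_mean + (
        rng.normal(0.0, settings.background_sd, size=len(idx))
        if settings.background_sd > 0
        else 0.0
    )
    signal = settings.intensity_per_molecule * frac * conc * cell_factor + background

    times = trace.times[idx]
    if t_mms_on is not None and (times < t_mms_on).any():
        baseline = float(np.mean(signal[times < t_mms_on]))
    else:
        baseline = settings.background_mean
    return pd.DataFrame(
        {
            "time_generations": times,
            "time_min": times * T,
            "signal": signal,
            "signal_bgsub": signal - baseline,
            "true_total": trace.total[idx],
            "true_concentration": conc,
        }
    )


def snapshot_counts(
    params: ModelParams,
    n_cells: int,
    rng: np.random.Generator,
    mean: float = 1.0,
    mode: str = "poisson",
    burn_in: float = 10.0,
) -> np.ndarray:
    """Single-molecule-counting snapshot of damage-free Ada copy numbers.

    ``mode="poisson"`` (default) draws Poisson(mean) counts, as used for
    the basal copy-number comparison.  ``mode="lineage"`` simulates each
    cell's basal lineage for ``burn_in`` generations plus a uniformly
    random cell-cycle phase and returns the count there (the stationary
    age-mixture, where the count at age a is Poisson(k_basal·(1+a))).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mode == "poisson":
        return rng.poisson(mean, size=n_cells).astype(np.int64)
    if mode == "lineage":
        counts = np.empty(n_cells, dtype=np.int64)
        sched = MMSSchedule.constant(0.0)
        for i in range(n_cells):
            t_end = burn_in + float(rng.uniform(0.0, 1.0))
            tr = simulate_cell(
                params, sched, t_end, rng=rng,
                sample_interval_min=params.generation_time_min * t_end,
            )
            counts[i] = tr.n_ada[-1]
        return counts
    raise ValueError(f"unknown snapshot mode {mode!r}")


@dataclass
class MotherMachineDataset:
    """Bundled synthetic dataset: fluorescence, ground truth, manifest."""

    fluorescence: pd.DataFrame
    ground_truth: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fluorescence": outdir / "fluorescence.csv",
            "ground_truth": outdir / "ground_truth.csv",
            "manifest": outdir / "manifest.json",
        }
        try:
            self.fluorescence.to_csv(paths["fluorescence"], index=False)
            self.ground_truth.to_csv(paths["ground_truth"], index=False)
            paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        except OSError as e:
            raise OSError(f"failed writing dataset under {outdir}: {e}") from e
        return {k: str(v) for k, v in paths.items()}


def mother_machine_dataset(
    n_cells: int,
    params: ModelParams,
    schedule: MMSSchedule,
    t_end: float,
    mode: PerturbationMode | None = None,
    settings: FluorescenceSettings | None = None,
    seed: int = 0,
    t_mms_on: float | None = None,
    **sim_kwargs,
) -> MotherMachineDataset:
    """Generate a reproducible mother-machine-style dataset.

    Simulates ``n_cells`` lineages, emulates the fluorescence channel for
    each, and bundles tidy per-cell tables with a manifest recording every
    parameter and the master seed.  Deterministic given ``seed``.
    """
    settings = settings or FluorescenceSettings()
    mode = mode or PerturbationMode.none()
    traces = simulate_population(
        n_cells, params, schedule, t_end, mode=mode, seed=seed,
        sample_interval_min=settings.sampling_interval_min, **sim_kwargs,
    )
    fluor_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1)))
    fluor_frames = []
    truth_frames = []
    for i, tr in enumerate(traces):
        f = emulate_fluorescence(tr, settings, fluor_rng, t_mms_on=t_mms_on)
        f.insert(0, "cell_id", i)
        fluor_frames.append(f)
        truth_frames.append(tr.to_dataframe(cell_id=i))
    manifest = {
        "n_cells": n_cells,
        "t_end_generations": t_end,
        "seed": seed,
        "t_mms_on": t_mms_on,
        "params": params.to_dict(),
        "schedule": schedule.to_list(),
        "mode": {"kind": mode.kind, "growth_time_min": mode.growth_time_min},
        "fluorescence": asdict(settings),
        "columns": {
            "fluorescence": ["cell_id", "time_generations", "time_min", "signal",
                             "signal_bgsub", "true_total", "true_concentration"],
            "ground_truth": ["cell_id", "time_generations", "time_min", "n_ada",
                             "n_me", "n_in", "n_bound", "volume", "total",
                             "concentration", "mms"],
        },
        "format_version": 1,
    }
    return MotherMachineDataset(
        fluorescence=pd.concat(fluor_frames, ignore_index=True),
        ground_truth=pd.concat(truth_frames, ignore_index=True),
        manifest=manifest,
    )
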
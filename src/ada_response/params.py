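"""Parameter sets, MMS exposure schedules and config-file round trips.

The Ada circuit model is parameterized by six rate constants plus timing
conventions.  All rates are expressed per cell generation, anchored to a
reference generation time (42 min, M9 glucose).  MMS concentrations are in
mM throughout; time is in generations unless a name says ``_min``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import yaml

LN2 = math.log(2.0)

#: Reference generation time (minutes) to which the default rates are anchored.
REFERENCE_GENERATION_MIN = 42.0


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the Ada regulatory circuit.

    Defaults are the single reference parameter set used throughout the
    package: basal and fully induced production, promoter binding kinetics,
    the effective methylation coefficient and the meAda inactivation rate.

    Attributes
    ----------
    k_basal : float
        Basal Ada production rate, molecules per generation per gene copy.
    k_ind : float
        Fully induced production rate (meAda-bound promoter), molecules per
        generation per gene copy.
    k_on : float
        Promoter association rate coefficient, per generation (applies at
        unit cell volume in the stochastic model).
    k_off : float
        Promoter dissociation rate, per generation.  (Table conventions
        carry a "molecules" unit so that K = k_off/k_on is in molecules.)
    k_me : float
        Methylation rate coefficient, per mM MMS per generation.
    rho : float
        meAda inactivation (proteolysis/autorepression) rate, per generation.
    generation_time_min : float
        Generation time in minutes that these per-generation rates refer to.
    gene_copies : int
        Number of *ada* gene copies; production scales per copy.
    """

    k_basal: float = 1.25
    k_ind: float = 1250.0
    k_on: float = 10.0
    k_off: float = 1200.0
    k_me: float = 1.25
    rho: float = 0.65
    generation_time_min: float = REFERENCE_GENERATION_MIN
    gene_copies: int = 1

    def __post_init__(self) -> None:
        for name in ("k_basal", "k_ind", "k_on", "k_off", "k_me", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.generation_time_min <= 0:
            raise ValueError("generation_time_min must be > 0")
        if self.gene_copies < 1 or int(self.gene_copies) != self.gene_copies:
            raise ValueError("gene_copies must be an integer >= 1")

    @property
    def K(self) -> float:
        """Promoter dissociation constant k_off / k_on, in molecules."""
        if self.k_on <= 0:
            raise ValueError("K undefined for k_on <= 0")
        return self.k_off / self.k_on

    def with_(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class MMSSchedule:
    """Piecewise-constant MMS concentration versus time (generations).

    ``segments`` is an ordered list of ``(start_time, concentration_mM)``
    pairs; the first start must be 0 and the last segment extends to the
    end of any simulation.  ``concentration(t)`` is right-continuous.
    """

    segments: tuple = ((0.0, 0.0),)

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(c)) for t, c in self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first segment must start at time 0")
        times = [t for t, _ in segs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(c < 0 for _, c in segs):
            raise ValueError("MMS concentrations must be >= 0")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, concentration: float) -> "MMSSchedule":
        return cls(((0.0, concentration),))

    @classmethod
    def pulse(cls, concentration: float, t_on: float, t_off: float) -> "MMSSchedule":
        """Zero before ``t_on``, ``concentration`` on [t_on, t_off), zero after."""
        if not 0 <= t_on < t_off:
            raise ValueError("need 0 <= t_on < t_off")
        segs = [(0.0, 0.0)] if t_on > 0 else []
        segs += [(t_on, concentration), (t_off, 0.0)]
        return cls(tuple(segs))

    def concentration(self, t: float) -> float:
        c = self.segments[0][1]
        for start, conc in self.segments:
            if t >= start:
                c = conc
            else:
                break
        return c

    def breakpoints(self, t_end: float) -> list:
        """Interior segment-change times in (0, t_end)."""
        return [t for t, _ in self.segments[1:] if 0.0 < t < t_end]

    def to_list(self) -> list:
        return [list(seg) for seg in self.segments]

    @classmethod
    def from_list(cls, segs: Sequence[Sequence[float]]) -> "MMSSchedule":
        return cls(tuple((t, c) for t, c in segs))


def load_config(path) -> dict:
    """Read a YAML (or JSON) config into a dict; YAML is a JSON superset."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def save_config(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2))
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def params_from_config(cfg: dict) -> ModelParams:
    return ModelParams.from_dict(cfg.get("params", {}))


def schedule_from_config(cfg: dict) -> MMSSchedule:
    sched = cfg.get("schedule")
    if sched is None:
        return MMSSchedule.constant(0.0)
    if isinstance(sched, dict):
        if "constant" in sched:
            return MMSSchedule.constant(float(sched["constant"]))
        if "pulse" in sched:
            p = sched["pulse"]
            return MMSSchedule.pulse(float(p["concentration"]), float(p["t_on"]), float(p["t_off"]))
        if "segments" in sched:
            return MMSSchedule.from_list(sched["segments"])
        raise ValueError(f"unrecognized schedule spec: {sorted(sched)}")
    return MMSSchedule.from_list(sched)
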
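"""Two-site methylation variant of the Ada circuit.

Ada carries two methyl-accepting cysteines (Cys38 and Cys321).  In this
variant both must be methylated, in sequence, before Ada activates its own
promoter: Ada -> Ada_me1 (singly methylated, transcriptionally inert) ->
meAda (doubly methylated activator).  The single-rate model is the limit
in which one methylation step is much faster than the other; comparing the
two dose-response curves quantifies when the lumped effective methylation
rate is a faithful reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

from .deterministic import induced_production
from .params import LN2, ModelParams


@dataclass(frozen=True)
class TwoCysParams:
    """Base circuit parameters plus per-site methylation coefficients."""

    base: ModelParams
    k_me_1: float
    k_me_2: float

    def __post_init__(self) -> None:
        if self.k_me_1 < 0 or self.k_me_2 < 0:
            raise ValueError("methylation coefficients must be >= 0")


@dataclass(frozen=True)
class TwoCysState:
    """Concentrations of (Ada, Ada_me1, meAda, inAda)."""

    ada: float
    ada_me1: float = 0.0
    me_ada: float = 0.0
    in_ada: float = 0.0

    def __post_init__(self) -> None:
        if min(self.ada, self.ada_me1, self.me_ada, self.in_ada) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def total(self) -> float:
        # Ada_me1 carries the fluorophore and counts toward total Ada.
        return self.ada + self.ada_me1 + self.me_ada + self.in_ada


def two_cys_rate_equations(
    state: TwoCysState, mms: float, params: TwoCysParams
) -> tuple[float, float, float, float]:
    """Derivatives of (Ada, Ada_me1, meAda, inAda).

    Sequential methylation at rates k_me_1·[MMS] and k_me_2·[MMS]; only the
    doubly methylated species activates transcription; every species is
    diluted at ln2 and meAda additionally lost at rho.
    """
    if mms < 0:
        raise ValueError("mms must be >= 0")
    b = params.base
    g = b.gene_copies
    production = g * (b.k_basal + induced_production(state.me_ada, b))
    m1 = params.k_me_1 * mms * state.ada
    m2 = params.k_me_2 * mms * state.ada_me1
    return (
        production - LN2 * state.ada - m1,
        m1 - LN2 * state.ada_me1 - m2,
        m2 - (LN2 + b.rho) * state.me_ada,
        b.rho * state.me_ada - LN2 * state.in_ada,
    )


def two_cys_steady_state(params: TwoCysParams, mms: float) -> TwoCysState:
    """Steady state of the two-site model at constant MMS.

    For a trial meAda level the chain Ada -> Ada_me1 -> meAda is linear, so
    the implied steady meAda is an increasing, saturating map g(meAda);
    the fixed point is bracketed and solved with Brent's method.
    """
    if mms < 0:
        raise ValueError("mms must be >= 0")
    b = params.base
    g = b.gene_copies
    if mms == 0 or params.k_me_1 == 0 or params.k_me_2 == 0:
        return TwoCysState(ada=g * b.k_basal / LN2)

    r1 = params.k_me_1 * mms
    r2 = params.k_me_2 * mms

    def chain_me(me: float) -> float:
        production = g * (b.k_basal + induced_production(me, b))
        ada = production / (LN2 + r1)
        ada1 = r1 * ada / (LN2 + r2)
        return r2 * ada1 / (LN2 + b.rho)

    # chain_me is increasing and bounded by its value at full induction;
    # take the largest fixed point (the induced branch when several exist)
    upper = chain_me(g * (b.k_basal + b.k_ind) / LN2) + 1.0
    f = lambda me: chain_me(me) - me
    import numpy as np

    grid = np.concatenate([[0.0], np.geomspace(1e-9, upper, 400)])
    fvals = np.array([f(x) for x in grid])
    pos = np.nonzero(fvals > 0)[0]
    if len(pos) == 0:
        me = 0.0
    else:
        lo = grid[pos[-1]]
        me = brentq(f, lo, upper, xtol=1e-12, rtol=1e-14)
    production = g * (b.k_basal + induced_production(me, b))
    ada = production / (LN2 + r1)
    ada1 = r1 * ada / (LN2 + r2)
    return TwoCysState(ada=ada, ada_me1=ada1, me_ada=me, in_ada=b.rho / LN2 * me)


def two_cys_dose_response(
    params: TwoCysParams, mms_values: Sequence[float]
) -> list[tuple[float, float]]:
    """Steady-state total Ada versus dose for the two-site model."""
    return [(float(m), two_cys_steady_state(params, m).total) for m in mms_values]


def dose_response_deviation(
    params: TwoCysParams, mms_values: Sequence[float]
) -> float:
    """Max relative deviation of the two-site dose response from the
    single-rate model with k_me = k_me_1, over a dose grid."""
    from .deterministic import steady_state

    single = params.base.with_(k_me=params.k_me_1)
    dev = 0.0
    for m in mms_values:
        t1 = steady_state(single, m).total
        t2 = two_cys_steady_state(params, m).total
        dev = max(dev, abs(t2 - t1) / max(t1, 1e-12))
    return dev
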
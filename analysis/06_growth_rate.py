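"""Growth-rate dependence of the response strength.

The ada gene sits near the replication terminus, so its expression rate
does not rise with growth rate while dilution does.  Holding real-time
expression rates fixed and changing only the division interval (42 min,
glucose vs 75 min, glycerol), slow growers sustain a response at 0.1 mM
MMS that fast growers lose.  Writes results/growth_rate.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ada_response import (
    ModelParams,
    MMSSchedule,
    PerturbationMode,
    convert_rates_for_generation_time,
    simulate_population,
    steady_state,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
THRESHOLD = 23.0


def main() -> None:
    params = ModelParams()
    rows = []
    for gen_min, seed in ((42.0, 55), (75.0, 56)):
        mode = None if gen_min == 42.0 else PerturbationMode.growth_time(gen_min)
        traces = simulate_population(
            200, params, MMSSchedule.constant(0.1), 25.0, seed=seed, mode=mode
        )
        late = traces[0].times >= 20.0
        per_cell = np.array([tr.total[late].mean() for tr in traces])
        det = steady_state(
            convert_rates_for_generation_time(params, gen_min), 0.1
        ).total
        rows.append({
            "generation_min": gen_min,
            "stochastic_mean_total": per_cell.mean(),
            "fraction_sustained": float(np.mean(per_cell > THRESHOLD)),
            "deterministic_steady_state": det,
        })
        print(f"  {gen_min:.0f}-min generations at 0.1 mM: stochastic mean "
              f"{per_cell.mean():7.1f} molecules, {100*rows[-1]['fraction_sustained']:.0f}% "
              f"of cells sustained (deterministic steady state {det:.0f})")
    pd.DataFrame(rows).to_csv(OUT / "growth_rate.csv", index=False)
    print("-> only slow growth sustains the response at this dose; note the "
          "stochastic extinction of induction at 42 min despite a deterministic "
          "steady state above threshold")


if __name__ == "__main__":
    main()
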
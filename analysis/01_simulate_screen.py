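#!/usr/bin/env python
"""Simulate a small-molecule screen plate: for each of the five drug
response regimes (no effect, sensitive, resistant short lag, resistant
long lag, mutator-specific synthetic growth defect), one WT and one
mutator drug well plus their DMSO controls, read every 15 min for 48 h.

Writes results/plate_od600.csv (one row per reading) with a JSON sidecar
of per-well simulation parameters.
"""

import dataclasses
import sys
from pathlib import Path

from mutscreen import SimParams, response_regimes, simulate_plate, write_plate_csv
from mutscreen.growth_sim import drug_free_control

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    grid, labels, params = [], {}, {}
    for col, (regime, (wt_p, mut_p)) in enumerate(response_regimes(seed=seed).items(), 1):
        for row, (strain, p) in enumerate([("WT", wt_p), ("msh2", mut_p)]):
            for drug, pp in [(regime, p), ("DMSO", drug_free_control(p))]:
                well = f"{'AB'[row]}{col}{'d' if drug != 'DMSO' else 'c'}"
                pp = dataclasses.replace(pp, seed=seed)
                grid.append((well, pp))
                labels[well] = (strain, drug, "10uM" if drug != "DMSO" else "")
                params[well] = pp
    curves = simulate_plate(grid, labels=labels)
    OUT.mkdir(exist_ok=True)
    write_plate_csv(curves, OUT / "plate_od600.csv", params=params)
    print(f"simulated {len(curves)} wells x {len(curves[0].times)} readings "
          f"-> {OUT / 'plate_od600.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
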
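#!/usr/bin/env python
"""Estimate lag/rate/endpoint metrics for every well of the simulated
plate and classify each compound's (WT, mutator) response pair.

Reads results/plate_od600.csv (from 01_simulate_screen.py); writes
results/well_metrics.tsv and results/response_classification.tsv and
prints the classification table.
"""

from pathlib import Path

import pandas as pd

from mutscreen import classify_response, estimate_growth_metrics, metrics_frame, read_plate_csv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    plate = RESULTS / "plate_od600.csv"
    if not plate.exists():
        raise SystemExit("run analysis/01_simulate_screen.py first")
    curves = read_plate_csv(plate)
    table = metrics_frame(curves)
    table.to_csv(RESULTS / "well_metrics.tsv", sep="\t", index=False)

    by_id = {c.well_id: c for c in curves}
    rows = []
    compounds = sorted({c.compound for c in curves if c.compound != "DMSO"})
    for i, compound in enumerate(compounds, 0):
        col = [c.well_id for c in curves if c.compound == compound][0][1]
        wells = {
            "wt": f"A{col}d", "mut": f"B{col}d", "wt_ctrl": f"A{col}c", "mut_ctrl": f"B{col}c",
        }
        m = {k: estimate_growth_metrics(by_id[w]) for k, w in wells.items()}
        call = classify_response(m["wt"], m["mut"], m["wt_ctrl"], m["mut_ctrl"])
        rows.append(
            {
                "compound": compound,
                "category": call.category.value,
                "mut_lag_h": m["mut"].lag_h,
                "mut_od_end": round(m["mut"].od_end, 3),
                "wt_od_end": round(m["wt"].od_end, 3),
                "prolonged_vs_control": call.prolonged_vs_control,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "response_classification.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    agree = (out.compound == out.category).mean()
    print(f"\n{agree:.0%} of regimes classified into their intended category")


if __name__ == "__main__":
    main()
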
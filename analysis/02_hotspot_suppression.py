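#!/usr/bin/env python
"""Paired hotspot experiment: does a K+ transient suppress local uptake?

Builds the reduced astrocyte, raises [K]o 2.5 -> 5 mM in a 20-um sphere for
1 s, delivers a 0.1 mM / 1 ms glutamate bolus in a 3-um sphere at 0.9 s, and
compares the peak volume-averaged transporter current against the same bolus
at baseline K+.  A voltage-clamp control (-85 mV everywhere) separates the
voltage-mediated from the direct K+-binding contribution.

Finding (seed 1): the K+ transient lowers the hotspot uptake peak by ~11%.
The clamped control retains ~11% suppression: in this kinetic scheme the
effect is carried almost entirely by extracellular K+ binding to the
transporter (state-6 sequestration), not by the ~0.5 mV depolarisation the
Kir model produces at these parameters.

Writes hotspot traces and a summary JSON under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from astroglt.hotspot import centered_field, suppression_experiment
from astroglt.morphology import build_reduced_morphology


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    graph = build_reduced_morphology(seed=args.seed)
    field = centered_field(graph)
    floating = suppression_experiment(graph, field)
    clamped = suppression_experiment(graph, field, clamp_mv=-85.0)

    for cond in ("baseline", "elevated"):
        pd.DataFrame({
            "time_ms": floating[cond]["times"],
            "i_glut_ma_cm2": floating[cond]["trace"],
        }).to_csv(args.out / f"hotspot_{cond}.csv", index=False)

    summary = dict(
        seed=args.seed,
        n_compartments=int(graph.n),
        suppression_pct=floating["suppression_pct"],
        suppression_pct_clamped=clamped["suppression_pct"],
        peak_baseline_ma_cm2=floating["baseline"]["peak_ma_cm2"],
        peak_elevated_ma_cm2=floating["elevated"]["peak_ma_cm2"],
        tau_decay_baseline_ms=floating["baseline"]["tau_decay_ms"],
    )
    (args.out / "hotspot_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"suppression (voltage floating): {summary['suppression_pct']:.2f}%")
    print(f"suppression (clamped -85 mV):   {summary['suppression_pct_clamped']:.2f}%")
    print(f"baseline peak: {summary['peak_baseline_ma_cm2']:.3e} mA/cm^2, "
          f"tau_decay {summary['tau_decay_baseline_ms']:.2f} ms")


if __name__ == "__main__":
    main()
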
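#!/usr/bin/env python
"""Uptake suppression across recording distances from the soma.

Repeats the paired glutamate-bolus experiment at 10 sites of increasing
somatic distance inside the K+ sphere, recording the peak uptake current
density per site under baseline and elevated K+.

Finding (seed 1): suppression is sign-consistent at all 10 sites
(elevated-K+ peak < baseline peak, paired), with per-site magnitudes near
the whole-hotspot value.  Writes results/distance_profile.csv.

Runtime: ~20 coupled simulations, a few minutes on one CPU.
"""

import argparse
from pathlib import Path

import pandas as pd

from astroglt.hotspot import centered_field, distance_profile
from astroglt.morphology import build_reduced_morphology


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-sites", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    graph = build_reduced_morphology(seed=args.seed)
    field = centered_field(graph)
    prof = distance_profile(graph, field, n_sites=args.n_sites)
    df = pd.DataFrame(prof)
    df.to_csv(args.out / "distance_profile.csv", index=False)

    n_sup = int((df.peak_elevated < df.peak_baseline).sum())
    print(df[["distance_um", "peak_baseline", "peak_elevated",
              "suppression_pct"]].to_string(index=False))
    print(f"suppressed at {n_sup}/{len(df)} sites; "
          f"median suppression {df.suppression_pct.median():.2f}%")


if __name__ == "__main__":
    main()
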
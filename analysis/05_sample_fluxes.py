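#!/usr/bin/env python
"""Uniform flux-space sampling of the two salinity conditions.

Hit-and-run samples the steady-state polytope under each condition (growth
pinned, ATPM fixed, osmolyte excretion closed), writes per-reaction
distribution summaries (min/quartiles/median/max) and glucose-normalized
medians, and drops the raw sample matrices under scratch/ for reuse.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from halogem.fba_engine import apply_condition
from halogem.flux_sampling import hit_and_run_sample, median_fluxes
from halogem.synthetic_data import ToySpec, make_condition_pair, make_toy_core_model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results", type=Path)
    ap.add_argument("--scratch-dir", default="scratch", type=Path)
    ap.add_argument("--n", type=int, default=5000,
                    help="valid points per condition (20000 reproduces the "
                    "full protocol; 5000 keeps this driver fast)")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    args.scratch_dir.mkdir(parents=True, exist_ok=True)

    model, _ = make_toy_core_model(ToySpec())
    pair = make_condition_pair()
    summaries = []
    medians = {}
    for name, cond, seed in (("low", pair.low, args.seed),
                             ("high", pair.high, args.seed + 1)):
        cm = apply_condition(model, cond)
        sample = hit_and_run_sample(cm, args.n, seed=seed, condition=name)
        df = sample.to_frame()
        q = df.quantile([0.0, 0.25, 0.5, 0.75, 1.0]).T
        q.columns = ["min", "q25", "median", "q75", "max"]
        q.insert(0, "condition", name)
        summaries.append(q)
        med = median_fluxes(sample, normalize_by="EX_glc")
        medians[name] = med
        df.to_csv(args.scratch_dir / f"samples_{name}.tsv", sep="\t", index=False)
        print(f"{name}: {sample.n_samples} valid points (seed {seed}), "
              f"median growth {df[cond.biomass_id].median():.4f} 1/h, "
              f"osmolyte flux median {df['ECT_SYN'].median():.4f}")

    pd.concat(summaries).to_csv(args.out_dir / "flux_histograms.tsv", sep="\t")
    norm = pd.DataFrame(medians)
    norm.to_csv(args.out_dir / "normalized_medians.tsv", sep="\t")
    print("glucose-normalized medians (selected):")
    print(norm.loc[["EX_glc", "ECT_SYN", "TCA", "OXPHOS"]].round(4))
    print(f"wrote {args.out_dir}/flux_histograms.tsv and normalized_medians.tsv; "
          f"raw samples under {args.scratch_dir}/")


if __name__ == "__main__":
    main()
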
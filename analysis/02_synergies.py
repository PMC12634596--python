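#!/usr/bin/env python
"""Extract muscle synergies per participant and select the number of synergies.

Reads the dataset written by 01_simulate.py, conditions every trial into an
MVC-normalized activation vector, factorizes the muscles x trials matrix by
NMF for N = 1..muscles, and applies the three selection criteria (R^2 > 0.9,
slope change of the R^2 curve, uniformity of cosine-tuning preferred
directions on disagreement).

Writes per-participant weight matrices, R^2 curves and a selection summary
under OUT/synergies.
"""

import argparse
import json
from pathlib import Path
import sys
import warnings

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from syncoh.io import read_dataset
from syncoh.pipeline import analyze_participant_synergies


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--restarts", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    ds = read_dataset(args.data)
    out = args.out / "synergies"
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    for part in ds.participants:
        _, curve, sel, model = analyze_participant_synergies(
            part, restarts=args.restarts,
            rng=np.random.default_rng(args.seed + part.participant_id))
        pd.DataFrame(model.W, index=part.muscles,
                     columns=[f"synergy_{i + 1}" for i in range(model.n)]) \
            .to_csv(out / f"W_participant_{part.participant_id:02d}.csv")
        pd.DataFrame({"n": np.arange(1, len(curve) + 1), "r2": curve}) \
            .to_csv(out / f"r2_curve_participant_{part.participant_id:02d}.csv",
                    index=False)
        summary.append({"participant": part.participant_id,
                        "n_selected": sel.n_selected, "n_r2": sel.n_r2,
                        "n_slope": sel.n_slope, "r2_at_selected": model.r2,
                        "n_generative": ds.config.n_synergies})
        print(f"participant {part.participant_id}: N={sel.n_selected} "
              f"(criterion i: {sel.n_r2}, ii: {sel.n_slope}), "
              f"R^2={model.r2:.3f}")
    (out / "selection.json").write_text(json.dumps(summary, indent=1))
    ns = [s["n_selected"] for s in summary]
    print(f"selected N across participants: mean {np.mean(ns):.1f} "
          f"+- {np.std(ns):.1f} (generative: {ds.config.n_synergies})")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
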
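#!/usr/bin/env python
"""Decompose coherence spectra into data-driven frequency layers.

Reads the long-format coherence table written by 03_coherence.py, builds
the f x (trials * pairs) matrix of thresholded Z spectra per participant,
factorizes it by NMF for k = 1..k_max, selects the layer count at the
first prominent local minimum of the across-participant SD of the aligned
coherence patterns, and derives each layer's dominance interval.

Writes the selection curve, per-participant W_c patterns and the layer
bounds table under OUT/layers.
"""

import argparse
from pathlib import Path
import sys
import warnings

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from syncoh.layers import CoherenceMatrix, decompose_layers, select_num_layers


def load_matrices(path: Path) -> dict[int, CoherenceMatrix]:
    df = pd.read_csv(path)
    out = {}
    for pid, g in df.groupby("participant"):
        piv = g.pivot_table(index="bin_center_hz",
                            columns=["trial", "muscle_i", "muscle_j"],
                            values="Z", sort=True)
        cols = [(int(t), (int(i), int(j))) for t, i, j in piv.columns]
        out[int(pid)] = CoherenceMatrix(values=piv.to_numpy(),
                                        bin_centers=piv.index.to_numpy(),
                                        columns=cols, participant_id=int(pid))
    return out


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--coherence", type=Path,
                    default=Path("results/coherence/coherence_long.csv.gz"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--k-max", type=int, default=15)
    ap.add_argument("--k", type=int, default=None,
                    help="fix the layer count instead of selecting it")
    ap.add_argument("--restarts", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    matrices = load_matrices(args.coherence)
    out = args.out / "layers"
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(args.seed)
    if args.k is None:
        models_per_k = {}
        for k in range(1, args.k_max + 1):
            models_per_k[k] = [
                decompose_layers(m, k, restarts=args.restarts,
                                 rng=np.random.default_rng(s))
                for m, s in zip(matrices.values(), root.spawn(len(matrices)))]
        curve = select_num_layers(models_per_k)
        pd.DataFrame({"k": curve.k_values, "aggregate_sd": curve.aggregate_sd}) \
            .to_csv(out / "selection_curve.csv", index=False)
        print("aggregate SD by k:",
              " ".join(f"{k}:{s:.4f}" for k, s in zip(curve.k_values,
                                                      curve.aggregate_sd)))
        print(f"selected k = {curve.selected_k}")
        selected = models_per_k[curve.selected_k]
    else:
        selected = [decompose_layers(m, args.k, restarts=args.restarts,
                                     rng=np.random.default_rng(s))
                    for m, s in zip(matrices.values(), root.spawn(len(matrices)))]
        print(f"layer count fixed at k = {args.k}")

    rows = []
    for model in selected:
        pd.DataFrame(model.W, index=model.bin_centers,
                     columns=[f"layer_{i + 1}" for i in range(model.k)]) \
            .to_csv(out / f"Wc_participant_{model.participant_id:02d}.csv")
        for layer, (f1, f2) in enumerate(model.bounds, start=1):
            rows.append({"participant": model.participant_id, "layer": layer,
                         "f1_hz": f1, "f2_hz": f2})
    bounds = pd.DataFrame(rows)
    bounds.to_csv(out / "layer_bounds.csv", index=False)
    mean_bounds = bounds.groupby("layer")[["f1_hz", "f2_hz"]].agg(["mean", "std"])
    print("layer bounds across participants (Hz):")
    print(mean_bounds.round(2).to_string())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
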
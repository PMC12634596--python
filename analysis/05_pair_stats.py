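#!/usr/bin/env python
"""Compare coherence of synergistic vs non-synergistic muscle pairs.

Reads the synergy weights (02), the coherence table (03), and the layer
bounds (04); classifies muscle pairs from row-normalized weights (both
> 0.75 in one synergy = synergistic; 0.75 vs < 0.25 = non-synergistic;
otherwise excluded), averages thresholded Z coherence within each layer
(I_Z), and fits, per layer and per frequency bin, a linear mixed model with
direction dummies, repetition and pair type as fixed effects and a random
intercept per participant.

Writes classification counts, the observation table, and the per-layer and
per-bin model results under OUT/stats.
"""

import argparse
import json
from pathlib import Path
import sys
import warnings

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from syncoh.coherence import CoherenceSpectrum
from syncoh.io import read_dataset
from syncoh.pairstats import (assemble_bin_observations, assemble_observations,
                              classify_pairs, normalize_weights,
                              per_bin_analysis, per_layer_analysis)


def spectra_from_table(df: pd.DataFrame) -> dict[int, list[CoherenceSpectrum]]:
    out: dict[int, list[CoherenceSpectrum]] = {}
    for (trial, i, j), g in df.groupby(["trial", "muscle_i", "muscle_j"]):
        g = g.sort_values("bin_center_hz")
        out.setdefault(int(trial), []).append(CoherenceSpectrum(
            pair=(int(i), int(j)), trial_id=int(trial),
            C=g["C"].to_numpy(), Z=g["Z"].to_numpy(),
            significant=g["significant"].to_numpy(bool),
            n_segments=29, bin_centers=g["bin_center_hz"].to_numpy()))
    return out


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--synergies", type=Path, default=Path("results/synergies"))
    ap.add_argument("--coherence", type=Path,
                    default=Path("results/coherence/coherence_long.csv.gz"))
    ap.add_argument("--layers", type=Path,
                    default=Path("results/layers/layer_bounds.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    ds = read_dataset(args.data)
    coh = pd.read_csv(args.coherence)
    bounds_df = pd.read_csv(args.layers)
    out = args.out / "stats"
    out.mkdir(parents=True, exist_ok=True)

    obs_frames, bin_frames, counts, class_rows = [], [], [], []
    for part in ds.participants:
        W = pd.read_csv(args.synergies / f"W_participant_"
                        f"{part.participant_id:02d}.csv", index_col=0).to_numpy()
        classes = classify_pairs(normalize_weights(W))
        for c in classes:
            class_rows.append({"participant": part.participant_id,
                               "muscle_i": part.muscles[c.pair[0]],
                               "muscle_j": part.muscles[c.pair[1]],
                               "label": c.label, "synergy": c.synergy})
        spectra = spectra_from_table(coh[coh.participant == part.participant_id])
        meta = {t.trial_id: (t.direction_index, t.repetition)
                for t in part.trials}
        b = bounds_df[bounds_df.participant == part.participant_id] \
            .sort_values("layer")
        bounds = list(zip(b.f1_hz, b.f2_hz))
        obs = assemble_observations(classes, spectra, bounds, meta,
                                    part.participant_id)
        obs_frames.append(obs)
        bin_frames.append(assemble_bin_observations(classes, spectra, meta,
                                                    part.participant_id))
        n_layers = max(len(bounds), 1)
        counts.append({
            "participant": part.participant_id,
            "synergistic": int((obs.pair_type == "synergistic").sum()) // n_layers,
            "non_synergistic":
                int((obs.pair_type == "non_synergistic").sum()) // n_layers,
        })

    obs = pd.concat(obs_frames, ignore_index=True)
    bin_obs = pd.concat(bin_frames, ignore_index=True)
    pd.DataFrame(class_rows).to_csv(out / "pair_classification.csv", index=False)
    obs.to_csv(out / "observations.csv.gz", index=False)
    (out / "pair_counts.json").write_text(json.dumps(counts, indent=1))
    print("pair-trial counts entering the model (per participant):")
    for c in counts:
        print(f"  participant {c['participant']}: {c['synergistic']} synergistic, "
              f"{c['non_synergistic']} non-synergistic")

    per_layer = per_layer_analysis(obs)
    layer_df = pd.DataFrame([vars(r) for r in per_layer])
    layer_df.to_csv(out / "lmm_per_layer.csv", index=False)
    print("\nper-layer pair-type effect (I_Z, synergistic - non-synergistic):")
    for r in per_layer:
        star = "*" if r.pvalue < args.alpha else " "
        print(f"  layer {r.unit}: estimate {r.estimate:8.3f} "
              f"(SE {r.se:.3f}), p = {r.pvalue:.3g} {star}")

    per_bin = per_bin_analysis(bin_obs)
    bin_df = pd.DataFrame([vars(r) for r in per_bin])
    bin_df.to_csv(out / "lmm_per_bin.csv", index=False)
    sig = [f"{r.unit:.1f}" for r in per_bin if r.pvalue < args.alpha]
    print(f"\nper-bin analysis: pair-type effect significant at "
          f"{len(sig)}/{len(per_bin)} bins ({', '.join(sig)} Hz)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
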
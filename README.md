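# syncoh

Muscle synergies, frequency-specific intermuscular coherence, and
data-driven spectral layers from multi-muscle surface EMG.

## The problem

During a multi-directional isometric force task, the nervous system
coordinates many muscles through a small set of **muscle synergies**:
nonnegative muscle weightings `W` recruited by direction-tuned activation
coefficients, extracted from EMG envelopes by nonnegative matrix
factorization (NMF), with `R^2 = 1 - SSE/SST` governing the choice of the
number of synergies.  If synergies are implemented by **common synaptic
drive** to motoneuron pools, muscle pairs within a synergy should show
higher **intermuscular coherence** — the frequency-resolved squared
correlation of their (amplitude-demodulated) EMG —

```
C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f)),     Z_xy = 2 Ns atanh(C_xy)
```

than pairs split across synergies, and only in the frequency bands that
carry the shared drive.  Rather than imposing literature band limits, the
pipeline detects **subject-specific frequency layers** by a second NMF on
the matrix of per-trial, per-pair coherence spectra, choosing the number of
layers whose spectral patterns are most consistent across participants, and
then compares layer-averaged coherence `I_Z` between synergistic and
non-synergistic pairs with a linear mixed model (direction, repetition and
pair type as fixed effects; participant as a random intercept).

The package is for motor-control and electrophysiology researchers who want
a tested, reproducible implementation of this chain.  Since raw recordings
are not distributable, a synthetic-EMG generator with known synergy
structure and known band-limited common drives (`syncoh.simulate`) defines
every study condition, and all claims are validated by parameter recovery.

## Worked example

The numbered drivers under `analysis/` run the chain on a scaled synthetic
study (4 participants, 12 muscles, 6 synergies, 32 trials each):

```bash
python analysis/01_simulate.py --seed 0 --out results
python analysis/02_synergies.py
python analysis/03_coherence.py
python analysis/04_layers.py
python analysis/05_pair_stats.py
```

`02_synergies.py` recovers the generative synergy count for every
participant:

```
participant 0: N=6 (criterion i: 6, ii: 6), R^2=1.000
...
selected N across participants: mean 6.0 +- 0.0 (generative: 6)
```

`04_layers.py` scans k = 1..15 and selects the layer count at the minimum
of the across-participant pattern SD, recovering the six generative drive
bands; every boundary lands within one bin width (3.91 Hz) of the true
edges (1, 8.7, 16.9, 25.7, 35.8, 48.6, 60 Hz):

```
aggregate SD by k: 1:0.0640 2:0.0281 3:0.0169 4:0.0197 5:0.0049 6:0.0042 7:0.0229 ...
selected k = 6
layer bounds across participants (Hz):
layer 1: 1.00 - 9.77    layer 4: 25.39 - 37.11
layer 2: 9.77 - 17.58   layer 5: 37.11 - 48.83
layer 3: 17.58 - 25.39  layer 6: 48.83 - 60.00
```

To reproduce the headline physiological contrast, generate data whose
within-synergy drives are confined below ~26 Hz while all muscles share
weak high-band drives, and fix the decomposition at six layers:

```bash
python analysis/01_simulate.py --seed 0 --out results/low --condition low-drives
python analysis/02_synergies.py --data results/low/data --out results/low
python analysis/03_coherence.py --data results/low/data --out results/low
python analysis/04_layers.py --coherence results/low/coherence/coherence_long.csv.gz \
    --out results/low --k 6
python analysis/05_pair_stats.py --data results/low/data --synergies results/low/synergies \
    --coherence results/low/coherence/coherence_long.csv.gz \
    --layers results/low/layers/layer_bounds.csv --out results/low
```

The per-layer mixed model then finds the pair-type effect exactly where the
generator put the synergy-specific drive — the three low-frequency layers —
and nothing in the two highest layers (the 27.3 Hz bin straddles the
25.7 Hz band edge, which is why layer 4 retains a small edge effect here):

```
per-layer pair-type effect (I_Z, synergistic - non-synergistic):
  layer 1: estimate   11.745 (SE 0.376), p = 3.74e-214 *
  layer 2: estimate   10.984 (SE 0.349), p = 8.3e-218  *
  layer 3: estimate    8.782 (SE 0.320), p = 3.71e-166 *
  layer 4: estimate    0.788 (SE 0.202), p = 9.91e-05  *
  layer 5: estimate    0.251 (SE 0.208), p = 0.226
  layer 6: estimate    0.342 (SE 0.217), p = 0.115

per-bin analysis: pair-type effect significant at 7/15 bins (3.9 ... 27.3 Hz)
```

Estimates are differences in Fisher-normalized coherence `I_Z` between
synergistic and non-synergistic pairs within a layer; `*` marks p < 0.05.

See `docs/methods.md` for the signal model, every numerical convention, and
what these synthetic recoveries do and do not establish about real EMG.

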
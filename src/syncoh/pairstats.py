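"""Synergistic vs non-synergistic muscle pairs and the pair-type mixed model.

Synergy weights are normalized so each muscle's squared contributions across
synergies sum to one.  A pair is *synergistic* when both muscles exceed a
0.75 normalized weight in the same synergy, *non-synergistic* when one
exceeds 0.75 while the other stays below 0.25 in that synergy, and
*excluded* otherwise.  Because sum_s w^2 = 1, no muscle can exceed 0.75 in
two synergies (0.75^2 + 0.75^2 > 1), so the labels are well defined.

Layer-averaged Fisher-normalized coherence (I_Z) of the labelled pairs is
then modelled with a linear mixed model: target-direction dummies,
repetition, and the pair-type indicator as fixed effects, and a random
intercept per participant (REML fit, Wald test on the pair-type
coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .coherence import CoherenceSpectrum
from .layers import layer_average_iz

__all__ = [
    "PairClassification",
    "LmmResult",
    "UPPER_THRESHOLD",
    "LOWER_THRESHOLD",
    "normalize_weights",
    "classify_pairs",
    "assemble_observations",
    "assemble_bin_observations",
    "fit_pair_lmm",
    "per_layer_analysis",
    "per_bin_analysis",
]

UPPER_THRESHOLD = 0.75
LOWER_THRESHOLD = 0.25


@dataclass
class PairClassification:
    pair: tuple[int, int]
    label: str                      # synergistic | non_synergistic | excluded
    synergy: int | None = None      # supporting synergy index


@dataclass
class LmmResult:
    unit: float | int               # layer index or bin center
    estimate: float
    se: float
    statistic: float
    pvalue: float
    n_obs: int
    n_participants: int
    converged: bool


def normalize_weights(W: np.ndarray) -> np.ndarray:
    """Scale each muscle row of the synergy weights to unit Euclidean norm."""
    W = np.asarray(W, float)
    if np.any(W < 0):
        raise ValueError("synergy weights must be nonnegative")
    norms = np.linalg.norm(W, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"muscle index {zero[0]} has an all-zero weight row")
    return W / norms[:, None]


def classify_pairs(weights: np.ndarray) -> list[PairClassification]:
    """Label every muscle pair from row-normalized synergy weights."""
    W = np.asarray(weights, float)
    if np.any(np.abs(np.sum(W ** 2, axis=1) - 1.0) > 1e-6):
        raise ValueError("weights must be row-normalized (sum of squares = 1)")
    m, n_syn = W.shape
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            label, syn = "excluded", None
            for s in range(n_syn):
                wi, wj = W[i, s], W[j, s]
                if wi > UPPER_THRESHOLD and wj > UPPER_THRESHOLD:
                    label, syn = "synergistic", s
                    break
                if (wi > UPPER_THRESHOLD and wj < LOWER_THRESHOLD) or \
                        (wj > UPPER_THRESHOLD and wi < LOWER_THRESHOLD):
                    label, syn = "non_synergistic", s
                    break
            out.append(PairClassification(pair=(i, j), label=label, synergy=syn))
    return out


def _pair_rows(classifications: list[PairClassification]) -> dict[tuple[int, int], PairClassification]:
    return {c.pair: c for c in classifications}


def assemble_observations(classifications: list[PairClassification],
                          spectra_by_trial: dict[int, list[CoherenceSpectrum]],
                          bounds: list[tuple[float, float]],
                          trial_meta: dict[int, tuple[int, int]],
                          participant_id: int) -> pd.DataFrame:
    """One row per (trial, labelled pair, layer) with the layer-averaged I_Z.

    ``trial_meta`` maps trial id to (direction index, repetition).  Pairs
    labelled *excluded* are dropped, as are (trial, pair) spectra with no
    significant bin anywhere in the analyzed range.
    """
    if not bounds:
        raise ValueError("no layer bounds supplied")
    lut = _pair_rows(classifications)
    rows = []
    for trial_id, spectra in spectra_by_trial.items():
        if trial_id not in trial_meta:
            raise ValueError(f"missing metadata for trial {trial_id}")
        d_idx, rep = trial_meta[trial_id]
        for spec in spectra:
            cls = lut.get(spec.pair)
            if cls is None or cls.label == "excluded":
                continue
            if not np.any(spec.Z > 0):
                continue
            for layer, (f1, f2) in enumerate(bounds, start=1):
                rows.append({
                    "participant": participant_id,
                    "trial": trial_id,
                    "muscle_i": spec.pair[0],
                    "muscle_j": spec.pair[1],
                    "layer": layer,
                    "iz": layer_average_iz(spec.Z, (f1, f2), spec.bin_centers),
                    "pair_type": cls.label,
                    "synergistic": int(cls.label == "synergistic"),
                    "direction": d_idx,
                    "repetition": rep,
                })
    return pd.DataFrame(rows)


def assemble_bin_observations(classifications: list[PairClassification],
                              spectra_by_trial: dict[int, list[CoherenceSpectrum]],
                              trial_meta: dict[int, tuple[int, int]],
                              participant_id: int) -> pd.DataFrame:
    """One row per (trial, labelled pair, frequency bin) with thresholded Z."""
    lut = _pair_rows(classifications)
    rows = []
    for trial_id, spectra in spectra_by_trial.items():
        d_idx, rep = trial_meta[trial_id]
        for spec in spectra:
            cls = lut.get(spec.pair)
            if cls is None or cls.label == "excluded":
                continue
            if not np.any(spec.Z > 0):
                continue
            for b, fc in enumerate(spec.bin_centers):
                rows.append({
                    "participant": participant_id,
                    "trial": trial_id,
                    "muscle_i": spec.pair[0],
                    "muscle_j": spec.pair[1],
                    "bin_center": float(fc),
                    "z": float(spec.Z[b]),
                    "pair_type": cls.label,
                    "synergistic": int(cls.label == "synergistic"),
                    "direction": d_idx,
                    "repetition": rep,
                })
    return pd.DataFrame(rows)


def fit_pair_lmm(observations: pd.DataFrame, value_col: str = "iz",
                 unit: float | int = 0) -> LmmResult:
    """Random-intercept mixed model of coherence on pair type.

    Fixed effects: direction dummies (first direction as reference),
    repetition (numeric), and the synergistic indicator; random intercept
    per participant; REML.  Returns the Wald test of the pair-type
    coefficient.
    """
    df = observations
    if df.empty:
        raise ValueError("empty observation table")
    if df["participant"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 participants")
    if df["synergistic"].nunique() < 2:
        raise ValueError("both pair types must be present")
    model = smf.mixedlm(f"{value_col} ~ C(direction) + repetition + synergistic",
                        data=df, groups=df["participant"])
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        res = model.fit(reml=True)
    return LmmResult(
        unit=unit,
        estimate=float(res.params["synergistic"]),
        se=float(res.bse["synergistic"]),
        statistic=float(res.tvalues["synergistic"]),
        pvalue=float(res.pvalues["synergistic"]),
        n_obs=int(len(df)),
        n_participants=int(df["participant"].nunique()),
        converged=bool(getattr(res, "converged", True)),
    )


def per_layer_analysis(observations: pd.DataFrame) -> list[LmmResult]:
    """Fit the pair-type mixed model separately within each layer."""
    return [fit_pair_lmm(g, value_col="iz", unit=int(layer))
            for layer, g in observations.groupby("layer")]


def per_bin_analysis(observations: pd.DataFrame) -> list[LmmResult]:
    """Fit the pair-type mixed model separately at each frequency bin.

    No multiple-comparison correction is applied; per-bin p-values are
    reported raw.
    """
    return [fit_pair_lmm(g, value_col="z", unit=float(fc))
            for fc, g in observations.groupby("bin_center")]
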
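"""End-to-end study pipeline: synergies -> coherence -> layers -> mixed model.

Convenience layer used by the analysis drivers, the tests, and the
acceptance script.  Every stage is a thin call into the corresponding
module, with seeding derived from a single integer so a whole study run is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coherence as coh
from . import layers as lay
from . import pairstats as ps
from . import synergies as syn
from .simulate import Dataset, ParticipantData

__all__ = ["ParticipantAnalysis", "StudyResult", "analyze_participant_synergies",
           "compute_trial_spectra", "run_study"]


@dataclass
class ParticipantAnalysis:
    participant_id: int
    samples: list[syn.ActivationSample]
    r2_curve: np.ndarray | None
    selection: syn.SelectionResult | None
    synergy_model: syn.SynergyModel
    classifications: list[ps.PairClassification]
    spectra_by_trial: dict[int, list[coh.CoherenceSpectrum]]
    trial_meta: dict[int, tuple[int, int]]
    coherence_matrix: lay.CoherenceMatrix
    layer_model: lay.LayerModel | None = None


@dataclass
class StudyResult:
    participants: list[ParticipantAnalysis]
    selection_curve: lay.LayerSelectionCurve | None
    k_layers: int
    observations: pd.DataFrame
    per_layer: list[ps.LmmResult] = field(default_factory=list)


def analyze_participant_synergies(part: ParticipantData, *,
                                  n_synergies: int | None = None,
                                  restarts: int = 10,
                                  rng: np.random.Generator | None = None,
                                  n_max: int | None = None):
    """Condition trials, extract synergies, and select N if not fixed.

    Returns ``(samples, r2_curve_or_None, selection_or_None, model)``.
    """
    mvc = part.ground_truth.mvc
    samples = [syn.condition_emg(t, mvc) for t in part.trials]
    X = syn.activation_matrix(samples)
    if n_synergies is not None:
        model = syn.extract_synergies(X, n_synergies, restarts=restarts, rng=rng)
        return samples, None, None, model
    curve, models = syn.r2_curve(X, n_max=n_max, restarts=restarts, rng=rng)
    dirs = np.stack([s.direction for s in samples])
    fits = {}
    for n, m in models.items():
        fits[n] = [syn.fit_cosine_tuning(m.C[s_i], dirs) for s_i in range(n)]
    sel = syn.select_num_synergies(curve, fits)
    return samples, curve, sel, models[sel.n_selected]


def compute_trial_spectra(part: ParticipantData, cfg: coh.SpectralConfig,
                          seed_seq: np.random.SeedSequence
                          ) -> dict[int, list[coh.CoherenceSpectrum]]:
    """Thresholded coherence spectra for every trial of one participant."""
    out = {}
    seeds = seed_seq.spawn(len(part.trials))
    for trial, s in zip(part.trials, seeds):
        rng = np.random.default_rng(s)
        out[trial.trial_id] = coh.pair_coherence_for_trial(trial, config=cfg,
                                                          rng=rng)
    return out


def run_study(dataset: Dataset, *, spectral: coh.SpectralConfig | None = None,
              n_synergies: int | None = None, k_layers: int | None = None,
              k_max: int = 15, restarts: int = 10, seed: int = 0,
              use_true_weights: bool = False) -> StudyResult:
    """Run the full analysis over a dataset and fit the per-layer model.

    ``n_synergies``/``k_layers`` fix the synergy and layer counts; when None
    they are selected by the R^2 / across-participant-stability criteria.
    ``use_true_weights`` classifies pairs from the generator's weight matrix
    instead of the recovered one (a ground-truth control).
    """
    cfg = spectral or coh.SpectralConfig(fs=dataset.config.fs)
    root = np.random.SeedSequence(seed)
    analyses = []
    for part, part_seq in zip(dataset.participants, root.spawn(len(dataset.participants))):
        syn_seq, coh_seq = part_seq.spawn(2)
        samples, curve, sel, model = analyze_participant_synergies(
            part, n_synergies=n_synergies, restarts=restarts,
            rng=np.random.default_rng(syn_seq))
        W = part.ground_truth.W_true if use_true_weights else model.W
        classes = ps.classify_pairs(ps.normalize_weights(W))
        spectra = compute_trial_spectra(part, cfg, coh_seq)
        meta = {t.trial_id: (t.direction_index, t.repetition) for t in part.trials}
        cmat = lay.build_coherence_matrix(
            [s for specs in spectra.values() for s in specs],
            participant_id=part.participant_id)
        analyses.append(ParticipantAnalysis(
            participant_id=part.participant_id, samples=samples,
            r2_curve=curve, selection=sel, synergy_model=model,
            classifications=classes, spectra_by_trial=spectra,
            trial_meta=meta, coherence_matrix=cmat))

    layer_seq = root.spawn(1)[0]
    curve = None
    if k_layers is None:
        models_per_k: dict[int, list[lay.LayerModel]] = {}
        for k in range(1, k_max + 1):
            k_models = []
            for a, s in zip(analyses, layer_seq.spawn(len(analyses))):
                k_models.append(lay.decompose_layers(
                    a.coherence_matrix, k, restarts=restarts,
                    rng=np.random.default_rng(s)))
            models_per_k[k] = k_models
        curve = lay.select_num_layers(models_per_k)
        k_layers = curve.selected_k
        for a, m in zip(analyses, models_per_k[k_layers]):
            a.layer_model = m
    else:
        for a, s in zip(analyses, layer_seq.spawn(len(analyses))):
            a.layer_model = lay.decompose_layers(
                a.coherence_matrix, k_layers, restarts=restarts,
                rng=np.random.default_rng(s))

    obs = pd.concat([
        ps.assemble_observations(a.classifications, a.spectra_by_trial,
                                 a.layer_model.bounds, a.trial_meta,
                                 a.participant_id)
        for a in analyses
    ], ignore_index=True)
    per_layer = ps.per_layer_analysis(obs) if not obs.empty else []
    return StudyResult(participants=analyses, selection_curve=curve,
                       k_layers=k_layers, observations=obs, per_layer=per_layer)
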
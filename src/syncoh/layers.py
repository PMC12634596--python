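"""Data-driven frequency layers from NMF of concatenated coherence spectra.

The thresholded Z spectra of all trials and muscle pairs of one participant
are concatenated into an f x (t*m) matrix and factorized by NMF for each
candidate layer count k.  The layer count is selected at the first local
minimum of the across-participant standard deviation of the aligned
coherence patterns W_c, and each layer's frequency bounds are the interval
over which it dominates the other layers, so the bounds of a participant
partition the 1-60 Hz range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nmf import nmf_best_of_restarts
from .coherence import CoherenceSpectrum

__all__ = [
    "CoherenceMatrix",
    "LayerModel",
    "LayerSelectionCurve",
    "build_coherence_matrix",
    "decompose_layers",
    "select_num_layers",
    "select_k_from_curve",
    "layer_bounds",
    "layer_average_iz",
]


@dataclass
class CoherenceMatrix:
    values: np.ndarray              # (f bins, trials * pairs), nonnegative
    bin_centers: np.ndarray
    columns: list[tuple[int, tuple[int, int]]]   # (trial_id, pair)
    participant_id: int = -1


@dataclass
class LayerModel:
    W: np.ndarray                   # (f, k) coherence patterns, unit-max columns
    C: np.ndarray                   # (k, trials * pairs) edge weights
    k: int
    bin_centers: np.ndarray
    bounds: list[tuple[float, float]] = field(default_factory=list)
    #: surviving layer index per original column after degeneracy merging
    participant_id: int = -1
    reconstruction_error: float = np.nan


@dataclass
class LayerSelectionCurve:
    k_values: np.ndarray
    aggregate_sd: np.ndarray
    selected_k: int


def build_coherence_matrix(spectra: list[CoherenceSpectrum],
                           participant_id: int = -1) -> CoherenceMatrix:
    """Concatenate thresholded Z spectra into the f x (t*m) NMF input.

    Columns are ordered by (trial, pair); all-zero columns from pairs that
    were not co-active are retained.
    """
    if not spectra:
        raise ValueError("no coherence spectra to concatenate")
    centers = spectra[0].bin_centers
    for s in spectra:
        if s.bin_centers.shape != centers.shape or \
                not np.allclose(s.bin_centers, centers):
            raise ValueError("coherence spectra use different bin grids")
    order = sorted(range(len(spectra)),
                   key=lambda i: (spectra[i].trial_id, spectra[i].pair))
    values = np.column_stack([spectra[i].Z for i in order])
    columns = [(spectra[i].trial_id, spectra[i].pair) for i in order]
    return CoherenceMatrix(values=values, bin_centers=centers,
                           columns=columns, participant_id=participant_id)


def decompose_layers(matrix: CoherenceMatrix, k: int, restarts: int = 10,
                     rng: np.random.Generator | None = None) -> LayerModel:
    """Best-of-restarts NMF of the coherence matrix at layer count k.

    W_c columns are rescaled to unit maximum with the compensating rescale
    applied to the C_c rows, and layers are ordered by spectral center of
    mass (the across-participant alignment key).
    """
    X = matrix.values
    if not np.any(X > 0):
        raise ValueError("coherence matrix is identically zero")
    W, C, _, _ = nmf_best_of_restarts(X, k, restarts=restarts, rng=rng)
    scale = W.max(axis=0)
    nz = scale > 0
    W = W.copy(); C = C.copy()
    W[:, nz] /= scale[nz]
    C[nz, :] *= scale[nz, None]
    order = np.argsort(_centers_of_mass(W, matrix.bin_centers), kind="stable")
    W, C = W[:, order], C[order, :]
    err = float(np.linalg.norm(X - W @ C))
    model = LayerModel(W=W, C=C, k=k, bin_centers=matrix.bin_centers,
                       participant_id=matrix.participant_id,
                       reconstruction_error=err)
    model.bounds = layer_bounds(model)
    return model


def _centers_of_mass(W: np.ndarray, centers: np.ndarray) -> np.ndarray:
    mass = W.sum(axis=0)
    com = np.full(W.shape[1], np.inf)
    nz = mass > 0
    com[nz] = (centers @ W[:, nz]) / mass[nz]
    return com


def select_num_layers(models_per_k: dict[int, list[LayerModel]]) -> LayerSelectionCurve:
    """Across-participant stability criterion for the layer count.

    For each k the aligned, unit-max W_c patterns of all participants are
    compared bin-by-bin; the aggregate is the mean over layers and bins of
    the across-participant standard deviation.  The selected k minimizes
    that curve — the layer count whose coherence patterns are most
    consistent across individuals — with ties resolved toward the smallest
    k (shallow secondary dips at intermediate k, where bands merge in a
    participant-independent way, are not treated as meaningful minima).
    """
    ks = np.array(sorted(models_per_k))
    sds = np.empty(len(ks))
    for idx, k in enumerate(ks):
        models = models_per_k[k]
        if len(models) < 2:
            raise ValueError("layer-count selection needs at least 2 participants")
        stack = np.stack([m.W for m in models])     # (participants, f, k)
        sds[idx] = stack.std(axis=0, ddof=0).mean()
    selected = select_k_from_curve(ks, sds)
    return LayerSelectionCurve(k_values=ks, aggregate_sd=sds, selected_k=selected)


def select_k_from_curve(ks: np.ndarray, sds: np.ndarray) -> int:
    """Layer count at the minimum of the SD-vs-k curve (smallest k on ties)."""
    ks = np.asarray(ks)
    sds = np.asarray(sds, float)
    return int(ks[np.argmin(sds)])


def layer_bounds(model: LayerModel) -> list[tuple[float, float]]:
    """Dominance intervals of each layer, tiling the full bin range.

    Each bin is assigned to the layer with the largest (unit-max) W_c value
    there; isolated outlier bins are reassigned to their surrounding layer
    and non-contiguous layers are reduced to their heaviest run.  Interior
    bounds fall on bin-edge frequencies; the outer bounds are the limits of
    the analyzed range.  A layer left without bins is merged into its
    neighbor (with a warning) and reported with an empty interval excluded
    from the output.
    """
    W = model.W
    centers = model.bin_centers
    f, k = W.shape
    if k < 1:
        raise ValueError("model has no layers")
    if k == 1:
        return [(float(min(1.0, centers[0])), float(max(60.0, centers[-1])))]
    assign = np.argmax(W, axis=1)
    # isolated outliers: a single bin differing from identical neighbors
    for i in range(1, f - 1):
        if assign[i - 1] == assign[i + 1] != assign[i]:
            assign[i] = assign[i - 1]
    # enforce contiguity: keep each layer's heaviest run, absorb the rest
    for _ in range(f):
        runs: dict[int, list[tuple[int, int]]] = {}
        start = 0
        for i in range(1, f + 1):
            if i == f or assign[i] != assign[start]:
                runs.setdefault(int(assign[start]), []).append((start, i))
                start = i
        multi = {lab: rs for lab, rs in runs.items() if len(rs) > 1}
        if not multi:
            break
        lab, rs = next(iter(multi.items()))
        weights = [W[a:b, lab].sum() for a, b in rs]
        for (a, b), w in zip(rs, weights):
            if w < max(weights) or (a, b) != rs[int(np.argmax(weights))]:
                nb_lab = assign[a - 1] if a > 0 else assign[b]
                assign[a:b] = nb_lab
    present = sorted(set(assign.tolist()))
    if len(present) < k:
        warnings.warn(f"{k - len(present)} degenerate layer(s) merged into neighbors")
    lo_edge = float(min(1.0, centers[0]))
    hi_edge = float(max(60.0, centers[-1]))
    bounds = []
    for lab in present:
        idx = np.flatnonzero(assign == lab)
        a, b = idx[0], idx[-1]
        f1 = lo_edge if a == 0 else float(0.5 * (centers[a - 1] + centers[a]))
        f2 = hi_edge if b == f - 1 else float(0.5 * (centers[b] + centers[b + 1]))
        bounds.append((f1, f2))
    bounds.sort()
    return bounds


def layer_average_iz(Z: np.ndarray, bounds: tuple[float, float],
                     bin_centers: np.ndarray) -> float:
    """Mean Fisher-normalized coherence over a layer's frequency interval.

    Discretization of I_Z(f1, f2) = (1/(f2-f1)) * integral of Z over the
    interval: the arithmetic mean of the bins whose centers fall in it.
    """
    f1, f2 = bounds
    if not f1 < f2:
        raise ValueError("layer bounds must satisfy f1 < f2")
    sel = (bin_centers >= f1) & (bin_centers <= f2)
    if not np.any(sel):
        raise ValueError(f"no bin center inside layer bounds ({f1}, {f2}) Hz")
    return float(np.asarray(Z, float)[sel].mean())
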
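"""EMG conditioning, muscle-synergy extraction, and synergy-count selection.

Conditioning follows the standard envelope pipeline: full-wave rectification,
2nd-order Butterworth low-pass at 5 Hz, resampling to 100 Hz, rest-baseline
subtraction, MVC normalization, and averaging over the hold phase.  Synergies
are extracted by best-of-restarts NMF from the muscles x trials activation
matrix, and the number of synergies N is chosen by three criteria:

(i)   the smallest N whose R^2 exceeds 0.9;
(ii)  the first N at which the straight-line fit to the R^2 vs N curve from N
      to the number of muscles has mean squared error below 1e-4;
(iii) on disagreement, the candidate whose synergy preferred directions
      (cosine directional-tuning maxima) are more uniformly distributed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._nmf import nmf_best_of_restarts
from .simulate import TrialRecording

__all__ = [
    "ActivationSample",
    "SynergyModel",
    "TuningFit",
    "SelectionResult",
    "condition_emg",
    "activation_matrix",
    "extract_synergies",
    "fit_cosine_tuning",
    "preferred_direction_uniformity",
    "select_num_synergies",
]

R2_THRESHOLD = 0.9
SLOPE_MSE_THRESHOLD = 1e-4
ENVELOPE_CUTOFF_HZ = 5.0
RESAMPLE_HZ = 100.0


@dataclass
class ActivationSample:
    """Hold-phase-averaged, MVC-normalized muscle activation of one trial."""

    values: np.ndarray          # (muscles,), nonnegative
    direction: np.ndarray
    repetition: int
    participant_id: int
    trial_id: int
    direction_index: int = -1


@dataclass
class SynergyModel:
    W: np.ndarray               # (muscles, N) nonnegative weights
    C: np.ndarray               # (N, trials) nonnegative coefficients
    r2: float
    n: int
    restart_r2s: list[float] = field(default_factory=list)


@dataclass
class TuningFit:
    """Least-squares cosine fit c = baseline + gain * <d, p> of one synergy."""

    preferred: np.ndarray       # 3-D unit vector
    baseline: float
    gain: float
    r2: float
    tuned: bool


@dataclass
class SelectionResult:
    n_selected: int
    n_r2: int | None            # criterion (i)
    n_slope: int                # criterion (ii)
    uniformity: dict[int, float] = field(default_factory=dict)


def _envelope(emg: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Rectify, low-pass (2nd-order Butterworth, 5 Hz), resample to 100 Hz."""
    sos = signal.butter(2, ENVELOPE_CUTOFF_HZ, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(emg), axis=0)
    down = int(round(fs / RESAMPLE_HZ))
    if down > 1:
        env = signal.resample_poly(env, up=1, down=down, axis=0)
    return env, fs / down if down > 1 else fs


def condition_emg(trial: TrialRecording, mvc: np.ndarray) -> ActivationSample:
    """Reduce one trial to a nonnegative MVC-normalized activation vector.

    The rest-phase mean envelope is subtracted per muscle before MVC
    normalization; negative baseline-subtracted values are clipped at zero
    (NMF requires nonnegative input) and the hold-phase samples are averaged.
    """
    mvc = np.asarray(mvc, float)
    bad = np.flatnonzero(mvc <= 0)
    if bad.size:
        raise ValueError(f"non-positive MVC for muscle index {bad[0]}")
    env, fs_out = _envelope(trial.emg, trial.fs)
    a, b, c = trial.phase_bounds
    scale = fs_out / trial.fs
    ra, rb, rc = (int(round(x * scale)) for x in (a, b, c))
    rest = env[ra:rb]
    hold = env[rb:rc]
    if rest.size == 0 or hold.size == 0:
        raise ValueError("trial is missing a rest or hold phase")
    activ = (hold - rest.mean(axis=0)) / mvc
    values = np.clip(activ, 0.0, None).mean(axis=0)
    return ActivationSample(
        values=values, direction=trial.direction, repetition=trial.repetition,
        participant_id=trial.participant_id, trial_id=trial.trial_id,
        direction_index=trial.direction_index)


def activation_matrix(samples: list[ActivationSample]) -> np.ndarray:
    """Stack activation vectors into the (muscles, trials) NMF input."""
    if not samples:
        raise ValueError("no activation samples")
    return np.column_stack([s.values for s in samples])


def extract_synergies(samples: np.ndarray, n: int, restarts: int = 10,
                      rng: np.random.Generator | None = None) -> SynergyModel:
    """Best-of-restarts NMF of the (muscles, trials) activation matrix."""
    W, C, r2, log = nmf_best_of_restarts(np.asarray(samples, float), n,
                                         restarts=restarts, rng=rng)
    return SynergyModel(W=W, C=C, r2=r2, n=n, restart_r2s=log)


def fit_cosine_tuning(activations: np.ndarray, directions: np.ndarray) -> TuningFit:
    """Fit ``c = baseline + gain * <d, p>`` by linear least squares.

    The model is linear in ``v = gain * p``; the preferred direction is the
    unit vector along the fitted ``v``.
    """
    c = np.asarray(activations, float)
    D = np.atleast_2d(np.asarray(directions, float))
    if len(np.unique(np.round(D, 9), axis=0)) < 4:
        raise ValueError("need at least 4 distinct directions for a cosine fit")
    if not np.any(c > 0):
        return TuningFit(preferred=np.array([1.0, 0.0, 0.0]), baseline=0.0,
                         gain=0.0, r2=0.0, tuned=False)
    A = np.column_stack([np.ones(len(D)), D])
    coef, *_ = np.linalg.lstsq(A, c, rcond=None)
    baseline, v = coef[0], coef[1:]
    gain = float(np.linalg.norm(v))
    resid = c - A @ coef
    sst = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 0.0
    tuned = gain > 1e-8 * max(1.0, float(np.abs(c).max()))
    pref = v / gain if tuned else np.array([1.0, 0.0, 0.0])
    return TuningFit(preferred=pref, baseline=float(baseline), gain=gain,
                     r2=r2, tuned=tuned)


def preferred_direction_uniformity(fits: list[TuningFit]) -> float:
    """Resultant length of the tuned preferred directions (0 = uniform)."""
    vs = [f.preferred for f in fits if f.tuned]
    if not vs:
        return np.inf
    return float(np.linalg.norm(np.sum(vs, axis=0)) / len(vs))


def _criterion_slope(r2: np.ndarray) -> int:
    """First N whose linear fit of R^2 over N..muscles has MSE < 1e-4."""
    m = len(r2)
    ns = np.arange(1, m + 1, dtype=float)
    for i in range(m):
        x, y = ns[i:], r2[i:]
        if len(x) == 1:
            return i + 1
        coef = np.polyfit(x, y, 1)
        mse = float(np.mean((y - np.polyval(coef, x)) ** 2))
        if mse < SLOPE_MSE_THRESHOLD:
            return i + 1
    return m


def select_num_synergies(r2_curve: np.ndarray,
                         tuning_fits: dict[int, list[TuningFit]] | None = None
                         ) -> SelectionResult:
    """Apply the three N-selection criteria to an R^2 vs N curve.

    ``r2_curve[i]`` is the best R^2 at N = i + 1.  The curve is made
    non-decreasing by a running maximum before the criteria are applied.
    ``tuning_fits`` maps candidate N to the per-synergy cosine-tuning fits of
    that model; it is only consulted when criteria (i) and (ii) disagree.
    """
    r2 = np.maximum.accumulate(np.asarray(r2_curve, float))
    above = np.flatnonzero(r2 > R2_THRESHOLD)
    n_r2 = int(above[0]) + 1 if above.size else None
    n_slope = _criterion_slope(r2)
    if n_r2 is None:
        warnings.warn("R^2 never exceeds 0.9; falling back to the slope criterion")
        return SelectionResult(n_selected=n_slope, n_r2=None, n_slope=n_slope)
    if n_r2 == n_slope:
        return SelectionResult(n_selected=n_r2, n_r2=n_r2, n_slope=n_slope)
    uniformity: dict[int, float] = {}
    if tuning_fits is None:
        # no tie-break information: prefer the R^2 criterion
        return SelectionResult(n_selected=n_r2, n_r2=n_r2, n_slope=n_slope)
    for cand in (n_r2, n_slope):
        if cand not in tuning_fits:
            raise ValueError(f"tuning fits missing for candidate N={cand}")
        uniformity[cand] = preferred_direction_uniformity(tuning_fits[cand])
    n_sel = min((n_r2, n_slope), key=lambda n: (uniformity[n], n))
    return SelectionResult(n_selected=n_sel, n_r2=n_r2, n_slope=n_slope,
                           uniformity=uniformity)


def r2_curve(samples: np.ndarray, n_max: int | None = None, restarts: int = 10,
             rng: np.random.Generator | None = None
             ) -> tuple[np.ndarray, dict[int, SynergyModel]]:
    """Best R^2 for every candidate N = 1..n_max plus the fitted models."""
    X = np.asarray(samples, float)
    if n_max is None:
        n_max = X.shape[0]
    models = {}
    curve = np.empty(n_max)
    for n in range(1, n_max + 1):
        models[n] = extract_synergies(X, n, restarts=restarts, rng=rng)
        curve[n - 1] = models[n].r2
    return curve, models
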